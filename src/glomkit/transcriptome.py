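"""Bulk transcriptome stage: RPKM, DEG calling, composite, PCA, ORA.

The differential-expression filter follows the three-way rule used for
glomerular-enriched RNA-seq in longitudinal lean-vs-obese comparisons: a
gene is differentially expressed at an age when its obese-vs-lean fold
change exceeds 2, its mean expression across the two cohorts exceeds
0.5 RPKM, and its Benjamini-Hochberg adjusted p-value is below 0.05.
The per-gene test is a Welch two-sample t-test on log2(RPKM + pseudocount),
chosen for determinism and small-n robustness; the test statistic itself is
not part of the DEG definition, which is a filter on its p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .synthetic import CountMatrix

__all__ = [
    "rpkm",
    "bh_adjust",
    "call_degs",
    "podocyte_composite",
    "pca_expressed",
    "classify_longitudinal",
    "ora_fisher",
    "ORAResult",
]


def rpkm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    ``rpkm[g, s] = counts[g, s] · 1e9 / (length[g] · library_size[s])`` with
    the library size taken as the raw column sum.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("gene_lengths missing for some genes in the count matrix")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        raise ValueError("every sample needs a positive library size")
    return counts.mul(1e9).div(lengths, axis=0).div(libsize, axis=1)


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _cohort_masks(
    meta: pd.DataFrame, age_week: int
) -> tuple[np.ndarray, np.ndarray]:
    at_age = meta["age_week"] == age_week
    lean = (at_age & (meta["group"] == "lean")).to_numpy()
    obese = (at_age & (meta["group"] == "obese")).to_numpy()
    if lean.sum() < 2 or obese.sum() < 2:
        raise ValueError(f"need ≥ 2 samples per cohort at age {age_week}")
    return lean, obese


def call_degs(
    cm: CountMatrix,
    age_week: int,
    fc_thresh: float = 2.0,
    rpkm_thresh: float = 0.5,
    alpha: float = 0.05,
    pseudocount: float = 0.25,
) -> pd.DataFrame:
    """Obese-vs-lean differential expression at one age.

    Returns one row per gene: ``log2_fc`` (from cohort mean RPKM with the
    pseudocount), ``mean_rpkm`` (across the two cohorts), the Welch p-value
    on log2(RPKM + pseudocount), the BH-adjusted p across all genes (no
    expression prefilter before testing), and the ``is_deg`` flag
    ``(|log2_fc| > log2(fc_thresh)) ∧ (mean_rpkm > rpkm_thresh) ∧ (adj_p < alpha)``.
    """
    lean, obese = _cohort_masks(cm.sample_meta, age_week)
    expr = rpkm(cm.counts, cm.gene_lengths)
    x = expr.to_numpy()
    log_expr = np.log2(x + pseudocount)
    mean_lean = x[:, lean].mean(axis=1)
    mean_obese = x[:, obese].mean(axis=1)
    log2_fc = np.log2((mean_obese + pseudocount) / (mean_lean + pseudocount))
    mean_rpkm = x[:, lean | obese].mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(
            log_expr[:, obese], log_expr[:, lean], axis=1, equal_var=False
        )
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance-in-both degenerate genes
    adj = bh_adjust(p)
    is_deg = (
        (np.abs(log2_fc) > math.log2(fc_thresh))
        & (mean_rpkm > rpkm_thresh)
        & (adj < alpha)
    )
    return pd.DataFrame(
        {
            "gene_id": cm.counts.index,
            "age_week": age_week,
            "log2_fc": log2_fc,
            "mean_rpkm": mean_rpkm,
            "p_value": p,
            "adj_p": adj,
            "is_deg": is_deg,
        }
    ).set_index("gene_id")


def _geomean(values: np.ndarray, eps: float) -> float:
    return float(np.exp(np.mean(np.log(values + eps))))


def podocyte_composite(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    podocyte_genes=None,
    eps: float = 0.01,
    baseline_age: int | None = None,
) -> "CompositeResult":
    """Podocyte-gene composite: percent of age-matched lean expression.

    Per gene and cohort the summary is the geometric mean of RPKM (+ eps)
    across that cohort's samples.  ``per_gene`` normalizes each cohort to
    the youngest (baseline-age) lean cohort — the fold-change-vs-baseline
    view; ``composite_pct`` is, per age, 100 × the mean over genes of the
    obese/lean geometric-mean ratio, so 100 means no reduction.
    """
    from .synthetic import PODOCYTE_GENES

    genes = tuple(podocyte_genes) if podocyte_genes is not None else PODOCYTE_GENES
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"podocyte genes absent from the matrix: {missing}")
    ages = sorted(meta["age_week"].unique())
    base_age = baseline_age if baseline_age is not None else ages[0]
    sample_of = {s: i for i, s in enumerate(expr.columns)}

    def cohort(group: str, age: int) -> np.ndarray:
        ids = meta.loc[
            (meta["group"] == group) & (meta["age_week"] == age), "sample_id"
        ]
        return expr.loc[list(genes), list(ids)].to_numpy()

    per_gene_rows = []
    composite = {}
    base = cohort("lean", base_age)
    base_gm = np.exp(np.mean(np.log(base + eps), axis=1))
    if np.any(base_gm <= eps):
        raise ValueError("baseline lean geometric means must be positive")
    for age in ages:
        gm = {}
        for group in ("lean", "obese"):
            vals = cohort(group, age)
            gm[group] = np.exp(np.mean(np.log(vals + eps), axis=1))
            for gi, g in enumerate(genes):
                per_gene_rows.append(
                    {"gene_id": g, "group": group, "age_week": age,
                     "rel_to_baseline": gm[group][gi] / base_gm[gi]}
                )
        composite[age] = 100.0 * float(np.mean(gm["obese"] / gm["lean"]))
    return CompositeResult(
        per_gene=pd.DataFrame(per_gene_rows),
        composite_pct=pd.Series(composite, name="composite_pct"),
    )


@dataclass(frozen=True)
class CompositeResult:
    per_gene: pd.DataFrame  # gene_id, group, age_week, rel_to_baseline
    composite_pct: pd.Series  # indexed by age_week; 100 = no reduction


def pca_expressed(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    min_mean_rpkm: float = 0.5,
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of detectably expressed genes (overall mean RPKM > threshold).

    Expression is log2(x + 1)-transformed and gene-centered before the
    decomposition.  Returns per-sample scores (merged with metadata) and
    the per-component explained-variance fractions.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    keep = expr.mean(axis=1) > min_mean_rpkm
    sub = np.log2(expr.loc[keep].to_numpy() + 1.0)
    if sub.shape[0] < n_components:
        raise ValueError("fewer expressed genes than requested components")
    sub = sub - sub.mean(axis=1, keepdims=True)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(sub.T)
    out = pd.DataFrame(
        scores, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    out.insert(0, "sample_id", list(expr.columns))
    out = out.merge(meta, on="sample_id", how="left")
    return out, pca.explained_variance_ratio_


def classify_longitudinal(
    deg_by_age: dict[int, pd.DataFrame],
    sustained_fc: float = 3.0,
    mono_tol: float = 0.1,
) -> tuple[list[str], list[str]]:
    """Longitudinal DEG classes: early-sustained and progressive genes.

    * ``early_sustained``: significant (``is_deg``) at every age and
      |fold change| ≥ ``sustained_fc`` at every age.
    * ``progressive``: significant at every age from the second onward, with
      a log2 fold-change sequence monotone over those ages up to a
      tolerance of ``mono_tol`` log2 units per step (either direction).
    """
    ages = sorted(deg_by_age)
    if len(ages) < 2:
        raise ValueError("need DEG records at ≥ 2 ages")
    genes = deg_by_age[ages[0]].index
    for age in ages[1:]:
        if not deg_by_age[age].index.equals(genes):
            raise ValueError("DEG tables must share one gene index")
    sig = np.column_stack([deg_by_age[a]["is_deg"].to_numpy() for a in ages])
    lfc = np.column_stack([deg_by_age[a]["log2_fc"].to_numpy() for a in ages])
    log2_cut = math.log2(sustained_fc)

    sustained = sig.all(axis=1) & (np.abs(lfc) >= log2_cut).all(axis=1)

    later = sig[:, 1:].all(axis=1)
    d = np.diff(lfc[:, 1:], axis=1)
    up = (d >= -mono_tol).all(axis=1) & (lfc[:, -1] > lfc[:, 1])
    down = (d <= mono_tol).all(axis=1) & (lfc[:, -1] < lfc[:, 1])
    progressive = later & (up | down) & ~sustained
    return sorted(genes[sustained]), sorted(genes[progressive])


@dataclass(frozen=True)
class ORAResult:
    set_id: str
    overlap: int
    p_right: float
    direction_z: float


def ora_fisher(
    deg_genes: dict[str, int] | list[str],
    gene_set: set[str] | list[str],
    universe: set[str] | list[str],
    set_id: str = "",
) -> ORAResult:
    """Right-tailed Fisher (hypergeometric) over-representation test.

    ``deg_genes`` may carry direction signs (+1/-1 per gene); the direction
    score is ``(n_up − n_down)/sqrt(overlap)`` over the overlapping genes
    (0 when the overlap is empty) — a simplified signed concordance, not a
    pathway-activation algorithm.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    signs = (
        dict(deg_genes) if isinstance(deg_genes, dict)
        else {g: 0 for g in deg_genes}
    )
    if not set(signs) <= universe:
        raise ValueError("deg_genes must be a subset of the universe")
    gset = set(gene_set)
    if not gset <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    overlap_genes = gset & set(signs)
    k = len(overlap_genes)
    M, K, n = len(universe), len(gset), len(signs)
    p_right = float(stats.hypergeom.sf(k - 1, M, K, n))
    if k:
        n_up = sum(1 for g in overlap_genes if signs[g] > 0)
        n_down = sum(1 for g in overlap_genes if signs[g] < 0)
        z = (n_up - n_down) / math.sqrt(k)
    else:
        z = 0.0
    return ORAResult(set_id=set_id, overlap=k, p_right=min(p_right, 1.0), direction_z=z)
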