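"""Synthetic ground-truth data for every stage of the pipeline.

Three generators, each returning both the observable tables the pipeline
consumes and a truth table sufficient to score the downstream estimators:

* spherical glomeruli with interior spherical podocyte nuclei, sectioned by
  random planes (``make_glomerulus`` / ``section_profile`` /
  ``sample_profiles``) — ground truth for the stereology chain;
* a longitudinal two-group (lean/obese) endpoint study with a latent
  fibrosis-severity process driving a urinary collagen-III breakdown
  biomarker (uC3M), albuminuria and an ordinal 1-5 trichrome score
  (``simulate_study``);
* a negative-binomial bulk RNA-seq count matrix over the group × age design
  with programmed fold-change trajectories, including a podocyte-gene
  decline reaching ~75% reduction at the final age (``simulate_counts``).

All generators are bit-reproducible given their parameters and seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .stereology import GlomerularProfile

__all__ = [
    "Glomerulus3D",
    "SectionPlane",
    "StudyDesign",
    "FibrosisParams",
    "CountSimParams",
    "DegSpec",
    "PODOCYTE_GENES",
    "make_glomerulus",
    "section_profile",
    "sample_profiles",
    "profiles_to_frame",
    "default_study_design",
    "simulate_study",
    "default_count_params",
    "simulate_counts",
]

#: The five podocyte-specific transcripts tracked by the composite statistic:
#: Nephrin, Podocin, WT-1, Synaptopodin, GLEPP1.
PODOCYTE_GENES = ("Nphs1", "Nphs2", "Wt1", "Synpo", "Ptpro")

#: Default obese/lean expression ratio of the podocyte genes at each age.
PODOCYTE_DECLINE = {12: 1.0, 20: 0.9, 24: 0.8, 29: 0.7, 34: 0.35, 41: 0.25}

DEFAULT_AGES = (12, 20, 24, 29, 34, 41)


# ---------------------------------------------------------------------------
# 3D glomeruli and planar sections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Glomerulus3D:
    """A spherical glomerulus with ``n_pod`` interior spherical nuclei.

    ``nucleus_centers`` are 3D coordinates (μm) relative to the glomerulus
    center; every center satisfies |c| ≤ radius_glom − radius_nuc so nuclei
    are fully interior (no edge clipping).
    """

    radius_glom: float
    radius_nuc: float
    nucleus_centers: np.ndarray
    seed: int | None = None

    @property
    def n_pod(self) -> int:
        return len(self.nucleus_centers)


@dataclass(frozen=True)
class SectionPlane:
    """A section plane at signed offset ``offset_h`` from the center.

    By spherical symmetry a canonical orientation (normal along z) is
    equivalent to an isotropic uniform-random plane.
    """

    offset_h: float


def make_glomerulus(
    radius_glom: float, n_pod: int, radius_nuc: float, seed: int | None = None
) -> Glomerulus3D:
    """Place ``n_pod`` nucleus centers uniformly in the interior sphere.

    Centers are uniform in the sphere of radius ``radius_glom − radius_nuc``
    (isotropic direction, radius ∝ U^{1/3}); deterministic given ``seed``.
    """
    if radius_glom <= 0 or radius_nuc <= 0:
        raise ValueError("radii must be positive")
    if radius_nuc >= radius_glom:
        raise ValueError("nuclear radius must be smaller than glomerular radius")
    if n_pod < 0:
        raise ValueError("n_pod must be non-negative")
    rng = np.random.default_rng(seed)
    if n_pod == 0:
        centers = np.empty((0, 3))
    else:
        v = rng.normal(size=(n_pod, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = (radius_glom - radius_nuc) * rng.random(n_pod) ** (1.0 / 3.0)
        centers = v * r[:, None]
    return Glomerulus3D(radius_glom, radius_nuc, centers, seed)


def section_profile(
    glom: Glomerulus3D, plane: SectionPlane
) -> GlomerularProfile | None:
    """Intersect a glomerulus with a plane; ``None`` for a missing profile.

    The tuft profile is the disc of area π(R² − h²).  A nucleus at height
    z_i is counted iff |h − z_i| < radius_nuc (its section is non-empty) and
    contributes π(ρ² − (h − z_i)²) of stained area; nuclear profile overlap
    is ignored (a documented low-volume-fraction approximation).
    """
    h, R, rho = plane.offset_h, glom.radius_glom, glom.radius_nuc
    if abs(h) >= R:
        return None
    tuft_area = math.pi * (R**2 - h**2)
    if glom.n_pod:
        dz = glom.nucleus_centers[:, 2] - h
        hit = np.abs(dz) < rho
        n = int(hit.sum())
        stain = float(np.pi * np.sum(rho**2 - dz[hit] ** 2))
    else:
        n, stain = 0, 0.0
    # stained area cannot exceed the tuft disc (only reachable in contrived
    # high-density configurations because overlap is ignored)
    stain = min(stain, tuft_area)
    if n == 0:
        stain = 0.0
    return GlomerularProfile(tuft_area=tuft_area, n_wt1=n, wt1_stain_area=stain)


def sample_profiles(
    gloms: Sequence[Glomerulus3D],
    sections_per_glom: int,
    min_rel_area: float = 0.0,
    seed: int | None = None,
) -> tuple[list[GlomerularProfile], int]:
    """Random uniform sections through each glomerulus.

    Offsets are uniform in (−R, R) per glomerulus.  Profiles whose tuft area
    falls below ``min_rel_area · πR²`` are dropped (not resampled); the
    dropped count is returned and a warning is raised if more than half of
    all profiles were dropped.
    """
    if not 0 <= min_rel_area < 1:
        raise ValueError("min_rel_area must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    profiles: list[GlomerularProfile] = []
    dropped = 0
    for gi, glom in enumerate(gloms):
        R = glom.radius_glom
        offsets = rng.uniform(-R, R, size=sections_per_glom)
        for si, h in enumerate(offsets):
            prof = section_profile(glom, SectionPlane(h))
            if prof is None or prof.tuft_area < min_rel_area * math.pi * R**2:
                dropped += 1
                continue
            profiles.append(
                replace(prof, glom_id=f"g{gi:04d}", section_id=f"s{si:03d}")
            )
    total = len(gloms) * sections_per_glom
    if total and dropped > 0.5 * total:
        warnings.warn(
            f"{dropped}/{total} profiles dropped by min_rel_area={min_rel_area}",
            stacklevel=2,
        )
    return profiles, dropped


def profiles_to_frame(profiles: Sequence[GlomerularProfile]) -> pd.DataFrame:
    """Profile list → the canonical profiles table."""
    return pd.DataFrame(
        {
            "glom_id": [p.glom_id for p in profiles],
            "section_id": [p.section_id for p in profiles],
            "tuft_area_um2": [p.tuft_area for p in profiles],
            "n_wt1": [p.n_wt1 for p in profiles],
            "wt1_area_um2": [p.wt1_stain_area for p in profiles],
            "colIV_area_um2": [p.colIV_area for p in profiles],
            "pas_area_um2": [p.pas_area for p in profiles],
        }
    )


# ---------------------------------------------------------------------------
# Longitudinal endpoint study with a latent fibrosis process
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FibrosisParams:
    """Latent fibrosis severity and its couplings to the observables.

    Per animal, severity ``s = trajectory[group][age] + N(0, severity_sd²)``;
    uC3M (ng/mL) and microalbumin (μg/dL) are linear in s with Gaussian noise
    and floored at 0; the trichrome score is ``1 + #{thresholds < s}``.
    """

    severity_mean: dict[str, dict[int, float]]
    severity_sd: float = 0.25
    uc3m_intercept: float = 20.0
    uc3m_slope: float = 30.0
    uc3m_noise_sd: float = 4.0
    albumin_intercept: float = 150.0
    albumin_slope: float = 900.0
    albumin_noise_sd: float = 60.0
    trichrome_thresholds: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)

    def __post_init__(self) -> None:
        if self.severity_sd < 0 or self.uc3m_noise_sd < 0 or self.albumin_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if list(self.trichrome_thresholds) != sorted(self.trichrome_thresholds):
            raise ValueError("trichrome thresholds must be increasing")


@dataclass(frozen=True)
class StudyDesign:
    """Two-group (lean/obese) terminal-cohort design over six ages."""

    groups: tuple[str, str] = ("lean", "obese")
    ages_weeks: tuple[int, ...] = DEFAULT_AGES
    n_per_cohort: int = 5
    endpoint_params: dict[str, dict[str, dict[int, tuple[float, float]]]] = field(
        default_factory=dict
    )  # analyte -> group -> age -> (log_mean, log_sd)
    fibrosis_params: FibrosisParams | None = None
    creatinine_log_mean: float = math.log(60.0)  # urine creatinine, mg/dL
    creatinine_log_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.ages_weeks) != sorted(set(self.ages_weeks)):
            raise ValueError("ages must be strictly increasing")
        if self.n_per_cohort < 2:
            raise ValueError("need at least 2 animals per cohort")
        for analyte, per_group in self.endpoint_params.items():
            for group, per_age in per_group.items():
                for age, (_, log_sd) in per_age.items():
                    if log_sd <= 0:
                        raise ValueError(
                            f"log-sd must be positive ({analyte}/{group}/{age})"
                        )


def _traj(lean: Sequence[float], obese: Sequence[float]) -> dict:
    return {
        "lean": dict(zip(DEFAULT_AGES, lean)),
        "obese": dict(zip(DEFAULT_AGES, obese)),
    }


def default_study_design(seed: int = 0) -> StudyDesign:
    """The default study: 5 animals/cohort, ages 12-41 weeks.

    Obese latent severity rises from 0.5 to 4.2 (crossing all four trichrome
    thresholds); lean severity stays low with a mild age drift.  Log-normal
    endpoint parameters give obese animals elevated BUN and tubular-injury
    markers (NGAL, Kim-1) that worsen with age.
    """
    fib = FibrosisParams(
        severity_mean=_traj(
            lean=(0.10, 0.18, 0.25, 0.35, 0.45, 0.55),
            obese=(0.50, 1.10, 1.70, 2.40, 3.30, 4.20),
        )
    )
    endpoint = {
        "BUN": {
            "lean": {a: (math.log(m), 0.10) for a, m in zip(DEFAULT_AGES, (16, 16, 17, 17, 18, 18))},
            "obese": {a: (math.log(m), 0.15) for a, m in zip(DEFAULT_AGES, (22, 26, 30, 36, 48, 60))},
        },
        "NGAL": {
            "lean": {a: (math.log(m), 0.20) for a, m in zip(DEFAULT_AGES, (8, 8, 9, 9, 10, 10))},
            "obese": {a: (math.log(m), 0.25) for a, m in zip(DEFAULT_AGES, (15, 25, 40, 60, 90, 120))},
        },
        "Kim-1": {
            "lean": {a: (math.log(m), 0.20) for a, m in zip(DEFAULT_AGES, (0.5, 0.5, 0.6, 0.6, 0.7, 0.7))},
            "obese": {a: (math.log(m), 0.25) for a, m in zip(DEFAULT_AGES, (1.0, 1.8, 2.8, 4.0, 6.0, 8.0))},
        },
    }
    return StudyDesign(endpoint_params=endpoint, fibrosis_params=fib, seed=seed)


_UNITS = {
    "BUN": "mg/dL",
    "NGAL": "ng/mL",
    "Kim-1": "ng/mL",
    "uC3M": "ng/mL",
    "microalbumin": "ug/dL",
}


def simulate_study(design: StudyDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the longitudinal endpoint study.

    Returns ``(endpoints, truth)``: a long-format endpoint table
    (animal_id, group, age_week, analyte, value, units, urine_creatinine)
    and a per-animal truth table carrying the latent severity and the
    trichrome score for estimator-recovery tests.
    """
    fib = design.fibrosis_params
    rng = np.random.default_rng(design.seed)
    endpoint_rows: list[dict] = []
    truth_rows: list[dict] = []
    for group in design.groups:
        for age in design.ages_weeks:
            for i in range(design.n_per_cohort):
                animal = f"{group[0].upper()}{age:02d}-{i + 1:02d}"
                creat = float(
                    np.exp(rng.normal(design.creatinine_log_mean, design.creatinine_log_sd))
                )
                row_common = {"animal_id": animal, "group": group, "age_week": age}
                for analyte, per_group in design.endpoint_params.items():
                    log_mean, log_sd = per_group[group][age]
                    value = float(np.exp(rng.normal(log_mean, log_sd)))
                    endpoint_rows.append(
                        {**row_common, "analyte": analyte, "value": value,
                         "units": _UNITS.get(analyte, "au"), "urine_creatinine": creat}
                    )
                if fib is not None:
                    s = fib.severity_mean[group][age] + rng.normal(0, fib.severity_sd)
                    uc3m = max(
                        0.0,
                        fib.uc3m_intercept + fib.uc3m_slope * s
                        + rng.normal(0, fib.uc3m_noise_sd),
                    )
                    alb = max(
                        0.0,
                        fib.albumin_intercept + fib.albumin_slope * s
                        + rng.normal(0, fib.albumin_noise_sd),
                    )
                    score = 1 + int(np.sum(np.asarray(fib.trichrome_thresholds) < s))
                    for analyte, value in (("uC3M", uc3m), ("microalbumin", alb)):
                        endpoint_rows.append(
                            {**row_common, "analyte": analyte, "value": value,
                             "units": _UNITS[analyte], "urine_creatinine": creat}
                        )
                    truth_rows.append(
                        {**row_common, "severity": float(s), "trichrome_score": score}
                    )
    return pd.DataFrame(endpoint_rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Negative-binomial count matrix with programmed differential expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DegSpec:
    """A block of genes sharing one obese-vs-lean log2 fold-change trajectory.

    ``baseline_boost`` multiplies the block's baseline abundance weights so a
    scenario can place its programmed genes in a chosen expression range.
    """

    label: str
    n_genes: int
    log2fc_by_age: dict[int, float]
    baseline_boost: float = 1.0


@dataclass(frozen=True)
class CountSimParams:
    """Parameters of the bulk RNA-seq count simulator.

    Gene baseline abundances are log-normal (``baseline_log_sd`` on the
    natural-log scale), normalized to relative proportions; counts are
    negative-binomial with ``var = m + dispersion·m²``.  Obese samples get
    the programmed fold changes; lean samples are the baseline.  The five
    podocyte genes receive a boosted baseline (they are among the most
    abundant glomerular transcripts) and the programmed decline trajectory.
    """

    n_genes: int = 12000
    baseline_log_sd: float = 1.5
    dispersion: float = 0.1
    deg_spec: tuple[DegSpec, ...] = ()
    podocyte_genes: tuple[str, ...] = PODOCYTE_GENES
    podocyte_ratio_by_age: dict[int, float] = field(
        default_factory=lambda: dict(PODOCYTE_DECLINE)
    )
    podocyte_baseline_boost: float = 50.0
    gene_length_log_mean: float = math.log(2000.0)
    gene_length_log_sd: float = 0.5
    library_size: float = 20_000_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_genes < len(self.podocyte_genes) + sum(
            s.n_genes for s in self.deg_spec
        ):
            raise ValueError("n_genes too small for the programmed gene blocks")
        if self.library_size <= 0:
            raise ValueError("library size must be positive")


def default_count_params(seed: int = 0, n_genes: int = 12000) -> CountSimParams:
    """Default simulator: podocyte decline plus sustained/progressive blocks."""
    up_sustained = DegSpec(
        "early_sustained_up", 10, {a: 2.0 for a in DEFAULT_AGES}
    )
    progressive = DegSpec(
        "progressive_up", 10,
        dict(zip(DEFAULT_AGES, (0.2, 1.2, 1.8, 2.3, 3.0, 3.4))),
    )
    return CountSimParams(
        n_genes=n_genes, deg_spec=(up_sustained, progressive), seed=seed
    )


@dataclass(frozen=True)
class CountMatrix:
    """Gene × sample raw counts with gene lengths and sample metadata."""

    counts: pd.DataFrame  # genes × samples, integer
    gene_lengths: pd.Series  # bp, indexed by gene
    sample_meta: pd.DataFrame  # sample_id, group, age_week

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(
            pd.Index(self.sample_meta["sample_id"])
        ):
            raise ValueError("counts columns must match sample_meta sample_id order")
        if not self.counts.index.equals(self.gene_lengths.index):
            raise ValueError("counts index must match gene_lengths index")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("every sample must have a positive library size")


def simulate_counts(
    params: CountSimParams, design: StudyDesign
) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial counts over the design, plus the DEG truth table.

    The truth table lists every non-null gene with its programmed log2
    fold-change at every age (podocyte genes expressed as log2 of the
    obese/lean ratio).
    """
    rng = np.random.default_rng(params.seed)
    n_prog = sum(s.n_genes for s in params.deg_spec)
    n_pod = len(params.podocyte_genes)
    gene_ids = list(params.podocyte_genes) + [
        f"gene{idx:05d}" for idx in range(params.n_genes - n_pod)
    ]
    genes = pd.Index(gene_ids, name="gene_id")

    weights = np.exp(rng.normal(0.0, params.baseline_log_sd, size=params.n_genes))
    weights[:n_pod] *= params.podocyte_baseline_boost
    start = n_pod
    for spec in params.deg_spec:
        weights[start : start + spec.n_genes] *= spec.baseline_boost
        start += spec.n_genes
    props = weights / weights.sum()
    lengths = np.exp(
        rng.normal(params.gene_length_log_mean, params.gene_length_log_sd,
                   size=params.n_genes)
    ).round().clip(min=200)

    # programmed log2 fold change per gene per age (obese vs lean)
    log2fc = {age: np.zeros(params.n_genes) for age in design.ages_weeks}
    truth_rows: list[dict] = []
    for gi, gene in enumerate(params.podocyte_genes):
        for age in design.ages_weeks:
            ratio = params.podocyte_ratio_by_age[age]
            log2fc[age][gi] = math.log2(ratio)
            truth_rows.append(
                {"gene_id": gene, "label": "podocyte", "age_week": age,
                 "log2_fc_programmed": math.log2(ratio)}
            )
    cursor = n_pod
    for spec in params.deg_spec:
        for gi in range(cursor, cursor + spec.n_genes):
            for age in design.ages_weeks:
                if age not in spec.log2fc_by_age:
                    raise ValueError(
                        f"deg_spec '{spec.label}' missing age {age}"
                    )
                log2fc[age][gi] = spec.log2fc_by_age[age]
                truth_rows.append(
                    {"gene_id": gene_ids[gi], "label": spec.label, "age_week": age,
                     "log2_fc_programmed": spec.log2fc_by_age[age]}
                )
        cursor += spec.n_genes

    meta_rows = []
    cols = []
    for group in design.groups:
        for age in design.ages_weeks:
            for i in range(design.n_per_cohort):
                sid = f"{group[0].upper()}{age:02d}-{i + 1:02d}"
                meta_rows.append({"sample_id": sid, "group": group, "age_week": age})
                fc = 2.0 ** log2fc[age] if group == "obese" else 1.0
                mean = params.library_size * props * fc
                if np.any((mean == 0) & (log2fc[age] != 0) & (group == "obese")):
                    raise ValueError("NB mean 0 with a nonzero fold-change spec")
                shape = 1.0 / params.dispersion
                lam = rng.gamma(shape, mean / shape)
                cols.append(rng.poisson(lam))
    counts = pd.DataFrame(
        np.column_stack(cols), index=genes,
        columns=[m["sample_id"] for m in meta_rows],
    )
    cm = CountMatrix(
        counts=counts,
        gene_lengths=pd.Series(lengths, index=genes, name="length_bp"),
        sample_meta=pd.DataFrame(meta_rows),
    )
    assert n_prog + n_pod == cursor
    return cm, pd.DataFrame(truth_rows)
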