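"""Pipeline stages behind the CLI: simulate → analyze → consolidated report.

Each stage reads/writes TSV tables under one output directory and registers
its outputs in a JSON run manifest carrying the seed, a configuration hash
and per-file checksums, so a run is fully reproducible from (config, seed).
"""

from __future__ import annotations

import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import endpoints as ep
from . import morphometry as mo
from . import stereology as st
from . import synthetic as syn
from . import transcriptome as tx
from .config import config_hash
from .io import derive_seed, read_tsv, sha256_file, write_tsv

log = logging.getLogger("glomkit")

URINARY_ANALYTES = ("uC3M", "microalbumin", "NGAL", "Kim-1")


def _meta(cfg: dict, stage: str) -> dict:
    return {"stage": stage, "seed": cfg["seed"], "config": config_hash(cfg)[:12]}


def _register(out: Path, cfg: dict, files: list[Path]) -> None:
    manifest_path = out / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    manifest.setdefault("seed", cfg["seed"])
    manifest.setdefault("config_sha256", config_hash(cfg))
    manifest.setdefault("files", {})
    for f in files:
        manifest["files"][f.name] = sha256_file(f)
    manifest["created_utc"] = datetime.now(timezone.utc).isoformat()
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _require(out: Path, *names: str) -> None:
    missing = [n for n in names if not (out / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"missing input file(s) in {out}: {', '.join(missing)}"
        )


def stage_simulate(cfg: dict, out: Path) -> list[Path]:
    """Generate every downstream input with known ground truth."""
    sim = cfg["simulate"]
    design = syn.default_study_design(seed=derive_seed(cfg["seed"], "study"))
    design = syn.StudyDesign(
        groups=design.groups,
        ages_weeks=design.ages_weeks,
        n_per_cohort=sim["n_per_cohort"],
        endpoint_params=design.endpoint_params,
        fibrosis_params=design.fibrosis_params,
        seed=design.seed,
    )
    endpoints_df, truth = syn.simulate_study(design)
    log.info("simulated %d endpoint records for %d animals",
             len(endpoints_df), len(truth))

    rng = np.random.default_rng(derive_seed(cfg["seed"], "profiles"))
    frames = []
    for _, animal in truth.iterrows():
        gloms = [
            syn.make_glomerulus(
                radius_glom=float(
                    sim["radius_glom_um"]
                    * np.exp(rng.normal(0, sim["radius_glom_log_sd"]))
                ),
                n_pod=int(rng.poisson(sim["n_pod_mean"])),
                radius_nuc=sim["radius_nuc_um"],
                seed=int(rng.integers(2**31)),
            )
            for _ in range(sim["gloms_per_animal"])
        ]
        profiles, _ = syn.sample_profiles(
            gloms, sections_per_glom=1, min_rel_area=sim["min_rel_area"],
            seed=int(rng.integers(2**31)),
        )
        frame = syn.profiles_to_frame(profiles)
        sev = float(animal["severity"])
        for stain, base, slope in (
            ("colIV_area_um2", sim["colIV_base_frac"], sim["colIV_sev_slope"]),
            ("pas_area_um2", sim["pas_base_frac"], sim["pas_sev_slope"]),
        ):
            frac = np.clip(
                base + slope * sev
                + rng.normal(0, sim["stain_frac_noise_sd"], len(frame)),
                0.0, 0.6,
            )
            frame[stain] = frac * frame["tuft_area_um2"]
        frame.insert(0, "animal_id", animal["animal_id"])
        frame.insert(1, "group", animal["group"])
        frame.insert(2, "age_week", animal["age_week"])
        frames.append(frame)
    profiles_df = pd.concat(frames, ignore_index=True)

    params = syn.default_count_params(
        seed=derive_seed(cfg["seed"], "counts"), n_genes=sim["n_genes"]
    )
    cm, deg_truth = syn.simulate_counts(params, design)

    prog = deg_truth.loc[
        deg_truth["label"] == "early_sustained_up", "gene_id"
    ].unique()
    null_genes = [g for g in cm.counts.index if g.startswith("gene")]
    rng_sets = np.random.default_rng(derive_seed(cfg["seed"], "gene_sets"))
    gene_sets = pd.concat(
        [
            pd.DataFrame({"set_id": "programmed_up_block",
                          "gene_id": list(prog) + list(null_genes[:10])}),
            pd.DataFrame({"set_id": "random_background",
                          "gene_id": rng_sets.choice(null_genes, 25, replace=False)}),
        ],
        ignore_index=True,
    )

    meta = _meta(cfg, "simulate")
    files = [
        write_tsv(endpoints_df, out / "endpoints.tsv", meta),
        write_tsv(truth, out / "study_truth.tsv", meta),
        write_tsv(profiles_df, out / "profiles.tsv", meta),
        write_tsv(cm.counts.reset_index(), out / "counts.tsv", meta),
        write_tsv(cm.gene_lengths.reset_index(), out / "gene_lengths.tsv", meta),
        write_tsv(cm.sample_meta, out / "sample_meta.tsv", meta),
        write_tsv(deg_truth, out / "deg_truth.tsv", meta),
        write_tsv(gene_sets, out / "gene_sets.tsv", meta),
    ]
    return files


def _load_counts(out: Path) -> syn.CountMatrix:
    counts = read_tsv(out / "counts.tsv").set_index("gene_id")
    lengths = read_tsv(out / "gene_lengths.tsv").set_index("gene_id")["length_bp"]
    meta = read_tsv(out / "sample_meta.tsv")
    return syn.CountMatrix(counts=counts[meta["sample_id"]], gene_lengths=lengths,
                           sample_meta=meta)


def stage_stereology(cfg: dict, out: Path) -> list[Path]:
    _require(out, "profiles.tsv")
    coeffs = st.StereologyCoefficients(**cfg["stereology"])
    profiles = read_tsv(out / "profiles.tsv")
    per_animal, per_cohort = st.estimate_by_animal(profiles, coeffs)
    meta = _meta(cfg, "stereology")
    meta["density_units"] = "podocytes per 1e6 um^3"
    return [
        write_tsv(per_animal, out / "stereology_per_animal.tsv", meta),
        write_tsv(per_cohort, out / "stereology_per_cohort.tsv", meta),
    ]


def stage_morphometry(cfg: dict, out: Path) -> list[Path]:
    _require(out, "profiles.tsv", "study_truth.tsv")
    profiles = read_tsv(out / "profiles.tsv")
    truth = read_tsv(out / "study_truth.tsv")
    frames = []
    for stain, col in (("colIV", "colIV_area_um2"), ("pas", "pas_area_um2")):
        summ = mo.stain_summary(
            profiles.rename(columns={col: "stain_area",
                                     "tuft_area_um2": "tuft_area"}),
            grouping=["group", "age_week"],
        )
        summ.insert(0, "stain", stain)
        frames.append(summ)
    summary = pd.concat(frames, ignore_index=True)
    rho = mo.score_vs_severity(truth["trichrome_score"], truth["severity"])
    scores = truth[["animal_id", "group", "age_week", "trichrome_score"]].copy()
    meta = _meta(cfg, "morphometry")
    meta["trichrome_vs_severity_spearman"] = f"{rho:.4f}"
    return [
        write_tsv(summary, out / "morphometry_summary.tsv", meta),
        write_tsv(scores, out / "trichrome_scores.tsv", meta),
    ]


def stage_degs(cfg: dict, out: Path) -> list[Path]:
    _require(out, "counts.tsv", "gene_lengths.tsv", "sample_meta.tsv",
             "gene_sets.tsv")
    d = cfg["degs"]
    cm = _load_counts(out)
    ages = sorted(cm.sample_meta["age_week"].unique())
    deg_by_age = {
        age: tx.call_degs(cm, age, fc_thresh=d["fc_thresh"],
                          rpkm_thresh=d["rpkm_thresh"], alpha=d["alpha"],
                          pseudocount=d["pseudocount"])
        for age in ages
    }
    deg_all = pd.concat([df.reset_index() for df in deg_by_age.values()],
                        ignore_index=True)
    log.info("DEG counts by age: %s",
             {a: int(df["is_deg"].sum()) for a, df in deg_by_age.items()})

    expr = tx.rpkm(cm.counts, cm.gene_lengths)
    composite = tx.podocyte_composite(expr, cm.sample_meta)
    comp_df = composite.composite_pct.rename_axis("age_week").reset_index()
    scores, var_frac = tx.pca_expressed(expr, cm.sample_meta,
                                        min_mean_rpkm=d["rpkm_thresh"])
    sustained, progressive = tx.classify_longitudinal(
        deg_by_age, sustained_fc=d["sustained_fc"], mono_tol=d["mono_tol"]
    )
    classes = pd.concat(
        [
            pd.DataFrame({"class": "early_sustained", "gene_id": sustained}),
            pd.DataFrame({"class": "progressive", "gene_id": progressive}),
        ],
        ignore_index=True,
    )

    last = deg_by_age[ages[-1]]
    deg_signs = {
        g: int(np.sign(last.loc[g, "log2_fc"]))
        for g in last.index[last["is_deg"]]
    }
    universe = list(cm.counts.index)
    gene_sets = read_tsv(out / "gene_sets.tsv")
    ora_rows = []
    for set_id, sub in gene_sets.groupby("set_id"):
        res = tx.ora_fisher(deg_signs, set(sub["gene_id"]), universe, set_id)
        ora_rows.append(
            {"set_id": res.set_id, "overlap": res.overlap,
             "p_right": res.p_right, "direction_z": res.direction_z}
        )

    meta = _meta(cfg, "degs")
    meta["pca_variance_fractions"] = ",".join(f"{v:.4f}" for v in var_frac)
    return [
        write_tsv(deg_all, out / "degs_by_age.tsv", meta),
        write_tsv(comp_df, out / "podocyte_composite.tsv", meta),
        write_tsv(composite.per_gene, out / "podocyte_per_gene.tsv", meta),
        write_tsv(scores, out / "pca_scores.tsv", meta),
        write_tsv(classes, out / "longitudinal_classes.tsv", meta),
        write_tsv(pd.DataFrame(ora_rows), out / "ora_results.tsv", meta),
    ]


def stage_endpoints(cfg: dict, out: Path) -> list[Path]:
    _require(out, "endpoints.tsv", "study_truth.tsv")
    alpha = cfg["endpoints"]["alpha"]
    records = read_tsv(out / "endpoints.tsv")
    truth = read_tsv(out / "study_truth.tsv")

    urinary = records[records["analyte"].isin(URINARY_ANALYTES)]
    ratios = ep.normalize_to_creatinine(urinary)

    stats_rows = []
    for analyte, sub in records.groupby("analyte"):
        data = (
            ratios[ratios["analyte"] == analyte].rename(columns={"ratio": "y"})
            if analyte in URINARY_ANALYTES
            else sub.rename(columns={"value": "y"})
        )
        fam = ep.anova_tukey(data, value_col="y", alpha=alpha)
        fam.insert(0, "analyte", analyte)
        stats_rows.append(fam)
    stats_df = pd.concat(stats_rows, ignore_index=True)

    ages = sorted(records["age_week"].unique())
    raw_fc, headline = ep.group_fold_change(
        ratios[ratios["analyte"] == "microalbumin"], age_week=ages[-1]
    )

    wide = ratios.pivot_table(index=["animal_id", "group", "age_week"],
                              columns="analyte", values="ratio").reset_index()
    wide = wide.merge(truth, on=["animal_id", "group", "age_week"])
    corr_rows = []
    pairs = [("uC3M", "microalbumin"), ("uC3M", "trichrome_score")]
    profiles_path = out / "profiles.tsv"
    if profiles_path.exists():
        prof = read_tsv(profiles_path)
        col4 = (prof.groupby("animal_id")["colIV_area_um2"].mean()
                .rename("colIV_mean_area"))
        wide = wide.merge(col4, on="animal_id", how="left")
        pairs.append(("uC3M", "colIV_mean_area"))
    for x_name, y_name in pairs:
        res = ep.correlate(wide[x_name], wide[y_name], x_name, y_name)
        corr_rows.append(
            {"x": res.x_name, "y": res.y_name, "slope": res.slope,
             "intercept": res.intercept, "r_squared": res.r_squared, "n": res.n}
        )

    meta = _meta(cfg, "endpoints")
    meta["microalbumin_fold_change_last_age"] = f"{raw_fc:.2f} (headline {headline:.0f})"
    return [
        write_tsv(ratios, out / "endpoint_ratios.tsv", meta),
        write_tsv(stats_df, out / "endpoint_statistics.tsv", meta),
        write_tsv(pd.DataFrame(corr_rows), out / "endpoint_correlations.tsv", meta),
    ]


def stage_report(cfg: dict, out: Path) -> list[Path]:
    """Consolidated run report across every stage that has produced output."""
    sections = {
        "stereology": "stereology_per_cohort.tsv",
        "morphometry": "morphometry_summary.tsv",
        "podocyte_composite": "podocyte_composite.tsv",
        "ora": "ora_results.tsv",
        "endpoint_statistics": "endpoint_statistics.tsv",
        "endpoint_correlations": "endpoint_correlations.tsv",
    }
    _require(out, *sections.values())
    report: dict = {"seed": cfg["seed"], "config_sha256": config_hash(cfg)}
    stacked = []
    for name, fname in sections.items():
        df = read_tsv(out / fname)
        report[name] = df.to_dict(orient="records")
        flat = df.copy()
        flat.insert(0, "section", name)
        stacked.append(flat)
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=str) + "\n")
    tsv_path = write_tsv(pd.concat(stacked, ignore_index=True),
                         out / "report.tsv", _meta(cfg, "report"))
    return [report_path, tsv_path]


STAGES = {
    "simulate": stage_simulate,
    "stereology": stage_stereology,
    "morphometry": stage_morphometry,
    "degs": stage_degs,
    "endpoints": stage_endpoints,
    "report": stage_report,
}
STAGE_ORDER = list(STAGES)


def run(subcommand: str, cfg: dict, out: str | Path) -> list[Path]:
    """Run one stage (or ``all``) and update the run manifest."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    names = STAGE_ORDER if subcommand == "all" else [subcommand]
    if any(n not in STAGES for n in names):
        raise KeyError(f"unknown stage: {subcommand}")
    written: list[Path] = []
    for name in names:
        log.info("running stage %s", name)
        files = STAGES[name](cfg, out)
        _register(out, cfg, files)
        written.extend(files)
    return written
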