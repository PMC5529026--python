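"""RPKM, DEG calling, BH, composite, PCA, classification and ORA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import silhouette_score

from glomkit import synthetic as syn
from glomkit import transcriptome as tx


def bh_step_up_brute(p):
    """Independent textbook step-up: sort, p·m/rank, right-to-left cummin."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def make_count_matrix(counts: np.ndarray, lengths, meta: pd.DataFrame):
    genes = pd.Index([f"g{i}" for i in range(counts.shape[0])], name="gene_id")
    return syn.CountMatrix(
        counts=pd.DataFrame(counts, index=genes,
                            columns=list(meta["sample_id"])),
        gene_lengths=pd.Series(lengths, index=genes, name="length_bp"),
        sample_meta=meta,
    )


class TestRPKM:
    def test_hand_computed_value(self):
        # 500 reads on a 2 kb gene in a 10M-read library → 25 RPKM
        counts = pd.DataFrame(
            {"s1": [500, 9_999_500]},
            index=pd.Index(["a", "b"], name="gene_id"),
        )
        lengths = pd.Series([2000, 1000], index=counts.index)
        out = tx.rpkm(counts, lengths)
        assert out.loc["a", "s1"] == pytest.approx(25.0)
        # 9,999,500 reads / (1 kb · 10 M reads) → 999,950 RPKM
        assert out.loc["b", "s1"] == pytest.approx(999_950.0)

    def test_zero_count_gives_zero(self):
        counts = pd.DataFrame({"s1": [0, 100]},
                              index=pd.Index(["a", "b"], name="gene_id"))
        out = tx.rpkm(counts, pd.Series([1000, 1000], index=counts.index))
        assert out.loc["a", "s1"] == 0.0

    def test_scaling_library_leaves_rpkm_unchanged(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.integers(1, 1000, size=(20, 3)),
            index=pd.Index([f"g{i}" for i in range(20)], name="gene_id"),
            columns=["s1", "s2", "s3"],
        )
        lengths = pd.Series(rng.integers(500, 5000, 20), index=counts.index)
        doubled = counts * 2
        pd.testing.assert_frame_equal(
            tx.rpkm(counts, lengths), tx.rpkm(doubled, lengths)
        )

    def test_zero_length_gene_rejected(self):
        counts = pd.DataFrame({"s1": [5]},
                              index=pd.Index(["a"], name="gene_id"))
        with pytest.raises(ValueError):
            tx.rpkm(counts, pd.Series([0], index=counts.index))


class TestBHAdjust:
    def test_textbook_example(self):
        assert tx.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_single_and_degenerate_vectors(self):
        assert tx.bh_adjust([0.2]) == pytest.approx([0.2])
        assert tx.bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tx.bh_adjust([0.5, 1.5])

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 60)))
            np.testing.assert_allclose(
                tx.bh_adjust(p), bh_step_up_brute(p), atol=1e-12
            )


class TestCallDegs:
    def test_identical_cohorts_give_no_degs(self):
        rng = np.random.default_rng(1)
        base = rng.integers(10, 5000, size=(50, 3))
        counts = np.hstack([base, base])  # obese duplicates lean
        meta = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(6)],
             "group": ["lean"] * 3 + ["obese"] * 3,
             "age_week": [41] * 6}
        )
        cm = make_count_matrix(counts, rng.integers(500, 5000, 50), meta)
        deg = tx.call_degs(cm, 41)
        assert deg.is_deg.sum() == 0
        assert deg.log2_fc.abs().max() == 0.0

    def test_programmed_eightfold_genes_recovered_exactly(self, single_age_design):
        """20-gene toy with 3 genes programmed 8-fold up at tight dispersion:
        the caller flags exactly those 3 (oracle: simulator truth table)."""
        spec = syn.DegSpec("eight", 3, {41: 3.0}, baseline_boost=0.1)
        params = syn.CountSimParams(
            n_genes=20, deg_spec=(spec,), baseline_log_sd=0.5,
            dispersion=0.005, podocyte_ratio_by_age={41: 1.0}, seed=2,
        )
        cm, truth = syn.simulate_counts(params, single_age_design)
        deg = tx.call_degs(cm, 41)
        called = set(deg.index[deg.is_deg])
        assert called == set(truth.loc[truth.label == "eight", "gene_id"])

    def test_lowering_fc_threshold_never_decreases_calls(self, small_count_matrix):
        cm, _ = small_count_matrix
        counts = [
            tx.call_degs(cm, 41, fc_thresh=t).is_deg.sum()
            for t in (4.0, 2.0, 1.5, 1.01)
        ]
        assert counts == sorted(counts)

    def test_single_sample_cohort_rejected(self):
        meta = pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "group": ["lean", "obese", "obese"],
             "age_week": [41] * 3}
        )
        cm = make_count_matrix(
            np.ones((5, 3), dtype=int) * 10, [1000] * 5, meta
        )
        with pytest.raises(ValueError):
            tx.call_degs(cm, 41)


class TestPodocyteComposite:
    @staticmethod
    def _expr_meta(lean_vals, obese_factor):
        genes = list(syn.PODOCYTE_GENES) + ["other"]
        ages = [12, 41]
        cols, meta_rows = {}, []
        for age in ages:
            for group, factor in (("lean", 1.0), ("obese", obese_factor)):
                for rep in range(3):
                    sid = f"{group}{age}r{rep}"
                    vals = np.array(lean_vals + [7.0]) * factor
                    cols[sid] = vals
                    meta_rows.append(
                        {"sample_id": sid, "group": group, "age_week": age}
                    )
        expr = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
        return expr, pd.DataFrame(meta_rows)

    def test_equal_cohorts_give_100_percent(self):
        expr, meta = self._expr_meta([100.0, 80.0, 60.0, 40.0, 20.0], 1.0)
        res = tx.podocyte_composite(expr, meta)
        assert res.composite_pct.to_numpy() == pytest.approx([100.0, 100.0])

    def test_uniform_halving_gives_50_percent(self):
        expr, meta = self._expr_meta([100.0, 80.0, 60.0, 40.0, 20.0], 0.5)
        res = tx.podocyte_composite(expr, meta)
        assert res.composite_pct.to_numpy() == pytest.approx(
            [50.0, 50.0], abs=0.1
        )

    def test_missing_podocyte_gene_raises(self):
        expr, meta = self._expr_meta([1.0] * 5, 1.0)
        with pytest.raises(KeyError):
            tx.podocyte_composite(expr.drop(index="Wt1"), meta)

    def test_programmed_decline_recovered_at_tight_dispersion(self, default_design):
        params = syn.CountSimParams(
            n_genes=500, dispersion=0.005, podocyte_baseline_boost=1.0, seed=6
        )
        cm, _ = syn.simulate_counts(params, default_design)
        expr = tx.rpkm(cm.counts, cm.gene_lengths)
        res = tx.podocyte_composite(expr, cm.sample_meta)
        programmed = {a: 100 * r for a, r in syn.PODOCYTE_DECLINE.items()}
        for age, expected in programmed.items():
            assert res.composite_pct[age] == pytest.approx(expected, abs=5.0)

    def test_invariant_to_gene_lengths_and_sample_order(self, default_design):
        params = syn.CountSimParams(n_genes=200, seed=8)
        cm, _ = syn.simulate_counts(params, default_design)
        expr = tx.rpkm(cm.counts, cm.gene_lengths)
        res1 = tx.podocyte_composite(expr, cm.sample_meta)
        # halving every length doubles RPKM uniformly per gene: pure ratio
        expr2 = tx.rpkm(cm.counts, cm.gene_lengths // 2 + 1)
        res2 = tx.podocyte_composite(expr2, cm.sample_meta)
        np.testing.assert_allclose(
            res1.composite_pct, res2.composite_pct, rtol=0.02
        )
        shuffled = cm.sample_meta.sample(frac=1, random_state=0)
        res3 = tx.podocyte_composite(expr, shuffled)
        np.testing.assert_allclose(res1.composite_pct, res3.composite_pct)


class TestPCA:
    def test_identical_samples_get_identical_scores(self):
        rng = np.random.default_rng(2)
        col = rng.uniform(1, 100, 50)
        expr = pd.DataFrame(
            {"s1": col, "s2": col, "s3": rng.uniform(1, 100, 50)},
            index=pd.Index([f"g{i}" for i in range(50)], name="gene_id"),
        )
        meta = pd.DataFrame(
            {"sample_id": ["s1", "s2", "s3"], "group": ["lean"] * 3,
             "age_week": [12] * 3}
        )
        scores, _ = tx.pca_expressed(expr, meta, min_mean_rpkm=0.0)
        np.testing.assert_allclose(
            scores.loc[0, ["PC1", "PC2"]].astype(float),
            scores.loc[1, ["PC1", "PC2"]].astype(float),
            atol=1e-9,
        )

    def test_variance_fractions_sum_to_one_with_full_rank(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(
            rng.uniform(1, 50, size=(100, 6)),
            index=pd.Index([f"g{i}" for i in range(100)], name="gene_id"),
            columns=[f"s{i}" for i in range(6)],
        )
        meta = pd.DataFrame(
            {"sample_id": expr.columns, "group": ["lean"] * 6,
             "age_week": [12] * 6}
        )
        _, frac = tx.pca_expressed(expr, meta, min_mean_rpkm=0.0,
                                   n_components=5)
        assert frac.sum() == pytest.approx(1.0, abs=1e-9)

    def test_strong_group_effect_separates_on_pc1(self, single_age_design):
        specs = (
            syn.DegSpec("up", 100, {41: 3.0}),
            syn.DegSpec("down", 100, {41: -3.0}),
        )
        params = syn.CountSimParams(
            n_genes=1000, deg_spec=specs,
            podocyte_ratio_by_age={41: 1.0}, seed=5,
        )
        cm, _ = syn.simulate_counts(params, single_age_design)
        expr = tx.rpkm(cm.counts, cm.gene_lengths)
        scores, _ = tx.pca_expressed(expr, cm.sample_meta)
        sil = silhouette_score(
            scores[["PC1"]].to_numpy(), scores["group"].to_numpy()
        )
        assert sil > 0.5


class TestClassifyLongitudinal:
    AGES = (12, 20, 24, 29, 34, 41)

    @classmethod
    def _tables(cls, lfc: dict, sig: dict):
        genes = pd.Index(sorted(lfc), name="gene_id")
        out = {}
        for i, age in enumerate(cls.AGES):
            out[age] = pd.DataFrame(
                {"log2_fc": [lfc[g][i] for g in genes],
                 "is_deg": [sig[g][i] for g in genes]},
                index=genes,
            )
        return out

    def test_sustained_and_progressive_rules(self):
        lfc = {
            "sus": [2.0] * 6,
            "prog": [0.2, 1.2, 1.8, 2.3, 3.0, 3.4],
            "weak": [1.1] * 6,  # significant but |FC| < 3
            "bounce": [0.1, 1.5, 1.1, 2.0, 1.2, 2.5],
        }
        sig = {
            "sus": [True] * 6,
            "prog": [False] + [True] * 5,
            "weak": [True] * 6,
            "bounce": [False] + [True] * 5,
        }
        sustained, progressive = tx.classify_longitudinal(self._tables(lfc, sig))
        assert sustained == ["sus"]
        assert progressive == ["prog"]

    def test_single_age_and_mismatched_genes_rejected(self):
        tables = self._tables({"g": [1.0] * 6}, {"g": [True] * 6})
        with pytest.raises(ValueError):
            tx.classify_longitudinal({41: tables[41]})
        tables[24] = tables[24].rename(index={"g": "h"})
        with pytest.raises(ValueError):
            tx.classify_longitudinal(tables)

    def test_simulation_truth_recovered_exactly(self, default_design):
        # near-flat baseline keeps library-composition shifts of the
        # RPKM fold changes well below the class thresholds
        params = syn.default_count_params(seed=3, n_genes=2000)
        params = syn.CountSimParams(
            n_genes=params.n_genes, deg_spec=params.deg_spec,
            baseline_log_sd=0.5, podocyte_baseline_boost=1.0,
            dispersion=0.005, seed=3,
        )
        cm, truth = syn.simulate_counts(params, default_design)
        ages = sorted(cm.sample_meta.age_week.unique())
        deg_by_age = {a: tx.call_degs(cm, a) for a in ages}
        sustained, progressive = tx.classify_longitudinal(deg_by_age)
        want_sus = set(
            truth.loc[truth.label == "early_sustained_up", "gene_id"]
        )
        want_prog = set(truth.loc[truth.label == "progressive_up", "gene_id"])
        assert set(sustained) == want_sus
        assert set(progressive) == want_prog


class TestOraFisher:
    def test_zero_overlap(self):
        res = tx.ora_fisher(["a"], {"b"}, {"a", "b", "c"})
        assert res.p_right == pytest.approx(1.0)
        assert res.direction_z == 0.0

    def test_derived_hypergeometric_value(self):
        """Universe 20, set 5, 4 DEGs, overlap 3:
        p = [C(5,3)C(15,1) + C(5,4)C(15,0)] / C(20,4) ≈ 0.03199."""
        universe = [f"u{i}" for i in range(20)]
        gene_set = universe[:5]
        degs = universe[:3] + [universe[10]]
        res = tx.ora_fisher(degs, gene_set, universe, set_id="s")
        assert res.overlap == 3
        assert res.p_right == pytest.approx(0.03199, abs=5e-5)

    def test_concordant_directions_give_extreme_z(self):
        universe = [f"u{i}" for i in range(10)]
        degs = {g: +1 for g in universe[:4]}
        res = tx.ora_fisher(degs, universe[:4], universe)
        assert res.direction_z == pytest.approx(math.sqrt(4))
        mixed = {**{g: +1 for g in universe[:2]}, **{g: -1 for g in universe[2:4]}}
        assert tx.ora_fisher(mixed, universe[:4], universe).direction_z == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tx.ora_fisher(["a"], {"a"}, set())
        with pytest.raises(ValueError):
            tx.ora_fisher(["z"], {"a"}, {"a", "b"})
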