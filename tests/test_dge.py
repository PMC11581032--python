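"""Differential-expression machinery: normalization, NB Wald test, BH, DEG
calling, common/distinct classification, sample PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddstress import dge, simulate

from _oracles import bh_brute


class TestSizeFactors:
    def test_identical_columns_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 5], "s2": [10, 20, 5]}, index=list("abc"))
        assert np.allclose(dge.size_factors(counts), 1.0)

    def test_doubled_column_sqrt2_split(self):
        """Median-of-ratios on col2 = 2 x col1 gives factors (1/sqrt2, sqrt2)."""
        counts = pd.DataFrame({"s1": [10, 20, 5], "s2": [20, 40, 10]}, index=list("abc"))
        f = dge.size_factors(counts)
        assert f["s1"] == pytest.approx(1 / np.sqrt(2))
        assert f["s2"] == pytest.approx(np.sqrt(2))

    def test_all_zero_gene_ignored(self):
        counts = pd.DataFrame({"s1": [10, 20, 5], "s2": [20, 40, 10]}, index=list("abc"))
        with_zero = pd.concat(
            [counts, pd.DataFrame({"s1": [0], "s2": [0]}, index=["z"])]
        )
        pd.testing.assert_series_equal(dge.size_factors(counts), dge.size_factors(with_zero))

    def test_no_common_gene_raises(self):
        counts = pd.DataFrame({"s1": [1, 0], "s2": [0, 1]}, index=list("ab"))
        with pytest.raises(dge.DesignError):
            dge.size_factors(counts)


class TestNormalizedCounts:
    def test_unit_factor_identity_and_halving(self):
        counts = pd.DataFrame({"s1": [10, 20], "s2": [8, 12]}, index=list("ab"))
        factors = pd.Series({"s1": 1.0, "s2": 2.0})
        norm = dge.normalized_counts(counts, factors)
        assert (norm["s1"] == counts["s1"]).all()
        assert (norm["s2"] == counts["s2"] / 2).all()

    def test_balanced_simulation_column_means_agree(self):
        cfg = simulate.SimConfig(
            n_genes=400, module_specs=(), seed=4, library_size_range=(0.5, 2.0)
        )
        counts, _meta, _truth = simulate.generate_timecourse_counts(cfg)
        norm = dge.normalized_counts(counts, dge.size_factors(counts))
        col_means = norm.mean(axis=0)
        spread = col_means.std(ddof=1)
        assert spread / col_means.mean() < 0.05  # depth effect removed


class TestBH:
    def test_hand_case(self):
        adj = dge.bh_adjust([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(adj, [0.02, 0.02, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert dge.bh_adjust([0.73]) == pytest.approx([0.73])
        assert np.allclose(dge.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dge.bh_adjust([0.5, 1.2])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 25))
            assert np.allclose(dge.bh_adjust(p), bh_brute(p), atol=1e-12)

    def test_nan_excluded_from_m(self):
        adj = dge.bh_adjust([0.005, np.nan, 0.01, 0.03, 0.04])
        assert np.isnan(adj[1])
        assert np.allclose(np.delete(adj, 1), [0.02, 0.02, 0.04, 0.04])


def _two_group_data(mu_a, mu_b, n=5, alpha=0.05, n_genes=400, seed=0):
    rng = np.random.default_rng(seed)
    nb_n = 1 / alpha
    a = rng.negative_binomial(nb_n, nb_n / (nb_n + mu_a), size=(n_genes, n))
    b = rng.negative_binomial(nb_n, nb_n / (nb_n + mu_b), size=(n_genes, n))
    counts = pd.DataFrame(
        np.hstack([b, a]),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"t0_r{i}" for i in range(n)] + [f"t1_r{i}" for i in range(n)],
    )
    meta = pd.DataFrame(
        {
            "sample_id": counts.columns,
            "condition": "NucDD",
            "timepoint_min": [0] * n + [240] * n,
            "replicate": list(range(1, n + 1)) * 2,
        }
    )
    return counts, meta


class TestWaldTest:
    def test_identical_groups_zero_lfc(self):
        counts, meta = _two_group_data(100, 100, seed=1)
        counts.iloc[:, 5:] = counts.iloc[:, :5].to_numpy()  # mirror replicates
        res = dge.test_timepoint(counts, meta, "NucDD", 240)
        assert np.allclose(res["log2fc"], 0.0)

    def test_planted_lfc_recovered(self):
        """Planted log2FC = 1 at mu = 500 is estimated within 0.1 on average
        (effect planted in a minority of genes so normalization is unaffected)."""
        rng = np.random.default_rng(2)
        nb_n = 1 / 0.05
        mu = np.full(800, 500.0)
        mu_shift = mu.copy()
        mu_shift[:80] = 1000.0  # planted doubling in 10% of genes
        b = rng.negative_binomial(nb_n, nb_n / (nb_n + mu), size=(5, 800)).T
        a = rng.negative_binomial(nb_n, nb_n / (nb_n + mu_shift), size=(5, 800)).T
        counts = pd.DataFrame(
            np.hstack([b, a]),
            index=[f"g{i}" for i in range(800)],
            columns=[f"t0_r{i}" for i in range(5)] + [f"t1_r{i}" for i in range(5)],
        )
        meta = pd.DataFrame(
            {
                "sample_id": counts.columns,
                "condition": "NucDD",
                "timepoint_min": [0] * 5 + [240] * 5,
                "replicate": list(range(1, 6)) * 2,
            }
        )
        res = dge.test_timepoint(counts, meta, "NucDD", 240)
        assert abs(res["log2fc"].iloc[:80].mean() - 1.0) < 0.1

    def test_null_pvalues_uniform(self):
        """No planted effect: p-values are near-uniform (KS < 0.05)."""
        cfg = simulate.SimConfig(n_genes=5000, module_specs=(), seed=3)
        counts, meta, _ = simulate.generate_timecourse_counts(cfg)
        res = dge.test_timepoint(counts, meta, "NucDD", 240)
        p = res["pvalue"].dropna().to_numpy()
        from scipy.stats import kstest

        assert kstest(p, "uniform").statistic < 0.05

    def test_all_zero_gene_untested(self):
        counts, meta = _two_group_data(100, 100, n_genes=50, seed=4)
        counts.iloc[0] = 0
        res = dge.test_timepoint(counts, meta, "NucDD", 240)
        assert np.isnan(res["pvalue"].iloc[0])
        assert np.isnan(res["padj"].iloc[0])

    def test_padj_at_least_p(self):
        counts, meta = _two_group_data(300, 100, n_genes=200, seed=5)
        res = dge.test_timepoint(counts, meta, "NucDD", 240)
        ok = res.dropna(subset=["pvalue"])
        assert (ok["padj"] >= ok["pvalue"] - 1e-12).all()


class TestCallDegs:
    @staticmethod
    def _row(lfc, padj):
        return pd.DataFrame(
            {
                "condition": "NucDD", "timepoint_min": 240.0, "base_mean": 100.0,
                "log2fc": [lfc], "se": 0.1, "stat": lfc / 0.1, "pvalue": padj,
                "padj": [padj],
            },
            index=pd.Index(["g0"], name="gene"),
        )

    def test_fc_just_below_threshold_not_deg(self):
        res = self._row(np.log2(1.39), 1e-6)
        assert not dge.call_degs(res)["deg"].iloc[0]

    def test_padj_above_alpha_not_deg(self):
        res = self._row(1.0, 0.02)
        assert not dge.call_degs(res)["deg"].iloc[0]

    def test_strong_up_is_deg(self):
        out = dge.call_degs(self._row(1.0, 1e-6))
        assert out["deg"].iloc[0] and out["direction"].iloc[0] == "up"

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        lfc=st.floats(-3, 3),
        padj=st.floats(0, 1),
        fc1=st.floats(1.01, 3),
        dfc=st.floats(0, 2),
        alpha1=st.floats(0.001, 0.2),
        dalpha=st.floats(0, 0.1),
    )
    def test_monotone_in_thresholds(self, lfc, padj, fc1, dfc, alpha1, dalpha):
        """Raising the FC threshold or lowering alpha never adds a DEG."""
        res = self._row(lfc, padj)
        loose = dge.call_degs(res, fc_threshold=fc1, alpha=min(alpha1 + dalpha, 0.99))
        strict = dge.call_degs(res, fc_threshold=fc1 + dfc, alpha=alpha1)
        assert not (strict["deg"].iloc[0] and not loose["deg"].iloc[0])

    def test_invalid_thresholds(self):
        res = self._row(1.0, 0.001)
        with pytest.raises(ValueError):
            dge.call_degs(res, fc_threshold=-1)
        with pytest.raises(ValueError):
            dge.call_degs(res, alpha=1.5)


class TestClassification:
    @staticmethod
    def _table(deg_flags):
        genes = [f"g{i}" for i in range(len(deg_flags))]
        return pd.DataFrame(
            {
                "condition": "x", "timepoint_min": 240.0,
                "log2fc": 1.0, "deg": deg_flags,
                "direction": ["up" if d else "none" for d in deg_flags],
            },
            index=pd.Index(genes, name="gene"),
        )

    def test_common_distinct_none(self):
        nuc = self._table([True, True, False])
        cyto = self._table([True, False, False])
        out = dge.classify_common_distinct(nuc, cyto).set_index("gene")
        assert out.loc["g0", "klass"] == "common"
        assert out.loc["g1", "klass"] == "distinct"
        assert out.loc["g2", "klass"] == "none"

    def test_mismatched_universe_rejected(self):
        nuc = self._table([True, False])
        cyto = self._table([True, False, True])
        with pytest.raises(dge.DesignError):
            dge.classify_common_distinct(nuc, cyto)


class TestPCA:
    def test_duplicated_sample_identical_coords(self):
        rng = np.random.default_rng(0)
        norm = pd.DataFrame(rng.lognormal(3, 1, size=(200, 6)),
                            columns=[f"s{i}" for i in range(6)])
        norm["s5"] = norm["s4"]
        coords, _ = dge.pca_samples(norm)
        assert np.allclose(coords.loc["s4"], coords.loc["s5"])

    def test_planted_groups_separate_on_pc1(self):
        """Two sample groups with different module means separate cleanly."""
        rng = np.random.default_rng(1)
        base = rng.lognormal(3, 0.5, size=(300, 1))
        a = base * rng.lognormal(0, 0.05, size=(300, 5))
        b = base * rng.lognormal(0, 0.05, size=(300, 5))
        b[:30] *= 8  # module shift in group b
        norm = pd.DataFrame(np.hstack([a, b]), columns=[f"s{i}" for i in range(10)])
        coords, _ = dge.pca_samples(norm, top_fraction=0.2)
        from sklearn.metrics import silhouette_score

        labels = [0] * 5 + [1] * 5
        assert silhouette_score(coords[["PC1"]], labels) > 0.5

    def test_variance_explained_bounded(self):
        rng = np.random.default_rng(2)
        norm = pd.DataFrame(rng.lognormal(3, 1, size=(100, 8)))
        _, explained = dge.pca_samples(norm, n_components=2)
        assert explained.sum() <= 1.0 + 1e-12

    def test_too_few_samples(self):
        norm = pd.DataFrame(np.ones((10, 2)))
        with pytest.raises(dge.DesignError):
            dge.pca_samples(norm)


class TestUniverseFilter:
    def test_detected_requires_every_group(self):
        cfg = simulate.SimConfig(n_genes=50, module_specs=(), seed=6)
        counts, meta, _ = simulate.generate_timecourse_counts(cfg)
        nuc0 = meta.loc[
            (meta["condition"] == "NucDD") & (meta["timepoint_min"] == 0), "sample_id"
        ]
        counts.loc[counts.index[0], nuc0] = 0
        kept = dge.detected_genes(counts, meta)
        assert counts.index[0] not in kept
        assert len(kept) == 49
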