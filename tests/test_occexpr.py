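"""Tests for occupancy-expression statistics, KS/rank-sum tests, ratio
curves, dominated-set selection and TSS shape classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coreprom.occexpr import (classify_tss_shape, ks_boot, mean_tags,
                              quantile_distribution, ranksum_positions,
                              ratio_curve, select_dominated,
                              sliding_window_expression, _ks_statistic)


def _series(vals, prefix="g"):
    return pd.Series(np.asarray(vals, dtype=float),
                     index=[f"{prefix}{i}" for i in range(len(vals))])


class TestSlidingWindow:
    def test_identity_gives_r1(self, rng):
        occ = _series(np.sort(rng.normal(size=500)))
        curve, r = sliding_window_expression(occ, occ.copy())
        assert r == pytest.approx(1.0, abs=1e-9)
        assert (curve["n_genes"] >= 10).all()

    def test_null_r_small(self):
        """Independent expression: the window curve shows no trend.

        The curve correlation over W ~ 60 windows has null sd ~ 1/sqrt(W)
        ~ 0.14 (bounds frozen from that simulation), far below the coupled
        generator's r > 0.9.
        """
        rs = []
        for seed in range(20):
            g = np.random.default_rng(seed)
            occ = _series(g.normal(size=2000))
            expr = _series(g.normal(size=2000))
            _, r = sliding_window_expression(occ, expr)
            rs.append(r)
            assert abs(r) < 0.5
        assert np.mean(np.abs(rs)) < 0.2

    def test_coupled_generator_high_r(self, top100_cohort):
        occ = top100_cohort.occupancy["TFIIB"]
        expr = top100_cohort.expression.set_index("promoter_id")["signal"]
        _, r = sliding_window_expression(occ, expr.reindex(occ.index),
                                         min_genes=5)
        assert r > 0.9

    def test_too_few_windows(self):
        occ = _series([1.0, 1.01, 1.02])
        with pytest.raises(ValueError):
            sliding_window_expression(occ, occ.copy(), step=0.1, min_genes=1)
        with pytest.raises(ValueError):
            sliding_window_expression(occ, occ.copy(), step=0)


class TestQuantileDistribution:
    def test_rows_sum_to_one(self, rng):
        occ = _series(rng.normal(size=300))
        expr = _series(rng.normal(size=300))
        tab, above = quantile_distribution(occ, expr)
        assert np.allclose(tab.sum(axis=1), 1.0)
        assert above.between(0, 1).all()

    def test_identity_diagonal_dominant(self):
        occ = _series(np.arange(1000.0))
        tab, above = quantile_distribution(occ, occ.copy())
        assert np.allclose(np.diag(tab), 1.0)
        assert above.iloc[-1] == 1.0 and above.iloc[0] == 0.0

    def test_independent_cells_uniform(self):
        g = np.random.default_rng(5)
        occ = _series(g.normal(size=20000))
        expr = _series(g.normal(size=20000))
        tab, _ = quantile_distribution(occ, expr)
        assert np.abs(tab.to_numpy() - 0.1).max() < 0.04


class TestKsBoot:
    def test_identical_samples(self):
        a = np.arange(50.0)
        res = ks_boot(a, a.copy(), n_boot=199, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_disjoint_supports(self):
        res = ks_boot(np.arange(10.0), np.arange(100.0, 110.0), n_boot=199, seed=0)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)
        assert res.p_value < 0.05

    def test_statistic_matches_scipy(self, rng):
        """Dual route: the fast pooled-ECDF statistic equals ks_2samp's D,
        including under ties."""
        for _ in range(30):
            a = rng.normal(size=rng.integers(5, 60))
            b = np.round(rng.normal(size=rng.integers(5, 60)), 1)
            d = _ks_statistic(a, b)
            assert d == pytest.approx(stats.ks_2samp(a, b).statistic, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            ks_boot([], [1.0])
        with pytest.raises(ValueError):
            ks_boot([1.0], [1.0], n_boot=50)

    def test_null_pvalues_roughly_uniform(self):
        """Bootstrap p-values under the null pass a KS uniformity check.

        Unequal group sizes keep the D lattice fine; with equal small sizes
        the point mass at the observed D makes the estimator conservative.
        """
        g = np.random.default_rng(77)
        ps = [ks_boot(g.normal(size=30), g.normal(size=41),
                      n_boot=500, seed=g).p_value for _ in range(200)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestRanksum:
    def test_identical_vectors(self):
        res = ranksum_positions(np.arange(30), np.arange(30))
        assert res.p_value > 0.9

    def test_complete_separation(self):
        a = np.arange(50)
        res = ranksum_positions(a, a + 1000)
        assert res.p_value < 1e-10
        assert res.statistic == 0.0  # U for the first sample

    def test_shift_invariance(self, rng):
        a = rng.integers(-300, 0, size=40)
        b = rng.integers(-200, 100, size=35)
        r1 = ranksum_positions(a, b)
        r2 = ranksum_positions(a + 5000, b + 5000)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)
        assert r1.statistic == r2.statistic


class TestRatioCurve:
    def test_identical_tracks_ratio_one(self, rng):
        t = _series(rng.normal(size=200))
        e = _series(rng.normal(size=200))
        rc = ratio_curve(t, t.copy(), e)
        assert np.allclose(rc.table["ratio"], 1.0)
        assert len(rc.table) == 20

    def test_common_shift_invariance(self, rng):
        t = _series(rng.normal(size=200))
        n = _series(rng.normal(size=200))
        e = _series(rng.normal(size=200))
        r1 = ratio_curve(t, n, e).table["ratio"]
        r2 = ratio_curve(t + 3.7, n + 3.7, e).table["ratio"]
        assert np.allclose(r1, r2)

    def test_bin_pct_must_divide_100(self, rng):
        t = _series(rng.normal(size=100))
        with pytest.raises(ValueError):
            ratio_curve(t, t.copy(), t.copy(), bin_pct=7)

    def test_coupled_cohort_rises_in_top_bins(self, sampling_cohort):
        """Expression tracks TFIIB but only partially NC2 (factor correlation
        0.8), so the TFIIB/NC2 ratio climbs toward the most highly expressed
        bins (90-95 and 95-100)."""
        occ = sampling_cohort.occupancy
        expr = sampling_cohort.expression.set_index("promoter_id")["signal"]
        rc = ratio_curve(occ["TFIIB"], occ["NC2"], expr.reindex(occ.index)).table
        mid = rc["ratio"].iloc[4:16].mean()
        assert rc["ratio"].iloc[-1] > mid
        assert rc["ratio"].iloc[-2] > mid


class TestSelectDominated:
    def test_brute_force_five_genes(self):
        t = _series([3.0, 2.0, 1.0, 0.0, -1.0])
        n = _series([0.0, 0.0, 0.0, 0.0, 0.0])
        e = _series([1.0, 1.0, 1.0, 1.0, 1.0])
        hi, lo = select_dominated(t, n, e, cutoff_pct=0, top_n=2)
        assert hi == ["g0", "g1"]
        assert lo == ["g4", "g3"]

    def test_all_equal_ratios_lexicographic(self):
        t = _series([1.0] * 6)
        hi, lo = select_dominated(t, t.copy(), t.copy(), cutoff_pct=0, top_n=2)
        assert hi == ["g0", "g1"] and lo == ["g0", "g1"]

    def test_disjoint_when_room(self, rng):
        t = _series(rng.normal(size=60))
        n = _series(rng.normal(size=60))
        e = _series(rng.normal(size=60))
        hi, lo = select_dominated(t, n, e, cutoff_pct=0, top_n=20)
        assert not set(hi) & set(lo)

    def test_insufficient_eligible_reports_count(self):
        t = _series(np.arange(10.0))
        with pytest.raises(ValueError, match="eligible"):
            select_dominated(t, t.copy(), t.copy(), cutoff_pct=60, top_n=9)


class TestTssShape:
    def test_single_site(self):
        s = classify_tss_shape({1: 100})
        assert s.class4 == "single" and s.class2 == "focused"

    def test_dominant_peak(self):
        s = classify_tss_shape({-40: 10, 1: 80, 30: 10})
        assert s.class4 == "dominant" and s.class2 == "focused"

    def test_two_equal_peaks_multimodal(self):
        s = classify_tss_shape({-50: 50, 50: 50})
        assert s.class4 == "multimodal" and s.class2 == "dispersed"

    def test_broad_without_strong_modes(self):
        tags = {p: 10 for p in range(-50, 51, 5)}
        s = classify_tss_shape(tags)
        assert s.class4 == "broad" and s.class2 == "dispersed"

    def test_translation_invariance(self, rng):
        tags = {int(p): int(c) for p, c in
                zip(rng.integers(-200, 200, 12), rng.integers(1, 50, 12))}
        a = classify_tss_shape(tags)
        b = classify_tss_shape({p + 137: c for p, c in tags.items()})
        assert a.class4 == b.class4

    def test_empty_error(self):
        with pytest.raises(ValueError):
            classify_tss_shape({})


class TestMeanTags:
    def test_examples(self):
        tags = {"a": {1: 100}, "b": {1: 150, 2: 50}, "c": {5: 300}}
        assert mean_tags(tags) == 200.0
        assert mean_tags(tags, ids=["a"]) == 100.0
        with pytest.raises(ValueError):
            mean_tags(tags, ids=[])

    def test_preset_mean_recovered(self, dominated_cohort):
        m = mean_tags(dominated_cohort.cage_tags)
        assert m == pytest.approx(948.0, rel=0.05)
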