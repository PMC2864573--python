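"""Tests for probe scaling, scoring, peak calling, concordance and profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coreprom.chipsignal import (PeakCallConfig, SignalTrack, all_probes,
                                 bin_offset, biweight_mean, build_profile,
                                 call_peaks, concordance, promoter_score,
                                 promoter_scores, scale_track,
                                 top_percentile_probes, track_from_signals)
from coreprom.synthcohort import generate_cohort


def _hand_biweight(values, c=5.0, eps=1e-4):
    """Direct evaluation of the one-step biweight formula (test oracle)."""
    x = np.asarray(values, dtype=float)
    m = np.median(x)
    s = np.median(np.abs(x - m))
    u = (x - m) / (c * s + eps)
    w = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0.0)
    return m if w.sum() == 0 else float((w * x).sum() / w.sum())


class TestBiweightMean:
    def test_constant(self):
        assert biweight_mean([5, 5, 5, 5]) == 5.0

    def test_outlier_downweighted(self):
        # M=3, S=1: the outlier gets weight 0, the rest pull the mean to ~2.60
        val = biweight_mean([1, 2, 3, 4, 100])
        assert val == pytest.approx(2.6023, abs=2e-4)
        assert val == pytest.approx(_hand_biweight([1, 2, 3, 4, 100]), abs=1e-12)

    def test_symmetric(self):
        assert biweight_mean([-2, -1, 0, 1, 2]) == pytest.approx(0.0, abs=1e-12)

    def test_zero_mad_falls_back_gracefully(self):
        # c*S+eps = eps: every non-median point weighs 0
        assert biweight_mean([1, 1, 1, 50]) == pytest.approx(1.0)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            biweight_mean([])

    def test_matches_hand_formula_on_random_data(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(3, 40))
            assert biweight_mean(x) == pytest.approx(_hand_biweight(x), abs=1e-12)


def _track(values, ids=None):
    n = len(values)
    ids = ids if ids is not None else [f"p{i // 15}" for i in range(n)]
    return SignalTrack(pd.DataFrame({
        "promoter_id": ids,
        "probe_index": [i % 15 for i in range(n)],
        "offset": [(i % 15) * 100 - 700 for i in range(n)],
        "value": values}))


class TestScaling:
    def test_constant_track_centers_to_zero(self):
        t = scale_track(_track([3.0] * 30))
        assert np.allclose(t.values(), 0.0)

    def test_idempotence(self, rng):
        for _ in range(10):
            t = _track(rng.normal(1.0, 2.0, size=150))
            scaled = scale_track(t)
            assert abs(biweight_mean(scaled.values())) < 1e-9

    def test_shift_matches_biweight_oracle(self, rng):
        vals = np.r_[[1, 2, 3, 4, 100.0], rng.normal(size=25)]
        t = _track(vals)
        shift = biweight_mean(vals)
        assert np.allclose(scale_track(t).values(), vals - shift)


class TestPromoterScore:
    def test_identical_values(self):
        assert promoter_score(_track([2.5] * 15), "p0") == 2.5

    def test_median_of_1_to_15(self):
        assert promoter_score(_track(list(range(1, 16))), "p0") == 8

    def test_missing_probes_named(self):
        t = _track([1.0] * 14 + [None] * 1)
        t.df = t.df.dropna()
        with pytest.raises(ValueError, match="p0"):
            promoter_score(t, "p0")
        with pytest.raises(ValueError, match="p0"):
            promoter_scores(t)

    def test_score_monotone_in_occupancy(self):
        """Generator oracle: at low probe noise, promoter scores rank with
        the planted occupancy."""
        from coreprom.synthcohort import CohortBlueprint
        bp = CohortBlueprint(n_promoters=300, seed=19, replicate_noise=0.02,
                             scrub=False)
        cohort = generate_cohort(bp)
        track = scale_track(track_from_signals(cohort.signals, "TFIIB", 1))
        scores = promoter_scores(track)
        occ = cohort.occupancy["TFIIB"].reindex(scores.index)
        rho = pd.Series(scores).corr(pd.Series(occ), method="spearman")
        assert rho > 0.9


class TestCallPeaks:
    def test_flat_series_no_peaks(self):
        assert call_peaks(np.zeros(10)) == []

    def test_two_nines_single_peak(self):
        # mean=1.8, population sd=3.6, t=5.4: only the 9s exceed it
        peaks = call_peaks([0, 0, 0, 9, 9, 0, 0, 0, 0, 0],
                           PeakCallConfig(k=1.0, min_run=2))
        assert len(peaks) == 1
        p = peaks[0]
        assert (p.start, p.end, p.apex, p.height) == (3, 4, 3, 9.0)

    def test_min_run_filters_spikes(self):
        series = [0, 0, 0, 9, 0, 0, 0, 0, 0, 0]
        assert call_peaks(series, PeakCallConfig(k=1.0, min_run=2)) == []
        assert len(call_peaks(series, PeakCallConfig(k=1.0, min_run=1))) == 1

    def test_apex_tie_leftmost(self):
        peaks = call_peaks([0, 0, 7, 7, 7, 0, 0, 0, 0, 0],
                           PeakCallConfig(k=1.0, min_run=2))
        assert peaks[0].apex == 2

    def test_series_positions_respected(self):
        s = pd.Series([0, 0, 0, 9, 9, 0, 0, 0, 0, 0],
                      index=range(-500, 500, 100))
        p = call_peaks(s, PeakCallConfig(k=1.0, min_run=2))[0]
        assert (p.start, p.end, p.apex) == (-200, -100, -200)

    def test_nesting_across_stringencies(self, rng):
        """Each peak at larger k lies inside a peak at smaller k, so counts
        are monotone non-increasing in k."""
        for _ in range(20):
            x = rng.normal(size=200) + 3.0 * (rng.random(200) < 0.05)
            by_k = {k: call_peaks(x, PeakCallConfig(k=k, min_run=2))
                    for k in (1.0, 2.0, 2.5)}
            assert len(by_k[2.5]) <= len(by_k[2.0]) <= len(by_k[1.0])
            for k_hi, k_lo in ((2.5, 2.0), (2.0, 1.0)):
                for p in by_k[k_hi]:
                    assert any(q.start <= p.start and p.end <= q.end
                               for q in by_k[k_lo])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PeakCallConfig(k=0)
        with pytest.raises(ValueError):
            PeakCallConfig(min_run=0)
        with pytest.raises(ValueError):
            call_peaks([1.0], PeakCallConfig(min_run=2))


class TestConcordance:
    def test_identical_maps(self):
        s = pd.Series(np.arange(20.0), index=[f"p{i}" for i in range(20)])
        rep = concordance(s, s.copy(), 25, 50)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.overlap_fraction == 1.0

    def test_negated_map(self):
        s = pd.Series(np.arange(20.0), index=[f"p{i}" for i in range(20)])
        assert concordance(s, -s, 25, 50).pearson_r == pytest.approx(-1.0)

    def test_overlap_by_enumeration(self):
        # 20 promoters; replicate b swaps two of a's top-4 out of its top set
        ids = [f"p{i}" for i in range(20)]
        a = pd.Series(np.arange(20.0), index=ids)
        b = a.copy()
        b["p19"], b["p0"] = 0.0, 19.0   # top-1 of a drops out of b's top-8
        # brute-force expectation
        top_a = {i for i in ids if a[i] >= np.percentile(a, 80)}       # top 20%
        top_b = {i for i in ids if b[i] >= np.percentile(b, 60)}       # top 40%
        expect = len(top_a & top_b) / len(top_a)
        rep = concordance(a, b, 20, 40)
        assert rep.overlap_fraction == pytest.approx(expect)
        assert expect < 1.0

    def test_errors(self):
        a = pd.Series([1.0, 2.0], index=["x", "y"])
        with pytest.raises(ValueError):
            concordance(a, a)
        b = pd.Series([1.0, 2.0, 3.0], index=["x", "y", "z"])
        with pytest.raises(ValueError):
            concordance(b, b.rename({"z": "w"}))


class TestTopPercentileProbes:
    def test_identical_values_all_returned(self):
        t = _track([1.0] * 30)
        assert len(top_percentile_probes(t, 5)) == 30

    def test_rank_enumeration_1_to_100(self):
        vals = list(range(1, 101))
        t = _track(vals, ids=[f"p{i}" for i in range(100)])
        top = top_percentile_probes(t, 5)
        got_vals = sorted(t.df.set_index("promoter_id").loc[[p for p, _ in top],
                                                            "value"])
        assert got_vals == [96, 97, 98, 99, 100]

    def test_bad_pct(self):
        with pytest.raises(ValueError):
            top_percentile_probes(_track([1.0] * 15), 0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(min_value=-745, max_value=745))
def test_bin_offset_nearest_multiple(o):
    b = bin_offset(o)
    assert b % 10 == 0
    assert abs(o - b) <= 5
    if abs(o) % 10 == 5:  # ties resolve toward zero
        assert abs(b) < abs(o)


class TestBuildProfile:
    def test_high_equals_all(self):
        probes = {(f"p{i}", o) for i in range(3) for o in range(-50, 60, 10)}
        prof = build_profile(probes, probes)
        assert (prof.table["fraction"] == 1.0).all()

    def test_availability_correction(self):
        high = {("a", 0)}
        all1 = {("a", 0), ("b", 1)}
        all2 = all1 | {("c", 2), ("d", 3)}
        f1 = build_profile(high, all1).table.set_index("bin_center")["fraction"][0]
        f2 = build_profile(high, all2).table.set_index("bin_center")["fraction"][0]
        assert f2 == pytest.approx(f1 / 2)

    def test_probe_conservation(self, rng):
        """Every high probe lands in exactly one bin."""
        offs = rng.integers(-750, 751, size=500)
        allp = {(f"p{i}", int(o)) for i, o in enumerate(offs)}
        high = set(list(allp)[::3])
        t = build_profile(high, allp).table
        assert t["high"].sum() == len(high)
        assert t["available"].sum() == len(allp)

    def test_subset_required(self):
        with pytest.raises(ValueError):
            build_profile({("a", 0)}, {("b", 0)})

    def test_max1_mode(self, rng):
        offs = rng.integers(-100, 100, size=200)
        allp = {(f"p{i}", int(o)) for i, o in enumerate(offs)}
        high = set(list(allp)[:50])
        prof = build_profile(high, allp, mode="max1")
        assert prof.table["fraction"].max() == pytest.approx(1.0)


def test_all_probes_roundtrip(top100_cohort):
    t = track_from_signals(top100_cohort.signals, "NC2", 2)
    assert len(all_probes(t)) == 15 * len(top100_cohort.promoters)
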