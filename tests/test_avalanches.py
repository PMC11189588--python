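"""Avalanche detection, branching ratios, and transition matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from avakit import (
    Avalanche,
    BinaryRaster,
    RoiTimeSeries,
    binarize,
    branching_ratio,
    branching_ratio_avalanche,
    compute_atm,
    detect_avalanches,
    rebin,
    select_bin_size,
)


def make_raster(bits, segments=None, fs=250.0):
    bits = np.asarray(bits, dtype=np.uint8)
    return BinaryRaster(bits=bits, fs=fs, segment_bounds=segments)


def brute_force_avalanches(bits, segments, min_duration):
    """Enumerate every maximal nonzero-column run, per segment."""
    out = []
    for a, b in segments:
        t = a
        while t < b:
            if bits[:, t].any():
                s = t
                while t < b and bits[:, t].any():
                    t += 1
                if s > a and t < b and t - s >= min_duration:
                    out.append((s, t))
            else:
                t += 1
    return out


class TestBinarize:
    def test_excursion_rule_both_signs(self):
        # Any sample whose z-score magnitude exceeds the threshold is active.
        rng = np.random.default_rng(0)
        data = rng.normal(size=(3, 500))
        ts = RoiTimeSeries(data, 250.0, ["a", "b", "c"])
        raster = binarize(ts, 2.0)
        z = (data - data.mean(1, keepdims=True)) / data.std(1, keepdims=True)
        np.testing.assert_array_equal(raster.bits, (np.abs(z) > 2.0).astype(np.uint8))
        assert raster.bin_size == 1
        assert raster.threshold_z == 2.0

    def test_gaussian_tail_rate(self):
        # Fraction of active samples matches the two-sided normal tail.
        rng = np.random.default_rng(7)
        n = 200_000
        ts = RoiTimeSeries(rng.normal(size=(3, n)), 250.0, list("abc"))
        frac = binarize(ts, 3.0).bits.mean()
        expect = 2 * norm.cdf(-3.0)
        tol = 4 * np.sqrt(expect / (3 * n))  # ~4 binomial SDs
        assert abs(frac - expect) < tol

    def test_zero_variance_roi_named(self):
        data = np.vstack([np.zeros(100), np.random.default_rng(0).normal(size=100)])
        ts = RoiTimeSeries(data, 250.0, ["flatline", "ok"])
        with pytest.raises(ValueError, match="flatline"):
            binarize(ts, 2.0)

    def test_nonfinite_rejected_by_container(self):
        data = np.ones((2, 100))
        data[0, 3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            RoiTimeSeries(data, 250.0, ["a", "b"])

    def test_threshold_must_be_positive(self):
        ts = RoiTimeSeries(np.random.default_rng(0).normal(size=(2, 50)), 250.0, ["a", "b"])
        with pytest.raises(ValueError):
            binarize(ts, 0.0)


class TestRebin:
    def test_or_aggregation(self):
        raster = make_raster([[0, 1, 0, 0, 1, 1]])
        np.testing.assert_array_equal(rebin(raster, 2).bits, [[1, 0, 1]])

    def test_identity_at_bin_one(self):
        raster = make_raster(np.random.default_rng(0).integers(0, 2, (3, 20)))
        assert rebin(raster, 1) is raster

    def test_trailing_partial_bin_dropped(self):
        raster = make_raster([[1, 0, 0, 0, 0, 0, 1]])
        out = rebin(raster, 2)
        assert out.n_bins == 3  # 7th sample discarded
        np.testing.assert_array_equal(out.bits, [[1, 0, 0]])

    def test_binning_restarts_at_segment_boundaries(self):
        bits = [[0, 1, 1, 0, 0, 1, 0]]
        raster = make_raster(bits, segments=[(0, 3), (3, 7)])
        out = rebin(raster, 2)
        # segment 1: samples (0,1) -> 1, sample 2 dropped; segment 2: (3,4),(5,6)
        np.testing.assert_array_equal(out.bits, [[1, 0, 1]])
        assert out.segment_bounds == [(0, 1), (1, 3)]

    def test_invalid_bin_size(self):
        with pytest.raises(ValueError):
            rebin(make_raster([[1, 0]]), 0)


class TestDetectAvalanches:
    def test_single_avalanche_structure(self):
        bits = np.array([[0, 1, 1, 0], [0, 0, 1, 0]])
        avs = detect_avalanches(make_raster(bits), 1)
        assert len(avs) == 1
        av = avs[0]
        assert (av.start_bin, av.end_bin) == (1, 3)
        np.testing.assert_array_equal(av.events_per_bin, [1, 2])
        assert [list(s) for s in av.active_sets] == [[0], [0, 1]]

    def test_all_zero_raster(self):
        assert detect_avalanches(make_raster(np.zeros((3, 10))), 1) == []

    def test_runs_touching_edges_dropped(self):
        bits = np.array([[1, 0, 1, 0, 1]])
        avs = detect_avalanches(make_raster(bits), 1)
        assert [(a.start_bin, a.end_bin) for a in avs] == [(2, 3)]

    def test_segment_boundaries_split_runs(self):
        bits = np.array([[0, 1, 1, 1, 0, 0]])
        whole = detect_avalanches(make_raster(bits), 1)
        assert [(a.start_bin, a.end_bin) for a in whole] == [(1, 4)]
        # A boundary inside the run leaves two edge-touching halves: dropped.
        split = detect_avalanches(make_raster(bits, segments=[(0, 2), (2, 6)]), 1)
        assert split == []

    def test_min_duration_filter(self):
        bits = np.array([[0, 1, 0, 1, 1, 0]])
        avs = detect_avalanches(make_raster(bits), 2)
        assert [(a.start_bin, a.end_bin) for a in avs] == [(3, 5)]

    @pytest.mark.parametrize("min_duration", [1, 2, 3])
    def test_matches_brute_force_oracle(self, min_duration):
        rng = np.random.default_rng(min_duration)
        for _ in range(300):
            n_rois = rng.integers(1, 7)
            n_bins = rng.integers(1, 13)
            bits = (rng.random((n_rois, n_bins)) < 0.35).astype(np.uint8)
            cut = int(rng.integers(1, n_bins)) if n_bins > 1 else None
            segments = [(0, cut), (cut, n_bins)] if cut else [(0, n_bins)]
            raster = make_raster(bits, segments=segments)
            got = [(a.start_bin, a.end_bin) for a in detect_avalanches(raster, min_duration)]
            assert got == brute_force_avalanches(bits, segments, min_duration)


class TestBranchingRatio:
    @pytest.mark.parametrize(
        "events,expected",
        [([1, 2], 2.0), ([2, 2, 2], 1.0), ([1, 3, 2], np.sqrt(2.0))],
    )
    def test_hand_computed_cases(self, events, expected):
        av = Avalanche(0, len(events), [np.arange(k) for k in events])
        assert branching_ratio_avalanche(av) == pytest.approx(expected, abs=1e-12)

    def test_single_bin_avalanche_rejected(self):
        av = Avalanche(0, 1, [np.array([0])])
        with pytest.raises(ValueError):
            branching_ratio_avalanche(av)

    @given(st.lists(st.integers(min_value=1, max_value=60), min_size=2, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_closed_form_equals_bin_by_bin_product(self, events):
        # The implementation must agree with the literal geometric product.
        av = Avalanche(0, len(events), [np.arange(k) for k in events])
        n = np.array(events, dtype=float)
        product = float(np.prod((n[1:] / n[:-1]) ** (1.0 / (len(n) - 1))))
        assert branching_ratio_avalanche(av) == pytest.approx(product, rel=1e-12)

    def test_geometric_mean_over_avalanches(self):
        avs = [
            Avalanche(0, 2, [np.array([0]), np.array([0, 1])]),  # sigma 2
            Avalanche(3, 5, [np.array([0, 1]), np.array([0])]),  # sigma 0.5
        ]
        est = branching_ratio(avs)
        assert est.sigma == pytest.approx(1.0, abs=1e-12)
        assert est.n_avalanches == 2

    def test_single_avalanche_passthrough_and_singletons_excluded(self):
        avs = [
            Avalanche(0, 1, [np.array([0])]),  # excluded (1 bin)
            Avalanche(2, 4, [np.array([0]), np.array([0, 1])]),
        ]
        est = branching_ratio(avs)
        assert est.sigma == pytest.approx(2.0)
        assert est.n_avalanches == 1

    def test_error_without_multi_bin_avalanche(self):
        with pytest.raises(ValueError):
            branching_ratio([Avalanche(0, 1, [np.array([0])])])


class TestSelectBinSize:
    def test_prefers_sigma_closest_to_one(self, monkeypatch):
        import avakit.avalanches as mod

        sigma_by_bin = {1: 1.0, 2: 1.3}
        monkeypatch.setattr(
            mod,
            "branching_ratio",
            lambda avs, bin_size=1: type(
                "E", (), {"sigma": sigma_by_bin[bin_size]}
            )(),
        )
        raster = make_raster(np.array([[0, 1, 1, 0] * 5]))
        assert select_bin_size(raster, [1, 2]) == 1

    def test_tie_broken_toward_smaller_bin(self, monkeypatch):
        import avakit.avalanches as mod

        sigma_by_bin = {1: 1.2, 2: 0.8}
        monkeypatch.setattr(
            mod,
            "branching_ratio",
            lambda avs, bin_size=1: type(
                "E", (), {"sigma": sigma_by_bin[bin_size]}
            )(),
        )
        raster = make_raster(np.array([[0, 1, 1, 0] * 5]))
        assert select_bin_size(raster, [2, 1]) == 1

    def test_all_candidates_skipped(self):
        raster = make_raster(np.zeros((2, 12)))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                select_bin_size(raster, [1, 2])


class TestTransitionMatrix:
    def test_single_ancestor_bin(self):
        av = Avalanche(0, 2, [np.array([0]), np.array([0, 1])])
        atm = compute_atm([av], 2)
        np.testing.assert_allclose(atm.probs, [[1, 1], [0, 0]])
        np.testing.assert_array_equal(atm.ancestor_counts, [1, 0])

    def test_alternating_activity(self):
        av = Avalanche(0, 3, [np.array([0]), np.array([1]), np.array([0])])
        atm = compute_atm([av], 2)
        np.testing.assert_allclose(atm.probs, [[0, 1], [1, 0]])

    def test_elementwise_mean_across_avalanches(self):
        avs = [
            Avalanche(0, 2, [np.array([0]), np.array([0, 1])]),
            Avalanche(3, 6, [np.array([0]), np.array([1]), np.array([0])]),
        ]
        atm = compute_atm(avs, 2)
        np.testing.assert_allclose(atm.probs, [[0.5, 1], [0.5, 0]])
        assert atm.n_avalanches_averaged == 2

    def test_entries_in_unit_interval_and_silent_rows_zero(self, rng):
        bits = (rng.random((5, 400)) < 0.1).astype(np.uint8)
        bits[3] = 0  # ROI 3 never active
        avs = detect_avalanches(make_raster(bits), 2)
        atm = compute_atm(avs, 5)
        assert ((atm.probs >= 0) & (atm.probs <= 1)).all()
        assert (atm.probs[3] == 0).all()

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_roi_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        bits = (rng.random((5, 60)) < 0.25).astype(np.uint8)
        avs = detect_avalanches(make_raster(bits), 2)
        if not avs:
            return
        perm = rng.permutation(5)
        avs_p = detect_avalanches(make_raster(bits[perm]), 2)
        atm = compute_atm(avs, 5)
        atm_p = compute_atm(avs_p, 5)
        np.testing.assert_allclose(atm_p.probs, atm.probs[np.ix_(perm, perm)], atol=1e-12)

    def test_binary_mode_counts_occurrence(self):
        # Two ancestor bins, transition 0->1 happens once: conditional 0.5, binary 1.
        av = Avalanche(0, 3, [np.array([0]), np.array([0, 1]), np.array([0])])
        cond = compute_atm([av], 2, mode="conditional")
        binr = compute_atm([av], 2, mode="binary")
        assert cond.probs[0, 1] == pytest.approx(0.5)
        assert binr.probs[0, 1] == 1.0

    def test_errors(self):
        with pytest.raises(ValueError):
            compute_atm([], 2)
        av = Avalanche(0, 1, [np.array([0])])
        with pytest.raises(ValueError):
            compute_atm([av], 2, delta_bins=1)
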