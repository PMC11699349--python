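"""Avalanche extraction: z-scoring, thresholding, segmentation, branching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from avafp.avalanche import (
    Avalanche,
    BinaryRaster,
    binarize,
    branching_ratio,
    coarse_grain,
    detect_avalanches,
    pick_scale,
    segment_sessions,
    select_scale,
    zscore_series,
)
from .conftest import make_recording


def raster_from(data):
    data = np.asarray(data, dtype=np.uint8)
    return BinaryRaster(data=data, bin_ms=4.0)


class TestZscore:
    def test_hand_example(self):
        rec = make_recording([[1.0, 3.0], [0.0, 2.0]], fs=2.0)
        z = zscore_series(rec)
        np.testing.assert_allclose(z.data, [[-1.0, 1.0], [-1.0, 1.0]])

    def test_standardized_region_unchanged(self, rng):
        x = rng.standard_normal(400)
        x = (x - x.mean()) / x.std()
        rec = make_recording([x], fs=10.0)
        np.testing.assert_allclose(zscore_series(rec).data[0], x, atol=1e-9)

    def test_output_moments(self, rng):
        rec = make_recording(3 + 5 * rng.standard_normal((4, 300)), fs=10.0)
        z = zscore_series(rec)
        np.testing.assert_allclose(z.data.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.data.std(axis=1), 1, rtol=1e-9)

    def test_constant_region_errors(self):
        rec = make_recording([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]], fs=2.0)
        with pytest.raises(ValueError, match="r0"):
            zscore_series(rec)


class TestBinarize:
    def test_hand_row(self):
        rec = make_recording([[0.5, -3.0, 2.9, 1.0]], fs=4.0)
        raster = binarize(rec, thresh=2.8)
        np.testing.assert_array_equal(raster.data, [[0, 1, 1, 0]])
        assert raster.bin_ms == 250.0

    def test_strict_inequality_at_threshold(self):
        rec = make_recording([[2.8, -2.8, 2.8001, 0.0]], fs=4.0)
        np.testing.assert_array_equal(binarize(rec, 2.8).data, [[0, 0, 1, 0]])

    def test_gaussian_tail_fraction(self, rng):
        # two-tailed N(0,1) mass beyond 2.8 SD: 2*(1 - Phi(2.8)) ~ 0.00511
        from scipy.stats import norm

        n = 400_000
        rec = make_recording(rng.standard_normal((1, n)), fs=100.0)
        frac = binarize(zscore_series(rec), 2.8).data.mean()
        expect = 2 * (1 - norm.cdf(2.8))
        assert abs(frac - expect) < 4 * np.sqrt(expect * (1 - expect) / n)

    def test_sign_symmetry(self, rng):
        rec = make_recording(rng.standard_normal((3, 200)), fs=10.0)
        a = binarize(rec, 1.5).data
        neg = make_recording(-rec.data, fs=10.0)
        np.testing.assert_array_equal(a, binarize(neg, 1.5).data)

    def test_nonpositive_threshold_rejected(self):
        rec = make_recording([[0.0, 1.0]], fs=2.0)
        with pytest.raises(ValueError):
            binarize(rec, 0.0)


class TestCoarseGrain:
    @pytest.mark.parametrize(
        "row, k, expected",
        [
            ([1, 0, 0, 0, 0, 1], 2, [1, 0, 1]),
            ([0, 0, 0, 0], 2, [0, 0]),
            ([1, 1, 1, 1, 1, 1, 1], 3, [1, 1]),  # trailing partial dropped
        ],
    )
    def test_examples(self, row, k, expected):
        out = coarse_grain(raster_from([row]), k)
        np.testing.assert_array_equal(out.data, [expected])
        assert out.bin_ms == 4.0 * k
        assert out.scale == k

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            coarse_grain(raster_from([[1, 0]]), 1)


class TestDetect:
    def test_two_avalanches(self):
        raster = raster_from([[0, 1, 1, 0, 0, 1]])
        avs = detect_avalanches(raster)
        assert [(a.start_bin, a.end_bin) for a in avs] == [(1, 2), (5, 5)]
        assert avs[1].boundary_truncated

    def test_all_zero(self):
        assert detect_avalanches(raster_from([[0, 0], [0, 0]])) == []

    def test_nevents_counts(self):
        raster = raster_from([[0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 1, 0]])
        (av,) = detect_avalanches(raster)
        np.testing.assert_array_equal(av.nevents, [1, 2])
        np.testing.assert_array_equal(av.sub_raster, [[1, 0], [0, 1], [0, 1]])

    def test_drop_boundary(self):
        raster = raster_from([[1, 0, 1, 0]])
        assert len(detect_avalanches(raster, drop_boundary=True)) == 1

    @given(hst.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_partition_property(self, seed):
        # avalanches plus gaps exactly tile the any-active indicator
        r = np.random.default_rng(seed).random((5, 60)) < 0.2
        raster = raster_from(r.astype(np.uint8))
        avs = detect_avalanches(raster)
        rebuilt = np.zeros(60, dtype=bool)
        for a in avs:
            assert (a.nevents >= 1).all()
            rebuilt[a.start_bin : a.end_bin + 1] = True
        np.testing.assert_array_equal(rebuilt, raster.data.any(axis=0))


class TestBranchingRatio:
    @pytest.mark.parametrize(
        "sequences, expected",
        [
            ([[1, 2, 4]], 2.0),
            ([[2, 1]], 0.5),
            ([[1, 2], [2, 1]], 1.0),  # geometric mean of 2 and 0.5
        ],
    )
    def test_hand_examples(self, sequences, expected):
        avs = [Avalanche.from_nevents(s) for s in sequences]
        assert branching_ratio(avs).sigma == pytest.approx(expected, abs=1e-12)

    def test_single_bin_excluded(self):
        avs = [Avalanche.from_nevents(s) for s in ([3], [1, 2, 4])]
        est = branching_ratio(avs)
        assert est.n_used == 1 and est.n_single == 1
        assert est.sigma == pytest.approx(2.0)

    def test_undefined_without_multibin(self):
        with pytest.raises(ValueError, match="undefined"):
            branching_ratio([Avalanche.from_nevents([2])])

    def test_matches_log_domain_oracle(self, rng):
        # oracle: mean of log successive ratios per avalanche, exponentiated
        for _ in range(200):
            n_av = int(rng.integers(1, 8))
            avs = []
            for _ in range(n_av):
                length = int(rng.integers(2, 12))
                avs.append(Avalanche.from_nevents(rng.integers(1, 10, size=length)))
            logs = [
                np.mean(np.log(a.nevents[1:] / a.nevents[:-1])) for a in avs
            ]
            oracle = np.exp(np.mean(logs))
            assert branching_ratio(avs).sigma == pytest.approx(oracle, abs=1e-12)


class TestScaleSelection:
    @pytest.mark.parametrize(
        "sigmas, expected",
        [
            ({1: 0.98, 2: 1.3, 3: 1.6}, 1),
            ({1: 1.06, 2: 0.95, 3: 1.2}, 2),
            ({1: 0.9, 2: 1.1, 3: 1.3}, 1),  # tie toward the smaller scale
        ],
    )
    def test_pick_scale(self, sigmas, expected):
        assert pick_scale(sigmas) == expected

    def test_select_scale_returns_estimates(self, rng):
        r = (rng.random((6, 240)) < 0.25).astype(np.uint8)
        scale, estimates = select_scale(raster_from(r))
        assert scale in estimates and set(estimates) <= {1, 2, 3}
        best = min(estimates, key=lambda k: (abs(estimates[k].sigma - 1), k))
        assert scale == best


class TestPermutationEquivariance:
    def test_roi_permutation(self, rng):
        data = rng.standard_normal((6, 400))
        rec = make_recording(data, fs=10.0)
        perm = rng.permutation(6)
        rec_p = make_recording(data[perm], fs=10.0)
        r1 = binarize(zscore_series(rec), 2.0)
        r2 = binarize(zscore_series(rec_p), 2.0)
        np.testing.assert_array_equal(r1.data[perm], r2.data)
        a1, a2 = detect_avalanches(r1), detect_avalanches(r2)
        assert len(a1) == len(a2)
        for x, y in zip(a1, a2):
            np.testing.assert_array_equal(x.nevents, y.nevents)
        if any(a.n_bins >= 2 for a in a1):
            assert branching_ratio(a1).sigma == pytest.approx(
                branching_ratio(a2).sigma, abs=1e-12
            )


class TestSegmentSessions:
    def _rec(self, n_s, fs=10.0, rng=None):
        rng = rng or np.random.default_rng(0)
        return make_recording(rng.standard_normal((2, int(n_s * fs))), fs=fs)

    def test_exact_halves_when_zero_slack(self):
        rec = self._rec(360)
        t, r = segment_sessions(rec, trial_s=180, use_s=180, seed=0)
        np.testing.assert_array_equal(t.data, rec.data[:, :1800])
        np.testing.assert_array_equal(r.data, rec.data[:, 1800:3600])
        assert (t.session, r.session) == ("test", "retest")

    def test_deterministic_windows(self):
        rec = self._rec(360)
        a = segment_sessions(rec, 180, 100, seed=42)
        b = segment_sessions(rec, 180, 100, seed=42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.data, y.data)
        assert a[0].n_samples == 1000

    def test_too_short_recording(self):
        with pytest.raises(ValueError, match="3600"):
            segment_sessions(self._rec(300), trial_s=180, use_s=100, seed=0)
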