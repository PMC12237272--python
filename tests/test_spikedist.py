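"""Tests for the rate-independent SPIKE-distance.

The independent oracle evaluates the corner-spike definitions directly on
a dense time grid (0.01 ms) and integrates by the trapezoid rule; the
implementation's piecewise-exact profiles and integrals are checked
against it on randomized train pairs.
"""

import numpy as np
import pytest

from freqdisc.fra import extract_fra_metrics
from freqdisc.spikedist import (
    delta_distance_vs_cf,
    multitrain_distance,
    pair_distance,
    pair_profile,
)

WINDOW = (0.0, 100.0)


# ---------------------------------------------------------------------------
# dense-grid brute-force oracle
# ---------------------------------------------------------------------------

def _aug(times, t0, t1):
    return np.unique(np.concatenate([[t0], np.asarray(times, float), [t1]]))


def brute_profile(train1, train2, window, ts):
    """Direct evaluation of the corner-spike dissimilarity at times ts."""
    t0, t1 = window
    a1, a2 = _aug(train1, t0, t1), _aug(train2, t0, t1)

    def one_side(a, other):
        tP = a[np.searchsorted(a, ts, side="right") - 1]
        idx = np.minimum(np.searchsorted(a, ts, side="left"), a.size - 1)
        tF = a[idx]
        tF = np.where(tF < ts, a[-1], tF)

        def nearest(p):
            j = np.searchsorted(other, p)
            r = np.abs(other[np.clip(j, 0, other.size - 1)] - p)
            l = np.abs(other[np.clip(j - 1, 0, other.size - 1)] - p)
            return np.minimum(r, l)

        dtP, dtF = nearest(tP), nearest(tF)
        x_isi = tF - tP
        s = (dtP * (tF - ts) + dtF * (ts - tP)) / x_isi
        return s, x_isi

    s1, x1 = one_side(a1, a2)
    s2, x2 = one_side(a2, a1)
    return (s1 + s2) / (x1 + x2)  # = (S1 + S2) / (2 <x_ISI>)


def brute_distance(train1, train2, window, dt=0.01):
    t0, t1 = window
    ts = np.arange(t0 + dt / 2, t1, dt)
    return np.trapezoid(brute_profile(train1, train2, window, ts), ts) / (t1 - t0)


def _random_pairs(n_pairs, max_spikes=10, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n_pairs):
        n1, n2 = rng.integers(0, max_spikes + 1, 2)
        yield (
            np.sort(rng.uniform(*WINDOW, n1)),
            np.sort(rng.uniform(*WINDOW, n2)),
        )


class TestPairProfile:
    def test_identical_trains_give_zero_profile_and_distance(self):
        t = np.array([5.0, 30.0, 31.5, 90.0])
        prof = pair_profile(t, t, WINDOW)
        assert np.all(prof.s_start == 0.0) and np.all(prof.s_end == 0.0)
        assert pair_distance(t, t, WINDOW) == 0.0

    def test_symmetry_in_arguments(self):
        a = np.array([10.0, 42.0, 43.0])
        b = np.array([12.0, 70.0])
        pab, pba = pair_profile(a, b, WINDOW), pair_profile(b, a, WINDOW)
        np.testing.assert_allclose(pab.s_start, pba.s_start)
        np.testing.assert_allclose(pab.s_end, pba.s_end)

    def test_profile_matches_dense_brute_force_pointwise(self):
        a, b = np.array([20.0]), np.array([30.0])
        ts = np.arange(0.005, 100.0, 0.01)
        prof = pair_profile(a, b, WINDOW)
        np.testing.assert_allclose(prof.value(ts), brute_profile(a, b, WINDOW, ts), atol=1e-3)

    def test_profile_nonnegative_and_piecewise_on_spikes(self):
        for a, b in _random_pairs(20, seed=3):
            prof = pair_profile(a, b, WINDOW)
            assert np.all(prof.s_start >= 0) and np.all(prof.s_end >= 0)
            events = np.unique(np.concatenate([[0.0], a, b, [100.0]]))
            np.testing.assert_allclose(prof.seg_start, events[:-1])

    def test_empty_window_is_an_error(self):
        with pytest.raises(ValueError, match="window"):
            pair_profile([1.0], [2.0], (50.0, 50.0))

    def test_exact_integral_matches_brute_force_on_random_pairs(self):
        for a, b in _random_pairs(40, seed=5):
            assert pair_distance(a, b, WINDOW) == pytest.approx(
                brute_distance(a, b, WINDOW), abs=1e-3
            )

    def test_time_rescaling_invariance(self):
        for s in (0.1, 3.0, 1000.0):
            for a, b in _random_pairs(10, seed=8):
                d0 = pair_distance(a, b, WINDOW)
                d1 = pair_distance(a * s, b * s, (0.0, 100.0 * s))
                assert d1 == pytest.approx(d0, abs=1e-6)


class TestMultitrain:
    def test_identical_trains_give_zero(self):
        t = np.array([10.0, 50.0])
        res = multitrain_distance([t, t, t, t], WINDOW)
        assert res.D == 0.0

    def test_two_trains_reduce_to_pair_distance(self):
        a, b = np.array([20.0, 60.0]), np.array([25.0])
        res = multitrain_distance([a, b], WINDOW)
        assert res.D == pytest.approx(pair_distance(a, b, WINDOW), abs=1e-12)

    def test_mean_of_pairwise_distances(self):
        rng = np.random.default_rng(4)
        trains = [np.sort(rng.uniform(*WINDOW, 6)) for _ in range(3)]
        res = multitrain_distance(trains, WINDOW, return_pair_matrix=True)
        pairs = [
            pair_distance(trains[i], trains[j], WINDOW)
            for i in range(3) for j in range(i + 1, 3)
        ]
        assert res.D == pytest.approx(np.mean(pairs), abs=1e-9)
        assert res.pair_matrix[0, 1] == pytest.approx(pairs[0])

    def test_train_order_invariance(self):
        rng = np.random.default_rng(9)
        trains = [np.sort(rng.uniform(*WINDOW, 5)) for _ in range(4)]
        d1 = multitrain_distance(trains, WINDOW).D
        d2 = multitrain_distance(trains[::-1], WINDOW).D
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_single_train_is_an_error(self):
        with pytest.raises(ValueError, match="two"):
            multitrain_distance([np.array([1.0])], WINDOW)


class TestDeltaDistance:
    def test_zero_at_cf_and_positive_trend(self, small_matrix):
        fm = extract_fra_metrics(small_matrix)
        df = delta_distance_vs_cf(small_matrix, fm, max_octaves=1.2)
        at_cf = df[df["octave_distance"] == 0.0]
        assert len(at_cf) == 1 and at_cf["delta_distance"].iloc[0] == 0.0
        # strongly driven CF trains vs remote baseline trains: delta at the
        # largest separation exceeds delta at the smallest
        df = df.assign(absd=df["octave_distance"].abs())
        far = df.loc[df["absd"] == df["absd"].max(), "delta_distance"].mean()
        near = df.loc[df["absd"] == df[df["absd"] > 0]["absd"].min(), "delta_distance"].mean()
        assert far > near

    def test_pool_and_cross_methods_agree_at_cf(self, small_matrix):
        fm = extract_fra_metrics(small_matrix)
        for method in ("pool", "cross"):
            df = delta_distance_vs_cf(small_matrix, fm, method=method)
            assert df.loc[df["octave_distance"] == 0.0, "delta_distance"].iloc[0] == 0.0

    def test_unresolved_cf_is_skipped_with_error(self, small_matrix):
        from freqdisc.fra import FRAMetrics

        fm = FRAMetrics(unit_id="x", cf_khz=None, min_threshold_db=None)
        with pytest.raises(ValueError, match="skip"):
            delta_distance_vs_cf(small_matrix, fm)

    def test_unknown_method_raises(self, small_matrix):
        fm = extract_fra_metrics(small_matrix)
        with pytest.raises(ValueError, match="method"):
            delta_distance_vs_cf(small_matrix, fm, method="average")
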