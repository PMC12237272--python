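"""Rate-independent SPIKE-distance between spike trains.

Time-resolved dissimilarity between spike trains, built from corner-spike
differences.  For a pair of trains and a time t, with t_P/t_F the
preceding/following spike of a train (after adding auxiliary spikes at the
window edges), x_P = t - t_P, x_F = t_F - t, x_ISI = t_F - t_P, and
Delta t_P / Delta t_F the distances from t_P / t_F to the nearest spike of
the other train, each train contributes

    S_n(t) = (Delta t_P * x_F + Delta t_F * x_P) / x_ISI .

The rate-independent profile leaves these contributions unweighted by the
local interspike intervals and normalizes by the mean ISI of the pair:

    S'(t) = (S_1(t) + S_2(t)) / (2 <x_ISI>)

which is dimensionless and invariant under a common rescaling of time.
For N > 2 trains the instantaneous profile is the average over all
N(N-1)/2 pairs, and the scalar distance is its time average,
D = (1/T) * integral of S_a(t) dt.  All profiles are piecewise linear
between spikes, so the integral is computed exactly segment by segment.

The dissimilarity-vs-frequency analysis (:func:`delta_distance_vs_cf`)
pools the 30 trains at a unit's CF with the 30 trains of a neighboring
frequency (at 40 dB above minimum threshold) and reports the pooled
distance in excess of the within-CF baseline, as a function of octave
distance from CF.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import SpikeTrain, TuningMatrix
from .fra import FRAMetrics

__all__ = [
    "DissimilarityProfile",
    "SpikeDistanceResult",
    "pair_profile",
    "pair_distance",
    "multitrain_distance",
    "delta_distance_vs_cf",
    "DEFAULT_DISTANCE_WINDOW",
]

#: Default integration window (ms re stimulus onset) for evoked analyses.
DEFAULT_DISTANCE_WINDOW = (0.0, 100.0)


def _as_times(train) -> np.ndarray:
    if isinstance(train, SpikeTrain):
        return train.times
    return np.asarray(train, dtype=float)


def _augment(times: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Clip to the window and add auxiliary edge spikes at t0 and t1."""
    t = times[(times >= t0) & (times <= t1)]
    return np.unique(np.concatenate([[t0], t, [t1]]))


def _nearest_dist(points: np.ndarray, arr: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest element of sorted ``arr``."""
    j = np.searchsorted(arr, points)
    right = np.abs(arr[np.clip(j, 0, arr.size - 1)] - points)
    left = np.abs(arr[np.clip(j - 1, 0, arr.size - 1)] - points)
    return np.minimum(right, left)


def _segment_terms(a: np.ndarray, other: np.ndarray, u: np.ndarray, v: np.ndarray):
    """Per-segment corner terms for one train against the other train.

    Segments (u, v) contain no spikes of either train in their interior,
    so t_P, t_F and the corner differences are constant per segment.
    """
    tP = a[np.searchsorted(a, u, side="right") - 1]
    tF = a[np.searchsorted(a, v, side="left")]
    dtP = _nearest_dist(tP, other)
    dtF = _nearest_dist(tF, other)
    xisi = tF - tP
    s_u = (dtP * (tF - u) + dtF * (u - tP)) / xisi
    s_v = (dtP * (tF - v) + dtF * (v - tP)) / xisi
    return tP, tF, dtP, dtF, xisi, s_u, s_v


def _pair_arrays(a1: np.ndarray, a2: np.ndarray):
    """Segment breakpoints and rate-independent profile values for a pair.

    Returns (u, v, s_u, s_v, terms1, terms2) with the profile evaluated at
    the interior limits of each segment.
    """
    events = np.unique(np.concatenate([a1, a2]))
    u, v = events[:-1], events[1:]
    t1 = _segment_terms(a1, a2, u, v)
    t2 = _segment_terms(a2, a1, u, v)
    denom = t1[4] + t2[4]  # 2 * mean ISI
    s_u = (t1[5] + t2[5]) / denom
    s_v = (t1[6] + t2[6]) / denom
    return u, v, s_u, s_v, t1, t2


def pair_distance(train1, train2, window=DEFAULT_DISTANCE_WINDOW) -> float:
    """Exact time-averaged rate-independent SPIKE-distance for one pair."""
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("empty window")
    a1 = _augment(_as_times(train1), t0, t1)
    a2 = _augment(_as_times(train2), t0, t1)
    u, v, s_u, s_v, _, _ = _pair_arrays(a1, a2)
    integral = float(np.sum(0.5 * (s_u + s_v) * (v - u)))
    return integral / (t1 - t0)


@dataclass
class DissimilarityProfile:
    """Piecewise-linear dissimilarity profile S'(t) for one train pair.

    ``seg_start``/``seg_end`` bound each linear segment; ``s_start`` and
    ``s_end`` are the profile's one-sided limits inside the segment.
    ``components`` holds the per-train corner terms per segment
    (t_P, t_F, Delta t_P, Delta t_F, x_ISI).
    """

    window: tuple[float, float]
    seg_start: np.ndarray
    seg_end: np.ndarray
    s_start: np.ndarray
    s_end: np.ndarray
    components: dict

    def value(self, t) -> np.ndarray:
        """Evaluate S'(t) (right-continuous at segment starts)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.clip(
            np.searchsorted(self.seg_start, t, side="right") - 1,
            0,
            self.seg_start.size - 1,
        )
        u = self.seg_start[idx]
        v = self.seg_end[idx]
        frac = np.where(v > u, (t - u) / (v - u), 0.0)
        return self.s_start[idx] + frac * (self.s_end[idx] - self.s_start[idx])

    @property
    def distance(self) -> float:
        """Exact time average of the profile over the window."""
        seg = self.seg_end - self.seg_start
        return float(
            np.sum(0.5 * (self.s_start + self.s_end) * seg)
            / (self.window[1] - self.window[0])
        )


def pair_profile(train1, train2, window=DEFAULT_DISTANCE_WINDOW) -> DissimilarityProfile:
    """Rate-independent dissimilarity profile for one train pair.

    Symmetric in its arguments; identically zero for identical trains.
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("empty window")
    a1 = _augment(_as_times(train1), t0, t1)
    a2 = _augment(_as_times(train2), t0, t1)
    u, v, s_u, s_v, c1, c2 = _pair_arrays(a1, a2)
    components = {}
    for name, c in (("train1", c1), ("train2", c2)):
        components[name] = {
            "t_P": c[0], "t_F": c[1],
            "dt_P": c[2], "dt_F": c[3], "x_isi": c[4],
        }
    return DissimilarityProfile(
        window=(float(t0), float(t1)),
        seg_start=u, seg_end=v, s_start=s_u, s_end=s_v,
        components=components,
    )


@dataclass
class SpikeDistanceResult:
    D: float
    n_trains: int
    window: tuple[float, float]
    pair_matrix: np.ndarray | None = None


def multitrain_distance(
    trains, window=DEFAULT_DISTANCE_WINDOW, return_pair_matrix: bool = False
) -> SpikeDistanceResult:
    """Time-averaged multi-train dissimilarity.

    The instantaneous multi-train profile is the mean of the pairwise
    profiles over all N(N-1)/2 pairs; since averaging and time integration
    commute, D equals the mean of the exact pairwise distances, which is
    how it is computed here.
    """
    times = [_as_times(tr) for tr in trains]
    n = len(times)
    if n < 2:
        raise ValueError("need at least two spike trains")
    t0, t1 = window
    aug = [_augment(t, t0, t1) for t in times]
    pair_D = np.zeros((n, n))
    total = 0.0
    for i, j in combinations(range(n), 2):
        u, v, s_u, s_v, _, _ = _pair_arrays(aug[i], aug[j])
        d = float(np.sum(0.5 * (s_u + s_v) * (v - u))) / (t1 - t0)
        pair_D[i, j] = pair_D[j, i] = d
        total += d
    D = total / (n * (n - 1) / 2)
    return SpikeDistanceResult(
        D=D, n_trains=n, window=(float(t0), float(t1)),
        pair_matrix=pair_D if return_pair_matrix else None,
    )


def _pairwise_sums(aug_a: list, aug_b: list, window) -> float:
    """Sum of pair distances across two lists of augmented trains."""
    t0, t1 = window
    total = 0.0
    for a in aug_a:
        for b in aug_b:
            u, v, s_u, s_v, _, _ = _pair_arrays(a, b)
            total += float(np.sum(0.5 * (s_u + s_v) * (v - u))) / (t1 - t0)
    return total


def _within_sums(aug: list, window) -> float:
    t0, t1 = window
    total = 0.0
    for a, b in combinations(aug, 2):
        u, v, s_u, s_v, _, _ = _pair_arrays(a, b)
        total += float(np.sum(0.5 * (s_u + s_v) * (v - u))) / (t1 - t0)
    return total


def delta_distance_vs_cf(
    matrix: TuningMatrix,
    metrics: FRAMetrics,
    level_offset_db: float = 40.0,
    window=DEFAULT_DISTANCE_WINDOW,
    max_octaves: float = 1.0,
    method: str = "cross",
) -> pd.DataFrame:
    """Excess dissimilarity of neighboring-frequency trains relative to CF.

    At the row ``min_threshold + level_offset_db`` (snapped to the nearest
    tested row at or below), the 30 trains at CF are compared with the 30
    trains at each frequency within ``max_octaves`` of CF.  With
    ``method='cross'`` (default) the 30 x 30 cross-pair distance matrix
    between the CF block and the comparison block is averaged;
    ``method='pool'`` instead takes the 60-train pooled multi-train
    distance.  Either way the within-CF 30-train distance is subtracted,
    so the curve vanishes at zero separation.

    Returns a tidy frame: freq_khz, octave_distance (signed re CF),
    delta_distance, d_comparison, d_within_cf.
    """
    if method not in ("pool", "cross"):
        raise ValueError(f"unknown method {method!r}")
    if not metrics.resolved:
        raise ValueError(f"unit {matrix.unit_id}: CF unresolved; skip unit")
    t0, t1 = window
    target = metrics.min_threshold_db + level_offset_db
    at_or_below = np.nonzero(matrix.levels <= target + 1e-9)[0]
    level = float(matrix.levels[at_or_below[-1]])
    cf = metrics.cf_khz
    aug_by_freq = {}
    for f in matrix.freqs:
        if abs(np.log2(f / cf)) <= max_octaves + 1e-9:
            trains = matrix.cell(float(f), level).trains
            aug_by_freq[float(f)] = [_augment(tr.times, t0, t1) for tr in trains]
    aug_cf = aug_by_freq[cf]
    n = len(aug_cf)
    n_pairs_within = n * (n - 1) / 2
    sum_cf = _within_sums(aug_cf, window)
    d_cf = sum_cf / n_pairs_within
    rows = []
    for f, aug_f in aug_by_freq.items():
        if f == cf:
            rows.append((f, 0.0, 0.0, d_cf, d_cf))
            continue
        sum_cross = _pairwise_sums(aug_cf, aug_f, window)
        if method == "pool":
            sum_f = _within_sums(aug_f, window)
            m = 2 * n
            d_comp = (sum_cf + sum_f + sum_cross) / (m * (m - 1) / 2)
        else:
            d_comp = sum_cross / (n * len(aug_f))
        rows.append((f, float(np.log2(f / cf)), d_comp - d_cf, d_comp, d_cf))
    df = pd.DataFrame(
        rows,
        columns=["freq_khz", "octave_distance", "delta_distance",
                 "d_comparison", "d_within_cf"],
    ).sort_values("octave_distance", ignore_index=True)
    df.insert(0, "unit_id", matrix.unit_id)
    df.insert(1, "genotype", matrix.genotype_label)
    return df
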