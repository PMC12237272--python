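"""Synthetic tone-evoked recordings and Go/No-Go behavioral sessions.

The generator emulates the statistical structure the downstream analyses
assume, so that every pipeline stage is testable without animal data:

* V-shaped frequency response areas: each simulated multi-unit cluster has a
  characteristic frequency (CF), a minimum threshold, and an excitatory
  region whose half-width (in octaves) grows linearly with level above
  threshold.  Spiking is inhomogeneous Poisson: a constant baseline rate
  throughout the analysis window plus an evoked rate confined to
  [latency, latency + duration] and scaled by a triangular profile in
  log-frequency.
* Genotype-like regimes: wild-type-like (all scales 1) versus knockout-like
  cortical regimes with elevated spontaneous rate, elevated evoked gain and
  broadened tuning, applied as multiplicative scales on a base population.
* Go/No-Go sessions: detection sessions (Go + ~30% catch trials) driven by a
  logistic d'-vs-level psychometric, and discrimination sessions (50:50
  Go/No-Go, No-Go tones in 1/12-octave steps up to 1 octave from the Go
  tone) driven by a sigmoid false-alarm-vs-octave-distance curve.

All generators are bit-reproducible for a fixed (seed, configuration).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import (
    DEFAULT_N_TRIALS,
    DEFAULT_WINDOW,
    SpikeTrain,
    SpikeTrainSet,
    TuningMatrix,
    default_freq_grid,
    default_level_grid,
)

__all__ = [
    "UnitGenParams",
    "GenotypeRegime",
    "BehaviorGenParams",
    "gen_unit_population",
    "gen_tuning_matrix",
    "gen_behavior_session",
    "WT_LIKE",
    "KO_ACX_LIKE",
    "KO_IC_LIKE",
]


@dataclass(frozen=True)
class UnitGenParams:
    """Generative parameters for one simulated multi-unit cluster.

    ``v_slope_oct_per_db`` is the growth of the excitatory half-width with
    level above threshold; if None it is derived from
    ``bw_octaves_at_40db`` (the nominal full bandwidth 40 dB above
    threshold) and ``min_halfwidth_oct`` (the half-width at threshold,
    kept nonzero so the nearest grid frequency responds at threshold).
    """

    cf_khz: float
    baseline_rate: float = 10.0  # spikes/s, multi-unit spontaneous activity
    peak_evoked_rate: float = 200.0  # spikes/s above baseline at CF, 40 dB above threshold
    min_threshold_db: float = 20.0
    bw_octaves_at_40db: float = 1.1
    v_slope_oct_per_db: float | None = None
    latency_ms: float = 15.0
    evoked_duration_ms: float = 25.0
    min_halfwidth_oct: float = 0.25
    onset_fraction: float = 0.5  # evoked amplitude at threshold, fraction of peak

    def __post_init__(self):
        if self.baseline_rate < 0 or self.peak_evoked_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.bw_octaves_at_40db <= 0:
            raise ValueError("bw_octaves_at_40db must be positive")
        if self.v_slope_oct_per_db is None:
            slope = (self.bw_octaves_at_40db / 2.0 - self.min_halfwidth_oct) / 40.0
            object.__setattr__(self, "v_slope_oct_per_db", max(slope, 0.0))

    def halfwidth_oct(self, level_db: float) -> float:
        """Excitatory half-width (octaves) at a level; 0 below threshold."""
        if level_db < self.min_threshold_db:
            return 0.0
        return self.min_halfwidth_oct + self.v_slope_oct_per_db * (
            level_db - self.min_threshold_db
        )

    def evoked_rate(self, freq_khz: float, level_db: float) -> float:
        """Evoked rate (spikes/s above baseline) during the evoked interval."""
        if level_db < self.min_threshold_db:
            return 0.0
        hw = self.halfwidth_oct(level_db)
        dist = abs(np.log2(freq_khz / self.cf_khz))
        if dist > hw:
            return 0.0
        amp = self.peak_evoked_rate * min(
            1.0,
            self.onset_fraction
            + (1.0 - self.onset_fraction) * (level_db - self.min_threshold_db) / 40.0,
        )
        return amp * (1.0 - dist / hw)


@dataclass(frozen=True)
class GenotypeRegime:
    """Multiplicative scales applied to a base unit population.

    The knockout-cortex-like default regime has elevated spontaneous rate,
    elevated evoked gain and broadened tuning; midbrain-like regimes leave
    all scales at 1.
    """

    label: str
    spont_scale: float = 1.0
    evoked_scale: float = 1.0
    width_scale: float = 1.0
    n_units: int = 12
    cf_range_khz: tuple[float, float] = (2.0, 32.0)

    def __post_init__(self):
        if min(self.spont_scale, self.evoked_scale, self.width_scale) <= 0:
            raise ValueError("regime scales must be positive")


WT_LIKE = GenotypeRegime("WT")
KO_ACX_LIKE = GenotypeRegime("KO", spont_scale=1.5, evoked_scale=1.3, width_scale=1.4)
KO_IC_LIKE = GenotypeRegime("KO_IC")


def gen_unit_population(
    regime: GenotypeRegime, seed: int | np.random.Generator
) -> list[UnitGenParams]:
    """Draw a population of unit parameters under a genotype regime.

    CFs are log-uniform over ``cf_range_khz``; base parameters are drawn
    from fixed uniform ranges (multi-unit magnitudes) and then multiplied
    by the regime scales.
    """
    if regime.n_units <= 0:
        raise ValueError("n_units must be positive")
    lo, hi = regime.cf_range_khz
    if not (0 < lo < hi):
        raise ValueError("invalid cf_range_khz")
    rng = np.random.default_rng(seed)
    cfs = 2.0 ** rng.uniform(np.log2(lo), np.log2(hi), regime.n_units)
    baselines = rng.uniform(5.0, 15.0, regime.n_units) * regime.spont_scale
    peaks = rng.uniform(150.0, 250.0, regime.n_units) * regime.evoked_scale
    # width scale multiplies the whole half-width function (threshold
    # half-width and bandwidth alike): uniformly broadened tuning
    bws = rng.uniform(0.8, 1.4, regime.n_units) * regime.width_scale
    thrs = rng.choice([10.0, 20.0, 30.0], regime.n_units)
    return [
        UnitGenParams(
            cf_khz=float(cfs[i]),
            baseline_rate=float(baselines[i]),
            peak_evoked_rate=float(peaks[i]),
            min_threshold_db=float(thrs[i]),
            bw_octaves_at_40db=float(bws[i]),
            min_halfwidth_oct=0.25 * regime.width_scale,
        )
        for i in range(regime.n_units)
    ]


def _poisson_train(rng: np.random.Generator, rate_hz: float, t0: float, t1: float) -> np.ndarray:
    """Homogeneous Poisson spike times in [t0, t1) ms at rate_hz spikes/s."""
    lam = rate_hz * (t1 - t0) / 1000.0
    n = rng.poisson(lam)
    return rng.uniform(t0, t1, n)


def gen_tuning_matrix(
    params: UnitGenParams,
    freqs: np.ndarray | None = None,
    levels: np.ndarray | None = None,
    n_trials: int = DEFAULT_N_TRIALS,
    seed: int | np.random.Generator = 0,
    window: tuple[float, float] = DEFAULT_WINDOW,
    unit_id: str = "unit0",
    genotype_label: str = "",
    animal_id: str = "",
    penetration_id: str = "",
) -> TuningMatrix:
    """Simulate a full tuning matrix for one unit.

    Each cell's trains are inhomogeneous Poisson: the baseline rate spans
    the whole window; the evoked rate (see
    :meth:`UnitGenParams.evoked_rate`) adds spikes during
    [latency, latency + duration].
    """
    if freqs is None:
        freqs = default_freq_grid()
    if levels is None:
        levels = default_level_grid()
    freqs = np.asarray(freqs, dtype=float)
    levels = np.asarray(levels, dtype=float)
    if not (levels.min() <= params.min_threshold_db <= levels.max()):
        raise ValueError("level grid does not cover the unit's minimum threshold")
    rng = np.random.default_rng(seed)
    t0, t1 = window
    ev0 = params.latency_ms
    ev1 = params.latency_ms + params.evoked_duration_ms
    cells = {}
    for f in freqs:
        for l in levels:
            ev_rate = params.evoked_rate(f, l)
            trains = []
            for _ in range(n_trials):
                base = _poisson_train(rng, params.baseline_rate, t0, t1)
                if ev_rate > 0:
                    ev = _poisson_train(rng, ev_rate, ev0, ev1)
                    t = np.sort(np.concatenate([base, ev]))
                else:
                    t = np.sort(base)
                trains.append(SpikeTrain(t, window))
            cells[(float(f), float(l))] = SpikeTrainSet(
                unit_id=unit_id, freq_khz=float(f), level_db=float(l), trains=trains
            )
    return TuningMatrix(
        unit_id=unit_id,
        freqs=freqs,
        levels=levels,
        cells=cells,
        genotype_label=genotype_label,
        animal_id=animal_id,
        penetration_id=penetration_id,
    )


@dataclass(frozen=True)
class BehaviorGenParams:
    """Generative psychometrics for a Go/No-Go session.

    Detection: d'(level) follows a logistic
    ``d_max / (1 + exp(-(L - midpoint)/slope))``; the simulated observer is
    the equal-variance Gaussian observer with a fixed criterion placed so
    the catch-trial false-alarm probability equals ``fa_floor``; hence
    hit(L) = Phi(d'(L) + z(fa_floor)) and the session is exactly
    invertible by the d' analysis.

    Discrimination: false-alarm probability declines with octave distance
    as ``fa_floor + (fa_ceiling - fa_floor) / (1 + exp((|oct| - midpoint)
    / slope))``; hit probability is constant.
    """

    go_freq_khz: float = 8.0
    d_prime_max: float = 3.5
    d_prime_midpoint_db: float = 25.0
    d_prime_slope_db: float = 4.0
    fa_floor: float = 0.05
    fa_ceiling: float = 0.85
    fa_midpoint_oct: float = 0.5
    fa_slope_oct: float = 0.08
    n_trials: int = 600
    catch_fraction: float = 0.30
    levels_db: tuple[float, ...] = (15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0)
    hit_rate_discrimination: float = 0.95
    nogo_steps_twelfths: tuple[int, ...] = tuple(range(1, 13))

    def __post_init__(self):
        for p in (self.fa_floor, self.fa_ceiling, self.catch_fraction,
                  self.hit_rate_discrimination):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def d_prime_at(self, level_db) -> np.ndarray:
        level_db = np.asarray(level_db, dtype=float)
        return self.d_prime_max / (
            1.0 + np.exp(-(level_db - self.d_prime_midpoint_db) / self.d_prime_slope_db)
        )

    def detection_threshold_true(self, criterion: float = 1.5) -> float:
        """Level at which the generative d' equals the criterion."""
        if not 0 < criterion < self.d_prime_max:
            raise ValueError("criterion outside generative d' range")
        return self.d_prime_midpoint_db - self.d_prime_slope_db * np.log(
            self.d_prime_max / criterion - 1.0
        )

    def hit_prob_at(self, level_db) -> np.ndarray:
        z_fa = norm.ppf(np.clip(self.fa_floor, 1e-9, 1 - 1e-9))
        return norm.cdf(self.d_prime_at(level_db) + z_fa)

    def fa_prob_at_octave(self, octave_distance) -> np.ndarray:
        oct_ = np.abs(np.asarray(octave_distance, dtype=float))
        return self.fa_floor + (self.fa_ceiling - self.fa_floor) / (
            1.0 + np.exp((oct_ - self.fa_midpoint_oct) / self.fa_slope_oct)
        )


def gen_behavior_session(
    params: BehaviorGenParams,
    mode: str = "detection",
    seed: int | np.random.Generator = 0,
    session_id: str = "s0",
) -> pd.DataFrame:
    """Simulate a Go/No-Go behavioral trial table.

    Columns: session_id, trial_index, trial_type (go|nogo|catch),
    freq_khz, level_db, responded, latency_ms.
    """
    if params.n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if mode not in ("detection", "discrimination"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    n = params.n_trials
    rows = {
        "session_id": np.full(n, session_id, dtype=object),
        "trial_index": np.arange(n),
        "trial_type": np.empty(n, dtype=object),
        "freq_khz": np.full(n, np.nan),
        "level_db": np.full(n, np.nan),
        "responded": np.zeros(n, dtype=int),
        "latency_ms": np.full(n, np.nan),
    }
    if mode == "detection":
        is_catch = rng.random(n) < params.catch_fraction
        levels = np.array(params.levels_db)
        lv = levels[rng.integers(0, levels.size, n)]
        p_hit = params.hit_prob_at(lv)
        p = np.where(is_catch, params.fa_floor, p_hit)
        responded = rng.random(n) < p
        rows["trial_type"] = np.where(is_catch, "catch", "go")
        rows["freq_khz"] = np.where(is_catch, np.nan, params.go_freq_khz)
        rows["level_db"] = np.where(is_catch, np.nan, lv)
        rows["responded"] = responded.astype(int)
    else:
        is_go = rng.random(n) < 0.5
        steps = np.array(params.nogo_steps_twelfths, dtype=float)
        signed = np.concatenate([steps, -steps])
        step = signed[rng.integers(0, signed.size, n)]
        nogo_freq = params.go_freq_khz * 2.0 ** (step / 12.0)
        p_fa = params.fa_prob_at_octave(step / 12.0)
        p = np.where(is_go, params.hit_rate_discrimination, p_fa)
        responded = rng.random(n) < p
        rows["trial_type"] = np.where(is_go, "go", "nogo")
        rows["freq_khz"] = np.where(is_go, params.go_freq_khz, nogo_freq)
        rows["level_db"] = 40.0  # 40 dB above sensation level
        rows["responded"] = responded.astype(int)
    rows["latency_ms"] = np.where(
        rows["responded"] == 1, np.round(rng.gamma(3.0, 120.0, n), 1), np.nan
    )
    return pd.DataFrame(rows)
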