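"""Go/No-Go behavioral analysis: hit/FA rates, d', thresholds, FA-by-octave.

Signal-detection conventions: d' = z(hit) - z(fa) with the standard-normal
quantile z and rates clipped to [1/(2n), 1 - 1/(2n)] for their respective
trial counts, so perfect rates remain finite.  Detection thresholds are the
lowest level at which the linearly interpolated d'-vs-level curve crosses a
criterion (default d' = 1.5) from below.  Discrimination false alarms are
summarized on a 1/12-octave step grid and in three octave-distance bands:
near [0, 1/3), middle [1/3, 2/3], far (2/3, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SessionRates",
    "Psychometric",
    "FAByOctave",
    "compute_session_rates",
    "dprime",
    "psychometric_from_trials",
    "detection_threshold",
    "fa_by_octave_band",
    "BAND_EDGES",
]

#: Octave-band edges: near [0, 1/3), middle [1/3, 2/3], far (2/3, 1].
BAND_EDGES = (1.0 / 3.0, 2.0 / 3.0)
BAND_NAMES = ("near", "middle", "far")


@dataclass
class SessionRates:
    n_go: int
    n_nogo: int
    n_catch: int
    hit_rate: float
    fa_rate: float
    per_stimulus: dict  # (freq_khz, level_db) -> (n, response proportion)


@dataclass
class Psychometric:
    levels_db: np.ndarray
    d_prime: np.ndarray
    threshold_db: float | None
    criterion: float

    @property
    def resolved(self) -> bool:
        return self.threshold_db is not None


@dataclass
class FAByOctave:
    per_step: pd.DataFrame  # columns: octave_distance, n, fa_rate, n_above, n_below
    bands: dict  # band name -> (n, fa_rate)


def compute_session_rates(trials: pd.DataFrame) -> SessionRates:
    """Hit and false-alarm rates for one session's trial table.

    Hit rate is over go trials.  FA rate is over catch trials when they are
    present (detection sessions) and over No-Go trials otherwise
    (discrimination sessions).
    """
    types = set(trials["trial_type"].unique())
    if not types <= {"go", "nogo", "catch"}:
        raise ValueError(f"unknown trial types {types - {'go', 'nogo', 'catch'}}")
    go = trials[trials["trial_type"] == "go"]
    nogo = trials[trials["trial_type"] == "nogo"]
    catch = trials[trials["trial_type"] == "catch"]
    if len(go) == 0:
        raise ValueError("session contains no go trials")
    hit_rate = float(go["responded"].mean())
    ref = catch if len(catch) else nogo
    fa_rate = float(ref["responded"].mean()) if len(ref) else float("nan")
    per_stim = {}
    stim = trials[trials["trial_type"] != "catch"]
    for (f, l), sub in stim.groupby(["freq_khz", "level_db"], dropna=False):
        per_stim[(f, l)] = (len(sub), float(sub["responded"].mean()))
    return SessionRates(
        n_go=len(go),
        n_nogo=len(nogo),
        n_catch=len(catch),
        hit_rate=hit_rate,
        fa_rate=fa_rate,
        per_stimulus=per_stim,
    )


def _clip_rate(p: float, n: int) -> float:
    if n <= 0:
        raise ValueError("trial count must be positive")
    lo = 1.0 / (2.0 * n)
    return float(np.clip(p, lo, 1.0 - lo))


def dprime(hit_rate: float, fa_rate: float, n_go: int, n_ref: int) -> float:
    """Sensitivity index z(hit) - z(fa) with 1/(2n) clipping of perfect rates."""
    if not (0.0 <= hit_rate <= 1.0 and 0.0 <= fa_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    h = _clip_rate(hit_rate, n_go)
    f = _clip_rate(fa_rate, n_ref)
    return float(norm.ppf(h) - norm.ppf(f))


def psychometric_from_trials(
    trials: pd.DataFrame, criterion: float = 1.5
) -> Psychometric:
    """Per-level d' for a detection session, with the interpolated threshold.

    The session-wide catch-trial FA rate is the reference for every level.
    """
    rates = compute_session_rates(trials)
    go = trials[trials["trial_type"] == "go"]
    levels = np.sort(go["level_db"].unique())
    d = np.empty(levels.size)
    for i, l in enumerate(levels):
        sub = go[go["level_db"] == l]
        d[i] = dprime(float(sub["responded"].mean()), rates.fa_rate,
                      len(sub), max(rates.n_catch, 1))
    thr = detection_threshold(levels, d, criterion)
    return Psychometric(levels_db=levels, d_prime=d, threshold_db=thr, criterion=criterion)


def detection_threshold(
    levels_db: np.ndarray, d_prime: np.ndarray, criterion: float = 1.5
) -> float | None:
    """Lowest level where the linearly interpolated d' crosses the criterion.

    Returns None (unresolved) when d' never reaches the criterion.  If d'
    already exceeds the criterion at the lowest tested level, that level is
    returned.  Non-monotone curves with several crossings return the first
    and warn.
    """
    levels_db = np.asarray(levels_db, dtype=float)
    d_prime = np.asarray(d_prime, dtype=float)
    if levels_db.size < 2:
        raise ValueError("need at least two levels")
    order = np.argsort(levels_db)
    lv, d = levels_db[order], d_prime[order]
    if d[0] >= criterion:
        return float(lv[0])
    crossings = [
        i for i in range(lv.size - 1) if d[i] < criterion <= d[i + 1]
    ]
    if not crossings:
        return None
    if len(crossings) > 1:
        warnings.warn("d' crosses the criterion more than once; using the first crossing")
    i = crossings[0]
    frac = (criterion - d[i]) / (d[i + 1] - d[i])
    return float(lv[i] + frac * (lv[i + 1] - lv[i]))


def fa_by_octave_band(
    trials: pd.DataFrame,
    go_freq_khz: float,
    band_edges: tuple[float, float] = BAND_EDGES,
    step_octaves: float = 1.0 / 12.0,
) -> FAByOctave:
    """False-alarm rate by tonal distance from the Go frequency.

    No-Go trials are pooled by absolute octave distance |log2(f/go)|,
    snapped to the nearest 1/12-octave step; the side of the Go tone is
    retained as per-step counts.  Band means are trial-weighted over the
    steps falling in each band: near [0, e1), middle [e1, e2], far (e2, 1].
    """
    nogo = trials[trials["trial_type"] == "nogo"]
    if len(nogo) == 0:
        raise ValueError("no No-Go trials present")
    oct_signed = np.log2(nogo["freq_khz"].to_numpy(dtype=float) / go_freq_khz)
    if np.any(np.abs(oct_signed) < 1e-12):
        warnings.warn("No-Go frequency equals the Go frequency (distance 0)")
    step = np.round(oct_signed / step_octaves) * step_octaves
    dist = np.abs(step)
    df = pd.DataFrame(
        {
            "octave_distance": dist,
            "side": np.where(step >= 0, "above", "below"),
            "responded": nogo["responded"].to_numpy(),
        }
    )
    per_step = (
        df.groupby("octave_distance")
        .agg(
            n=("responded", "size"),
            fa_rate=("responded", "mean"),
            n_above=("side", lambda s: int((s == "above").sum())),
            n_below=("side", lambda s: int((s == "below").sum())),
        )
        .reset_index()
        .sort_values("octave_distance", ignore_index=True)
    )
    e1, e2 = band_edges
    tol = 1e-9
    def band_of(d):
        if d < e1 - tol:
            return "near"
        if d <= e2 + tol:
            return "middle"
        return "far"
    df["band"] = [band_of(d) for d in df["octave_distance"]]
    bands = {}
    for name in BAND_NAMES:
        sub = df[df["band"] == name]
        bands[name] = (len(sub), float(sub["responded"].mean()) if len(sub) else float("nan"))
    return FAByOctave(per_step=per_step, bands=bands)
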