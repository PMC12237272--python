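"""Core domain types and operations for tone-evoked multi-unit recordings.

The recording model: a multi-unit cluster is probed with tone bursts on a
frequency x intensity grid (default 1-64 kHz in 20 logarithmic steps,
0-90 dB SPL in 10-dB steps), with 30 repeats per combination.  Spike times
are stored in milliseconds relative to stimulus onset, inside a fixed
analysis window (default -40 ms to +100 ms).

This module provides the shared containers (:class:`SpikeTrain`,
:class:`SpikeTrainSet`, :class:`TuningMatrix`, :class:`PSTH`), the CSV
spike-table reader/writer, peristimulus-time-histogram construction, and
the evoked-response criterion (any 5-ms bin in the 0-40 ms post-onset
window exceeding the pre-stimulus mean by 4 pre-stimulus SDs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default analysis window in ms relative to stimulus onset.
DEFAULT_WINDOW = (-40.0, 100.0)
#: Default PSTH bin width in ms.
DEFAULT_BIN_WIDTH = 5.0
#: Default post-onset window searched for evoked activity, ms.
DEFAULT_EVOKED_WINDOW = (0.0, 40.0)
#: Default pre-stimulus window used for baseline statistics, ms.
DEFAULT_PRE_WINDOW = (-40.0, 0.0)
#: Default number of repeats per frequency/intensity combination.
DEFAULT_N_TRIALS = 30

#: Columns of the spike-table CSV schema.
SPIKE_TABLE_COLUMNS = [
    "unit_id",
    "animal_id",
    "penetration_id",
    "genotype",
    "trial_index",
    "freq_khz",
    "level_db",
    "spike_time_ms",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ParseError(ValueError):
    """A value in an input table could not be parsed."""


def default_freq_grid(n: int = 20, f_lo: float = 1.0, f_hi: float = 64.0) -> np.ndarray:
    """Log-spaced tone frequencies in kHz (default 20 steps over 1-64 kHz)."""
    return f_lo * 2.0 ** np.linspace(0.0, np.log2(f_hi / f_lo), n)


def default_level_grid(lo: float = 0.0, hi: float = 90.0, step: float = 10.0) -> np.ndarray:
    """Tone intensities in dB SPL (default 0-90 dB in 10-dB steps)."""
    return np.arange(lo, hi + 0.5 * step, step)


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times (ms re stimulus onset) for one stimulus repeat.

    Times must be nondecreasing and lie inside ``window``.
    """

    times: np.ndarray
    window: tuple[float, float] = DEFAULT_WINDOW

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError("spike times must be nondecreasing")
        lo, hi = self.window
        if t.size and (t[0] < lo or t[-1] > hi):
            raise ValueError(
                f"spike times outside analysis window [{lo}, {hi}] ms"
            )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass
class SpikeTrainSet:
    """Repeated-trial spike trains for one unit at one (frequency, level)."""

    unit_id: str
    freq_khz: float
    level_db: float
    trains: list[SpikeTrain]

    @property
    def n_trials(self) -> int:
        return len(self.trains)

    @property
    def window(self) -> tuple[float, float]:
        if not self.trains:
            return DEFAULT_WINDOW
        return self.trains[0].window

    def total_spikes(self) -> int:
        return sum(tr.n_spikes for tr in self.trains)

    def rate_in(self, t0: float, t1: float) -> float:
        """Mean firing rate (spikes/s) in [t0, t1) ms across trials."""
        if not self.trains:
            raise ValueError("empty SpikeTrainSet")
        n = sum(
            int(np.count_nonzero((tr.times >= t0) & (tr.times < t1)))
            for tr in self.trains
        )
        return n / self.n_trials / ((t1 - t0) / 1000.0)


@dataclass
class TuningMatrix:
    """Full frequency x intensity grid of spike-train sets for one unit."""

    unit_id: str
    freqs: np.ndarray
    levels: np.ndarray
    cells: Mapping[tuple[float, float], SpikeTrainSet]
    genotype_label: str = ""
    penetration_id: str = ""
    animal_id: str = ""

    def __post_init__(self):
        self.freqs = np.sort(np.asarray(self.freqs, dtype=float))
        self.levels = np.sort(np.asarray(self.levels, dtype=float))
        missing = [
            (f, l)
            for f in self.freqs
            for l in self.levels
            if (f, l) not in self.cells
        ]
        if missing:
            raise ValueError(
                f"TuningMatrix for {self.unit_id}: {len(missing)} grid cells "
                f"missing, first {missing[0]}"
            )

    def cell(self, freq_khz: float, level_db: float) -> SpikeTrainSet:
        return self.cells[(freq_khz, level_db)]

    @property
    def window(self) -> tuple[float, float]:
        first = self.cells[(self.freqs[0], self.levels[0])]
        return first.window

    def spontaneous_rate(self, pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW) -> float:
        """Mean pre-stimulus firing rate (spikes/s) pooled over the grid."""
        t0, t1 = pre_window
        total = 0
        trials = 0
        for ts in self.cells.values():
            total += sum(
                int(np.count_nonzero((tr.times >= t0) & (tr.times < t1)))
                for tr in ts.trains
            )
            trials += ts.n_trials
        return total / trials / ((t1 - t0) / 1000.0)


@dataclass
class PSTH:
    """Peristimulus time histogram: trial-averaged counts per bin."""

    bin_edges: np.ndarray
    counts_per_bin: np.ndarray
    bin_width: float
    n_trials: int

    def bins_in(self, t0: float, t1: float) -> np.ndarray:
        """Indices of bins fully inside [t0, t1]."""
        lo = self.bin_edges[:-1]
        hi = self.bin_edges[1:]
        return np.nonzero((lo >= t0 - 1e-9) & (hi <= t1 + 1e-9))[0]


@dataclass
class EvokedResult:
    """Outcome of the evoked-response criterion on one PSTH."""

    evoked: bool
    peak_bin: int | None
    peak_time_ms: float | None
    threshold_counts: float
    pre_mean: float
    pre_sd: float


def build_psth(
    train_set: SpikeTrainSet,
    bin_width: float = DEFAULT_BIN_WIDTH,
    window: tuple[float, float] | None = None,
) -> PSTH:
    """Trial-averaged spike-count histogram with half-open [lo, hi) bins.

    ``counts_per_bin[i]`` is the total number of spikes across trials
    falling in bin ``i`` divided by the number of trials.
    """
    if train_set.n_trials == 0:
        raise ValueError("cannot build a PSTH from an empty SpikeTrainSet")
    if window is None:
        window = train_set.window
    lo, hi = window
    span = hi - lo
    n_bins = span / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(
            f"bin width {bin_width} ms does not divide window length {span} ms"
        )
    n_bins = int(round(n_bins))
    edges = lo + bin_width * np.arange(n_bins + 1)
    all_times = np.concatenate([tr.times for tr in train_set.trains]) if train_set.trains else np.empty(0)
    # np.histogram's last bin is closed; shift spikes at exactly `hi` out.
    counts, _ = np.histogram(all_times[all_times < hi], bins=edges)
    return PSTH(
        bin_edges=edges,
        counts_per_bin=counts / train_set.n_trials,
        bin_width=bin_width,
        n_trials=train_set.n_trials,
    )


def detect_evoked(
    psth: PSTH,
    evoked_window: tuple[float, float] = DEFAULT_EVOKED_WINDOW,
    pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW,
    k: float = 4.0,
    pre_stats: tuple[float, float] | None = None,
) -> EvokedResult:
    """Flag a PSTH as tone-evoked.

    Evoked iff any bin fully inside ``evoked_window`` exceeds
    ``mean(pre) + k * SD(pre)``, with mean and SD taken across the bins
    fully inside ``pre_window``.

    The empirical SD across the handful of pre-stimulus bins is a noisy,
    downward-biased estimate when baseline counts are sparse (and the
    criterion is undefined outright at SD = 0), so the SD of the
    trial-averaged count of a Poisson bin at the pre-stimulus mean rate,
    ``sqrt(mean / n_trials)``, acts as a lower bound, with an absolute
    floor of ``1 / n_trials`` counts.

    ``pre_stats`` optionally supplies externally pooled baseline
    (mean, SD); spontaneous activity is stimulus-independent, so pooling
    the pre-stimulus statistics over a whole tuning matrix (see
    :func:`evoked_map`) estimates them far more precisely than the few
    pre-stimulus bins of a single cell.
    """
    pre_bins = psth.bins_in(*pre_window)
    ev_bins = psth.bins_in(*evoked_window)
    if pre_bins.size == 0 or ev_bins.size == 0:
        raise ValueError("PSTH does not span the pre-stimulus and evoked windows")
    if pre_stats is None:
        pre = psth.counts_per_bin[pre_bins]
        mean = float(np.mean(pre))
        sd = float(np.std(pre))
    else:
        mean, sd = (float(v) for v in pre_stats)
    sd = max(sd, np.sqrt(mean / psth.n_trials), 1.0 / psth.n_trials)
    threshold = mean + k * sd
    ev = psth.counts_per_bin[ev_bins]
    exceed = ev > threshold
    if not np.any(exceed):
        return EvokedResult(False, None, None, threshold, mean, sd)
    peak_local = int(np.argmax(ev))
    peak_bin = int(ev_bins[peak_local])
    peak_time = float(psth.bin_edges[peak_bin])
    return EvokedResult(True, peak_bin, peak_time, threshold, mean, sd)


def evoked_map(
    matrix: TuningMatrix,
    bin_width: float = DEFAULT_BIN_WIDTH,
    evoked_window: tuple[float, float] = DEFAULT_EVOKED_WINDOW,
    pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW,
    k: float = 4.0,
    pooled_baseline: bool = True,
) -> np.ndarray:
    """Boolean (n_freqs, n_levels) array of per-cell evoked flags.

    With ``pooled_baseline`` (default) the pre-stimulus mean and SD are
    pooled over every cell of the matrix before applying the per-cell
    exceedance test, since spontaneous activity does not depend on the
    stimulus; per-cell baselines (``pooled_baseline=False``) reproduce
    the single-PSTH behavior of :func:`detect_evoked`.
    """
    psths = [
        [build_psth(matrix.cell(f, l), bin_width=bin_width) for l in matrix.levels]
        for f in matrix.freqs
    ]
    pre_stats = None
    if pooled_baseline:
        pooled = np.concatenate(
            [p.counts_per_bin[p.bins_in(*pre_window)] for row in psths for p in row]
        )
        pre_stats = (float(np.mean(pooled)), float(np.std(pooled)))
    out = np.zeros((matrix.freqs.size, matrix.levels.size), dtype=bool)
    for i in range(matrix.freqs.size):
        for j in range(matrix.levels.size):
            out[i, j] = detect_evoked(
                psths[i][j], evoked_window, pre_window, k, pre_stats=pre_stats
            ).evoked
    return out


# ---------------------------------------------------------------------------
# Spike-table I/O
#
# One CSV row per spike; trials that contain no spikes are kept as a single
# row with an empty spike_time_ms field so that trial counts round-trip.
# ---------------------------------------------------------------------------

def write_spike_table(matrices: Sequence[TuningMatrix], path) -> None:
    """Write tuning matrices to the spike-table CSV schema (times to 3 dp)."""
    rows = []
    for m in matrices:
        for f in m.freqs:
            for l in m.levels:
                ts = m.cell(f, l)
                for k_trial, tr in enumerate(ts.trains):
                    if tr.n_spikes == 0:
                        rows.append((m.unit_id, m.animal_id, m.penetration_id,
                                     m.genotype_label, k_trial, f, l, ""))
                    else:
                        for t in tr.times:
                            rows.append((m.unit_id, m.animal_id, m.penetration_id,
                                         m.genotype_label, k_trial, f, l, f"{t:.3f}"))
    df = pd.DataFrame(rows, columns=SPIKE_TABLE_COLUMNS)
    df.to_csv(path, index=False)


def read_spike_table(path, window: tuple[float, float] = DEFAULT_WINDOW) -> list[TuningMatrix]:
    """Read a spike-table CSV into a list of :class:`TuningMatrix`.

    Rows with spike times outside ``window`` are rejected (count logged).
    Raises :class:`SchemaError` for missing columns and :class:`ParseError`
    (with the offending row number) for non-numeric spike times.
    """
    df = pd.read_csv(path, dtype={"spike_time_ms": str}, keep_default_na=False)
    for col in SPIKE_TABLE_COLUMNS:
        if col != "genotype" and col not in df.columns:
            raise SchemaError(f"spike table is missing required column '{col}'")
    if "genotype" not in df.columns:
        df["genotype"] = ""
    if df.empty:
        return []

    raw = df["spike_time_ms"].str.strip()
    has_time = raw != ""
    times = pd.to_numeric(raw.where(has_time), errors="coerce")
    bad = has_time & times.isna()
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise ParseError(
            f"non-numeric spike time {raw.iloc[row]!r} at data row {row + 1}"
        )
    df = df.assign(_t=times, _has=has_time)

    lo, hi = window
    out_of_window = df["_has"] & ((df["_t"] < lo) | (df["_t"] > hi))
    n_rejected = int(out_of_window.sum())
    if n_rejected:
        logger.warning("read_spike_table: rejected %d spikes outside window %s", n_rejected, window)
        # keep the trial rows, drop only the spike values
        df.loc[out_of_window, "_has"] = False

    matrices = []
    for unit_id, g in df.groupby("unit_id", sort=True):
        freqs = np.sort(g["freq_khz"].unique().astype(float))
        levels = np.sort(g["level_db"].unique().astype(float))
        n_trials = int(g["trial_index"].max()) + 1
        cells = {}
        grouped = {
            key: sub for key, sub in g.groupby(["freq_khz", "level_db"], sort=False)
        }
        for f in freqs:
            for l in levels:
                sub = grouped.get((f, l))
                trains = []
                if sub is None:
                    logger.warning(
                        "read_spike_table: unit %s missing cell (%.3g kHz, %g dB); filled empty",
                        unit_id, f, l,
                    )
                    trains = [SpikeTrain(np.empty(0), window) for _ in range(n_trials)]
                else:
                    by_trial = {
                        int(k): np.sort(v.loc[v["_has"], "_t"].to_numpy(dtype=float))
                        for k, v in sub.groupby("trial_index")
                    }
                    for k_trial in range(n_trials):
                        t = by_trial.get(k_trial, np.empty(0))
                        trains.append(SpikeTrain(t, window))
                cells[(float(f), float(l))] = SpikeTrainSet(
                    unit_id=str(unit_id), freq_khz=float(f), level_db=float(l), trains=trains
                )
        first = g.iloc[0]
        matrices.append(
            TuningMatrix(
                unit_id=str(unit_id),
                freqs=freqs,
                levels=levels,
                cells=cells,
                genotype_label=str(first["genotype"]),
                penetration_id=str(first["penetration_id"]),
                animal_id=str(first["animal_id"]),
            )
        )
    return matrices
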