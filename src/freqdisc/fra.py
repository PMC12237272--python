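"""Frequency-response-area (FRA) tuning metrics.

For each unit, the per-frequency threshold is the lowest intensity whose
cell passes the evoked-response criterion; the characteristic frequency
(CF) is the frequency with the minimal threshold, and the minimum
threshold is that value.  Bandwidth at 10/20/30/40 dB above the minimum
threshold is the span from the first to the last evoked cell in that
intensity row (no contiguity requirement), and Q = CF / (f_hi - f_lo)
with linear-kHz bandwidth, so that Q is scale-free in frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_EVOKED_WINDOW,
    DEFAULT_PRE_WINDOW,
    TuningMatrix,
    evoked_map,
)

__all__ = ["FRAMetrics", "extract_fra_metrics", "bandwidth_at", "q_value", "DELTA_DBS"]

#: Suprathreshold offsets (dB above minimum threshold) used for bandwidth/Q.
DELTA_DBS = (10, 20, 30, 40)


@dataclass
class FRAMetrics:
    unit_id: str
    cf_khz: float | None
    min_threshold_db: float | None
    bw: dict = field(default_factory=dict)  # delta_db -> (f_lo, f_hi) or None
    q: dict = field(default_factory=dict)  # delta_db -> Q or None
    flags: list = field(default_factory=list)
    genotype_label: str = ""

    @property
    def resolved(self) -> bool:
        return self.cf_khz is not None


def supported_map(emap: np.ndarray) -> np.ndarray:
    """Keep evoked cells whose response persists one level up.

    The excitatory region of a V-shaped FRA is upward-closed in level, so
    a genuine evoked cell (below the top tested row) has an evoked cell
    directly above it, while an isolated false exceedance of the 4-SD
    criterion almost never recurs.  This is the automatic stand-in for
    manual curation of discernible tuning curves.
    """
    sup = emap.copy()
    sup[:, :-1] &= emap[:, 1:]
    return sup


def q_value(cf_khz: float, f_lo_khz: float, f_hi_khz: float) -> float | None:
    """Q = CF / bandwidth (linear kHz).  None (flagged) for zero bandwidth."""
    bw = f_hi_khz - f_lo_khz
    if bw < 0:
        raise ValueError("negative bandwidth")
    if bw == 0:
        return None
    return cf_khz / bw


def bandwidth_at(
    matrix: TuningMatrix,
    metrics: FRAMetrics,
    delta_db: int,
    emap: np.ndarray | None = None,
    require_support: bool = True,
    **detect_kwargs,
) -> tuple[float, float] | None:
    """First/last evoked frequency in the row ``min_threshold + delta_db``.

    There is no contiguity requirement along the frequency axis.  If the
    nominal row is not on the level grid, the nearest tested row at or
    below is used (flagged); rows above the tested range are unresolved.
    Returns None when no cell in the row is evoked.  ``require_support``
    applies the :func:`supported_map` curation when the evoked map is
    computed here.
    """
    if not metrics.resolved:
        return None
    if emap is None:
        emap = evoked_map(matrix, **detect_kwargs)
        if require_support:
            emap = supported_map(emap)
    target = metrics.min_threshold_db + delta_db
    if target > matrix.levels[-1] + 1e-9:
        return None
    at_or_below = np.nonzero(matrix.levels <= target + 1e-9)[0]
    j = int(at_or_below[-1])
    if abs(matrix.levels[j] - target) > 1e-9:
        metrics.flags.append(f"bw{delta_db}_row_snapped_to_{matrix.levels[j]:g}dB")
    row = emap[:, j]
    idx = np.nonzero(row)[0]
    if idx.size == 0:
        return None
    f_lo = float(matrix.freqs[idx[0]])
    f_hi = float(matrix.freqs[idx[-1]])
    if f_lo == f_hi:
        metrics.flags.append(f"bw{delta_db}_single_cell")
    if not (f_lo <= metrics.cf_khz <= f_hi):
        warnings.warn(
            f"unit {matrix.unit_id}: evoked region at +{delta_db} dB excludes CF"
        )
        metrics.flags.append(f"bw{delta_db}_excludes_cf")
    return (f_lo, f_hi)


def extract_fra_metrics(
    matrix: TuningMatrix,
    delta_dbs: tuple[int, ...] = DELTA_DBS,
    bin_width: float = DEFAULT_BIN_WIDTH,
    evoked_window: tuple[float, float] = DEFAULT_EVOKED_WINDOW,
    pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW,
    k: float = 4.0,
    pooled_baseline: bool = True,
    require_support: bool = True,
) -> FRAMetrics:
    """CF, minimum threshold, and bandwidth/Q at suprathreshold levels.

    Unresolved metrics (no evoked cell anywhere) are a valid outcome, not
    an error.  Ties at the minimum threshold are broken toward the
    frequency with the larger evoked-window rate at threshold, then toward
    the lower frequency (flagged).

    ``require_support`` applies the :func:`supported_map` curation (a
    cell counts only if its response persists one level up) to both the
    per-frequency thresholds and the bandwidth rows; set it False for
    the raw per-cell criterion.
    """
    emap = evoked_map(
        matrix, bin_width=bin_width, evoked_window=evoked_window,
        pre_window=pre_window, k=k, pooled_baseline=pooled_baseline,
    )
    if require_support:
        emap = supported_map(emap)
    metrics = FRAMetrics(
        unit_id=matrix.unit_id, cf_khz=None, min_threshold_db=None,
        genotype_label=matrix.genotype_label,
    )
    # per-frequency threshold: lowest (curated) evoked level
    thresholds = np.full(matrix.freqs.size, np.inf)
    for i in range(matrix.freqs.size):
        evoked_levels = np.nonzero(emap[i])[0]
        if evoked_levels.size:
            thresholds[i] = matrix.levels[evoked_levels[0]]
    if not np.isfinite(thresholds).any():
        metrics.flags.append("unresolved")
        return metrics
    min_thr = float(np.min(thresholds))
    tied = np.nonzero(thresholds == min_thr)[0]
    if tied.size > 1:
        metrics.flags.append("cf_tie")
        t0, t1 = evoked_window
        rates = [
            matrix.cell(float(matrix.freqs[i]), min_thr).rate_in(t0, t1) for i in tied
        ]
        best = tied[int(np.argmax(rates))]  # argmax takes the first (lower f) on ties
    else:
        best = tied[0]
    metrics.cf_khz = float(matrix.freqs[best])
    metrics.min_threshold_db = min_thr
    for delta in delta_dbs:
        band = bandwidth_at(matrix, metrics, delta, emap=emap)
        metrics.bw[delta] = band
        if band is None:
            metrics.q[delta] = None
        else:
            metrics.q[delta] = q_value(metrics.cf_khz, band[0], band[1])
    return metrics


def metrics_to_frame(all_metrics: list[FRAMetrics]) -> pd.DataFrame:
    """Tidy CSV-ready table of FRA metrics."""
    rows = []
    for m in all_metrics:
        row = {
            "unit_id": m.unit_id,
            "genotype": m.genotype_label,
            "cf_khz": m.cf_khz,
            "min_threshold_db": m.min_threshold_db,
            "flags": ";".join(m.flags),
        }
        for delta in sorted(m.bw):
            band = m.bw[delta]
            row[f"bw{delta}_lo_khz"] = band[0] if band else None
            row[f"bw{delta}_hi_khz"] = band[1] if band else None
            row[f"q{delta}"] = m.q.get(delta)
        rows.append(row)
    return pd.DataFrame(rows)
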