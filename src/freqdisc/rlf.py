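"""Rate-level functions (RLFs) and the 6-parameter logistic-plus-Gaussian fit.

An RLF is the mean driven discharge rate at a unit's characteristic
frequency (CF) as a function of tone intensity.  It is fit with

    y(x) = a + (d - a) / (1 + exp((b - x) / c)) + e * exp(-(x - f)^2 / (2 c^2))

where a is the lower asymptote (response minimum), d the upper asymptote
(response maximum), b the logistic inflection point, c the shared
slope/width parameter, e the Gaussian amplitude and f the Gaussian center.
This accommodates both monotone and non-monotone (bump-shaped) RLFs with a
single width parameter.

Derived quantities:

* threshold: the lowest level at which the fitted curve first reaches 20%
  of the range above the lower asymptote, a + 0.2 (d - a), evaluated on a
  1-dB grid;
* gain: the maximum slope of the fitted curve over its ascending portion,
  evaluated numerically on the same grid.

Fits with root-mean-square error >= 100 spikes/s are excluded downstream
(:func:`filter_fits`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import DEFAULT_EVOKED_WINDOW, TuningMatrix

__all__ = [
    "RateLevelFunction",
    "RLFFit",
    "RateLevelGaussianModel",
    "rlf_curve",
    "build_cf_rlf",
    "fit_rlf",
    "filter_fits",
    "RMSE_CUTOFF",
]

#: Admission cutoff on fit RMSE (spikes/s).
RMSE_CUTOFF = 100.0

PARAM_NAMES = ("a", "b", "c", "d", "e", "f")


def rlf_curve(x, a, b, c, d, e, f):
    """Evaluate the logistic-plus-Gaussian rate-level model."""
    x = np.asarray(x, dtype=float)
    return (
        a
        + (d - a) / (1.0 + np.exp((b - x) / c))
        + e * np.exp(-((x - f) ** 2) / (2.0 * c**2))
    )


@dataclass
class RateLevelFunction:
    """Mean driven rate (spikes/s) per level at one unit's CF column."""

    unit_id: str
    levels_db: np.ndarray
    rates: np.ndarray
    freq_khz: float | None = None
    genotype_label: str = ""

    def __post_init__(self):
        self.levels_db = np.asarray(self.levels_db, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.levels_db.shape != self.rates.shape:
            raise ValueError("levels and rates must have equal length")
        if np.any(self.rates < 0):
            raise ValueError("rates must be nonnegative")


@dataclass
class RLFFit:
    """Fitted Eq parameters plus derived response metrics."""

    unit_id: str
    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    rmse: float
    threshold_db: float | None
    gain: float
    converged: bool
    genotype_label: str = ""

    @property
    def resp_min(self) -> float:
        return self.a

    @property
    def resp_max(self) -> float:
        return self.d

    @property
    def params(self) -> tuple[float, ...]:
        return (self.a, self.b, self.c, self.d, self.e, self.f)


def build_cf_rlf(
    matrix: TuningMatrix,
    cf_khz: float,
    evoked_window: tuple[float, float] = DEFAULT_EVOKED_WINDOW,
) -> RateLevelFunction:
    """Rate-level function from the CF column of a tuning matrix.

    The rate at each level is the mean spike count in the evoked window
    across trials divided by the window duration.  ``cf_khz`` must be one
    of the matrix's grid frequencies (no interpolation across frequency).
    """
    hits = np.isclose(matrix.freqs, cf_khz, rtol=1e-9)
    if not hits.any():
        raise ValueError(f"CF {cf_khz} kHz is not on the matrix frequency grid")
    f = float(matrix.freqs[np.argmax(hits)])
    t0, t1 = evoked_window
    rates = np.array(
        [matrix.cell(f, l).rate_in(t0, t1) for l in matrix.levels]
    )
    return RateLevelFunction(
        unit_id=matrix.unit_id,
        levels_db=matrix.levels.copy(),
        rates=rates,
        freq_khz=f,
        genotype_label=matrix.genotype_label,
    )


class RateLevelGaussianModel:
    """Least-squares estimator for the 6-parameter rate-level model.

    scikit-learn style: construct with hyperparameters, ``fit(X, y)`` on
    levels (dB) and rates (spikes/s), then read the fitted parameters from
    trailing-underscore attributes and evaluate with ``predict``.

    Parameters
    ----------
    n_starts : int
        Number of multi-start initializations spanning monotone and
        non-monotone shapes; the best-RMSE solution wins, ties broken
        toward the smallest width ``c``.
    threshold_fraction : float
        Fraction of the (d - a) range defining the derived threshold.
    eval_step_db : float
        Grid step for the numeric threshold/gain evaluation.
    bounds_margin_db : float
        How far b and f may sit outside the tested level span.
    c_bounds : tuple
        Bounds on the shared width c (dB): the lower bound keeps the
        Gaussian from collapsing onto a single tested level, the upper
        bound from stretching the logistic rise far beyond the tested
        span — both are degenerate overfits of noisy rates.
    weighting : str
        'none' (default) is ordinary least squares; 'poisson' weights
        residuals by the inverse Poisson standard deviation of each rate
        (the noise model of trial-averaged spike counts).  The reported
        ``rmse_`` is always unweighted (spikes/s).
    """

    def __init__(
        self,
        n_starts: int = 16,
        threshold_fraction: float = 0.2,
        eval_step_db: float = 1.0,
        bounds_margin_db: float = 10.0,
        c_bounds: tuple[float, float] = (2.5, 25.0),
        weighting: str = "none",
    ):
        self.n_starts = n_starts
        self.threshold_fraction = threshold_fraction
        self.eval_step_db = eval_step_db
        self.bounds_margin_db = bounds_margin_db
        self.c_bounds = c_bounds
        self.weighting = weighting

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_starts": self.n_starts,
            "threshold_fraction": self.threshold_fraction,
            "eval_step_db": self.eval_step_db,
            "bounds_margin_db": self.bounds_margin_db,
            "c_bounds": self.c_bounds,
            "weighting": self.weighting,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting ------------------------------------------------------------
    def _starts(self, x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
        rng_span = float(np.ptp(y))
        a0 = float(np.min(y))
        d0 = float(np.max(y))
        q = np.quantile(x, [0.25, 0.5, 0.75])
        e_small = max(0.05 * rng_span, 0.1)
        e_big = max(0.8 * rng_span, 0.5)
        starts = []
        for b0 in (q[0], q[2]):
            for f0 in (q[1], float(x[-1])):
                for e0 in (e_small, e_big):
                    starts.append(np.array([a0, b0, 10.0, d0, e0, f0]))
        # refinement starts: steep/shallow monotone and bump-at-peak shapes
        x_peak = float(x[np.argmax(y)])
        starts.append(np.array([a0, q[1], 4.0, d0, e_small, x_peak]))
        starts.append(np.array([a0, q[1], 20.0, d0, e_small, x_peak]))
        starts.append(np.array([a0, q[0], 8.0, max(a0 + 0.1, np.median(y)), e_big, x_peak]))
        starts.append(np.array([a0, q[2], 8.0, d0, e_big, x_peak]))
        starts.append(np.array([a0, q[1], 4.0, d0, e_big, x_peak]))
        starts.append(np.array([a0, q[1], 10.0, d0, e_big, x_peak]))
        # shoulder-before-sigmoid shapes: Gaussian center below the inflection
        starts.append(np.array([a0, q[1], 4.0, d0, e_small, q[0]]))
        starts.append(np.array([a0, q[2], 4.0, d0, e_big, q[0]]))
        return starts[: max(self.n_starts, 1)]

    def fit(self, X, y):
        """Fit to levels ``X`` (dB) and mean driven rates ``y`` (spikes/s)."""
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("X and y must have equal length")
        if x.size < 6:
            raise ValueError("need at least 6 levels to fit 6 parameters")
        order = np.argsort(x)
        x, y = x[order], y[order]
        lo_b = x[0] - self.bounds_margin_db
        hi_b = x[-1] + self.bounds_margin_db
        # asymptotes and bump amplitude stay near the observed rate range:
        # unbounded d/e admit degenerate fits whose rise is extrapolated
        # beyond the tested levels, wrecking the derived threshold
        y_hi = max(float(np.max(y)) * 1.5 + 10.0, 10.0)
        lower = np.array([0.0, lo_b, self.c_bounds[0], 0.0, 0.0, lo_b])
        upper = np.array([y_hi, hi_b, self.c_bounds[1], y_hi, y_hi, hi_b])

        if self.weighting == "poisson":
            w = 1.0 / np.sqrt(np.maximum(y, 1.0))
        elif self.weighting == "none":
            w = np.ones_like(y)
        else:
            raise ValueError(f"unknown weighting {self.weighting!r}")

        def resid(p):
            return w * (rlf_curve(x, *p) - y)

        best = None

        def try_start(p0):
            nonlocal best
            p0 = np.clip(p0, lower + 1e-9, upper - 1e-9)
            try:
                sol = least_squares(
                    resid, p0, bounds=(lower, upper), method="trf",
                    xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000,
                )
            except Exception:  # pragma: no cover - optimizer failure path
                return
            cost = float(np.sqrt(np.mean(sol.fun**2)))  # weighted objective
            cand = (cost, float(sol.x[2]), sol)
            if (
                best is None
                or cand[0] < best[0] - 1e-12
                or (abs(cand[0] - best[0]) <= 1e-12 and cand[1] < best[1])
            ):
                best = cand

        for p0 in self._starts(x, y):
            try_start(p0)
        # staged starts: fit the sigmoid alone, then seed the Gaussian from
        # the residual peak — rescues bump-on-shoulder shapes
        for c0 in (4.0, 10.0):
            try:
                sig = least_squares(
                    lambda p: w * (rlf_curve(x, p[0], p[1], p[2], p[3], 0.0, x[0]) - y),
                    np.clip(
                        [float(np.min(y)), float(np.median(x)), c0, float(np.max(y))],
                        lower[[0, 1, 2, 3]] + 1e-9, upper[[0, 1, 2, 3]] - 1e-9,
                    ),
                    bounds=(lower[[0, 1, 2, 3]], upper[[0, 1, 2, 3]]),
                    method="trf", max_nfev=500,
                )
            except Exception:  # pragma: no cover
                continue
            r = y - rlf_curve(x, sig.x[0], sig.x[1], sig.x[2], sig.x[3], 0.0, x[0])
            f0 = float(x[np.argmax(r)])
            e0 = max(float(np.max(r)), 0.1)
            try_start(np.array([sig.x[0], sig.x[1], sig.x[2], sig.x[3], e0, f0]))
        # polish: re-descend from perturbations of the incumbent — the
        # shared width c and the roles of the inflection b and center f are
        # the common basin confusions
        if best is not None and best[0] > 1e-9:
            incumbent = best[2].x.copy()
            for c_scale in (0.5, 2.0):
                p0 = incumbent.copy()
                p0[2] *= c_scale
                try_start(p0)
            swap = incumbent.copy()
            swap[1], swap[5] = incumbent[5], incumbent[1]
            try_start(swap)
        if best is None:
            self.converged_ = False
            self.rmse_ = float("inf")
            self.a_ = self.b_ = self.c_ = self.d_ = self.e_ = self.f_ = float("nan")
            self.threshold_db_ = None
            self.gain_ = float("nan")
            return self
        _, _, sol = best
        self.a_, self.b_, self.c_, self.d_, self.e_, self.f_ = (float(v) for v in sol.x)
        self.rmse_ = float(np.sqrt(np.mean((rlf_curve(x, *sol.x) - y) ** 2)))
        self.converged_ = bool(sol.success) or rmse < 1e6
        self.levels_span_ = (float(x[0]), float(x[-1]))
        self.threshold_db_, self.gain_ = self._derive(x)
        return self

    def predict(self, X):
        """Evaluate the fitted curve at levels ``X`` (dB)."""
        self._check_fitted()
        return rlf_curve(np.asarray(X, dtype=float), *self.coef_)

    @property
    def coef_(self) -> tuple[float, ...]:
        self._check_fitted()
        return (self.a_, self.b_, self.c_, self.d_, self.e_, self.f_)

    def _check_fitted(self):
        if not hasattr(self, "rmse_"):
            raise AttributeError("model is not fitted; call fit() first")

    def _derive(self, x: np.ndarray) -> tuple[float | None, float]:
        grid = np.arange(x[0], x[-1] + 0.5 * self.eval_step_db, self.eval_step_db)
        y = rlf_curve(grid, self.a_, self.b_, self.c_, self.d_, self.e_, self.f_)
        rng_span = self.d_ - self.a_
        threshold = None
        if rng_span > 1e-9:
            target = self.a_ + self.threshold_fraction * rng_span
            above = np.nonzero(y >= target)[0]
            if above.size:
                threshold = float(grid[above[0]])
        slopes = np.diff(y) / self.eval_step_db
        gain = float(max(np.max(slopes), 0.0)) if slopes.size else 0.0
        return threshold, gain


def fit_rlf(rlf: RateLevelFunction, **model_kwargs) -> RLFFit:
    """Fit one RLF; thin wrapper over :class:`RateLevelGaussianModel`."""
    model = RateLevelGaussianModel(**model_kwargs).fit(rlf.levels_db, rlf.rates)
    return RLFFit(
        unit_id=rlf.unit_id,
        a=model.a_,
        b=model.b_,
        c=model.c_,
        d=model.d_,
        e=model.e_,
        f=model.f_,
        rmse=model.rmse_,
        threshold_db=model.threshold_db_,
        gain=model.gain_,
        converged=model.converged_,
        genotype_label=rlf.genotype_label,
    )


def filter_fits(
    fits: list[RLFFit], rmse_cutoff: float = RMSE_CUTOFF
) -> tuple[list[RLFFit], pd.DataFrame]:
    """Keep fits with RMSE below the cutoff; report kept/excluded by genotype."""
    kept = [f for f in fits if f.converged and f.rmse < rmse_cutoff]
    excluded = [f for f in fits if not (f.converged and f.rmse < rmse_cutoff)]
    labels = sorted({f.genotype_label for f in fits})
    report = pd.DataFrame(
        [
            {
                "genotype": lab,
                "n_kept": sum(1 for f in kept if f.genotype_label == lab),
                "n_excluded": sum(1 for f in excluded if f.genotype_label == lab),
                "excluded_units": [f.unit_id for f in excluded if f.genotype_label == lab],
            }
            for lab in labels
        ]
    )
    return kept, report


def fits_to_frame(fits: list[RLFFit]) -> pd.DataFrame:
    """Tidy CSV-ready table of fit parameters and derived metrics."""
    return pd.DataFrame(
        [
            {
                "unit_id": f.unit_id,
                "genotype": f.genotype_label,
                "a": f.a, "b": f.b, "c": f.c, "d": f.d, "e": f.e, "f": f.f,
                "rmse": f.rmse,
                "resp_min": f.resp_min,
                "resp_max": f.resp_max,
                "threshold_db": f.threshold_db,
                "gain": f.gain,
                "converged": f.converged,
            }
            for f in fits
        ]
    )
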