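"""Bayesian population decoder linking cortical tuning to discrimination.

A population of tonotopically arranged model neurons (default 640,
preferred frequencies equally log-spaced over 1-64 kHz) shares a Gaussian
tuning profile on the octave axis,

    f(x) = A * exp(-(x - B)^2 / sigma^2) + N ,

with A the peak evoked drive above baseline, B the preferred frequency
(octaves re 1 kHz), sigma the tuning width and N the baseline drive.  The
exponent uses sigma^2 as a plain scale (set ``squared_form=False`` for the
conventional 2 sigma^2 denominator).  Tuning width is informed by measured
bandwidth: the tuning edge is where the Gaussian first diverges from the
baseline asymptote, approximated by the 99% point of the normal CDF
written with the error function,

    P(X <= x) = 1/2 [1 + Erf((x - mu) / (sigma sqrt(2)))] ,

so sigma = (bandwidth / 2) / z_0.99 (solved by root finding on the Erf
form, :func:`sigma_from_bandwidth`).

Single-trial activity is a Poisson draw with mean f(stimulus) per neuron,
propagated to the readout only if it surpasses 90% of the baseline drive
(sub-threshold draws are transmitted as zero: a censored-Poisson readout).
A Bayesian classifier compares the censored-Poisson likelihood of the
population vector under the Go and No-Go hypotheses.  Experiments sweep
No-Go offsets in 1/12-octave steps up to one octave from Go tones at 4, 8,
16 and 32 kHz, with balanced Go/No-Go error rates per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import erf
from scipy.stats import poisson

__all__ = [
    "TuningSummary",
    "DecoderPopulation",
    "DecoderExperimentResult",
    "sigma_from_bandwidth",
    "bandwidth_from_sigma",
    "build_population",
    "simulate_readout",
    "CensoredPoissonBayesDecoder",
    "bayes_classify",
    "run_discrimination_experiment",
    "parameter_permutation_experiment",
    "parameter_sweep",
    "scaled_summary",
    "summary_from_recordings",
    "WT_SUMMARY",
    "MIDDLE_BAND_TWELFTHS",
]

#: Offsets (twelfth-octaves) forming the 1/3-2/3-octave band.
MIDDLE_BAND_TWELFTHS = (4, 5, 6, 7, 8)

#: Edge-probability defining the tuning edge on the normal CDF.
EDGE_P = 0.99


def _z_from_erf(p: float) -> float:
    """Standard-normal quantile solved from the Erf form of the CDF."""
    if not 0.5 < p < 1.0:
        raise ValueError("edge probability must lie in (0.5, 1)")
    return brentq(lambda z: 0.5 * (1.0 + erf(z / np.sqrt(2.0))) - p, 0.0, 40.0, xtol=1e-14)


def sigma_from_bandwidth(full_bandwidth_oct: float, edge_p: float = EDGE_P) -> float:
    """Tuning width sigma (octaves) from a measured full bandwidth.

    The bandwidth edges are where the cumulative normal reaches
    ``edge_p``; hence half the bandwidth equals z_p * sigma.
    """
    if full_bandwidth_oct <= 0:
        raise ValueError("bandwidth must be positive")
    return (full_bandwidth_oct / 2.0) / _z_from_erf(edge_p)


def bandwidth_from_sigma(sigma_oct: float, edge_p: float = EDGE_P) -> float:
    """Inverse of :func:`sigma_from_bandwidth`."""
    if sigma_oct <= 0:
        raise ValueError("sigma must be positive")
    return 2.0 * sigma_oct * _z_from_erf(edge_p)


@dataclass(frozen=True)
class TuningSummary:
    """Mean tuning parameters feeding the decoder population.

    ``amplitude`` and ``baseline`` are per-trial readout drive (Poisson
    means); ``sigma_oct`` is the Gaussian tuning width in octaves.
    ``center_oct`` is optional (populations assign centers on a grid).
    """

    amplitude: float
    sigma_oct: float
    baseline: float
    center_oct: float | None = None

    def __post_init__(self):
        if self.amplitude < 0 or self.baseline < 0:
            raise ValueError("amplitude and baseline must be nonnegative")
        if self.sigma_oct <= 0:
            raise ValueError("sigma must be positive")


#: Wild-type-like base summary: broad suprathreshold tuning (2.5-octave
#: bandwidth) and a per-trial readout drive placing the 640-neuron decoder
#: in the overlap-limited regime, off floor and ceiling in the
#: 1/3-2/3-octave band.
WT_SUMMARY = TuningSummary(amplitude=0.2, sigma_oct=sigma_from_bandwidth(2.5), baseline=0.08)


def scaled_summary(
    base: TuningSummary,
    spont_scale: float = 1.0,
    evoked_scale: float = 1.0,
    width_scale: float = 1.0,
) -> TuningSummary:
    """Apply genotype-like multiplicative scales to a base summary."""
    return TuningSummary(
        amplitude=base.amplitude * evoked_scale,
        sigma_oct=base.sigma_oct * width_scale,
        baseline=base.baseline * spont_scale,
    )


@dataclass
class DecoderPopulation:
    """Gaussian-tuned model neurons on the octave axis."""

    B_oct: np.ndarray
    amplitude: np.ndarray
    sigma_oct: np.ndarray
    baseline: np.ndarray
    label: str = ""
    squared_form: bool = True  # exponent (x-B)^2 / sigma^2 as printed

    def __post_init__(self):
        self.B_oct = np.asarray(self.B_oct, dtype=float)
        n = self.B_oct.size
        if np.any(np.diff(self.B_oct) <= 0):
            raise ValueError("preferred frequencies must be strictly increasing")
        for name in ("amplitude", "sigma_oct", "baseline"):
            v = np.broadcast_to(np.asarray(getattr(self, name), dtype=float), (n,)).copy()
            setattr(self, name, v)

    @property
    def n_neurons(self) -> int:
        return int(self.B_oct.size)

    def rates(self, stim_freq_khz: float) -> np.ndarray:
        """Mean drive per neuron for a stimulus frequency (kHz)."""
        x = np.log2(stim_freq_khz)
        denom = self.sigma_oct**2 * (1.0 if self.squared_form else 2.0)
        return self.amplitude * np.exp(-((x - self.B_oct) ** 2) / denom) + self.baseline


def build_population(
    summary: TuningSummary,
    n_neurons: int = 640,
    f_range_khz: tuple[float, float] = (1.0, 64.0),
    label: str = "",
    squared_form: bool = True,
) -> DecoderPopulation:
    """Population sharing the mean tuning summary, centers on a log grid."""
    lo, hi = f_range_khz
    if not 0 < lo < hi:
        raise ValueError("invalid frequency range")
    B = np.linspace(np.log2(lo), np.log2(hi), n_neurons)
    return DecoderPopulation(
        B_oct=B,
        amplitude=summary.amplitude,
        sigma_oct=summary.sigma_oct,
        baseline=summary.baseline,
        label=label,
        squared_form=squared_form,
    )


def _kmin(baseline: np.ndarray, threshold_frac: float) -> np.ndarray:
    """Smallest integer count that surpasses the propagation threshold."""
    return np.ceil(threshold_frac * baseline - 1e-12).astype(int)


def simulate_readout(
    pop: DecoderPopulation,
    stim_freq_khz: float,
    n_trials: int,
    seed: int | np.random.Generator = 0,
    threshold_frac: float = 0.9,
) -> np.ndarray:
    """Censored-Poisson single-trial activity, shape (n_trials, n_neurons).

    Each draw is Poisson with mean f(stimulus); draws below
    ``threshold_frac * baseline`` are propagated as zero.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    rng = np.random.default_rng(seed)
    lam = pop.rates(stim_freq_khz)
    k = rng.poisson(lam, size=(n_trials, pop.n_neurons))
    kmin = _kmin(pop.baseline, threshold_frac)
    k[k < kmin[None, :]] = 0
    return k


class CensoredPoissonBayesDecoder:
    """Bayesian Go/No-Go classifier under the censored-Poisson model.

    scikit-learn style classifier: ``fit()`` precomputes the per-neuron
    log-likelihood terms for the two hypothesis frequencies; ``predict``
    labels trial x neuron activity matrices; ``predict_proba`` returns the
    posterior.  The decoding likelihood matches the generation model
    exactly: the probability mass of all sub-threshold counts is assigned
    to the observed zero, and the plain Poisson pmf applies above
    threshold.  Exact posterior ties are broken by a fair coin.
    """

    classes_ = np.array(["go", "nogo"])

    def __init__(
        self,
        population: DecoderPopulation,
        go_freq_khz: float,
        nogo_freq_khz: float,
        prior_go: float = 0.5,
        threshold_frac: float = 0.9,
        random_state: int | np.random.Generator | None = None,
    ):
        self.population = population
        self.go_freq_khz = go_freq_khz
        self.nogo_freq_khz = nogo_freq_khz
        self.prior_go = prior_go
        self.threshold_frac = threshold_frac
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "population": self.population,
            "go_freq_khz": self.go_freq_khz,
            "nogo_freq_khz": self.nogo_freq_khz,
            "prior_go": self.prior_go,
            "threshold_frac": self.threshold_frac,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None):
        """Precompute likelihood terms (the model is generative, no learning)."""
        if not 0.0 < self.prior_go < 1.0:
            raise ValueError("prior must lie in (0, 1)")
        pop = self.population
        tiny = 1e-300
        self.lam_go_ = pop.rates(self.go_freq_khz)
        self.lam_nogo_ = pop.rates(self.nogo_freq_khz)
        self.kmin_ = _kmin(pop.baseline, self.threshold_frac)
        # P(observed 0) under each hypothesis: all sub-threshold mass, or
        # the plain pmf at zero when nothing is censored.
        k0 = np.maximum(self.kmin_ - 1, 0)
        p0_go = poisson.cdf(k0, self.lam_go_)
        p0_nogo = poisson.cdf(k0, self.lam_nogo_)
        self._c0 = np.log(np.maximum(p0_go, tiny)) - np.log(np.maximum(p0_nogo, tiny))
        self._lr = np.log(np.maximum(self.lam_go_, tiny)) - np.log(
            np.maximum(self.lam_nogo_, tiny)
        )
        self._dlam = self.lam_go_ - self.lam_nogo_
        self._rng = np.random.default_rng(self.random_state)
        return self

    def _check_fitted(self):
        if not hasattr(self, "_c0"):
            raise AttributeError("decoder is not fitted; call fit() first")

    def decision_function(self, X) -> np.ndarray:
        """Log posterior odds for 'go', one value per trial."""
        self._check_fitted()
        K = np.atleast_2d(np.asarray(X))
        pos = K > 0
        score = (
            np.where(pos, K * self._lr[None, :] - self._dlam[None, :], 0.0).sum(axis=1)
            + (~pos) @ self._c0
        )
        return score + np.log(self.prior_go / (1.0 - self.prior_go))

    def predict_proba(self, X) -> np.ndarray:
        """Posterior [P(go), P(nogo)] per trial."""
        s = self.decision_function(X)
        p_go = 1.0 / (1.0 + np.exp(-s))
        return np.column_stack([p_go, 1.0 - p_go])

    def predict(self, X) -> np.ndarray:
        """Maximum-posterior label per trial; exact ties -> fair coin."""
        s = self.decision_function(X)
        labels = np.where(s > 0, "go", "nogo")
        ties = s == 0
        if np.any(ties):
            flips = self._rng.random(int(ties.sum())) < 0.5
            labels[ties] = np.where(flips, "go", "nogo")
        return labels


def bayes_classify(
    activity,
    population: DecoderPopulation,
    go_freq_khz: float,
    nogo_freq_khz: float,
    prior_go: float = 0.5,
    threshold_frac: float = 0.9,
    random_state=None,
) -> tuple[str, float]:
    """Classify one trial's activity vector; returns (label, P(go))."""
    dec = CensoredPoissonBayesDecoder(
        population, go_freq_khz, nogo_freq_khz, prior_go=prior_go,
        threshold_frac=threshold_frac, random_state=random_state,
    ).fit()
    x = np.atleast_2d(np.asarray(activity))
    label = dec.predict(x)[0]
    p_go = float(dec.predict_proba(x)[0, 0])
    return str(label), p_go


@dataclass
class DecoderExperimentResult:
    """Per-run, per-condition decoder error rates."""

    results: pd.DataFrame  # run, go_freq_khz, offset_twelfths, miss, fa, error
    n_trials: int
    n_runs: int
    seed: int
    label: str = ""

    def error_vs_offset(self) -> pd.DataFrame:
        """Mean error by |offset| aggregated over Go frequencies and sign."""
        df = self.results.assign(abs_offset=self.results["offset_twelfths"].abs())
        return (
            df.groupby(["run", "abs_offset"])["error"].mean().reset_index()
        )

    def band_error(self, band_twelfths=MIDDLE_BAND_TWELFTHS) -> pd.Series:
        """Per-run mean error over |offset| in the band (default 1/3-2/3 oct)."""
        df = self.results
        mask = df["offset_twelfths"].abs().isin(band_twelfths)
        return df[mask].groupby("run")["error"].mean()


def _resolve_population(pop_or_summary, n_neurons, f_range_khz, squared_form, label=""):
    if isinstance(pop_or_summary, DecoderPopulation):
        return pop_or_summary
    return build_population(
        pop_or_summary, n_neurons=n_neurons, f_range_khz=f_range_khz,
        label=label, squared_form=squared_form,
    )


def run_discrimination_experiment(
    pop_or_summary,
    go_freqs_khz: tuple[float, ...] = (4.0, 8.0, 16.0, 32.0),
    offsets_twelfths: tuple[int, ...] | None = None,
    n_trials: int = 10_000,
    n_runs: int = 15,
    seed: int = 0,
    n_neurons: int = 640,
    f_range_khz: tuple[float, float] = (1.0, 64.0),
    threshold_frac: float = 0.9,
    prior_go: float = 0.5,
    squared_form: bool = True,
    label: str = "",
) -> DecoderExperimentResult:
    """Balanced Go/No-Go decoding error per (run, Go frequency, offset).

    For each condition, ``n_trials`` Go-stimulus and ``n_trials``
    No-Go-stimulus trials are simulated and classified; the error rate is
    the balanced mean of the miss and false-alarm rates.  Seeds for each
    (run, condition) are spawned deterministically from the master seed.
    """
    if offsets_twelfths is None:
        offsets_twelfths = tuple(range(-12, 0)) + tuple(range(1, 13))
    pop = _resolve_population(pop_or_summary, n_neurons, f_range_khz, squared_form, label)
    master = np.random.SeedSequence(seed)
    run_seqs = master.spawn(n_runs)
    rows = []
    for run, run_seq in enumerate(run_seqs):
        cond_seqs = iter(run_seq.spawn(len(go_freqs_khz) * len(offsets_twelfths)))
        for go in go_freqs_khz:
            for off in offsets_twelfths:
                sq = next(cond_seqs)
                nogo = go * 2.0 ** (off / 12.0)
                dec = CensoredPoissonBayesDecoder(
                    pop, go, nogo, prior_go=prior_go,
                    threshold_frac=threshold_frac,
                    random_state=np.random.default_rng(sq),
                ).fit()
                rng_go, rng_nogo = (np.random.default_rng(s) for s in sq.spawn(2))
                k_go = simulate_readout(pop, go, n_trials, rng_go, threshold_frac)
                k_nogo = simulate_readout(pop, nogo, n_trials, rng_nogo, threshold_frac)
                miss = float(np.mean(dec.predict(k_go) == "nogo"))
                fa = float(np.mean(dec.predict(k_nogo) == "go"))
                rows.append((run, go, off, miss, fa, 0.5 * (miss + fa)))
    df = pd.DataFrame(
        rows, columns=["run", "go_freq_khz", "offset_twelfths", "miss", "fa", "error"]
    )
    return DecoderExperimentResult(
        results=df, n_trials=n_trials, n_runs=n_runs, seed=seed, label=label or pop.label
    )


#: The eight parameter permutations of the swap experiment.
PERMUTATIONS = (
    ("WT_full", ()),
    ("KO_spont", ("spont",)),
    ("KO_evoked", ("evoked",)),
    ("KO_width", ("width",)),
    ("KO_spont+evoked", ("spont", "evoked")),
    ("KO_spont+width", ("spont", "width")),
    ("KO_evoked+width", ("evoked", "width")),
    ("KO_full", ("spont", "evoked", "width")),
)


def _permuted_summary(wt: TuningSummary, ko: TuningSummary, swapped: tuple) -> TuningSummary:
    return TuningSummary(
        amplitude=ko.amplitude if "evoked" in swapped else wt.amplitude,
        sigma_oct=ko.sigma_oct if "width" in swapped else wt.sigma_oct,
        baseline=ko.baseline if "spont" in swapped else wt.baseline,
    )


def parameter_permutation_experiment(
    wt_summary: TuningSummary,
    ko_summary: TuningSummary,
    band_twelfths: tuple[int, ...] = MIDDLE_BAND_TWELFTHS,
    go_freqs_khz: tuple[float, ...] = (4.0, 8.0, 16.0, 32.0),
    n_trials: int = 10_000,
    n_runs: int = 15,
    seed: int = 0,
    **experiment_kwargs,
) -> pd.DataFrame:
    """Band error for every WT/KO parameter swap combination.

    Each permutation takes the knockout value for the named parameters
    (spontaneous baseline, evoked amplitude, tuning width) and the
    wild-type value otherwise, and is evaluated over the No-Go offsets in
    the 1/3-2/3-octave band.  Tidy output: permutation, run, band_error.
    """
    offsets = tuple(-o for o in band_twelfths) + tuple(band_twelfths)
    rows = []
    for i, (name, swapped) in enumerate(PERMUTATIONS):
        summary = _permuted_summary(wt_summary, ko_summary, swapped)
        res = run_discrimination_experiment(
            summary,
            go_freqs_khz=go_freqs_khz,
            offsets_twelfths=offsets,
            n_trials=n_trials,
            n_runs=n_runs,
            seed=seed + i,
            label=name,
            **experiment_kwargs,
        )
        for run, err in res.band_error(band_twelfths).items():
            rows.append((name, run, err))
    return pd.DataFrame(rows, columns=["permutation", "run", "band_error"])


def parameter_sweep(
    base_summary: TuningSummary,
    axis: str,
    grid: tuple[float, ...],
    band_twelfths: tuple[int, ...] = MIDDLE_BAND_TWELFTHS,
    go_freqs_khz: tuple[float, ...] = (4.0, 8.0, 16.0, 32.0),
    n_trials: int = 10_000,
    n_runs: int = 15,
    seed: int = 0,
    **experiment_kwargs,
) -> pd.DataFrame:
    """Band error while sweeping one summary parameter multiplicatively.

    ``axis`` is one of ``width`` (tuning sigma), ``noise`` (baseline
    drive) or ``amplitude`` (evoked drive); ``grid`` holds multipliers
    applied to the base summary.  Tidy output: axis, multiplier, run,
    band_error.
    """
    if axis not in ("width", "noise", "amplitude"):
        raise ValueError(f"unknown sweep axis {axis!r}")
    if len(grid) == 0:
        raise ValueError("sweep grid must be nonempty")
    offsets = tuple(-o for o in band_twelfths) + tuple(band_twelfths)
    rows = []
    for i, mult in enumerate(grid):
        scales = {
            "width": dict(width_scale=mult),
            "noise": dict(spont_scale=mult),
            "amplitude": dict(evoked_scale=mult),
        }[axis]
        summary = scaled_summary(base_summary, **scales)
        res = run_discrimination_experiment(
            summary,
            go_freqs_khz=go_freqs_khz,
            offsets_twelfths=offsets,
            n_trials=n_trials,
            n_runs=n_runs,
            seed=seed + i,
            label=f"{axis}x{mult:g}",
            **experiment_kwargs,
        )
        for run, err in res.band_error(band_twelfths).items():
            rows.append((axis, mult, run, err))
    return pd.DataFrame(rows, columns=["axis", "multiplier", "run", "band_error"])


def summary_from_recordings(
    matrices,
    fra_metrics,
    drive_scale: float = 0.002,
    evoked_window: tuple[float, float] = (0.0, 40.0),
    delta_db: int = 40,
) -> TuningSummary:
    """Mean tuning summary from analyzed recordings.

    The per-unit inputs are the measured spontaneous rate, the driven rate
    at CF at ``delta_db`` above minimum threshold (minus baseline), and
    the bandwidth at that level (in octaves, converted to sigma through
    the tuning-edge relation).  ``drive_scale`` converts spikes/s into the
    decoder's per-trial readout drive.
    """
    amps, sigmas, bases = [], [], []
    for m, fm in zip(matrices, fra_metrics):
        if not fm.resolved:
            continue
        spont = m.spontaneous_rate()
        target = fm.min_threshold_db + delta_db
        at_or_below = np.nonzero(m.levels <= target + 1e-9)[0]
        level = float(m.levels[at_or_below[-1]])
        driven = m.cell(fm.cf_khz, level).rate_in(*evoked_window) - spont
        band = fm.bw.get(delta_db)
        if band is None or band[1] <= band[0]:
            continue
        bw_oct = np.log2(band[1] / band[0])
        amps.append(max(driven, 0.0))
        sigmas.append(sigma_from_bandwidth(bw_oct))
        bases.append(spont)
    if not amps:
        raise ValueError("no resolvable units to summarize")
    return TuningSummary(
        amplitude=float(np.mean(amps)) * drive_scale,
        sigma_oct=float(np.mean(sigmas)),
        baseline=float(np.mean(bases)) * drive_scale,
    )
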