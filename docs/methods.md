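# Methods

This note documents the models and procedures implemented in `freqdisc`,
the numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the known limitations. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Recording model and evoked-response criterion

Spike times are stored in milliseconds relative to tone onset within an
analysis window of −40 to +100 ms. A *tuning matrix* holds the full
frequency × intensity grid for one multi-unit cluster (default 20
log-spaced frequencies over 1–64 kHz × 10 levels over 0–90 dB SPL, 30
repeats per cell). PSTHs use half-open 5-ms bins `[lo, hi)` and
trial-averaged counts.

A cell is *evoked* when any bin fully inside 0–40 ms post-onset exceeds
`mean(pre) + 4·SD(pre)`, the pre-stimulus statistics coming from the
−40–0 ms bins. Two refinements make this criterion usable at realistic
spontaneous rates:

* **SD floor.** The empirical SD over eight pre-stimulus bins is a noisy,
  downward-biased estimate for sparse baselines, and is undefined at
  exactly zero; `sqrt(mean / n_trials)` — the SD of a trial-averaged
  Poisson bin at the pre-stimulus mean rate — acts as a lower bound, with
  an absolute floor of `1/n_trials` counts.
* **Pooled baseline (FRA analyses).** Spontaneous activity does not
  depend on the stimulus, so `evoked_map` pools the pre-stimulus mean and
  SD over every cell of the matrix (1,600 bins) before applying the
  per-cell exceedance test. A per-cell mode is available
  (`pooled_baseline=False`), matching the single-PSTH behavior of
  `detect_evoked`.

Even with exact baseline statistics, a 4-SD Poisson test applied to
~1,600 baseline bins per unit produces on the order of one false positive
per unit. Real analyses handle this with manual curation of "discernible
tuning curves"; the automatic stand-in here is the **persistence rule**
(`require_support=True` in `extract_fra_metrics`): an evoked cell counts
toward per-frequency thresholds and bandwidth rows only if the cell one
level up is also evoked. The excitatory region of a V-shaped FRA is
upward-closed in level, so genuine responses persist and isolated false
exceedances (which essentially never recur in the adjacent cell) are
discarded. The raw per-cell rule remains available.

## Synthetic recordings

Each simulated unit has a characteristic frequency (CF, log-uniform over
2–32 kHz), a baseline rate (uniform 5–15 spikes/s), a peak evoked rate
(uniform 150–250 spikes/s above baseline — multi-unit magnitudes), a
minimum threshold (10/20/30 dB SPL) and a V-shaped excitatory region
whose half-width in octaves grows linearly with level:
`hw(L) = hw₀ + slope·(L − threshold)`, with `hw₀ = 0.25` octave at
threshold (so the nearest grid frequency, at most 0.16 octave from CF,
responds at threshold) and the slope set so the full width at
threshold + 40 dB equals the unit's nominal 40-dB bandwidth (uniform
0.8–1.4 octaves). Within the region the evoked rate falls off linearly in
octave distance (triangular profile) and ramps with level from 50% of
peak at threshold to 100% at threshold + 40 dB. Spiking is inhomogeneous
Poisson: baseline throughout the window plus the evoked rate during
[latency, latency + duration] = [15, 40] ms, placing evoked spikes inside
the 0–40 ms detection window.

Genotype-like regimes are multiplicative scales on the base population:
wild-type-like {spont 1.0, evoked 1.0, width 1.0}; knockout-cortex-like
{1.5, 1.3, 1.4} (elevated spontaneous rate, elevated evoked gain,
broadened tuning — the width scale multiplies the entire half-width
function, threshold width included); knockout-midbrain-like {1.0, 1.0,
1.0}. The magnitudes are fixture choices that set the direction and
rough size of the effects, not measured values.

Behavioral sessions: the detection generator is an equal-variance
Gaussian observer with a single fixed criterion placed so the catch-trial
false-alarm probability equals the configured floor; hence
`hit(L) = Φ(d′(L) + z(fa_floor))` with a logistic d′-vs-level curve
(default maximum 3.5, midpoint 25 dB, slope 4 dB), ~30% catch trials, and
the session is exactly invertible by the d′ analysis. (A criterion
parameterized per-level would make the catch-trial FA level-dependent,
which is incoherent for catch trials.) The discrimination generator emits
50:50 Go/No-Go trials with No-Go tones in 1/12-octave steps up to one
octave from the Go tone and a sigmoid FA-vs-octave-distance curve
(floor 0.05, ceiling 0.85, midpoint 0.5 octave).

All generators are bit-reproducible given (seed, configuration).

## Psychophysics

`d′ = z(hit) − z(fa)` with rates clipped to `[1/(2n), 1 − 1/(2n)]` for
their respective trial counts — chosen over the log-linear correction
because it preserves the antisymmetry `d′(h, f) = −d′(f, h)`. Detection
thresholds interpolate the d′-vs-level curve linearly in dB and report
the lowest crossing of the criterion (default 1.5) from below; a curve
already above criterion at the lowest tested level resolves to that
level, and a curve that never crosses is unresolved. FA-by-octave pools
No-Go trials by |log₂(f/go)| snapped to the nearest 1/12 octave, keeping
the side (above/below) as counts; band edges are near [0, 1/3), middle
[1/3, 2/3], far (2/3, 1] octaves, and band means are trial-weighted.

## Rate-level functions

The RLF is the mean evoked-window (0–40 ms) rate at the CF column versus
level. The model is logistic-plus-Gaussian with a shared width:

    y(x) = a + (d − a)/(1 + exp((b − x)/c)) + e·exp(−(x − f)²/(2c²))

Derived: threshold = lowest level (1-dB grid over the tested span) where
the fitted curve reaches `a + 0.2(d − a)`; gain = maximum ascending slope
on the same grid (a closed form for the composite curve's maximum slope
does not exist). Admission: unweighted RMSE < 100 spikes/s.

Fitting numerics: trust-region least squares with 16 multi-starts
spanning monotone and bump shapes, plus a staged start (sigmoid-only fit,
Gaussian seeded from the residual peak) and a polish phase re-descending
from the incumbent with the width halved/doubled and the roles of `b` and
`f` swapped. Ties in the objective break toward the smaller width.
Bounds: asymptotes and amplitude within 1.5× the observed maximum + 10
(unbounded values admit degenerate fits whose rise is extrapolated beyond
the tested levels), `b`, `f` within the tested span ± 10 dB, and
`c ∈ [2.5, 25]` dB so the Gaussian can neither collapse onto a single
tested level nor stretch the logistic rise far beyond the span. Ordinary
least squares is the default; `weighting='poisson'` (inverse Poisson SD
per point) is available.

Identifiability caveat: with 10 levels, 6 parameters and 30-trial Poisson
noise, near-equivalent minima with displaced thresholds exist for a
minority of shapes; the derived threshold is then only stable to several
dB. The acceptance suite measures this directly.

## Frequency response areas

Per-frequency threshold = lowest (curated) evoked level; CF = frequency
with the minimal threshold; ties break toward the frequency with the
larger evoked-window rate at threshold, then toward the lower frequency
(flagged). Bandwidth at +10/+20/+30/+40 dB re threshold spans the first
to last evoked cell of the row with no contiguity requirement along
frequency; rows falling off the tested grid snap to the nearest row at or
below (flagged) or are unresolved above it. `Q = CF/(f_hi − f_lo)` uses
linear-kHz bandwidth, which makes Q invariant to a common rescaling of
all frequencies; zero bandwidth leaves Q undefined (flagged). Unresolved
units are a valid outcome, not an error.

## Rate-independent SPIKE-distance

For a train pair at time t, each train contributes
`S_n(t) = (Δt_P·x_F + Δt_F·x_P)/x_ISI`, built from the preceding and
following spikes around t and their distances to the nearest spike of
the other train. The rate-independent profile leaves these contributions
unweighted by the local interspike intervals:

    S'(t) = (S₁(t) + S₂(t)) / (2⟨x_ISI⟩)

with ⟨x_ISI⟩ the mean of the two current interspike intervals. The
first-power normalization is the published rate-independent convention;
it is the only dimensionally consistent choice and the one under which
the distance is exactly invariant to a uniform rescaling of time (a
property the test suite asserts). Auxiliary spikes at the window edges
(standard edge correction) make all terms defined near the boundaries,
and identical trains give exactly zero.

The profile is piecewise linear between the spikes of either train, so
the time integral is computed segment-by-segment exactly; a dense-grid
(0.01 ms) brute-force evaluation of the definitions is kept in the test
suite as the independent oracle. For N trains the instantaneous profile
is the mean over all N(N−1)/2 pairs; since averaging commutes with
integration, D equals the mean of the exact pairwise distances, which is
how it is computed.

The Δ-distance analysis runs at 40 dB above a unit's minimum threshold
(the level of the behavioral discrimination task) over the window 0–100
ms post-onset (pre-stimulus spikes excluded; config-exposed). The default
comparison averages the 30 × 30 cross-pair distance matrix between the
CF block and each neighboring-frequency block within ±1 octave (the
pooled 60-train distance is the config alternative), minus the within-CF
30-train distance, so Δ = 0 at zero separation by construction. The
cross-matrix form mirrors how such comparisons are tabulated and is
markedly more stable per unit than pooling.

## Population decoder

A population of 640 neurons with preferred frequencies B equally spaced
on the octave axis over 1–64 kHz shares a Gaussian tuning profile
`f(x) = A·exp(−(x − B)²/σ²) + N`; all stimulus arithmetic is in octaves,
so 1/12-octave steps and "equally log-spaced" are uniform and error rates
are invariant to a common rescaling of frequency units. The exponent uses
σ² as a plain scale, as the tuning model is stated; the conventional 2σ²
form is available (`squared_form=False`) for sensitivity analysis.
Tuning width comes from measured bandwidth via the tuning-edge relation:
the edge is where the cumulative normal written with the error function
reaches 0.99, so `σ = (bandwidth/2)/z₀.₉₉` with z₀.₉₉ obtained by root
finding on the Erf form (not a hard-coded constant).

Single-trial activity is Poisson with mean f(stimulus) per neuron,
propagated only if it surpasses 90% of the baseline drive — sub-threshold
draws transmit as zero (censored Poisson). The Bayesian readout uses the
matching censored likelihood (all sub-threshold mass assigned to the
observed zero; plain Poisson pmf above threshold), so the decoding model
equals the generation model; any mismatched likelihood would be an extra
assumption. Posterior ties break by a fair coin, which makes the
zero-separation error exactly binomial around 1/2. Experiments run
balanced Go and No-Go trials per condition (error = (miss + FA)/2,
"10,000 trials" read as per stimulus condition), with per-(run,
condition) seeds spawned deterministically from one master seed.

**Base tuning summary (design calibration).** The decoder has two
qualitatively different regimes. With very small per-trial drive it is
spike-count-limited: broader tuning recruits more driven spikes and
*helps* discrimination — the opposite of the cortical phenomenon. With
moderate drive and broad tuning it is overlap-limited: broader tuning
blurs the population pattern, error declines gradedly with octave
distance, and width degrades performance. The wild-type-like default
summary — per-trial drive A = 0.2 above baseline N = 0.08, suprathreshold
bandwidth 2.5 octaves (σ ≈ 0.54 oct) — was fixed by a Fisher-information
estimate to sit in the overlap-limited regime with middle-band
(1/3–2/3 octave) error off floor and ceiling, and not revisited. The
absolute drive is a readout normalization, not a literal cortical rate;
only directions and relative effects are interpretable.

The parameter-swap experiment evaluates all eight combinations of taking
the knockout value for {spontaneous baseline, evoked amplitude, tuning
width} against the wild-type summary, restricted to the 1/3–2/3-octave
band (offsets ±4..8 twelfths); parameter sweeps scale one axis (width,
noise, amplitude) multiplicatively. Statistical comparison of per-run
errors (rank tests etc.) is left to standard tools.

`summary_from_recordings` derives a population summary from analyzed
matrices (spontaneous rate, driven rate at CF at +40 dB, bandwidth → σ),
with a `drive_scale` (default 0.002 per spikes/s) converting firing rates
to per-trial readout drive.

## Pipeline

`run_pipeline` executes simulate → behavior → fra → rlf → spikedist →
decode → report in dependency order; every stage is a pure function of
(inputs, config, seed), child seeds are spawned from the master seed, and
a JSON manifest records files, seeds, versions and record counts. The
default run uses 6 units per regime and a reduced decoder (1,000 trials ×
5 runs); the CLI exposes each stage and `run-all`.

## Problem sizes

The test and acceptance runs use: 50 random parameter sets for rate-level
recovery; 100 random train pairs (≤ 10 spikes) against the 0.01-ms
brute-force oracle; exhaustive outcome enumeration on ≤ 3-neuron toy
populations; decoder experiments at 1,000 trials × 5 runs (10,000 × 1 for
the chance floor); 12 + 12 synthetic units for the population-level
tuning and Δ-distance comparisons; and 20 seeded behavioral sessions per
mode. These sizes keep a full run in the minutes range on one CPU while
leaving the direction-of-effect comparisons well clear of their sampling
noise.

## Limitations

* The generator omits adaptation, across-trial nonstationarity,
  correlated noise across units and non-V (multi-peaked, inhibitory)
  FRAs; passing tests demonstrate correctness of the analyses under the
  stated statistical structure, not robustness to every pathology of real
  recordings.
* The evoked-response persistence rule emulates curation for V-shaped
  regions; units whose true response does not persist with level would be
  under-detected.
* The derived RLF threshold is only identifiable to a few dB under
  30-trial Poisson noise for shallow or strongly non-monotone shapes (see
  the identifiability caveat above).
* Decoder error magnitudes depend on the readout-drive normalization and
  are not comparable to behavioral FA rates; only their dependence on
  octave distance and on tuning parameters is meaningful.
* Inferential statistics (mixed models, rank tests, post-hoc corrections)
  are out of scope; the pipeline emits tidy per-run/per-unit tables for
  standard statistical tooling.
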