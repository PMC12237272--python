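"""Tests for the censored-Poisson Bayesian population decoder.

The independent oracle for classification enumerates every observable
outcome vector of a tiny population and applies Bayes' rule with
explicitly summed Poisson probability masses.
"""

import itertools

import numpy as np
import pytest
from scipy.stats import norm, poisson, spearmanr

from freqdisc.decoder import (
    CensoredPoissonBayesDecoder,
    DecoderPopulation,
    TuningSummary,
    WT_SUMMARY,
    bandwidth_from_sigma,
    bayes_classify,
    build_population,
    parameter_permutation_experiment,
    parameter_sweep,
    run_discrimination_experiment,
    scaled_summary,
    sigma_from_bandwidth,
    simulate_readout,
)


class TestSigmaSolver:
    def test_matches_normal_quantile_oracle(self):
        z99 = norm.ppf(0.99)
        assert sigma_from_bandwidth(2.0 * z99) == pytest.approx(1.0, abs=1e-6)
        for bw in (0.3, 1.0, 2.5):
            assert sigma_from_bandwidth(bw) == pytest.approx(
                bw / 2.0 / z99, abs=1e-9
            )

    def test_linearity(self):
        assert sigma_from_bandwidth(1.0) == pytest.approx(
            2.0 * sigma_from_bandwidth(0.5), rel=1e-12
        )

    def test_round_trip(self):
        for bw in (0.2, 1.7, 4.0):
            assert bandwidth_from_sigma(sigma_from_bandwidth(bw)) == pytest.approx(
                bw, abs=1e-9
            )

    def test_nonpositive_bandwidth_raises(self):
        with pytest.raises(ValueError):
            sigma_from_bandwidth(0.0)


class TestPopulation:
    def test_centers_on_octave_grid(self):
        pop = build_population(WT_SUMMARY, n_neurons=4, f_range_khz=(1.0, 8.0))
        np.testing.assert_allclose(pop.B_oct, [0.0, 1.0, 2.0, 3.0])

    def test_rate_at_preferred_frequency_is_amplitude_plus_baseline(self):
        s = TuningSummary(amplitude=3.0, sigma_oct=0.4, baseline=0.7)
        pop = build_population(s, n_neurons=9, f_range_khz=(1.0, 16.0))
        lam = pop.rates(4.0)  # 2 octaves re 1 kHz: on the 9-point grid
        i = int(np.argmin(np.abs(pop.B_oct - 2.0)))
        assert lam[i] == pytest.approx(3.7)

    def test_conventional_width_form_is_wider(self):
        s = TuningSummary(amplitude=1.0, sigma_oct=0.4, baseline=0.0)
        printed = build_population(s, 9, (1.0, 16.0), squared_form=True)
        conventional = build_population(s, 9, (1.0, 16.0), squared_form=False)
        off = 4.0 * 2.0 ** (0.3)
        i = int(np.argmin(np.abs(printed.B_oct - 2.0)))
        assert conventional.rates(off)[i] > printed.rates(off)[i]


class TestReadout:
    def test_censoring_rate_matches_poisson_cdf_oracle(self):
        # A = 0: propagation probability is P(Poisson(N) >= ceil(0.9 N))
        s = TuningSummary(amplitude=0.0, sigma_oct=0.3, baseline=4.0)
        pop = build_population(s, n_neurons=50, f_range_khz=(1.0, 64.0))
        k = simulate_readout(pop, 8.0, 400, seed=2)
        p_prop = 1.0 - poisson.cdf(np.ceil(0.9 * 4.0) - 1, 4.0)
        observed = np.mean(k > 0)
        se = np.sqrt(p_prop * (1 - p_prop) / k.size)
        assert abs(observed - p_prop) < 3 * se

    def test_zero_baseline_propagates_everything(self):
        s = TuningSummary(amplitude=2.0, sigma_oct=0.3, baseline=0.0)
        pop = build_population(s, n_neurons=20, f_range_khz=(4.0, 16.0))
        rng = np.random.default_rng(0)
        raw = rng.poisson(pop.rates(8.0), size=(500, 20))
        k = simulate_readout(pop, 8.0, 500, seed=np.random.default_rng(0))
        np.testing.assert_array_equal(k, raw)

    def test_remote_stimulus_leaves_censored_baseline(self):
        s = TuningSummary(amplitude=5.0, sigma_oct=0.1, baseline=1.0)
        pop = build_population(s, n_neurons=10, f_range_khz=(1.0, 2.0))
        k = simulate_readout(pop, 60.0, 2000, seed=3)
        lam = 1.0
        kmin = int(np.ceil(0.9))
        expected = np.sum(
            np.arange(kmin, 50) * poisson.pmf(np.arange(kmin, 50), lam)
        )
        assert k.mean() == pytest.approx(expected, abs=0.05)

    def test_readout_determinism(self):
        pop = build_population(WT_SUMMARY, n_neurons=30)
        a = simulate_readout(pop, 8.0, 50, seed=11)
        b = simulate_readout(pop, 8.0, 50, seed=11)
        np.testing.assert_array_equal(a, b)


def _enumeration_oracle(activity, lam_go, lam_nogo, kmin, prior=0.5):
    """Bayes with explicitly summed censored-Poisson masses."""

    def like(obs, lam):
        p = 1.0
        for k, l, km in zip(obs, lam, kmin):
            if k == 0:
                p *= poisson.cdf(max(km - 1, 0), l)
            else:
                p *= poisson.pmf(k, l)
        return p

    num = like(activity, lam_go) * prior
    den = num + like(activity, lam_nogo) * (1 - prior)
    return num / den


class TestBayesClassifier:
    def _toy_population(self):
        # 3 neurons, integer means <= 5 for both hypotheses
        pop = DecoderPopulation(
            B_oct=np.array([1.0, 2.0, 3.0]),
            amplitude=4.0, sigma_oct=0.5, baseline=1.0,
        )
        return pop

    def test_decisions_match_enumeration_oracle_on_all_outcomes(self):
        pop = self._toy_population()
        go, nogo = 4.0, 6.0
        dec = CensoredPoissonBayesDecoder(pop, go, nogo).fit()
        lam_go, lam_nogo = pop.rates(go), pop.rates(nogo)
        kmin = np.ceil(0.9 * pop.baseline - 1e-12).astype(int)
        outcomes = [0] + list(range(int(kmin[0]), 13))
        for vec in itertools.product(outcomes, repeat=3):
            x = np.array(vec)
            p_go = _enumeration_oracle(x, lam_go, lam_nogo, kmin)
            assert dec.predict_proba([x])[0, 0] == pytest.approx(p_go, abs=1e-10)
            if p_go != 0.5:
                expected = "go" if p_go > 0.5 else "nogo"
                assert dec.predict([x])[0] == expected

    def test_identical_hypotheses_give_posterior_half(self):
        pop = self._toy_population()
        label, p_go = bayes_classify([0, 3, 1], pop, 8.0, 8.0)
        assert p_go == pytest.approx(0.5)
        assert label in ("go", "nogo")

    def test_prior_shifts_posterior(self):
        pop = self._toy_population()
        _, p1 = bayes_classify([0, 0, 0], pop, 8.0, 8.0, prior_go=0.9)
        assert p1 == pytest.approx(0.9)

    def test_far_separated_strong_tones_are_classified_correctly(self):
        s = TuningSummary(amplitude=20.0, sigma_oct=0.2, baseline=0.1)
        pop = build_population(s, n_neurons=64, f_range_khz=(1.0, 64.0))
        dec = CensoredPoissonBayesDecoder(pop, 4.0, 32.0, random_state=0).fit()
        k_go = simulate_readout(pop, 4.0, 200, seed=1)
        k_nogo = simulate_readout(pop, 32.0, 200, seed=2)
        assert np.mean(dec.predict(k_go) == "go") == 1.0
        assert np.mean(dec.predict(k_nogo) == "nogo") == 1.0

    def test_sklearn_param_protocol(self):
        pop = self._toy_population()
        dec = CensoredPoissonBayesDecoder(pop, 4.0, 8.0)
        assert dec.get_params()["go_freq_khz"] == 4.0
        dec.set_params(prior_go=0.25)
        assert dec.prior_go == 0.25
        with pytest.raises(AttributeError):
            dec.predict([[0, 0, 0]])


class TestExperiments:
    def test_zero_offset_error_is_half_within_binomial_ci(self):
        res = run_discrimination_experiment(
            WT_SUMMARY, go_freqs_khz=(8.0,), offsets_twelfths=(0,),
            n_trials=4000, n_runs=1, seed=13,
        )
        err = res.results["error"].iloc[0]
        se = np.sqrt(0.25 / (2 * 4000))
        assert abs(err - 0.5) < 2.58 * se

    def test_error_decreases_with_offset_in_each_run(self):
        res = run_discrimination_experiment(
            WT_SUMMARY, go_freqs_khz=(8.0,), offsets_twelfths=(1, 3, 6, 9, 12),
            n_trials=400, n_runs=2, seed=21,
        )
        for _, g in res.error_vs_offset().groupby("run"):
            rho = spearmanr(g["abs_offset"], g["error"]).statistic
            assert rho < 0

    def test_experiment_determinism(self):
        kwargs = dict(go_freqs_khz=(8.0,), offsets_twelfths=(2, 6),
                      n_trials=200, n_runs=2, seed=5)
        a = run_discrimination_experiment(WT_SUMMARY, **kwargs)
        b = run_discrimination_experiment(WT_SUMMARY, **kwargs)
        assert a.results.equals(b.results)

    def test_wider_tuning_increases_expected_error(self):
        errs = []
        for width in (1.0, 1.6, 2.4):
            s = scaled_summary(WT_SUMMARY, width_scale=width)
            res = run_discrimination_experiment(
                s, go_freqs_khz=(8.0,), offsets_twelfths=(4, 6, 8),
                n_trials=600, n_runs=2, seed=31,
            )
            errs.append(res.results["error"].mean())
        assert errs[0] <= errs[1] <= errs[2]

    def test_degenerate_permutation_experiment_is_flat(self):
        # KO summary equal to WT: every permutation has the same expected
        # band error; the spread across permutations stays within noise
        df = parameter_permutation_experiment(
            WT_SUMMARY, WT_SUMMARY, go_freqs_khz=(8.0,),
            n_trials=500, n_runs=2, seed=7,
        )
        means = df.groupby("permutation")["band_error"].mean()
        se = np.sqrt(means.mean() * (1 - means.mean()) / (2 * 500 * 10 * 2))
        assert means.max() - means.min() < 6 * se

    def test_single_point_sweep_reduces_to_experiment(self):
        sweep = parameter_sweep(
            WT_SUMMARY, "width", (1.0,), go_freqs_khz=(8.0,),
            n_trials=300, n_runs=2, seed=9,
        )
        res = run_discrimination_experiment(
            WT_SUMMARY, go_freqs_khz=(8.0,),
            offsets_twelfths=(-4, -5, -6, -7, -8, 4, 5, 6, 7, 8),
            n_trials=300, n_runs=2, seed=9,
        )
        np.testing.assert_allclose(
            sweep["band_error"].to_numpy(), res.band_error().to_numpy()
        )

    def test_unknown_sweep_axis_raises(self):
        with pytest.raises(ValueError, match="axis"):
            parameter_sweep(WT_SUMMARY, "gain", (1.0,))

    def test_frequency_unit_rescaling_invariance(self):
        # everything operates in octaves: scaling all frequencies by a
        # common factor leaves error rates unchanged
        res1 = run_discrimination_experiment(
            WT_SUMMARY, go_freqs_khz=(8.0,), offsets_twelfths=(4, 8),
            n_trials=300, n_runs=1, seed=17, f_range_khz=(1.0, 64.0),
        )
        res2 = run_discrimination_experiment(
            WT_SUMMARY, go_freqs_khz=(8.0 * 4,), offsets_twelfths=(4, 8),
            n_trials=300, n_runs=1, seed=17, f_range_khz=(4.0, 256.0),
        )
        np.testing.assert_allclose(
            res1.results["error"], res2.results["error"]
        )
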