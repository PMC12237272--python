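"""Tests for spike containers, PSTH construction, evoked detection and I/O."""

import numpy as np
import pytest

from freqdisc.core import (
    ParseError,
    PSTH,
    SchemaError,
    SpikeTrain,
    build_psth,
    detect_evoked,
    evoked_map,
    read_spike_table,
    write_spike_table,
)
from freqdisc.synth import UnitGenParams, gen_tuning_matrix

from conftest import SMALL_FREQS, SMALL_LEVELS, make_train_set


class TestSpikeTrain:
    def test_rejects_decreasing_times(self):
        with pytest.raises(ValueError, match="nondecreasing"):
            SpikeTrain(np.array([5.0, 3.0]))

    def test_rejects_out_of_window_times(self):
        with pytest.raises(ValueError, match="window"):
            SpikeTrain(np.array([150.0]))


class TestBuildPsth:
    def test_single_spike_per_trial_lands_in_one_bin(self):
        ts = make_train_set([[10.0]] * 30)
        psth = build_psth(ts, bin_width=5.0)
        idx = psth.bins_in(10.0, 15.0)
        assert psth.counts_per_bin[idx[0]] == pytest.approx(1.0)
        others = np.delete(psth.counts_per_bin, idx[0])
        assert np.all(others == 0.0)

    def test_no_spikes_gives_all_zero_psth(self):
        psth = build_psth(make_train_set([[]] * 10))
        assert np.all(psth.counts_per_bin == 0.0)
        assert psth.bin_edges[0] == -40.0 and psth.bin_edges[-1] == 100.0

    def test_empty_train_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            build_psth(make_train_set([]))

    def test_bad_bin_width_is_an_error(self):
        with pytest.raises(ValueError, match="divide"):
            build_psth(make_train_set([[0.0]]), bin_width=9.0)

    def test_invariant_to_trial_order(self):
        trials = [[1.0, 20.0], [], [33.0], [5.0, 5.5, 60.0]]
        a = build_psth(make_train_set(trials))
        b = build_psth(make_train_set(trials[::-1]))
        np.testing.assert_array_equal(a.counts_per_bin, b.counts_per_bin)

    def test_poisson_rate_oracle(self):
        # homogeneous Poisson at rate r: mean bin count ~= r * bin_width
        rng = np.random.default_rng(11)
        rate, n_trials = 40.0, 300
        trains = []
        for _ in range(n_trials):
            n = rng.poisson(rate * 0.14)
            trains.append(np.sort(rng.uniform(-40.0, 100.0, n)))
        psth = build_psth(make_train_set(trains))
        expected = rate * 0.005
        se = np.sqrt(expected / n_trials / psth.counts_per_bin.size)
        assert abs(psth.counts_per_bin.mean() - expected) < 3 * se * np.sqrt(psth.counts_per_bin.size)


class TestDetectEvoked:
    def _psth(self, counts, n_trials=30):
        counts = np.asarray(counts, dtype=float)
        edges = -40.0 + 5.0 * np.arange(counts.size + 1)
        return PSTH(edges, counts, 5.0, n_trials)

    def test_flat_psth_is_not_evoked(self):
        res = detect_evoked(self._psth(np.full(28, 0.5)))
        assert not res.evoked

    def test_silent_baseline_with_evoked_bin_uses_sd_floor(self):
        counts = np.zeros(28)
        counts[10] = 1.0  # bin [10, 15) ms, well above 4/n_trials floor
        res = detect_evoked(self._psth(counts))
        assert res.evoked and res.peak_time_ms == pytest.approx(10.0)

    def test_uniform_shift_with_fixed_stats_shifts_threshold_with_mean(self):
        # adding a constant to every bin moves mean and exceedance together
        counts = np.tile([0.0, 2.0], 14)  # empirical SD above the Poisson floor
        base = detect_evoked(self._psth(counts))
        shifted = detect_evoked(self._psth(counts + 1.0))
        assert not base.evoked and not shifted.evoked
        assert shifted.threshold_counts - base.threshold_counts == pytest.approx(
            1.0, abs=1e-2
        )

    def test_window_outside_psth_span_is_an_error(self):
        with pytest.raises(ValueError, match="span"):
            detect_evoked(self._psth(np.zeros(8)), evoked_window=(50.0, 90.0))

    def test_detection_on_generator_ground_truth(self):
        # recall over solidly driven cells and false positives over silent
        # cells at the default effect size
        params = UnitGenParams(
            cf_khz=8.0, baseline_rate=10.0, peak_evoked_rate=200.0,
            min_threshold_db=20.0,
        )
        m = gen_tuning_matrix(params, freqs=SMALL_FREQS, levels=SMALL_LEVELS, seed=5)
        em = evoked_map(m)
        hits = misses = fps = n_neg = 0
        for i, f in enumerate(m.freqs):
            for j, l in enumerate(m.levels):
                rate = params.evoked_rate(f, l)
                if rate >= 0.25 * params.peak_evoked_rate:
                    hits += em[i, j]
                    misses += not em[i, j]
                elif rate == 0.0:
                    fps += em[i, j]
                    n_neg += 1
        assert hits / (hits + misses) >= 0.95
        assert fps / n_neg <= 0.05


class TestSpikeTableIO:
    def test_round_trip_is_bit_exact_to_schema_precision(self, small_matrix, tmp_path):
        path = tmp_path / "spikes.csv"
        write_spike_table([small_matrix], path)
        (back,) = read_spike_table(path)
        assert back.unit_id == small_matrix.unit_id
        assert back.genotype_label == small_matrix.genotype_label
        np.testing.assert_allclose(back.freqs, small_matrix.freqs)
        for f_orig, f_rt in zip(small_matrix.freqs, back.freqs):
            for l in small_matrix.levels:
                orig = small_matrix.cell(float(f_orig), float(l))
                rt = back.cell(float(f_rt), float(l))
                assert rt.n_trials == orig.n_trials
                for a, b in zip(orig.trains, rt.trains):
                    np.testing.assert_allclose(b.times, np.round(a.times, 3))

    def test_grouping_counts(self, tmp_path):
        m = gen_tuning_matrix(
            UnitGenParams(cf_khz=8.0, min_threshold_db=20.0),
            freqs=np.array([4.0, 8.0]), levels=np.array([20.0, 60.0]),
            n_trials=30, seed=0,
        )
        path = tmp_path / "spikes.csv"
        write_spike_table([m], path)
        (back,) = read_spike_table(path)
        assert len(back.cells) == 4
        assert all(ts.n_trials == 30 for ts in back.cells.values())

    def test_header_only_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(
            "unit_id,animal_id,penetration_id,genotype,trial_index,freq_khz,level_db,spike_time_ms\n"
        )
        assert read_spike_table(path) == []

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("unit_id,animal_id,trial_index,freq_khz,level_db,spike_time_ms\n")
        with pytest.raises(SchemaError, match="penetration_id"):
            read_spike_table(path)

    def test_non_numeric_time_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "unit_id,animal_id,penetration_id,genotype,trial_index,freq_khz,level_db,spike_time_ms\n"
            "u0,a0,p0,WT,0,8.0,60.0,oops\n"
        )
        with pytest.raises(ParseError, match="row 1"):
            read_spike_table(path)

    def test_out_of_window_spikes_are_rejected_not_fatal(self, tmp_path, caplog):
        path = tmp_path / "clip.csv"
        path.write_text(
            "unit_id,animal_id,penetration_id,genotype,trial_index,freq_khz,level_db,spike_time_ms\n"
            "u0,a0,p0,WT,0,8.0,60.0,10.0\n"
            "u0,a0,p0,WT,0,8.0,60.0,250.0\n"
        )
        (m,) = read_spike_table(path)
        assert m.cell(8.0, 60.0).total_spikes() == 1
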