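import numpy as np
import pytest

from freqdisc.core import SpikeTrain, SpikeTrainSet, TuningMatrix
from freqdisc.synth import UnitGenParams, gen_tuning_matrix

#: Small stimulus grid used by most synthetic-unit tests: 8 log-spaced
#: frequencies over 2-32 kHz, 0-70 dB in 10-dB steps.
SMALL_FREQS = 2.0 * 2.0 ** np.linspace(0.0, 4.0, 8)
SMALL_LEVELS = np.arange(0.0, 71.0, 10.0)


def make_train_set(spike_lists, freq=8.0, level=60.0, unit="u0", window=(-40.0, 100.0)):
    trains = [SpikeTrain(np.asarray(s, dtype=float), window) for s in spike_lists]
    return SpikeTrainSet(unit_id=unit, freq_khz=freq, level_db=level, trains=trains)


@pytest.fixture(scope="session")
def small_unit_params():
    return UnitGenParams(
        cf_khz=8.0,
        baseline_rate=10.0,
        peak_evoked_rate=200.0,
        min_threshold_db=20.0,
        bw_octaves_at_40db=1.1,
    )


@pytest.fixture(scope="session")
def small_matrix(small_unit_params):
    """One synthetic tuning matrix on the small grid (session-cached)."""
    return gen_tuning_matrix(
        small_unit_params,
        freqs=SMALL_FREQS,
        levels=SMALL_LEVELS,
        seed=7,
        unit_id="unit_small",
        genotype_label="WT",
    )


def silent_matrix(freqs=SMALL_FREQS[:3], levels=SMALL_LEVELS[:3], n_trials=5):
    """A matrix with no spikes anywhere."""
    window = (-40.0, 100.0)
    cells = {
        (float(f), float(l)): SpikeTrainSet(
            "silent", float(f), float(l),
            [SpikeTrain(np.empty(0), window) for _ in range(n_trials)],
        )
        for f in freqs
        for l in levels
    }
    return TuningMatrix("silent", np.asarray(freqs), np.asarray(levels), cells)
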