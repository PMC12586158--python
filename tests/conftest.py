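import numpy as np
import pytest

from icdecode import stimgen, synthdata


@pytest.fixture(scope="session")
def battery():
    return stimgen.render_battery(stimgen.StimulusSpec())


@pytest.fixture(scope="session")
def small_sessions(battery):
    """One planted and one null (no emergent drive) small session, sharing
    the trial plan."""
    common = dict(n_v1=80, n_hva=0, n_ic_encoders=12, n_segment=32,
                  n_center=8)
    reps = synthdata.default_ic_block_reps(60, 40)
    trials = synthdata.build_trial_table(reps, seed=11)
    planted_neurons = synthdata.make_population(21, **common)
    null_neurons = synthdata.make_population(22, emergent_amp=0.0, **common)
    return {
        "planted_neurons": planted_neurons,
        "planted": synthdata.simulate_population(planted_neurons, battery,
                                                 trials, seed=31),
        "null": synthdata.simulate_population(null_neurons, battery, trials,
                                              seed=32),
        "trials": trials,
    }


@pytest.fixture(scope="session")
def spike_fixture():
    """Short spike-train set: one planted 3-ms synapse and an independent
    pair, 10 Hz, 10 minutes."""
    return synthdata.simulate_spike_trains(
        {0: 10.0, 1: 10.0, 2: 10.0, 3: 10.0},
        [(0, 1, 3.0, 0.25)], duration_s=600.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
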