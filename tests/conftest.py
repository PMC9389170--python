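import numpy as np
import pytest

from apnea_st.pipeline import run_synthetic_experiment
from apnea_st.synthetic import SimConfig, generate_beats, synthesize_ecg


@pytest.fixture(scope="session")
def sim_record():
    """A 10-min noise-free record with two planted apnea episodes plus its truth."""
    cfg = SimConfig(duration_s=600.0, apnea_intervals=((60.0, 240.0), (360.0, 480.0)), seed=11)
    truth = generate_beats(cfg)
    ecg = synthesize_ecg(truth, cfg)
    return cfg, truth, ecg


@pytest.fixture(scope="session")
def e2e_result():
    """The full synthetic experiment: 8 records, tiny model, 5 epochs, seed 7."""
    return run_synthetic_experiment(seed=7)


@pytest.fixture()
def dense_beats():
    """A regular 0.8-s beat series spanning 10 min (amp 1 mV), as plain arrays."""
    times = np.arange(0.4, 600.0, 0.8)
    return times
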