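import numpy as np
import pytest

import emodcm as e


@pytest.fixture(scope="session")
def small_design():
    """One short run: 60 scans, 12 faces."""
    return e.sample_design(11, n_runs=1, scans_per_run=60, n_faces=12,
                           valence_split=(4, 4, 4))


@pytest.fixture(scope="session")
def small_inputs(small_design):
    return e.events_to_inputs(small_design, dt=2.4 / 8, n_runs=1,
                              scans_per_run=60)


@pytest.fixture(scope="session")
def bu_singleton():
    """BU model modulating only IOG->OFC."""
    return e.enumerate_bottom_up()[0]


@pytest.fixture(scope="session")
def group_params(bu_singleton):
    return e.default_group_parameters(bu_singleton)


@pytest.fixture(scope="session")
def noisy_subject(bu_singleton, small_design, small_inputs):
    """One subject simulated at fine microtime with SNR ~ 5 noise,
    B(IOG->OFC) = 0.4 for both valences."""
    from emodcm.model_space import INPUT_INDEX, REGION_INDEX
    p = e.default_group_parameters(bu_singleton)
    for val in ("negative", "positive"):
        p.B[INPUT_INDEX[val], REGION_INDEX["OFC"], REGION_INDEX["IOG"]] = 0.4
    fine = e.events_to_inputs(small_design, dt=2.4 / 16, n_runs=1,
                              scans_per_run=60)
    ts = e.simulate_bold(p, fine, bu_singleton)
    sd = ts.data.std(axis=0)
    noise = np.where(sd > 0, sd, sd.max()) / 5.0
    rng = np.random.default_rng(99)
    ts.data = ts.data + rng.normal(0, 1, ts.data.shape) * noise
    return ts, p
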