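import logging

import numpy as np
import pytest

import linc_ephys as le

# the recovery suites log one line per rejected sweep; keep test output usable
logging.getLogger("linc_ephys").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tapers_3s():
    """Default tapers for a 3 s window at 1 kHz."""
    return le.compute_tapers(3000, 3, 5)


@pytest.fixture(scope="session")
def single_freq_protocol():
    """One-frequency (~6.67 Hz) pulsed-light protocol."""
    return le.StimProtocol()


@pytest.fixture(scope="session")
def short_session(single_freq_protocol):
    """A 12-epoch opsin+ session with entrainment gain 1."""
    params = le.LFPSimParams(session_duration=410, entrainment_gain=1.0, seed=7)
    return le.simulate_lfp_session(params, single_freq_protocol)


@pytest.fixture(scope="session")
def noiseless_cell():
    sweeps, truth = le.simulate_current_clamp(le.CellSimParams(seed=1))
    return sweeps, truth


def make_trialset(pre, during, fs=1000.0, stim_freq=20.0 / 3.0, **kw):
    defaults = dict(animal_id="t", genotype="opsin+", location="HI")
    defaults.update(kw)
    return le.AlignedTrialSet(pre=pre, during=during, fs=fs,
                              stim_freq=stim_freq, **defaults)
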