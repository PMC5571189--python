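"""Shared fixtures: reference rule and small, fast synthetic configurations."""

import numpy as np
import pytest

from rstdp import ProtocolSpec, SynthParams, reference_rule


@pytest.fixture(scope="session")
def rule():
    """Reference plasticity rule (conjunction normalization cached once)."""
    r = reference_rule()
    r.c_ref  # warm the cache
    return r


@pytest.fixture
def quiet_protocol():
    """4 s protocol with no stimulation/reinforcement events."""
    return ProtocolSpec(n_events=1, event_rate_hz=0.25, stim_on=False,
                        light_on=False, bsr_on=False, baseline_s=0.0, test_s=0.0)


@pytest.fixture
def noiseless_params():
    """Exact noiseless generator limit at a light sampling rate."""
    return SynthParams(noise_sd_mv=0.0, dwell_cv=0.0, osc_freq_hz=1.0,
                       sampling_rate_hz=2000.0, seed=1)


def light_only_protocol(n_events, light_delay_s=0.4, rate_hz=0.1):
    """Protocol delivering only light flashes, for latency analyses."""
    return ProtocolSpec(n_events=n_events, event_rate_hz=rate_hz, stim_on=False,
                        light_on=True, bsr_on=False, light_delay_s=light_delay_s,
                        baseline_s=0.0, test_s=2.0)
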