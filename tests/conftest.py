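"""Shared fixtures and signal builders for the test suite."""

import numpy as np
import pytest
from hypothesis import settings

from vae_impedance.acquisition import ImpedanceTrace
from vae_impedance.config import AppConfig

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def sinusoid_trace(
    duration_s=60.0,
    period_s=5.0,
    amplitude=5.0,
    baseline=100.0,
    rate_hz=100.0,
    noise_sigma=0.0,
    seed=0,
    phase=0.0,
) -> ImpedanceTrace:
    """Baseline + amplitude*sin carrier, optional seeded white noise.

    ``amplitude`` here is the sine amplitude (half the peak-to-peak swing).
    """
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    z = baseline + amplitude * np.sin(2 * np.pi * t / period_s + phase)
    if noise_sigma > 0:
        z = z + np.random.default_rng(seed).normal(0, noise_sigma, n)
    return ImpedanceTrace(t, z, rate_hz)


def constant_trace(value=7.0, duration_s=60.0, rate_hz=100.0) -> ImpedanceTrace:
    n = int(round(duration_s * rate_hz))
    return ImpedanceTrace(np.arange(n) / rate_hz, np.full(n, float(value)), rate_hz)


@pytest.fixture
def app_config() -> AppConfig:
    cfg = AppConfig()
    cfg.validate()
    return cfg
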