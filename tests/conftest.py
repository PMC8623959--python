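import warnings

import numpy as np
import pytest

from lrfa.pipeline import PipelineConfig, run_full_demo
from lrfa.preprocess import AcquisitionConfig, Spectrum
from lrfa.synth import SimulationConfig


@pytest.fixture(scope="session")
def default_acquisition() -> AcquisitionConfig:
    """The study's data-logger settings: 100 kHz, 2 s, 10 Hz pulses, 2 ms purge."""
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def short_acquisition() -> AcquisitionConfig:
    """A 0.2-s acquisition (2 pulses) for fast unit tests."""
    return AcquisitionConfig(record_duration=0.2)


@pytest.fixture()
def quiet_sim() -> SimulationConfig:
    """Noise-free single-mode simulator: analytic ground truth for the peak."""
    return SimulationConfig(
        n_modes=1,
        damping_rates=(100.0,),
        mode_amplitudes=(1.0,),
        noise_sd=0.0,
        tilt_jitter_sd=0.0,
        pulse_jitter_sd=0.0,
        rng_seed=0,
    )


@pytest.fixture()
def flat_spectrum() -> Spectrum:
    freqs = np.arange(0.0, 1000.0, 10.0)
    return Spectrum(frequencies=freqs, intensities=np.ones_like(freqs))


@pytest.fixture(scope="session")
def polyaxial_demo():
    """The full synthetic polyaxial experiment at the canonical seed.

    Shared session-wide: it is the costly end-to-end run (57 simulated
    records, 2000-resample bootstrap-Lasso, exhaustive power-of-two SVR
    grid) that several structural and statistical checks inspect.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_full_demo(PipelineConfig(seed=1))
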