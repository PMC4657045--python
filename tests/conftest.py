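import numpy as np
import pytest

from mtbuckle import FilamentMechanics, FilamentTrace, units


@pytest.fixture
def mt_mechanics() -> FilamentMechanics:
    """The sparse-kinesin (10 nM) filament constants: E = 49.75 MPa,
    I = 32.82e-32 m^4."""
    return FilamentMechanics(49.75 * units.MPA, 32.82e-32)


@pytest.fixture
def sinusoid_trace():
    """Factory for sinusoidal traces y = A sin(2πx/λ + φ) + noise (μm)."""

    def make(wavelength=10.0, amplitude=2.0, length=40.0, step=0.1,
             phase=0.0, noise_sigma=0.0, seed=0, **trace_kwargs):
        x = np.arange(0.0, length, step)
        y = amplitude * np.sin(2 * np.pi * x / wavelength + phase)
        if noise_sigma > 0:
            y = y + np.random.default_rng(seed).normal(0, noise_sigma,
                                                       x.shape)
        return FilamentTrace(np.column_stack([x, y]), **trace_kwargs)

    return make
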