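import numpy as np
import pytest

import pulsewss as pw


@pytest.fixture
def cosine_wave():
    """Single-harmonic test waveform: mean 0.20 m/s, amplitude 0.05, T = 1 s."""
    return pw.make_cosine(mean=0.20, amplitude=0.05, period=1.0, M=256)


@pytest.fixture
def cosine_spectrum(cosine_wave):
    return pw.fourier_decompose(cosine_wave, N=20)


@pytest.fixture
def vessel(cosine_wave):
    """4 mm vessel with whole-blood defaults at the cosine's frequency."""
    return pw.VesselFluidSpec.from_diameter(4e-3, omega=cosine_wave.omega)


@pytest.fixture
def fine_r(vessel):
    return np.linspace(0.0, vessel.radius, 801)


def template_case(name, rate=70.0, M=256, harmonics=20):
    """(waveform, spectrum, spec) for a named arterial template at a heart rate."""
    w = pw.make_template(pw.TEMPLATES[name].at_rate(rate), M=M)
    spec = pw.VesselFluidSpec.from_diameter(pw.default_diameter(name), omega=w.omega)
    return w, pw.fourier_decompose(w, N=harmonics), spec
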