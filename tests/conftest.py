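import numpy as np
import pytest

from nmrdeconv import CompoundSpectrum, Coupling, Resonance, make_grid


@pytest.fixture
def rng():
    return np.random.default_rng(20240404)


@pytest.fixture
def fine_grid():
    """Grid fine enough to resolve a 2 Hz line at 500 MHz (0.004 ppm fwhm)."""
    return make_grid(0.0, 10.0, 2**16)


@pytest.fixture
def two_compound_library():
    """Two well-separated singlet-only compounds with tight shift priors."""
    a = CompoundSpectrum(
        "A", [Resonance(2.0, 2.0), Resonance(7.0, 1.0)], shift_sigma=0.05
    )
    b = CompoundSpectrum(
        "B", [Resonance(3.5, 1.0), Resonance(8.2, 3.0)], shift_sigma=0.05
    )
    return [a, b]


@pytest.fixture
def coupled_resonance():
    return Resonance(shift=2.0, weight=1.0, couplings=[Coupling(10.0, 2)])
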