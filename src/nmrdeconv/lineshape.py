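"""Forward simulation of 1H NMR spectra.

A compound's spectrum is modelled as a sum of Lorentzian lines: each proton
environment (a :class:`Resonance`) contributes an amplitude-weighted,
unit-area Lorentzian centred at its chemical shift, split into a first-order
multiplet by its scalar couplings.  The Lorentzian full width at half maximum
encodes the exponential decay rate of the underlying time-domain signal
(``lambda = pi * fwhm``).  Gaussian apodization — convolution of the spectrum
with a unit-area Gaussian — broadens the near-delta simulated lines so that
they resemble (and share gradient support with) experimental lineshapes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "Coupling",
    "Resonance",
    "CompoundSpectrum",
    "Spectrum",
    "make_grid",
    "expand_multiplet",
    "render_spectrum",
    "render_mixture",
    "gaussian_apodize",
    "normalize_density",
    "DEFAULT_MHZ",
]

logger = logging.getLogger(__name__)

#: Default proton Larmor frequency (MHz).  1 Hz == 1/DEFAULT_MHZ ppm.
DEFAULT_MHZ = 500.0

#: Default intrinsic Lorentzian linewidth (Hz), matching typical solution
#: spectra of small molecules.
DEFAULT_LORENTZ_FWHM_HZ = 2.0


@dataclass(frozen=True)
class Coupling:
    """One group of N equivalent coupling partners with scalar coupling J (Hz)."""

    j_hz: float
    n: int = 1

    def __post_init__(self) -> None:
        if self.j_hz < 0:
            raise ValueError(f"negative J-coupling: {self.j_hz}")
        if self.n < 1:
            raise ValueError(f"coupling multiplicity N must be >= 1, got {self.n}")


@dataclass
class Resonance:
    """One proton environment.

    Parameters
    ----------
    shift
        Isotropic chemical shift delta (ppm).
    weight
        Signal amplitude, proportional to the proton count (>= 0).
    couplings
        Scalar couplings; each entry splits the line by the N+1 rule.
    lorentz_fwhm
        Lorentzian full width at half maximum (Hz).  Encodes the
        time-domain decay via ``lambda = pi * fwhm``.
    """

    shift: float
    weight: float = 1.0
    couplings: list[Coupling] = field(default_factory=list)
    lorentz_fwhm: float = DEFAULT_LORENTZ_FWHM_HZ

    def __post_init__(self) -> None:
        self.couplings = [
            c if isinstance(c, Coupling) else Coupling(*c) for c in self.couplings
        ]
        if not math.isfinite(self.shift):
            raise ValueError("resonance shift must be finite")
        if self.weight < 0:
            raise ValueError(f"resonance weight must be >= 0, got {self.weight}")
        if self.lorentz_fwhm <= 0:
            raise ValueError(f"lorentz_fwhm must be > 0, got {self.lorentz_fwhm}")


@dataclass
class CompoundSpectrum:
    """A named candidate compound: its resonances plus a shift-prior width.

    ``shift_sigma`` is the 1-sigma uncertainty (ppm) of the predicted shifts
    and depends on the prediction method: ~0.4 ppm for rule-based predictors,
    ~0.1 ppm for DFT with linear-scaled shieldings, ~0.01 ppm for shifts taken
    from a spectral library.
    """

    name: str
    resonances: list[Resonance]
    shift_sigma: float = 0.1

    def __post_init__(self) -> None:
        if not self.resonances:
            raise ValueError(f"compound {self.name!r} has no resonances")
        if self.shift_sigma <= 0:
            raise ValueError(f"compound {self.name!r}: shift_sigma must be > 0")

    @property
    def total_weight(self) -> float:
        """Sum of resonance amplitudes (the compound's total integral)."""
        return float(sum(r.weight for r in self.resonances))


@dataclass
class Spectrum:
    """A sampled 1-D spectrum: intensity over a strictly increasing ppm grid."""

    grid: np.ndarray
    intensity: np.ndarray
    spectrometer_mhz: float = DEFAULT_MHZ

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.intensity.shape:
            raise ValueError("grid and intensity must be 1-D arrays of equal length")
        if self.grid.size < 2 or np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing with >= 2 points")
        if self.spectrometer_mhz <= 0:
            raise ValueError("spectrometer_mhz must be > 0")

    @property
    def dx(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def integral(self) -> float:
        return float(np.trapezoid(self.intensity, self.grid))

    def copy(self) -> "Spectrum":
        return Spectrum(self.grid.copy(), self.intensity.copy(), self.spectrometer_mhz)


def make_grid(lo: float = 0.0, hi: float = 10.0, n: int = 2**14) -> np.ndarray:
    """Uniform ppm axis, default 0-10 ppm with 2**14 points."""
    if not (hi > lo and n >= 2):
        raise ValueError("grid requires hi > lo and n >= 2")
    return np.linspace(lo, hi, n)


def expand_multiplet(
    res: Resonance, spectrometer_mhz: float = DEFAULT_MHZ
) -> list[tuple[float, float]]:
    """First-order multiplet pattern of a resonance.

    Each coupling group (J, N) splits every existing line into N+1 lines with
    binomial (Pascal's triangle row N) intensities, adjacent lines spaced J Hz
    apart and the pattern centred on the parent line; a doublet therefore sits
    at +/- J/2 about the shift.  Offsets are returned in ppm relative to the
    resonance shift; relative intensities sum to one, so multiplying by the
    resonance weight conserves total signal.
    """
    lines: list[tuple[float, float]] = [(0.0, 1.0)]
    for c in res.couplings:
        row = [math.comb(c.n, k) for k in range(c.n + 1)]
        norm = float(sum(row))  # 2**n
        offs_ppm = [
            ((k - c.n / 2.0) * c.j_hz) / spectrometer_mhz for k in range(c.n + 1)
        ]
        lines = [
            (off + o2, rel * (row_k / norm))
            for off, rel in lines
            for o2, row_k in zip(offs_ppm, row)
        ]
    return lines


def _lorentzian(x: np.ndarray, center: float, fwhm_ppm: float) -> np.ndarray:
    """Unit-area Lorentzian."""
    hwhm = 0.5 * fwhm_ppm
    return (hwhm / math.pi) / ((x - center) ** 2 + hwhm**2)


def render_spectrum(
    compound: CompoundSpectrum,
    grid: np.ndarray,
    spectrometer_mhz: float = DEFAULT_MHZ,
) -> Spectrum:
    """Render a compound as a sum of unit-area Lorentzian multiplet lines.

    The trapezoid integral approaches the sum of resonance weights provided
    the grid extends well past the outermost line and resolves the linewidth
    (a grid coarser than 4 points per fwhm triggers a logged warning).
    """
    grid = np.asarray(grid, dtype=float)
    intensity = np.zeros_like(grid)
    dx = grid[1] - grid[0]
    for res in compound.resonances:
        if res.weight == 0.0:
            continue
        fwhm_ppm = res.lorentz_fwhm / spectrometer_mhz
        if fwhm_ppm / dx < 4.0:
            logger.warning(
                "grid spacing %.2g ppm resolves fwhm %.2g ppm with fewer than "
                "4 points per linewidth (compound %s)",
                dx,
                fwhm_ppm,
                compound.name,
            )
        for off, rel in expand_multiplet(res, spectrometer_mhz):
            intensity += res.weight * rel * _lorentzian(grid, res.shift + off, fwhm_ppm)
    return Spectrum(grid, intensity, spectrometer_mhz)


def render_mixture(
    compounds: list[CompoundSpectrum],
    weights: np.ndarray,
    grid: np.ndarray,
    spectrometer_mhz: float = DEFAULT_MHZ,
) -> Spectrum:
    """Weighted sum of rendered compound spectra (linear in the weights)."""
    weights = np.asarray(weights, dtype=float)
    if len(compounds) != weights.size:
        raise ValueError("one weight per compound required")
    grid = np.asarray(grid, dtype=float)
    intensity = np.zeros_like(grid)
    for w, comp in zip(weights, compounds):
        intensity += w * render_spectrum(comp, grid, spectrometer_mhz).intensity
    return Spectrum(grid, intensity, spectrometer_mhz)


def gaussian_apodize(spec: Spectrum, fwhm_hz: float) -> Spectrum:
    """Convolve with a unit-area Gaussian of the given fwhm (Hz).

    Implemented as an FFT convolution on the uniform grid; total integral is
    preserved away from the grid edges.
    """
    if fwhm_hz <= 0:
        raise ValueError("apodization fwhm must be > 0")
    dx = np.diff(spec.grid)
    if not np.allclose(dx, dx[0], rtol=1e-8):
        raise ValueError("gaussian_apodize requires a uniform grid")
    step = float(dx[0])
    sigma_ppm = (fwhm_hz / spec.spectrometer_mhz) / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    half_width = max(int(math.ceil(6.0 * sigma_ppm / step)), 1)
    t = np.arange(-half_width, half_width + 1) * step
    kernel = np.exp(-0.5 * (t / sigma_ppm) ** 2)
    kernel /= kernel.sum()  # discrete unit area (kernel * step integrates to step sum)
    smoothed = fftconvolve(spec.intensity, kernel, mode="same")
    return Spectrum(spec.grid, smoothed, spec.spectrometer_mhz)


def normalize_density(spec: Spectrum) -> Spectrum:
    """Rescale so the trapezoid integral over the grid equals one."""
    area = spec.integral()
    if area <= 0:
        raise ValueError("empty spectrum: integral is not positive")
    return Spectrum(spec.grid, spec.intensity / area, spec.spectrometer_mhz)
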