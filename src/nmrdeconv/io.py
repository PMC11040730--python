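"""File formats and the JSON run report.

Spectra are two-column text (ppm, intensity); ``#``-prefixed header lines
carry ``KEY=VALUE`` metadata, of which ``MHZ`` (spectrometer frequency) is
understood.  Candidate libraries are JSON: each compound has a name, a shift
uncertainty, and a resonance list giving either a chemical shift or a DFT
shielding (converted through the active calibration line), a proton weight,
couplings, and an optional linewidth.  The run report is schema-stable JSON
with deterministic key order.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .bayes import FitResult
from .calibration import DEFAULT_LINE, CalibrationLine, shielding_to_shift
from .lineshape import DEFAULT_MHZ, CompoundSpectrum, Coupling, Resonance, Spectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_library",
    "write_library",
    "build_report",
    "write_report",
]

logger = logging.getLogger(__name__)


def read_spectrum(path) -> Spectrum:
    """Read a two-column (ppm, intensity) text spectrum.

    Header lines start with ``#``; ``# MHZ=...`` sets the spectrometer
    frequency (defaulting to 500 with a logged warning).  A descending ppm
    axis is re-sorted ascending.
    """
    path = Path(path)
    mhz: Optional[float] = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                if key.strip().upper() == "MHZ":
                    mhz = float(val)
        elif line:
            break
    if mhz is None:
        mhz = DEFAULT_MHZ
        logger.warning("%s: no MHZ metadata, assuming %.0f MHz", path, mhz)
    data = np.loadtxt(path, comments="#", delimiter=None)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (ppm, intensity)")
    grid, intensity = data[:, 0], data[:, 1]
    d = np.diff(grid)
    if np.all(d < 0):
        grid, intensity = grid[::-1], intensity[::-1]
    elif not np.all(d > 0):
        raise ValueError(f"{path}: ppm axis is not monotone")
    return Spectrum(grid, intensity, mhz)


def write_spectrum(spec: Spectrum, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# MHZ={spec.spectrometer_mhz:g}\n")
        for x, y in zip(spec.grid, spec.intensity):
            fh.write(f"{x:.8g}\t{y:.10g}\n")


def _parse_resonance(obj: dict, cname: str, idx: int, line: CalibrationLine) -> Resonance:
    where = f"compound {cname!r}, resonance {idx}"
    if "shift_ppm" in obj:
        shift = float(obj["shift_ppm"])
    elif "shielding" in obj:
        shift = float(shielding_to_shift(float(obj["shielding"]), line))
    else:
        raise ValueError(f"{where}: needs 'shift_ppm' or 'shielding'")
    couplings = [
        Coupling(j_hz=float(c["J_hz"]), n=int(c.get("N", 1)))
        for c in obj.get("couplings", [])
    ]
    try:
        return Resonance(
            shift=shift,
            weight=float(obj.get("weight", 1.0)),
            couplings=couplings,
            lorentz_fwhm=float(obj.get("fwhm_hz", 2.0)),
        )
    except ValueError as exc:
        raise ValueError(f"{where}: {exc}") from exc


def read_library(path, calibration: CalibrationLine | None = None) -> list[CompoundSpectrum]:
    """Read a candidate library from JSON.

    Accepts either a bare list of compound objects or
    ``{"calibration": {...}, "compounds": [...]}``; shieldings are converted
    to shifts through the calibration line (file header, argument, or the
    shipped default, in that priority).
    """
    path = Path(path)
    doc = json.loads(path.read_text())
    if isinstance(doc, dict):
        cal = doc.get("calibration")
        if calibration is None and cal is not None:
            calibration = CalibrationLine(
                slope=float(cal["slope"]), intercept=float(cal["intercept"])
            )
        compounds = doc["compounds"]
    else:
        compounds = doc
    line = calibration or DEFAULT_LINE
    out: list[CompoundSpectrum] = []
    for entry in compounds:
        name = entry["name"]
        resonances = entry.get("resonances", [])
        if not resonances:
            raise ValueError(f"compound {name!r}: empty resonance list")
        out.append(
            CompoundSpectrum(
                name=name,
                resonances=[
                    _parse_resonance(r, name, i, line) for i, r in enumerate(resonances)
                ],
                shift_sigma=float(entry.get("shift_sigma", 0.1)),
            )
        )
    names = [c.name for c in out]
    if len(set(names)) != len(names):
        raise ValueError("duplicate compound names in library")
    return out


def write_library(library: list[CompoundSpectrum], path) -> None:
    doc = {
        "compounds": [
            {
                "name": c.name,
                "shift_sigma": c.shift_sigma,
                "resonances": [
                    {
                        "shift_ppm": r.shift,
                        "weight": r.weight,
                        "couplings": [{"J_hz": cp.j_hz, "N": cp.n} for cp in r.couplings],
                        "fwhm_hz": r.lorentz_fwhm,
                    }
                    for r in c.resonances
                ],
            }
            for c in library
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def build_report(
    fit: FitResult,
    inputs: dict | None = None,
    truth: dict | None = None,
) -> dict:
    """Assemble the JSON-serialisable run report for a completed fit.

    ``truth`` may carry ``{"composition": {name: fraction}, "present": [names]}``;
    when given, the report includes ``mae_pct`` and ``accuracy_pct``.
    """
    from .compositional import classification_accuracy, composition_mae

    names = fit.library_names or fit.names
    ci = fit.credible_interval()
    report = {
        "version": __version__,
        "inputs": inputs or {},
        "present": {n: bool(p) for n, p in zip(names, fit.present)}
        if fit.present is not None
        else None,
        "center": {n: float(x) for n, x in zip(fit.names, fit.center)},
        "center_full": {n: float(x) for n, x in zip(names, fit.center_full)}
        if fit.center_full is not None
        else None,
        "credible_interval_95": {
            n: [float(ci[0, i]), float(ci[1, i])] for i, n in enumerate(fit.names)
        },
        "shifts": [
            {
                "compound": fit.names[int(c)],
                "prior_mean_ppm": float(m0),
                "prior_sd_ppm": float(s0),
                "posterior_mean_ppm": float(m),
                "posterior_sd_ppm": float(s),
            }
            for c, m0, s0, m, s in zip(
                fit.res_compound,
                fit.res_prior_mean,
                fit.res_prior_sd,
                fit.shift_posterior_mean,
                fit.shift_posterior_sd,
            )
        ],
        "intervals": [
            {
                "lo": iv.lo,
                "hi": iv.hi,
                "entropy_bits": iv.entropy,
                "members": sorted(iv.members),
            }
            for iv in fit.intervals
        ]
        if fit.intervals is not None
        else None,
        "history": fit.history,
        "converged": fit.converged,
        "diagnostics": fit.diagnostics,
    }
    if truth:
        if "composition" in truth and fit.center_full is not None:
            true_vec = np.array([truth["composition"].get(n, 0.0) for n in names])
            report["mae_pct"] = composition_mae(fit.center_full, true_vec)
        if "present" in truth and fit.present is not None:
            true_present = np.array([n in truth["present"] for n in names])
            report["accuracy_pct"] = 100.0 * classification_accuracy(
                fit.present, true_present
            )
    return report


def write_report(fit: FitResult, path, inputs: dict | None = None, truth: dict | None = None) -> None:
    """Write the run report as deterministic (sorted-key) JSON."""
    report = build_report(fit, inputs=inputs, truth=truth)
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True, default=float))
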