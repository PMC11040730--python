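"""Entropy-guided spectral segmentation.

The predicted candidate lines partition the spectrum into merged intervals
(+/- a half-width around every line).  Each interval is scored by the
Bernoulli information entropy of the fraction of library compounds predicted
to resonate inside it: intervals where about half the candidates appear are
the most informative, because fitting them is most likely to eliminate
candidates.  Intervals are fit in order of decreasing entropy, ties broken
from least shielded (highest ppm) to most shielded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .lineshape import CompoundSpectrum

__all__ = ["SpectralInterval", "build_intervals", "interval_entropy", "rank_intervals"]


@dataclass
class SpectralInterval:
    lo: float
    hi: float
    members: set[str] = field(default_factory=set)
    entropy: float = 0.0

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("interval requires lo < hi")
        if self.entropy < 0:
            raise ValueError("entropy must be >= 0")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)

    def contains(self, ppm: float) -> bool:
        return self.lo <= ppm <= self.hi


def build_intervals(
    library: list[CompoundSpectrum], halfwidth_ppm: float = 0.5
) -> list[SpectralInterval]:
    """Merged +/- halfwidth intervals around every predicted line.

    Overlapping or touching intervals are merged across all compounds; the
    result is a sorted, disjoint list with entropies already computed against
    the library size.
    """
    if not library:
        raise ValueError("build_intervals requires a nonempty library")
    spans = sorted(
        (res.shift - halfwidth_ppm, res.shift + halfwidth_ppm)
        for comp in library
        for res in comp.resonances
    )
    merged: list[list[float]] = []
    for lo, hi in spans:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    intervals = []
    for lo, hi in merged:
        members = {
            comp.name
            for comp in library
            if any(lo <= res.shift <= hi for res in comp.resonances)
        }
        iv = SpectralInterval(lo, hi, members)
        iv.entropy = interval_entropy(iv, len(library))
        intervals.append(iv)
    return intervals


def interval_entropy(interval: SpectralInterval, library_size: int) -> float:
    """Bernoulli entropy (bits) of the member fraction p = |members| / library."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    k = len(interval.members)
    if not 0 <= k <= library_size:
        raise ValueError("member count exceeds library size")
    p = k / library_size
    h = 0.0
    for q in (p, 1.0 - p):
        if q > 0.0:
            h -= q * math.log2(q)
    return h


def rank_intervals(intervals: list[SpectralInterval]) -> list[SpectralInterval]:
    """Sort by descending entropy; ties broken by descending chemical shift."""
    return sorted(intervals, key=lambda iv: (-iv.entropy, -iv.midpoint))
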