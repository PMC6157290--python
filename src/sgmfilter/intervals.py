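"""Greedy selection of fragment-dense mass intervals and their reversal.

The spectrum graph of a whole top-down spectrum is usually a scatter of small
disconnected components, so search is run on subspectra instead: fixed-width
(``delta``) mass windows that are dense in fragment masses.  Up to ``gamma``
windows are picked greedily by mass count, suppressing candidates that
overlap an already-reported window by at least ``rho``.  Each window can also
be mirrored through the precursor mass (mass ``b`` becomes ``M - b``), which
turns suffix-fragment ladders into prefix-like ladders readable in protein
N-to-C order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np

from .spectrum import DeconvolutedSpectrum

__all__ = ["MassInterval", "overlap_ratio", "select_intervals", "reverse_interval",
           "MIN_INTERVAL_MASSES"]

#: Minimum number of fragment masses an interval must contain to be reported.
MIN_INTERVAL_MASSES = 6

_WIDTH_RTOL = 1e-9


@dataclass
class MassInterval:
    """A width-``delta`` mass window of a spectrum and the masses inside it."""

    lo: float
    hi: float
    masses: np.ndarray
    intensities: np.ndarray
    #: indices of these masses in the source (noise-filtered) spectrum
    source_indices: np.ndarray = field(default=None)
    orientation: str = "forward"

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.source_indices is None:
            self.source_indices = np.arange(self.masses.size)
        self.source_indices = np.asarray(self.source_indices, dtype=int)

    @property
    def width(self) -> float:
        return self.hi - self.lo

    @property
    def score(self) -> int:
        """Mass-count score of the interval."""
        return int(self.masses.size)


def overlap_ratio(i1: MassInterval, i2: MassInterval) -> float:
    """Fraction of the common width shared by two equal-width intervals.

    For intervals [a, a+delta] and [b, b+delta] with a <= b this is
    ``max(a + delta - b, 0) / delta``; symmetric in its arguments.
    """
    delta = i1.width
    if abs(i1.width - i2.width) > _WIDTH_RTOL * max(1.0, delta):
        raise ValueError(
            f"intervals have unequal widths {i1.width} and {i2.width}"
        )
    a, b = sorted((i1.lo, i2.lo))
    return max(a + delta - b, 0.0) / delta


def _window(spectrum: DeconvolutedSpectrum, lo: float, delta: float) -> MassInterval:
    i = int(np.searchsorted(spectrum.masses, lo, side="left"))
    j = int(np.searchsorted(spectrum.masses, lo + delta, side="right"))
    return MassInterval(
        lo=lo,
        hi=lo + delta,
        masses=spectrum.masses[i:j],
        intensities=spectrum.intensities[i:j],
        source_indices=np.arange(i, j),
    )


def select_intervals(
    spectrum: DeconvolutedSpectrum,
    delta: float,
    gamma: int,
    rho: float,
) -> List[MassInterval]:
    """Greedily pick up to ``gamma`` top-scoring width-``delta`` intervals.

    Candidate windows are anchored at each observed fragment mass ``x`` as
    ``[x, x + delta]``; this finite set attains every achievable mass count.
    The best-scoring candidate (ties: smallest ``lo``) is reported, candidates
    overlapping any reported interval by a ratio of at least ``rho`` are
    dropped (for ``rho = 0``, any positive overlap disqualifies), and the
    process repeats.  Only intervals holding at least 6 masses are reported.
    """
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    if gamma <= 0:
        raise ValueError(f"gamma must be a positive integer, got {gamma}")
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    candidates = [_window(spectrum, float(x), delta) for x in spectrum.masses]
    candidates = [c for c in candidates if c.score >= MIN_INTERVAL_MASSES]
    reported: List[MassInterval] = []
    while candidates and len(reported) < gamma:
        best = max(candidates, key=lambda c: (c.score, -c.lo))
        reported.append(best)
        if rho > 0:
            candidates = [c for c in candidates if overlap_ratio(c, best) < rho]
        else:
            candidates = [c for c in candidates if overlap_ratio(c, best) == 0.0]
    return reported


def reverse_interval(interval: MassInterval, precursor_mass: float) -> MassInterval:
    """Mirror an interval through the precursor mass M.

    ``[m_l, m_r]`` with masses ``b_i`` becomes ``[M - m_r, M - m_l]`` with
    masses ``M - b_i`` (sorted ascending, intensities carried along).
    Reversing twice with the same M restores the original interval.
    """
    if precursor_mass <= interval.hi:
        raise ValueError(
            f"precursor mass {precursor_mass} must exceed the interval upper "
            f"bound {interval.hi}"
        )
    rev = precursor_mass - interval.masses[::-1]
    return MassInterval(
        lo=precursor_mass - interval.hi,
        hi=precursor_mass - interval.lo,
        masses=rev,
        intensities=interval.intensities[::-1].copy(),
        source_indices=interval.source_indices[::-1].copy(),
        orientation="reversed" if interval.orientation == "forward" else "forward",
    )
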