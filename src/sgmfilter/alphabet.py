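"""Discretized residue-mass alphabet and amino-acid composition tables.

Residue masses are discretized by multiplying by an integer scale factor
(default 100) and rounding, which turns mass arithmetic into exact integer
arithmetic.  At scale 100 leucine and isoleucine collapse onto the same
integer (11308), so the working alphabet Sigma has 19 symbols rather than 20.

The :class:`CompositionTable` enumerates, for any integer mass ``m``, every
ordered string of residues whose discretized masses sum to ``m`` (within an
integer tolerance).  These are the strings a mass gap between two fragment
peaks may spell, and the table is the workhorse behind gapped-edge validation
and search-space analysis (the expansion factor ``r``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import numpy as np

__all__ = [
    "RESIDUE_MASSES",
    "ResidueAlphabet",
    "CompositionTable",
    "discretize_mass",
    "build_composition_table",
    "expansion_factor",
]

#: Monoisotopic residue masses (Da) of the 20 common amino acids.
RESIDUE_MASSES: Mapping[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

# Table sizes above this many integer mass bins are refused; lowering the
# maximum gap mass (alpha) keeps the table small.
_MAX_TABLE_CELLS = 5_000_000


def discretize_mass(mass: float, scale: int = 100) -> int:
    """Discretize a mass in Da to an integer at the given scale factor.

    Rounding is half-away-from-zero, so e.g. ``discretize_mass(113.084, 100)``
    is 11308 and ``discretize_mass(114.04, 100)`` is 11404.
    """
    if mass < 0:
        raise ValueError(f"mass must be non-negative, got {mass}")
    if scale <= 0:
        raise ValueError(f"scale must be a positive integer, got {scale}")
    return int(math.floor(mass * scale + 0.5))


@dataclass(frozen=True)
class ResidueAlphabet:
    """The integer residue-mass alphabet Sigma at a fixed scale factor."""

    scale: int = 100
    residues: Mapping[str, float] = field(default_factory=lambda: dict(RESIDUE_MASSES))

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be a positive integer")

    @property
    def int_mass_of(self) -> Dict[str, int]:
        """One-letter code -> discretized residue mass."""
        return {aa: discretize_mass(m, self.scale) for aa, m in self.residues.items()}

    @property
    def int_masses(self) -> Tuple[int, ...]:
        """Sorted distinct discretized residue masses (the symbols of Sigma)."""
        return tuple(sorted(set(self.int_mass_of.values())))

    @property
    def canonical_letter(self) -> Dict[int, str]:
        """Discretized mass -> lexicographically smallest letter with that mass."""
        out: Dict[int, str] = {}
        for aa, m in sorted(self.int_mass_of.items()):
            out.setdefault(m, aa)
        return out

    @property
    def min_int_mass(self) -> int:
        return self.int_masses[0]

    def mass_of_string(self, residues: str) -> int:
        """Discretized mass of an amino-acid string (sum of symbol masses)."""
        table = self.int_mass_of
        return sum(table[aa] for aa in residues)


@dataclass
class CompositionTable:
    """All residue strings per integer mass: the precomputed realization of C(e).

    ``counts_by_length[j, m]`` is the number of ordered strings over Sigma of
    length ``j`` whose masses sum exactly to ``m`` (computed eagerly by dynamic
    programming).  String lists are materialized lazily per queried mass, since
    near the upper mass bound there are thousands of strings per bin.
    """

    alphabet: ResidueAlphabet
    max_mass: int
    tol: int = 0
    counts_by_length: np.ndarray = field(repr=False, default=None)
    _strings_cache: Dict[int, List[str]] = field(default_factory=dict, repr=False)

    # -- counts ---------------------------------------------------------

    def count(self, m: int, j: int | None = None) -> int:
        """Number of strings of exact mass ``m`` (optionally of length ``j``)."""
        if m < 0 or m > self.max_mass:
            return 0
        if j is None:
            return int(self.counts_by_length[1:, m].sum())
        if j < 0 or j >= self.counts_by_length.shape[0]:
            return 0
        return int(self.counts_by_length[j, m])

    # -- strings --------------------------------------------------------

    def _enumerate_exact(self, m: int) -> List[str]:
        """All strings of exact mass ``m``, lexicographic, cached."""
        if m in self._strings_cache:
            return self._strings_cache[m]
        letters = sorted(self.alphabet.canonical_letter.items(), key=lambda kv: kv[1])
        min_mass = self.alphabet.min_int_mass
        out: List[str] = []
        buf: List[str] = []

        def rec(remaining: int) -> None:
            if remaining == 0:
                out.append("".join(buf))
                return
            if remaining < min_mass:
                return
            for w, aa in letters:
                if w <= remaining:
                    buf.append(aa)
                    rec(remaining - w)
                    buf.pop()

        if 0 < m <= self.max_mass:
            rec(m)
        out.sort()
        self._strings_cache[m] = out
        return out

    def strings(self, m: int) -> List[str]:
        """All strings whose exact mass lies within ``tol`` of ``m``.

        With ``tol = 0`` this is the exact composition set for mass ``m``.
        Letters are canonical (one representative per Sigma symbol, e.g. 'I'
        stands for the shared Leu/Ile mass).
        """
        out: List[str] = []
        for mm in range(m - self.tol, m + self.tol + 1):
            out.extend(self._enumerate_exact(mm))
        return out

    def has_composition(self, m: int) -> bool:
        """True if some residue string has mass within ``tol`` of ``m``."""
        lo = max(0, m - self.tol)
        hi = min(self.max_mass, m + self.tol)
        if lo > hi:
            return False
        return bool(self.counts_by_length[1:, lo : hi + 1].any())


def build_composition_table(
    alphabet: ResidueAlphabet, max_mass: int, tol: int = 0
) -> CompositionTable:
    """Build the composition table for all integer masses up to ``max_mass``."""
    if tol < 0:
        raise ValueError("tol must be non-negative")
    if max_mass < alphabet.min_int_mass:
        raise ValueError(
            f"max_mass {max_mass} is below the smallest residue mass "
            f"{alphabet.min_int_mass}"
        )
    symbols = alphabet.int_masses
    max_len = max_mass // alphabet.min_int_mass
    if (max_len + 1) * (max_mass + 1) > _MAX_TABLE_CELLS:
        raise MemoryError(
            "composition table too large; lower the maximum gap mass (alpha) "
            "or the scale factor"
        )
    counts = np.zeros((max_len + 1, max_mass + 1), dtype=np.int64)
    counts[0, 0] = 1
    for j in range(1, max_len + 1):
        prev = counts[j - 1]
        cur = counts[j]
        for w in symbols:
            if w <= max_mass:
                cur[w:] += prev[: max_mass + 1 - w]
    return CompositionTable(alphabet=alphabet, max_mass=max_mass, tol=tol,
                            counts_by_length=counts)


def expansion_factor(table: CompositionTable) -> float:
    """Maximum expansion factor r = max over (m, j) of |C(m, j)|^(1/j).

    Defined on the exact (zero-tolerance) composition counts; r bounds the
    per-symbol growth of the candidate-string space during graph search.
    """
    counts = table.counts_by_length
    if counts is None or not counts[1:].any():
        raise ValueError("composition table is empty")
    best = 0.0
    for j in range(1, counts.shape[0]):
        cmax = counts[j].max()
        if cmax > 0:
            best = max(best, float(cmax) ** (1.0 / j))
    return best
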