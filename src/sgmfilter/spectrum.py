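"""Deconvoluted spectra: parsing, noise filtering and fragment scoring.

A deconvoluted top-down MS/MS spectrum is a precursor (molecular) mass plus a
list of neutral monoisotopic fragment masses with intensities.  Two text
dialects are read: the msalign block format produced by deconvolution tools
(``BEGIN IONS`` / ``END IONS`` with a ``PRECURSOR_MASS`` header and
``mass intensity [charge]`` rows) and a plain TSV with columns
``spectrum_id, precursor_mass, mass, intensity``.

Noise removal is windowed: a fragment survives only if it is among the top
``lambda`` intensities within +/-100 Da of its own mass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DeconvolutedSpectrum",
    "FragmentScores",
    "read_spectra",
    "write_msalign",
    "filter_noise",
    "score_fragments",
    "NOISE_WINDOW_HALF_WIDTH",
]

#: Half-width (Da) of the intensity-ranking window used in noise removal.
NOISE_WINDOW_HALF_WIDTH = 100.0


@dataclass
class DeconvolutedSpectrum:
    """A deconvoluted MS/MS spectrum: precursor mass + fragment mass list."""

    spectrum_id: str
    precursor_mass: float
    masses: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.masses.shape != self.intensities.shape:
            raise ValueError("masses and intensities must have equal length")
        if np.any(self.masses <= 0):
            raise ValueError(f"spectrum {self.spectrum_id}: non-positive fragment mass")
        order = np.argsort(self.masses, kind="stable")
        self.masses = self.masses[order]
        self.intensities = self.intensities[order]
        if self.masses.size and self.precursor_mass < self.masses[-1]:
            warnings.warn(
                f"spectrum {self.spectrum_id}: precursor mass "
                f"{self.precursor_mass:.4f} below largest fragment mass "
                f"{self.masses[-1]:.4f}",
                stacklevel=2,
            )

    @property
    def fragments(self) -> List[Tuple[float, float]]:
        return list(zip(self.masses.tolist(), self.intensities.tolist()))

    def __len__(self) -> int:
        return int(self.masses.size)


@dataclass
class FragmentScores:
    """Per-fragment scores under one of the three scoring schemes."""

    scheme: str
    scores: np.ndarray = field(repr=False)


def _parse_msalign(path: Path) -> List[DeconvolutedSpectrum]:
    spectra: List[DeconvolutedSpectrum] = []
    block: dict | None = None
    n_anonymous = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                block = {"headers": {}, "masses": [], "intens": []}
                continue
            if line == "END IONS":
                if block is None:
                    raise ValueError(f"{path}:{lineno}: END IONS without BEGIN IONS")
                sid = block["headers"].get("ID")
                if sid is None:
                    n_anonymous += 1
                    sid = f"spectrum_{n_anonymous}"
                prec = block["headers"].get("PRECURSOR_MASS")
                if prec is None:
                    raise ValueError(
                        f"{path}: spectrum {sid!r} has no PRECURSOR_MASS header"
                    )
                spectra.append(
                    DeconvolutedSpectrum(
                        spectrum_id=str(sid),
                        precursor_mass=float(prec),
                        masses=np.array(block["masses"], dtype=float),
                        intensities=np.array(block["intens"], dtype=float),
                    )
                )
                block = None
                continue
            if block is None:
                continue  # tolerate junk between blocks
            if "=" in line and not line[0].isdigit():
                key, _, value = line.partition("=")
                block["headers"][key.strip()] = value.strip()
                continue
            cols = line.split()
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'mass intensity [charge]'")
            try:
                mass = float(cols[0])
                inten = float(cols[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric peak row {line!r}") from exc
            block["masses"].append(mass)
            block["intens"].append(inten)
    if block is not None:
        raise ValueError(f"{path}: unterminated BEGIN IONS block at end of file")
    return spectra


def _parse_tsv(path: Path) -> List[DeconvolutedSpectrum]:
    df = pd.read_csv(path, sep="\t")
    required = {"spectrum_id", "precursor_mass", "mass", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    spectra = []
    for sid, grp in df.groupby("spectrum_id", sort=False):
        prec = grp["precursor_mass"].unique()
        if prec.size != 1:
            raise ValueError(f"{path}: spectrum {sid!r} has conflicting precursor masses")
        spectra.append(
            DeconvolutedSpectrum(
                spectrum_id=str(sid),
                precursor_mass=float(prec[0]),
                masses=grp["mass"].to_numpy(dtype=float),
                intensities=grp["intensity"].to_numpy(dtype=float),
            )
        )
    return spectra


def read_spectra(path: str | Path, format: str | None = None) -> List[DeconvolutedSpectrum]:
    """Read deconvoluted spectra from an msalign or TSV file.

    ``format`` is "msalign" or "tsv"; when omitted it is inferred from the
    file extension (".msalign" vs ".tsv"/".txt").
    """
    path = Path(path)
    if format is None:
        format = "msalign" if path.suffix.lower() == ".msalign" else "tsv"
    if format == "msalign":
        return _parse_msalign(path)
    if format == "tsv":
        return _parse_tsv(path)
    raise ValueError(f"unknown spectrum format {format!r}")


def write_msalign(spectra: Iterable[DeconvolutedSpectrum], path: str | Path) -> None:
    """Write spectra in the msalign block dialect read by :func:`read_spectra`."""
    with open(path, "w") as fh:
        for sp in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"ID={sp.spectrum_id}\n")
            fh.write(f"PRECURSOR_MASS={sp.precursor_mass:.5f}\n")
            for m, h in zip(sp.masses, sp.intensities):
                fh.write(f"{m:.5f}\t{h:.4f}\t1\n")
            fh.write("END IONS\n")


def filter_noise(
    spectrum: DeconvolutedSpectrum, lam: float | int
) -> DeconvolutedSpectrum:
    """Remove low-intensity fragments by windowed intensity rank.

    A fragment at mass ``x`` is kept iff it ranks among the top ``lam``
    intensities of all fragments within ``[x - 100, x + 100]`` Da.  Equal
    intensities are ranked by ascending mass (deterministic).  ``lam`` may be
    ``math.inf`` to disable filtering.
    """
    if lam != math.inf:
        if lam <= 0 or int(lam) != lam:
            raise ValueError(f"lambda must be a positive integer or inf, got {lam}")
        lam = int(lam)
    if lam == math.inf or len(spectrum) == 0:
        return spectrum
    masses = spectrum.masses
    intens = spectrum.intensities
    keep = np.zeros(len(spectrum), dtype=bool)
    lo = np.searchsorted(masses, masses - NOISE_WINDOW_HALF_WIDTH, side="left")
    hi = np.searchsorted(masses, masses + NOISE_WINDOW_HALF_WIDTH, side="right")
    for i in range(len(spectrum)):
        w = slice(lo[i], hi[i])
        better = np.sum(
            (intens[w] > intens[i])
            | ((intens[w] == intens[i]) & (masses[w] < masses[i]))
        )
        keep[i] = better < lam
    return DeconvolutedSpectrum(
        spectrum_id=spectrum.spectrum_id,
        precursor_mass=spectrum.precursor_mass,
        masses=masses[keep],
        intensities=intens[keep],
    )


def score_fragments(spectrum: DeconvolutedSpectrum, scheme: str) -> FragmentScores:
    """Assign per-fragment scores.

    Schemes: ``mass_count`` gives every fragment score 1; ``log_intensity``
    gives ``log2(2 h / b)`` with ``b`` the smallest intensity in the spectrum
    (always positive); ``rank`` gives ``1 + i / k`` with ``i`` the 1-based
    rank by increasing intensity and ``k`` the fragment count, so the most
    intense fragment scores exactly 2.
    """
    k = len(spectrum)
    if scheme in ("mass_count", "count"):
        return FragmentScores("mass_count", np.ones(k))
    if k == 0:
        raise ValueError(f"cannot compute {scheme} scores for an empty spectrum")
    if scheme in ("log_intensity", "log"):
        b = spectrum.intensities.min()
        return FragmentScores("log_intensity", np.log2(2.0 * spectrum.intensities / b))
    if scheme == "rank":
        # ties broken by ascending mass: fragments are mass-sorted, stable sort
        order = np.argsort(spectrum.intensities, kind="stable")
        ranks = np.empty(k, dtype=float)
        ranks[order] = np.arange(1, k + 1)
        return FragmentScores("rank", 1.0 + ranks / k)
    raise ValueError(f"unknown scoring scheme {scheme!r}")
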