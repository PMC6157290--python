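"""Seeded synthetic protein databases and deconvoluted spectra.

The generator emulates the structure of deconvoluted top-down CID spectra: a
prefix fragment-mass ladder of the target protein (plain residue-mass prefix
sums), a precursor equal to the molecular mass (residue total plus water by
default), peaks dropped independently with a missing-peak probability, a few
uniform-random noise masses, optional PTM mass shifts applied to every
cleavage downstream of the modified residue, and log-normal intensities.
Everything is driven by one integer seed, so fixtures are reproducible
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .alphabet import RESIDUE_MASSES
from .spectrum import DeconvolutedSpectrum, write_msalign

__all__ = [
    "FixtureSpec",
    "WATER_MASS",
    "generate_proteins",
    "generate_protein_db",
    "generate_spectrum",
    "write_fixture_set",
]

#: Monoisotopic mass of water; molecular mass = residue sum + water.
WATER_MASS = 18.010565

_AA = sorted(RESIDUE_MASSES)


@dataclass
class FixtureSpec:
    """Parameters of the synthetic data generator."""

    n_proteins: int = 50
    length_range: Tuple[int, int] = (40, 80)
    miss_prob: float = 0.0
    n_noise: int = 0
    #: (position fraction in (0, 1), mass shift in Da) per modification
    ptm_shifts: List[Tuple[float, float]] = field(default_factory=list)
    #: parameters (mu, sigma) of log-normal fragment intensities
    intensity_mu: float = 3.0
    intensity_sigma: float = 1.0
    #: additive constant on the precursor (water: molecular mass convention)
    precursor_offset: float = WATER_MASS
    #: also emit the suffix-fragment ladder (masses M - prefix)
    include_suffix: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError(f"degenerate length range {self.length_range}")
        if not 0.0 <= self.miss_prob <= 1.0:
            raise ValueError("miss_prob must lie in [0, 1]")
        for frac, _ in self.ptm_shifts:
            if not 0.0 <= frac <= 1.0:
                raise ValueError("PTM position fractions must lie in [0, 1]")


def generate_proteins(spec: FixtureSpec) -> List[Tuple[str, str]]:
    """Uniform-random protein sequences, deterministic under the seed."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    out = []
    for i in range(spec.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_AA, size=length))
        out.append((f"P{i:04d}", seq))
    return out


def generate_protein_db(
    spec: FixtureSpec, path: str | Path, decoys: bool = False
) -> List[Tuple[str, str]]:
    """Write a random FASTA database; optionally append shuffled decoys."""
    records = generate_proteins(spec)
    if decoys:
        rng = np.random.default_rng(spec.seed + 1)
        records = records + [
            (f"DECOY_{pid}", "".join(rng.permutation(list(seq))))
            for pid, seq in records
        ]
    with open(path, "w") as fh:
        for pid, seq in records:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return records


def generate_spectrum(
    protein: str,
    spec: FixtureSpec,
    spectrum_id: str = "S0",
    rng: Optional[np.random.Generator] = None,
) -> DeconvolutedSpectrum:
    """Synthesize a deconvoluted spectrum of one protein.

    Fragments are the prefix residue-mass sums (cleavages 1..n-1), each kept
    with probability ``1 - miss_prob`` and shifted by every PTM located at or
    before the cleavage; ``n_noise`` uniform masses span the ladder range and
    the precursor is the (modified) residue total plus ``precursor_offset``.
    """
    if not protein:
        raise ValueError("protein sequence is empty")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    res = np.array([RESIDUE_MASSES[aa] for aa in protein])
    n = len(protein)
    prefix = np.cumsum(res)  # prefix[i-1] = mass of residues 1..i
    shifts = np.zeros(n)
    for frac, dmass in spec.ptm_shifts:
        site = min(n - 1, int(frac * n))  # 0-based modified residue
        shifts[site:] += dmass
    ladder = prefix[:-1] + shifts[:-1]
    total = float(prefix[-1] + shifts[-1])
    precursor = total + spec.precursor_offset
    keep = rng.random(ladder.size) > spec.miss_prob
    masses = list(ladder[keep])
    if spec.include_suffix:
        suffix = precursor - ladder
        keep_s = rng.random(suffix.size) > spec.miss_prob
        masses.extend(suffix[keep_s])
    if spec.n_noise > 0 and ladder.size:
        lo, hi = float(ladder[0]), float(ladder[-1])
        masses.extend(rng.uniform(lo, hi, size=spec.n_noise))
    masses_arr = np.array(masses, dtype=float)
    intensities = rng.lognormal(spec.intensity_mu, spec.intensity_sigma,
                                size=masses_arr.size)
    return DeconvolutedSpectrum(
        spectrum_id=spectrum_id,
        precursor_mass=precursor,
        masses=masses_arr,
        intensities=intensities,
    )


def write_fixture_set(
    spec: FixtureSpec,
    out_dir: str | Path,
    n_spectra: Optional[int] = None,
) -> Tuple[Path, Path, Path]:
    """Write a complete fixture set: FASTA, msalign spectra and a truth TSV.

    Each spectrum is generated from a protein drawn uniformly from the
    database; the truth file maps spectrum ids to the source protein ids.
    Returns the three file paths (fasta, msalign, truth).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "proteins.fasta"
    records = generate_protein_db(spec, fasta)
    rng = np.random.default_rng(spec.seed + 2)
    n_spectra = n_spectra if n_spectra is not None else spec.n_proteins
    spectra = []
    truth: List[Tuple[str, str]] = []
    for i in range(n_spectra):
        pid, seq = records[int(rng.integers(len(records)))]
        sid = f"S{i:04d}"
        spectra.append(generate_spectrum(seq, spec, spectrum_id=sid, rng=rng))
        truth.append((sid, pid))
    msalign = out_dir / "spectra.msalign"
    write_msalign(spectra, msalign)
    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("spectrum_id\tprotein_id\n")
        for sid, pid in truth:
            fh.write(f"{sid}\t{pid}\n")
    return fasta, msalign, truth_path
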