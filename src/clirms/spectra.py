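"""Peak-list data model, MGF input/output, and theoretical fragment ladders.

Spectra are centroided peak lists with a precursor m/z and charge; doublet
partners (light/heavy) are represented as two separate MS2 spectra, which
keeps the files standard MGF.  Fragmentation follows the b/y ladder of the
peptide backbone: a prefix ion carries the full RNA-adduct mass iff the
cross-linked residue falls inside the prefix, and symmetrically for suffix
ions -- this asymmetry is what localizes the cross-link site.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .chem import DEFAULT_TABLE, PROTON_MASS, ResidueTable

__all__ = [
    "Peak",
    "Spectrum",
    "Fragment",
    "read_mgf",
    "write_mgf",
    "theoretical_fragments",
    "neutral_mass",
]


@dataclass(frozen=True)
class Peak:
    """A single centroided peak."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")


@dataclass
class Spectrum:
    """An MS2 spectrum: precursor descriptor plus a sorted peak list."""

    id: str
    precursor_mz: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray
    precursor_intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"spectrum {self.id!r}: charge must be >= 1")
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError(f"spectrum {self.id!r}: m/z and intensity length mismatch")
        if len(self.mz) and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def neutral_mass(self) -> float:
        """Neutral (uncharged) precursor mass in Da."""
        return neutral_mass(self.precursor_mz, self.charge)


def neutral_mass(mz: float, charge: int) -> float:
    return mz * charge - charge * PROTON_MASS


# ---------------------------------------------------------------------------
# MGF I/O (pyteomics-backed)
# ---------------------------------------------------------------------------

def _check_block_balance(path: Path) -> None:
    """Fail early, naming the offending block, on unbalanced BEGIN/END IONS."""
    open_line = None
    n_blocks = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip().upper()
            if token == "BEGIN IONS":
                if open_line is not None:
                    raise ValueError(
                        f"{path}: block {n_blocks + 1} starting at line {open_line} "
                        f"has no END IONS (new BEGIN IONS at line {lineno})"
                    )
                open_line = lineno
                n_blocks += 1
            elif token == "END IONS":
                if open_line is None:
                    raise ValueError(f"{path}: stray END IONS at line {lineno}")
                open_line = None
    if open_line is not None:
        raise ValueError(
            f"{path}: block {n_blocks} starting at line {open_line} has no END IONS"
        )


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF peak-list file into Spectrum objects.

    An empty file yields an empty list; malformed BEGIN/END IONS nesting
    raises a ``ValueError`` naming the offending block.
    """
    path = Path(path)
    _check_block_balance(path)
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            title = str(params.get("title", f"index_{len(spectra)}"))
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise ValueError(f"{path}: block {title!r} lacks PEPMASS")
            if "charge" not in params:
                raise ValueError(f"{path}: block {title!r} lacks CHARGE")
            charge = int(params["charge"][0])
            prec_int = 0.0
            if isinstance(pepmass, (tuple, list)) and len(pepmass) > 1 and pepmass[1]:
                prec_int = float(pepmass[1])
            spectra.append(
                Spectrum(
                    id=title,
                    precursor_mz=float(pepmass[0]),
                    charge=charge,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    precursor_intensity=prec_int,
                )
            )
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra to MGF; read(write(S)) reproduces S to float precision."""
    entries = [
        {
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": {
                "title": s.id,
                "pepmass": (s.precursor_mz, s.precursor_intensity),
                "charge": [s.charge],
            },
        }
        for s in spectra
    ]
    with open(path, "w") as fh:
        _mgf.write(entries, fh)


# ---------------------------------------------------------------------------
# Theoretical fragments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fragment:
    label: str  # e.g. "b3", "y2+RNA", "M+RNA"
    mz: float
    charge: int


def theoretical_fragments(
    peptide: str,
    site: int,
    adduct_mass: float,
    fragment_charges: Sequence[int] = (1,),
    include_precursor: bool = True,
    precursor_charge: int | None = None,
    table: ResidueTable = DEFAULT_TABLE,
) -> list[Fragment]:
    """b/y fragment ladder of a cross-linked peptide.

    ``site`` is the 1-based cross-linked residue within the peptide;
    ``adduct_mass`` is the neutral mass added by the RNA adduct (light or
    heavy, after any neutral loss).  A prefix ion b_i carries the adduct iff
    ``site <= i``; a suffix ion y_j carries it iff ``site >= len - j + 1``.
    Adduct-bearing ions are labeled with a ``+RNA`` suffix.  For a length-1
    peptide there is no b/y ladder, only the (always adduct-bearing)
    precursor species ``M+RNA``.
    """
    n = len(peptide)
    if not 1 <= site <= n:
        raise ValueError(f"site {site} out of bounds for peptide of length {n}")
    residues = [table.amino_mass(aa) for aa in peptide]
    water = table.water_mass
    frags: list[Fragment] = []

    def emit(label: str, neutral: float, charges: Sequence[int]) -> None:
        for z in charges:
            mz = (neutral + z * PROTON_MASS) / z
            frags.append(Fragment(f"{label}^{z}" if z > 1 else label, mz, z))

    prefix = 0.0
    for i in range(1, n):
        prefix += residues[i - 1]
        if site <= i:
            emit(f"b{i}+RNA", prefix + adduct_mass, fragment_charges)
        else:
            emit(f"b{i}", prefix, fragment_charges)
    suffix = 0.0
    for j in range(1, n):
        suffix += residues[n - j]
        if site >= n - j + 1:
            emit(f"y{j}+RNA", suffix + water + adduct_mass, fragment_charges)
        else:
            emit(f"y{j}", suffix + water, fragment_charges)
    if include_precursor:
        z = precursor_charge or max(fragment_charges)
        neutral = sum(residues) + water + adduct_mass
        emit("M+RNA", neutral, [z])
    return frags
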