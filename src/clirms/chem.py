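"""Elemental compositions, monoisotopic masses, and isotope-label mass shifts.

This module provides the mass model underlying cross-linked
peptide-oligonucleotide identification: elemental compositions with exact
monoisotopic masses, residue tables for the 20 standard amino acids and the
four ribonucleotides, and the light/heavy mass shift (``dm``) produced by
stable-isotope labeling of the RNA.

Two labeling strategies are supported:

* ``full_13C15N`` -- RNA transcribed from uniformly 13C/15N-labeled NTPs.
  Every carbon and nitrogen atom of a nucleotide is heavy, so ``dm`` is
  additive over the adduct composition (a single uridine shifts by
  ~11.0243 Da, a cytidine by ~12.0213 Da, a purine by ~15.0187 Da).
* ``post_digest_18O`` -- an 18O-labeled phosphate is enzymatically
  transferred onto the 5'-hydroxyl of cross-linked oligonucleotides after
  digestion; ``dm`` is a constant (heavy-oxygen count x ~2.0042 Da)
  independent of the adduct composition.

Nucleotide residues follow the 3'-phosphate convention (nucleoside
3'-monophosphate minus water), matching the chemistry of RNase T1/A
digestion products: an oligonucleotide with 5'-OH and 3'-phosphate termini
weighs ``sum(residues) + H2O``, so a mononucleotide adduct equals the free
NMP.  A 5'-phosphate terminal state adds one HPO3; a 2',3'-cyclic phosphate
is the default state minus one water.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import yaml

__all__ = [
    "ElementalComposition",
    "ResidueTable",
    "LabelScheme",
    "DEFAULT_TABLE",
    "PROTON_MASS",
    "C13_DELTA",
    "N15_DELTA",
    "O18_DELTA",
    "monoisotopic_mass",
    "peptide_composition",
    "peptide_neutral_mass",
    "oligo_composition",
    "oligo_neutral_mass",
    "label_shift",
    "nucleotide_shift",
    "load_table",
]

#: Monoisotopic atomic masses (Da), NIST/CODATA values.  Heavy isotopes are
#: tracked as separate symbols so labeled and unlabeled atoms never mix.
MONOISOTOPIC_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "13C": 13.0033548378,
    "15N": 15.0001088982,
    "18O": 17.9991610,
}

PROTON_MASS = 1.00727646688

C13_DELTA = MONOISOTOPIC_MASSES["13C"] - MONOISOTOPIC_MASSES["C"]
N15_DELTA = MONOISOTOPIC_MASSES["15N"] - MONOISOTOPIC_MASSES["N"]
O18_DELTA = MONOISOTOPIC_MASSES["18O"] - MONOISOTOPIC_MASSES["O"]

_FORMULA_TOKEN = re.compile(r"(\d*[A-Z][a-z]?)(\d*)")


class ElementalComposition(Mapping[str, int]):
    """An immutable element -> count map with element-wise arithmetic.

    Heavy isotopes are distinct symbols (``"13C"``, ``"15N"``, ``"18O"``).
    Addition and subtraction are element-wise; subtraction that would drive
    any count negative raises ``ValueError`` (a composition is a physical
    multiset of atoms).
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None) -> None:
        clean: dict[str, int] = {}
        for sym, n in (counts or {}).items():
            if not isinstance(n, int):
                raise TypeError(f"count for {sym!r} must be an integer, got {n!r}")
            if n < 0:
                raise ValueError(f"negative count for element {sym!r}: {n}")
            if n:
                clean[sym] = n
        object.__setattr__(self, "_counts", clean)

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse ``"C9H11N2O8P"`` style formulas; ``"13C9"`` marks isotopes."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r} at {pos}")
            sym, num = m.group(1), m.group(2)
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
            pos = m.end()
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r} at {pos}")
        return cls(counts)

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, sym: str) -> int:
        return self._counts.get(sym, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, sym: object) -> bool:
        return sym in self._counts

    # Arithmetic -----------------------------------------------------------
    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        counts = dict(self._counts)
        for sym, n in other.items():
            counts[sym] = counts.get(sym, 0) + n
        return ElementalComposition(counts)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        counts = dict(self._counts)
        for sym, n in other.items():
            new = counts.get(sym, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction would make {sym!r} negative ({new})"
                )
            counts[sym] = new
        return ElementalComposition(counts)

    def __mul__(self, k: int) -> "ElementalComposition":
        if not isinstance(k, int) or k < 0:
            raise ValueError("multiplier must be a nonnegative integer")
        return ElementalComposition({s: n * k for s, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalComposition):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __repr__(self) -> str:
        return f"ElementalComposition({self.formula()!r})"

    def formula(self) -> str:
        return "".join(
            f"{sym}{n}" if n != 1 else sym
            for sym, n in sorted(self._counts.items())
        )

    def mass(self, element_masses: Mapping[str, float] | None = None) -> float:
        return monoisotopic_mass(self, element_masses)


def monoisotopic_mass(
    comp: Mapping[str, int],
    element_masses: Mapping[str, float] | None = None,
) -> float:
    """Sum of count x monoisotopic atomic mass over the composition (Da).

    Raises ``KeyError`` for an element symbol absent from the mass table.
    """
    masses = element_masses or MONOISOTOPIC_MASSES
    total = 0.0
    for sym, n in comp.items():
        if sym not in masses:
            raise KeyError(f"unknown element symbol {sym!r}")
        total += n * masses[sym]
    return total


WATER = ElementalComposition.from_formula("H2O")
HPO3 = ElementalComposition.from_formula("HPO3")

# Residue compositions: amino acids as peptide-bond residues, nucleotides as
# nucleoside 3'-monophosphate minus water.
_AMINO_ACIDS = {
    "G": "C2H3NO", "A": "C3H5NO", "S": "C3H5NO2", "P": "C5H7NO",
    "V": "C5H9NO", "T": "C4H7NO2", "C": "C3H5NOS", "L": "C6H11NO",
    "I": "C6H11NO", "N": "C4H6N2O2", "D": "C4H5NO3", "Q": "C5H8N2O2",
    "K": "C6H12N2O", "E": "C5H7NO3", "M": "C5H9NOS", "H": "C6H7N3O",
    "F": "C9H9NO", "R": "C6H12N4O", "Y": "C9H9NO2", "W": "C11H10N2O",
}
_NUCLEOTIDES = {
    "A": "C10H12N5O6P",
    "C": "C9H12N3O7P",
    "G": "C10H12N5O7P",
    "U": "C9H11N2O8P",
}

#: Recognized oligonucleotide terminal states.
TERMINAL_STATES = ("5OH_3p", "5p_3p", "cyclic")


@dataclass(frozen=True)
class ResidueTable:
    """Residue compositions plus the constants every mass computation needs.

    All entries are overridable from a plain-text (YAML) config via
    :func:`load_table`, so nonstandard chemistries can be expressed without
    touching code.
    """

    amino_acids: Mapping[str, ElementalComposition]
    nucleotides: Mapping[str, ElementalComposition]
    element_masses: Mapping[str, float] = field(
        default_factory=lambda: dict(MONOISOTOPIC_MASSES)
    )
    water: ElementalComposition = WATER
    phosphate: ElementalComposition = HPO3

    def __post_init__(self) -> None:
        for std in "GASPVTCLINDQKEMHFRYW":
            if std not in self.amino_acids:
                raise ValueError(f"missing standard amino acid {std!r}")
        for nt in "ACGU":
            if nt not in self.nucleotides:
                raise ValueError(f"missing nucleotide {nt!r}")
        for name, comp in {**self.amino_acids, **self.nucleotides}.items():
            if monoisotopic_mass(comp, self.element_masses) <= 0:
                raise ValueError(f"residue {name!r} has nonpositive mass")

    def amino_mass(self, aa: str) -> float:
        if aa not in self.amino_acids:
            raise KeyError(f"unknown amino acid {aa!r}")
        return monoisotopic_mass(self.amino_acids[aa], self.element_masses)

    def nucleotide_mass(self, nt: str) -> float:
        if nt not in self.nucleotides:
            raise KeyError(f"unknown nucleotide {nt!r}")
        return monoisotopic_mass(self.nucleotides[nt], self.element_masses)

    @property
    def water_mass(self) -> float:
        return monoisotopic_mass(self.water, self.element_masses)

    @property
    def phosphate_mass(self) -> float:
        return monoisotopic_mass(self.phosphate, self.element_masses)


DEFAULT_TABLE = ResidueTable(
    amino_acids={a: ElementalComposition.from_formula(f) for a, f in _AMINO_ACIDS.items()},
    nucleotides={n: ElementalComposition.from_formula(f) for n, f in _NUCLEOTIDES.items()},
)


def load_table(path: str) -> ResidueTable:
    """Build a ResidueTable from a YAML file of overrides.

    Recognized top-level keys: ``element_masses``, ``amino_acids``,
    ``nucleotides`` (residue formulas as strings).  Anything omitted keeps
    its default.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - {"element_masses", "amino_acids", "nucleotides"}
    if unknown:
        raise ValueError(f"unknown chemistry-config keys: {sorted(unknown)}")
    masses = dict(MONOISOTOPIC_MASSES)
    masses.update(raw.get("element_masses", {}))
    aas = dict(DEFAULT_TABLE.amino_acids)
    for a, f in raw.get("amino_acids", {}).items():
        aas[a] = ElementalComposition.from_formula(f)
    nts = dict(DEFAULT_TABLE.nucleotides)
    for n, f in raw.get("nucleotides", {}).items():
        nts[n] = ElementalComposition.from_formula(f)
    return ResidueTable(amino_acids=aas, nucleotides=nts, element_masses=masses)


# ---------------------------------------------------------------------------
# Peptide and oligonucleotide masses
# ---------------------------------------------------------------------------

def peptide_composition(
    sequence: str, table: ResidueTable = DEFAULT_TABLE
) -> ElementalComposition:
    """Elemental composition of a neutral peptide (residues + water)."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    comp = table.water
    for aa in sequence:
        if aa not in table.amino_acids:
            raise KeyError(f"unknown amino acid {aa!r} in {sequence!r}")
        comp = comp + table.amino_acids[aa]
    return comp


def peptide_neutral_mass(sequence: str, table: ResidueTable = DEFAULT_TABLE) -> float:
    """Neutral monoisotopic mass of a peptide (Da)."""
    return monoisotopic_mass(peptide_composition(sequence, table), table.element_masses)


def oligo_composition(
    counts: Mapping[str, int],
    terminal_state: str = "5OH_3p",
    table: ResidueTable = DEFAULT_TABLE,
) -> ElementalComposition:
    """Elemental composition of a neutral oligonucleotide adduct.

    ``counts`` is a nucleotide multiset (e.g. ``{"U": 1, "C": 1}``); the
    sequence is irrelevant since only the composition is mass-observable.
    """
    if sum(counts.values()) < 1:
        raise ValueError("oligonucleotide composition must contain >= 1 nucleotide")
    if terminal_state not in TERMINAL_STATES:
        raise ValueError(
            f"unknown terminal state {terminal_state!r}; expected one of {TERMINAL_STATES}"
        )
    comp = table.water
    for nt, n in counts.items():
        if nt not in table.nucleotides:
            raise KeyError(f"unknown nucleotide {nt!r}")
        comp = comp + n * table.nucleotides[nt]
    if terminal_state == "5p_3p":
        comp = comp + table.phosphate
    elif terminal_state == "cyclic":
        comp = comp - table.water
    return comp


def oligo_neutral_mass(
    counts: Mapping[str, int],
    terminal_state: str = "5OH_3p",
    table: ResidueTable = DEFAULT_TABLE,
) -> float:
    """Neutral monoisotopic mass of an oligonucleotide adduct (Da)."""
    return monoisotopic_mass(
        oligo_composition(counts, terminal_state, table), table.element_masses
    )


# ---------------------------------------------------------------------------
# Isotope labeling
# ---------------------------------------------------------------------------

SCHEME_IDS = ("none", "full_13C15N", "post_digest_18O")


@dataclass(frozen=True)
class LabelScheme:
    """An RNA isotope-labeling scheme and its heavy-atom bookkeeping.

    ``heavy_oxygens`` only matters for ``post_digest_18O``: the transferred
    gamma-phosphate retains its three nonbridging heavy oxygens (the bridging
    oxygen comes from the acceptor 5'-OH), hence the default of 3 giving
    ``dm`` ~ 6.0127 Da.  It is configurable for variant labeling chemistries.
    """

    name: str = "full_13C15N"
    heavy_oxygens: int = 3

    def __post_init__(self) -> None:
        if self.name not in SCHEME_IDS:
            raise ValueError(f"unknown labeling scheme {self.name!r}; expected {SCHEME_IDS}")
        if self.heavy_oxygens < 0:
            raise ValueError("heavy_oxygens must be >= 0")

    @classmethod
    def none(cls) -> "LabelScheme":
        return cls(name="none")

    @classmethod
    def full_13c15n(cls) -> "LabelScheme":
        return cls(name="full_13C15N")

    @classmethod
    def post_digest_18o(cls, heavy_oxygens: int = 3) -> "LabelScheme":
        return cls(name="post_digest_18O", heavy_oxygens=heavy_oxygens)


def nucleotide_shift(
    nt: str, scheme: LabelScheme, table: ResidueTable = DEFAULT_TABLE
) -> float:
    """Heavy-light mass difference contributed by one nucleotide (Da)."""
    if scheme.name != "full_13C15N":
        return 0.0
    comp = table.nucleotides[nt]
    return comp["C"] * C13_DELTA + comp["N"] * N15_DELTA


def label_shift(
    counts: Mapping[str, int],
    scheme: LabelScheme,
    table: ResidueTable = DEFAULT_TABLE,
) -> float:
    """Mass shift dm between heavy- and light-labeled forms of an adduct (Da).

    For uniform 13C/15N labeling the shift is the sum over nucleotides of
    (carbons x 1.0033548 + nitrogens x 0.9970349); for post-digestion 18O
    labeling it is ``heavy_oxygens x 2.0042464`` regardless of composition;
    for an unlabeled scheme it is zero.  Applied to an empty composition the
    shift is zero for every scheme.
    """
    if scheme.name == "none":
        return 0.0
    if scheme.name == "post_digest_18O":
        if sum(counts.values()) == 0:
            return 0.0
        return scheme.heavy_oxygens * O18_DELTA
    return sum(n * nucleotide_shift(nt, scheme, table) for nt, n in counts.items())
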