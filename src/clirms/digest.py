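"""In-silico digestion and precursor-candidate generation.

Proteins are digested with trypsin (cleavage C-terminal of K/R, suppressed
before proline); RNAs with RNase T1 (3' of G), RNase A (3' of pyrimidines)
or benzonase.  Benzonase is nonspecific, so it is modeled exhaustively as
"every substring up to the adduct-length cap" -- the search operates on
nucleotide compositions, where completeness of the hypothesis space matters
more than the product-length distribution of a stochastic nuclease.

Candidate precursors are the Cartesian product of peptides, oligonucleotide
compositions and neutral losses, each carrying a light and a heavy neutral
mass whose difference is the labeling-scheme shift dm.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from . import chem
from .chem import DEFAULT_TABLE, LabelScheme, ResidueTable

__all__ = [
    "SequenceRecord",
    "Peptide",
    "RnaFragment",
    "OligoComposition",
    "NeutralLoss",
    "PrecursorCandidate",
    "DEFAULT_LOSSES",
    "read_fasta",
    "digest_protein",
    "digest_rna",
    "enumerate_compositions",
    "generate_candidates",
    "peptides_to_frame",
    "candidates_to_frame",
]

_PROTEIN_ALPHABET = set("GASPVTCLINDQKEMHFRYW")
_RNA_ALPHABET = set("ACGU")


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein or RNA sequence."""

    id: str
    kind: str  # "protein" | "rna"
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.kind not in ("protein", "rna"):
            raise ValueError(f"record {self.id!r}: unknown kind {self.kind!r}")
        alphabet = _PROTEIN_ALPHABET if self.kind == "protein" else _RNA_ALPHABET
        bad = set(self.sequence) - alphabet
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid {self.kind} letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, kind: str) -> list[SequenceRecord]:
    """Read FASTA records; RNA sequences are uppercased and T -> U normalized."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if kind == "rna":
            seq = seq.replace("T", "U")
        records.append(SequenceRecord(id=rec.id, kind=kind, sequence=seq))
    return records


@dataclass(frozen=True)
class Peptide:
    """A protease product located on its parent protein (1-based inclusive)."""

    protein_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int = 0
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid peptide span [{self.start}, {self.end}]")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("peptide sequence length does not match its span")

    def __len__(self) -> int:
        return len(self.sequence)

    def neutral_mass(self, table: ResidueTable = DEFAULT_TABLE) -> float:
        return chem.peptide_neutral_mass(self.sequence, table)


@dataclass(frozen=True)
class RnaFragment:
    """A nuclease product located on its parent RNA (1-based inclusive)."""

    rna_id: str
    start: int
    end: int
    sequence: str

    def composition(self) -> "OligoComposition":
        return OligoComposition.from_sequence(self.sequence)


@dataclass(frozen=True, order=True)
class OligoComposition:
    """An order-free nucleotide multiset -- what MS can see of an adduct."""

    a: int = 0
    c: int = 0
    g: int = 0
    u: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.c, self.g, self.u) < 0:
            raise ValueError("nucleotide counts must be nonnegative")

    @classmethod
    def from_sequence(cls, seq: str) -> "OligoComposition":
        return cls(seq.count("A"), seq.count("C"), seq.count("G"), seq.count("U"))

    @classmethod
    def from_key(cls, key: str) -> "OligoComposition":
        """Parse a canonical key like ``"C1U2"``."""
        import re

        counts = {"A": 0, "C": 0, "G": 0, "U": 0}
        pos = 0
        for m in re.finditer(r"([ACGU])(\d+)", key):
            if m.start() != pos:
                raise ValueError(f"cannot parse composition key {key!r}")
            counts[m.group(1)] += int(m.group(2))
            pos = m.end()
        if pos != len(key):
            raise ValueError(f"cannot parse composition key {key!r}")
        return cls(counts["A"], counts["C"], counts["G"], counts["U"])

    def counts(self) -> dict[str, int]:
        return {"A": self.a, "C": self.c, "G": self.g, "U": self.u}

    @property
    def length(self) -> int:
        return self.a + self.c + self.g + self.u

    def key(self) -> str:
        """Canonical serialization, alphabetical: e.g. ``"C1U1"``."""
        return "".join(
            f"{nt}{n}" for nt, n in sorted(self.counts().items()) if n > 0
        )

    def neutral_mass(
        self, terminal_state: str = "5OH_3p", table: ResidueTable = DEFAULT_TABLE
    ) -> float:
        return chem.oligo_neutral_mass(self.counts(), terminal_state, table)

    def __str__(self) -> str:
        return self.key()


@dataclass(frozen=True)
class NeutralLoss:
    id: str
    mass: float


#: Default neutral losses considered on the precursor: none, water, and
#: metaphosphate (HPO3).
DEFAULT_LOSSES: tuple[NeutralLoss, ...] = (
    NeutralLoss("none", 0.0),
    NeutralLoss("H2O", chem.WATER.mass()),
    NeutralLoss("HPO3", chem.HPO3.mass()),
)


def losses_by_id(ids: Iterable[str]) -> list[NeutralLoss]:
    table = {l.id: l for l in DEFAULT_LOSSES}
    out = []
    for i in ids:
        if i not in table:
            raise ValueError(f"unknown neutral loss {i!r}; known: {sorted(table)}")
        out.append(table[i])
    return out


# ---------------------------------------------------------------------------
# Protein digestion
# ---------------------------------------------------------------------------

def _tryptic_sites(seq: str) -> list[int]:
    # 0-based indices i such that cleavage occurs between seq[i] and seq[i+1]
    return [
        i
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]


def digest_protein(
    record: SequenceRecord,
    enzyme: str = "trypsin",
    max_missed: int = 0,
    length_range: tuple[int, int] = (1, 60),
) -> list[Peptide]:
    """Tryptic peptides of a protein with up to ``max_missed`` missed cleavages.

    Cleavage occurs C-terminal of K or R except when the next residue is P.
    Peptides outside ``length_range`` (inclusive bounds) are dropped.
    Positions are 1-based inclusive protein coordinates.
    """
    if record.kind != "protein":
        raise ValueError(f"record {record.id!r} is not a protein")
    if enzyme != "trypsin":
        raise ValueError(f"unsupported enzyme {enzyme!r}")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = record.sequence
    cuts = [-1] + _tryptic_sites(seq) + [len(seq) - 1]
    lo, hi = length_range
    peptides = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(cuts))):
            start, end = cuts[i] + 1, cuts[j]  # 0-based inclusive
            sub = seq[start : end + 1]
            if lo <= len(sub) <= hi:
                peptides.append(
                    Peptide(
                        protein_id=record.id,
                        start=start + 1,
                        end=end + 1,
                        sequence=sub,
                        missed_cleavages=j - i - 1,
                    )
                )
    return peptides


# ---------------------------------------------------------------------------
# RNA digestion
# ---------------------------------------------------------------------------

NUCLEASES = ("rnase_t1", "rnase_a", "benzonase")


def digest_rna(
    record: SequenceRecord,
    nucleases: Iterable[str] = ("rnase_t1", "rnase_a"),
    benzonase_max_length: int = 4,
) -> list[RnaFragment]:
    """Nuclease products of an RNA with 1-based positions.

    RNase T1 cleaves 3' of G; RNase A cleaves 3' of C and U.  If benzonase
    is included, its nonspecific activity is modeled as all substrings up to
    ``benzonase_max_length`` nucleotides (completeness of the composition
    hypothesis space, not a kinetic model).
    """
    if record.kind != "rna":
        raise ValueError(f"record {record.id!r} is not an RNA")
    chosen = set(nucleases)
    unknown = chosen - set(NUCLEASES)
    if unknown:
        raise ValueError(f"unknown nuclease ids {sorted(unknown)}; known: {NUCLEASES}")
    seq = record.sequence
    if "benzonase" in chosen:
        frags = []
        for width in range(1, min(benzonase_max_length, len(seq)) + 1):
            for start in range(len(seq) - width + 1):
                frags.append(
                    RnaFragment(record.id, start + 1, start + width,
                                seq[start : start + width])
                )
        return frags
    cutters = ""
    if "rnase_t1" in chosen:
        cutters += "G"
    if "rnase_a" in chosen:
        cutters += "CU"
    cut_after = [i for i in range(len(seq) - 1) if seq[i] in cutters]
    bounds = [-1] + cut_after + [len(seq) - 1]
    return [
        RnaFragment(record.id, bounds[i] + 2, bounds[i + 1] + 1,
                    seq[bounds[i] + 1 : bounds[i + 1] + 1])
        for i in range(len(bounds) - 1)
    ]


def enumerate_compositions(max_len: int) -> list[OligoComposition]:
    """All nucleotide multisets of length 1..max_len (C(k+3, 3) per length k)."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    out = []
    for k in range(1, max_len + 1):
        for combo in itertools.combinations_with_replacement("ACGU", k):
            out.append(OligoComposition.from_sequence("".join(combo)))
    return out


# ---------------------------------------------------------------------------
# Precursor candidates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrecursorCandidate:
    """A peptide + oligonucleotide adduct (+ neutral loss) precursor hypothesis.

    ``light_mass`` is the neutral mass of the unlabeled form
    (peptide + oligo - loss + cross-link offset); ``heavy_mass - light_mass``
    equals the labeling-scheme shift ``dm`` for the adduct composition.
    """

    peptide: Peptide
    composition: OligoComposition
    loss: NeutralLoss
    light_mass: float
    heavy_mass: float
    dm: float

    @property
    def is_decoy(self) -> bool:
        return self.peptide.is_decoy

    def adduct_mass(self) -> float:
        """Mass added to the peptide by the (light) adduct after the loss."""
        return self.light_mass - chem.peptide_neutral_mass(self.peptide.sequence)


def generate_candidates(
    peptides: Sequence[Peptide],
    compositions: Sequence[OligoComposition],
    losses: Sequence[NeutralLoss] = DEFAULT_LOSSES,
    scheme: LabelScheme = LabelScheme.full_13c15n(),
    terminal_state: str = "5OH_3p",
    xlink_offset: float = 0.0,
    table: ResidueTable = DEFAULT_TABLE,
) -> list[PrecursorCandidate]:
    """Cartesian product of peptides x compositions x losses with masses.

    ``xlink_offset`` is an optional constant added to every light mass for
    chemistries where covalent-bond formation changes the adduct mass
    (e.g. -2.016 for a loss of H2); the default assumes pure additivity.
    """
    if not peptides or not compositions:
        raise ValueError("peptides and compositions must be nonempty")
    pep_masses = {p: p.neutral_mass(table) for p in set(peptides)}
    oligo_masses = {
        c: c.neutral_mass(terminal_state, table) for c in set(compositions)
    }
    shifts = {c: chem.label_shift(c.counts(), scheme, table) for c in set(compositions)}
    out = []
    for pep in peptides:
        for comp in compositions:
            for loss in losses:
                light = pep_masses[pep] + oligo_masses[comp] - loss.mass + xlink_offset
                dm = shifts[comp]
                out.append(
                    PrecursorCandidate(
                        peptide=pep,
                        composition=comp,
                        loss=loss,
                        light_mass=light,
                        heavy_mass=light + dm,
                        dm=dm,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# TSV exports
# ---------------------------------------------------------------------------

def peptides_to_frame(peptides: Sequence[Peptide]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [p.protein_id for p in peptides],
            "start": [p.start for p in peptides],
            "end": [p.end for p in peptides],
            "sequence": [p.sequence for p in peptides],
            "missed_cleavages": [p.missed_cleavages for p in peptides],
            "is_decoy": [p.is_decoy for p in peptides],
        }
    )


def candidates_to_frame(candidates: Sequence[PrecursorCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [c.peptide.protein_id for c in candidates],
            "peptide": [c.peptide.sequence for c in candidates],
            "composition": [c.composition.key() for c in candidates],
            "loss": [c.loss.id for c in candidates],
            "light_mass": [c.light_mass for c in candidates],
            "heavy_mass": [c.heavy_mass for c in candidates],
            "dm": [c.dm for c in candidates],
            "is_decoy": [c.is_decoy for c in candidates],
        }
    )
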