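"""Residue-level cross-link maps, RNA mapping, motifs, and phase comparison.

Spectral counts per protein residue are the semiquantitative abundance proxy
of the workflow; because MS observes the adduct's nucleotide composition but
not its sequence, mapping back onto the RNA enumerates every sequence window
whose multiset matches (ambiguity is reported, never resolved silently).
The two-phase comparison is deliberately qualitative: only identical
cross-link keys are compared between samples, and no statistical test is
attached to the count ratios.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .digest import OligoComposition, SequenceRecord
from .search import CsmIdentification

__all__ = [
    "ResidueXlMap",
    "RnaInterval",
    "PhaseComparison",
    "IUPAC_RNA",
    "residue_map",
    "map_composition_to_rna",
    "find_motif_matches",
    "compare_phases",
]


@dataclass
class ResidueXlMap:
    """Per-residue spectral counts for one protein."""

    protein_id: str
    length: int
    counts: dict[int, int] = field(default_factory=dict)
    compositions: dict[int, dict[str, int]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        """One row per residue 1..length (zeros included), plus breakdown."""
        rows = []
        for pos in range(1, self.length + 1):
            comp = self.compositions.get(pos, {})
            rows.append(
                {
                    "protein_id": self.protein_id,
                    "position": pos,
                    "spectral_count": self.counts.get(pos, 0),
                    "compositions": ";".join(
                        f"{k}:{n}" for k, n in sorted(comp.items())
                    ),
                }
            )
        return pd.DataFrame(rows)


def residue_map(
    csms: Sequence[CsmIdentification],
    proteins: Mapping[str, SequenceRecord] | Sequence[SequenceRecord],
    protein_id: str,
) -> ResidueXlMap:
    """Aggregate FDR-passing identifications into per-residue counts.

    Raises ``KeyError`` if ``protein_id`` (or any identification's protein)
    is not among the given records.
    """
    if not isinstance(proteins, Mapping):
        proteins = {p.id: p for p in proteins}
    if protein_id not in proteins:
        raise KeyError(f"unknown protein {protein_id!r}")
    xmap = ResidueXlMap(protein_id=protein_id, length=len(proteins[protein_id]))
    for c in csms:
        if c.peptide.protein_id != protein_id:
            if c.peptide.protein_id not in proteins:
                raise KeyError(
                    f"identification references unknown protein "
                    f"{c.peptide.protein_id!r}"
                )
            continue
        xmap.counts[c.site] = xmap.counts.get(c.site, 0) + 1
        comp = xmap.compositions.setdefault(c.site, {})
        key = c.composition.key()
        comp[key] = comp.get(key, 0) + 1
    return xmap


@dataclass(frozen=True)
class RnaInterval:
    """A candidate RNA window for an adduct composition (inclusive, offset-shifted)."""

    rna_id: str
    composition: str
    start: int
    end: int
    sequence: str


def map_composition_to_rna(
    comp: OligoComposition,
    rna: SequenceRecord,
    offset: int = 0,
) -> list[RnaInterval]:
    """All windows of the RNA whose nucleotide multiset equals ``comp``.

    ``offset`` shifts local 1-based positions into an external numbering
    (reported position = local position + offset), e.g. for placing a
    subcloned element back into genomic coordinates.  Overlapping windows
    are allowed; an empty result means the composition cannot derive from
    this RNA.
    """
    if rna.kind != "rna":
        raise ValueError(f"record {rna.id!r} is not an RNA")
    width = comp.length
    seq = rna.sequence
    if width > len(seq):
        return []
    target = comp.counts()
    window = Counter(seq[:width])
    out = []
    for start in range(len(seq) - width + 1):
        if start:
            window[seq[start - 1]] -= 1
            window[seq[start + width - 1]] += 1
        if all(window.get(nt, 0) == n for nt, n in target.items()):
            out.append(
                RnaInterval(
                    rna_id=rna.id,
                    composition=comp.key(),
                    start=start + 1 + offset,
                    end=start + width + offset,
                    sequence=seq[start : start + width],
                )
            )
    return out


#: IUPAC degenerate nucleotide codes over the RNA alphabet.
IUPAC_RNA: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}


def find_motif_matches(motif: str, rna: SequenceRecord) -> list[int]:
    """1-based start positions of (possibly overlapping) IUPAC motif matches."""
    if not motif:
        raise ValueError("empty motif")
    bad = set(motif.upper()) - set(IUPAC_RNA)
    if bad:
        raise ValueError(f"invalid IUPAC codes {sorted(bad)} in motif {motif!r}")
    pattern = "".join(
        f"[{IUPAC_RNA[c]}]" if len(IUPAC_RNA[c]) > 1 else IUPAC_RNA[c]
        for c in motif.upper()
    )
    return [
        m.start() + 1 for m in re.finditer(f"(?=({pattern}))", rna.sequence)
    ]


@dataclass
class PhaseComparison:
    """Qualitative comparison of two FDR-filtered result sets.

    Keys are (protein, site, composition) tuples; shared keys carry their
    paired spectral counts, and phase-specific keys are listed without any
    cross-phase ratio (counts from different samples are not comparable
    unless the site is identical).
    """

    key_fields: tuple[str, ...]
    shared: pd.DataFrame  # key columns + count_a + count_b
    unique_a: pd.DataFrame  # key columns + count_a
    unique_b: pd.DataFrame  # key columns + count_b
    labels: tuple[str, str] = ("A", "B")

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    def partition_sizes(self) -> tuple[int, int, int]:
        return (len(self.shared), len(self.unique_a), len(self.unique_b))


DEFAULT_COMPARISON_KEY = ("protein_id", "site", "composition")


def compare_phases(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    key_fields: Sequence[str] = DEFAULT_COMPARISON_KEY,
    labels: tuple[str, str] = ("A", "B"),
) -> PhaseComparison:
    """Partition cross-link keys into shared / A-only / B-only with counts.

    Inputs are identification tables (one row per FDR-passing spectrum
    match); spectral counts are row counts per key.  Raises if either table
    lacks a key column.
    """
    key_fields = tuple(key_fields)
    for name, df in (("first", results_a), ("second", results_b)):
        missing = set(key_fields) - set(df.columns)
        if missing:
            raise ValueError(
                f"{name} result set lacks key columns {sorted(missing)}"
            )

    def counts(df: pd.DataFrame) -> pd.DataFrame:
        if len(df) == 0:
            return pd.DataFrame(columns=[*key_fields, "n"])
        return (
            df.groupby(list(key_fields), as_index=False)
            .size()
            .rename(columns={"size": "n"})
        )

    ca = counts(results_a).rename(columns={"n": "count_a"})
    cb = counts(results_b).rename(columns={"n": "count_b"})
    merged = ca.merge(cb, on=list(key_fields), how="outer", indicator=True)
    shared = (
        merged[merged["_merge"] == "both"]
        .drop(columns="_merge")
        .reset_index(drop=True)
    )
    only_a = (
        merged[merged["_merge"] == "left_only"]
        .drop(columns=["_merge", "count_b"])
        .reset_index(drop=True)
    )
    only_b = (
        merged[merged["_merge"] == "right_only"]
        .drop(columns=["_merge", "count_a"])
        .reset_index(drop=True)
    )
    for df in (shared, only_a, only_b):
        df.sort_values(list(key_fields), inplace=True, ignore_index=True)
    return PhaseComparison(
        key_fields=key_fields,
        shared=shared,
        unique_a=only_a,
        unique_b=only_b,
        labels=labels,
    )
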