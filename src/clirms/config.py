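"""Pipeline configuration: a flat, validated key/value schema.

The config is a plain YAML mapping of scalar keys (lists allowed for the
multi-valued ones).  Unknown keys are rejected so that a typo in a
tolerance never silently falls back to a default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .chem import SCHEME_IDS, LabelScheme

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, with documented defaults.

    Tolerances default to precursor 10 ppm / fragment 20 ppm (typical
    high-resolution instrument settings); the adduct-length cap defaults to
    4 nucleotides (mono- to tetra-nucleotide adducts dominate in practice);
    the FDR threshold defaults to 1% at unique (peptide, adduct mass, site)
    combinations.
    """

    protein_fasta: str = ""
    rna_fasta: str = ""
    mgf: list[str] = field(default_factory=list)  # one or two peak-list files
    phase_labels: list[str] = field(
        default_factory=lambda: ["dispersed", "condensed"]
    )
    scheme: str = "full_13C15N"
    heavy_oxygens: int = 3
    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    min_peptide_length: int = 1
    max_peptide_length: int = 60
    max_adduct_length: int = 4
    losses: list[str] = field(default_factory=lambda: ["none", "H2O", "HPO3"])
    terminal_state: str = ""  # empty = infer from scheme
    xlink_offset: float = 0.0
    precursor_ppm: float = 10.0
    fragment_ppm: float = 20.0
    fdr: float = 0.01
    rna_offset: int = 0
    motif: str = ""  # optional IUPAC motif to annotate on the RNA
    seed: int = 0
    out_dir: str = "clirms_out"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scheme not in SCHEME_IDS:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected {SCHEME_IDS}")
        if not 1 <= len(self.mgf) <= 2 and self.mgf:
            raise ValueError("mgf must list one or two peak-list files")
        if len(self.phase_labels) < len(self.mgf):
            raise ValueError("need a phase label per MGF file")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if not 1 <= self.min_peptide_length <= self.max_peptide_length:
            raise ValueError("invalid peptide length range")
        if self.max_adduct_length < 1:
            raise ValueError("max_adduct_length must be >= 1")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        for tol in (self.precursor_ppm, self.fragment_ppm):
            if tol <= 0:
                raise ValueError("tolerances must be positive")

    def label_scheme(self) -> LabelScheme:
        return LabelScheme(name=self.scheme, heavy_oxygens=self.heavy_oxygens)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a flat key/value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text
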