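"""End-to-end pipeline runner: digestion -> search -> FDR -> maps -> comparison.

Each stage logs its counts (spectra read, doublets found, matches, unique
identifications pre/post FDR) so silent-filter bugs are visible; all
outputs are TSV plus a JSON manifest with a config hash and per-file
checksums.  A failing stage removes any partial outputs and re-raises with
the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .digest import (
    Peptide,
    digest_protein,
    enumerate_compositions,
    generate_candidates,
    losses_by_id,
    read_fasta,
)
from .mapping import (
    PhaseComparison,
    compare_phases,
    find_motif_matches,
    map_composition_to_rna,
    residue_map,
)
from .search import build_decoys, csms_to_frame, filter_fdr, search_spectra
from .spectra import read_mgf

log = logging.getLogger("clirms")

__all__ = ["PipelineResult", "run_pipeline"]

_FLOAT_FMT = "%.6f"


@dataclass
class PipelineResult:
    """Outputs of a pipeline run, in memory and on disk."""

    config: PipelineConfig
    identifications: dict[str, pd.DataFrame]  # phase -> accepted CSM table
    unique: dict[str, pd.DataFrame]  # phase -> unique-combination table
    estimated_fdr: dict[str, float]
    comparison: PhaseComparison | None
    manifest: dict
    out_dir: Path


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full identification workflow described by ``config``.

    With two MGF inputs the two phases are searched independently and then
    compared on identical (protein, site, composition) keys.  The run is
    deterministic: identical config and inputs give byte-identical outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "validate-inputs"
    try:
        for path in [config.protein_fasta, config.rna_fasta, *config.mgf]:
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"input file not found: {path!r}")

        stage = "read-inputs"
        proteins = read_fasta(config.protein_fasta, kind="protein")
        rnas = read_fasta(config.rna_fasta, kind="rna")
        if not proteins or not rnas:
            raise ValueError("need at least one protein and one RNA record")
        datasets = {}
        for mgf_path, label in zip(config.mgf, config.phase_labels):
            datasets[label] = read_mgf(mgf_path)
            log.info("phase %s: %d spectra read", label, len(datasets[label]))

        stage = "digest"
        peptides: list[Peptide] = []
        for prot in proteins:
            peptides.extend(
                digest_protein(
                    prot,
                    enzyme=config.enzyme,
                    max_missed=config.max_missed_cleavages,
                    length_range=(config.min_peptide_length, config.max_peptide_length),
                )
            )
        decoy_peptides = build_decoys(peptides)
        log.info("%d target peptides, %d decoys", len(peptides), len(decoy_peptides))

        stage = "candidates"
        scheme = config.label_scheme()
        compositions = enumerate_compositions(config.max_adduct_length)
        losses = losses_by_id(config.losses)
        terminal = config.terminal_state or (
            "5p_3p" if scheme.name == "post_digest_18O" else "5OH_3p"
        )
        candidates = generate_candidates(
            peptides + decoy_peptides, compositions, losses, scheme,
            terminal_state=terminal, xlink_offset=config.xlink_offset,
        )
        log.info("%d precursor candidates", len(candidates))

        stage = "search"
        identifications, unique, est_fdr, accepted = {}, {}, {}, {}
        for label, spectra in datasets.items():
            csms = search_spectra(
                spectra, candidates, scheme,
                precursor_ppm=config.precursor_ppm,
                fragment_ppm=config.fragment_ppm,
                phase=label,
            )
            log.info("phase %s: %d spectrum matches", label, len(csms))
            result = filter_fdr(csms, q_threshold=config.fdr)
            accepted[label] = result.accepted_csms
            identifications[label] = csms_to_frame(result.accepted_csms)
            unique[label] = result.unique
            est_fdr[label] = result.estimated_fdr
            log.info(
                "phase %s: %d unique combinations pre-FDR, %d accepted "
                "(estimated FDR %.3f%%)",
                label,
                int((~result.unique["is_decoy"]).sum()),
                int(result.unique["accepted"].sum()),
                100 * result.estimated_fdr,
            )

        stage = "write-identifications"
        for label in datasets:
            for name, df in (
                (f"identifications_{label}.tsv", identifications[label]),
                (f"unique_{label}.tsv", unique[label]),
            ):
                p = out_dir / name
                df.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
                written.append(p)

        stage = "residue-map"
        prot_index = {p.id: p for p in proteins}
        map_frames = []
        for label in datasets:
            for prot in proteins:
                xmap = residue_map(accepted[label], prot_index, prot.id)
                df = xmap.to_frame()
                df.insert(0, "phase", label)
                map_frames.append(df)
        residue_df = pd.concat(map_frames, ignore_index=True)
        p = out_dir / "residue_map.tsv"
        residue_df.to_csv(p, sep="\t", index=False)
        written.append(p)

        stage = "rna-map"
        interval_rows = []
        for label in datasets:
            comps = {
                c.composition for c in accepted[label]
            }
            for comp in sorted(comps):
                for rna in rnas:
                    for iv in map_composition_to_rna(comp, rna, config.rna_offset):
                        interval_rows.append(
                            {
                                "phase": label,
                                "rna_id": iv.rna_id,
                                "composition": iv.composition,
                                "start": iv.start,
                                "end": iv.end,
                                "sequence": iv.sequence,
                            }
                        )
        intervals_df = pd.DataFrame(
            interval_rows,
            columns=["phase", "rna_id", "composition", "start", "end", "sequence"],
        )
        p = out_dir / "rna_intervals.tsv"
        intervals_df.to_csv(p, sep="\t", index=False)
        written.append(p)

        if config.motif:
            motif_rows = [
                {"rna_id": rna.id, "motif": config.motif,
                 "position": pos + config.rna_offset}
                for rna in rnas
                for pos in find_motif_matches(config.motif, rna)
            ]
            motif_df = pd.DataFrame(
                motif_rows, columns=["rna_id", "motif", "position"]
            )
            p = out_dir / "motif_matches.tsv"
            motif_df.to_csv(p, sep="\t", index=False)
            written.append(p)

        stage = "compare-phases"
        comparison = None
        if len(datasets) == 2:
            a, b = list(datasets)
            comparison = compare_phases(
                identifications[a], identifications[b], labels=(a, b)
            )
            for name, df in (
                ("comparison_shared.tsv", comparison.shared),
                (f"comparison_only_{a}.tsv", comparison.unique_a),
                (f"comparison_only_{b}.tsv", comparison.unique_b),
            ):
                p = out_dir / name
                df.to_csv(p, sep="\t", index=False)
                written.append(p)

        stage = "manifest"
        cfg_text = config.to_yaml()
        manifest = {
            "tool": "clirms",
            "version": __version__,
            "seed": config.seed,
            "config": json.loads(json.dumps(cfg_text)),
            "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
            "counts": {
                label: {
                    "spectra": len(datasets[label]),
                    "accepted_identifications": len(identifications[label]),
                    "accepted_unique": int(unique[label]["accepted"].sum()),
                    "estimated_fdr": est_fdr[label],
                }
                for label in datasets
            },
            "outputs": {p.name: _sha256(p) for p in written},
        }
        p = out_dir / "manifest.json"
        p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(p)
    except Exception as exc:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        config=config,
        identifications=identifications,
        unique=unique,
        estimated_fdr=est_fdr,
        comparison=comparison,
        manifest=manifest,
        out_dir=out_dir,
    )
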