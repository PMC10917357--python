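"""Ground-truth simulator for doublet-bearing cross-link datasets.

The simulator emulates the observable output of a UV cross-linking
experiment on an equimolar mixture of light and heavy isotope-labeled RNA:
each ground-truth cross-link site yields a pair of MS2 spectra (one light,
one heavy precursor) separated by the labeling-scheme mass shift dm, with
precursor intensities split according to the heavy fraction of the RNA pool
(default 0.5, i.e. 50%/50% mixing).  Fragment peaks follow the theoretical
b/y ladder with the adduct on the cross-linked residue; optional noise adds
uniform random decoy peaks, log-normal intensity jitter, and m/z jitter.

What the simulator does *not* emulate: chromatographic retention, isotope
envelope shapes beyond the light/heavy pair, co-fragmentation of chimeric
precursors, and enrichment losses.  Tests passing on simulated data
therefore validate the identification logic, not instrument effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import chem, digest
from .chem import DEFAULT_TABLE, PROTON_MASS, LabelScheme, ResidueTable
from .digest import OligoComposition, Peptide, SequenceRecord
from .spectra import Spectrum, theoretical_fragments, write_mgf

__all__ = [
    "CrosslinkSite",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_two_phase",
    "toy_protein",
    "toy_rna",
    "default_scenario",
    "two_phase_scenario",
]

TRUTH_COLUMNS = [
    "light_id",
    "heavy_id",
    "protein_id",
    "peptide",
    "pep_start",
    "pep_end",
    "site",
    "composition",
    "loss",
    "charge",
    "phase",
]


@dataclass(frozen=True)
class CrosslinkSite:
    """A ground-truth cross-link: protein residue + RNA adduct composition."""

    protein_id: str
    residue: int  # 1-based protein coordinate
    composition: OligoComposition
    loss: str = "none"
    n_spectra: int = 1  # number of doublet pairs to emit for this site


@dataclass
class SimulatedDataset:
    """Simulated spectra plus the ground-truth table that generated them."""

    spectra: list[Spectrum]
    truth: pd.DataFrame
    phase: str = "dispersed"

    def write(self, out_dir: str | Path, stem: str | None = None) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = stem or self.phase
        mgf_path = out_dir / f"{stem}.mgf"
        truth_path = out_dir / f"{stem}_truth.tsv"
        write_mgf(self.spectra, mgf_path)
        self.truth.to_csv(truth_path, sep="\t", index=False)
        return {"mgf": mgf_path, "truth": truth_path}


def _peptide_for_site(
    protein: SequenceRecord, residue: int, peptides: Sequence[Peptide]
) -> Peptide:
    covering = [p for p in peptides if p.start <= residue <= p.end]
    if not covering:
        raise ValueError(
            f"no tryptic peptide covers residue {residue} of {protein.id!r}"
        )
    # prefer fully cleaved, then shortest -- the species trypsin actually yields
    covering.sort(key=lambda p: (p.missed_cleavages, len(p), p.start))
    return covering[0]


def simulate_dataset(
    proteins: Sequence[SequenceRecord],
    sites: Sequence[CrosslinkSite],
    scheme: LabelScheme = LabelScheme.full_13c15n(),
    heavy_fraction: float = 0.5,
    charges: Sequence[int] = (2, 3),
    noise_peaks: int = 0,
    noise_intensity: float = 500.0,
    intensity_jitter_sigma: float = 0.0,
    mz_jitter_ppm: float = 0.0,
    base_intensity: float = 1.0e5,
    fragment_intensity: float = 1.0e3,
    terminal_state: str | None = None,
    seed: int = 0,
    phase: str = "dispersed",
    table: ResidueTable = DEFAULT_TABLE,
) -> SimulatedDataset:
    """Emit one light and one heavy MS2 spectrum per ground-truth doublet.

    The heavy precursor's intensity share is exactly ``heavy_fraction`` of
    the pair total, reflecting the heavy:light molar ratio of the RNA pool.
    With ``noise_peaks = 0`` and zero jitter the output is an exact,
    deterministic rendering of the theoretical spectra (the same seed always
    reproduces the same dataset regardless).

    ``terminal_state`` defaults to 5'-OH/3'-phosphate, or 5'-phosphate when
    the scheme is post-digestion 18O labeling (the transferred phosphate).
    """
    if not 0.0 < heavy_fraction < 1.0:
        raise ValueError("heavy_fraction must lie strictly between 0 and 1")
    if terminal_state is None:
        terminal_state = "5p_3p" if scheme.name == "post_digest_18O" else "5OH_3p"
    rng = np.random.default_rng(seed)
    prot_by_id = {p.id: p for p in proteins}
    pep_cache: dict[str, list[Peptide]] = {}
    loss_table = {l.id: l for l in digest.DEFAULT_LOSSES}

    spectra: list[Spectrum] = []
    rows = []
    pair_index = 0
    for site in sites:
        if site.protein_id not in prot_by_id:
            raise KeyError(f"unknown protein {site.protein_id!r}")
        protein = prot_by_id[site.protein_id]
        if site.protein_id not in pep_cache:
            pep_cache[site.protein_id] = digest.digest_protein(
                protein, max_missed=0, length_range=(1, 60)
            )
        pep = _peptide_for_site(protein, site.residue, pep_cache[site.protein_id])
        pep_site = site.residue - pep.start + 1
        loss = loss_table[site.loss]
        oligo_mass = site.composition.neutral_mass(terminal_state, table)
        adduct_light = oligo_mass - loss.mass
        dm = chem.label_shift(site.composition.counts(), scheme, table)
        pep_mass = pep.neutral_mass(table)

        for k in range(site.n_spectra):
            z = charges[pair_index % len(charges)]
            light_neutral = pep_mass + adduct_light
            pair_total = base_intensity
            specs = {}
            for tag, adduct, neutral, frac in (
                ("L", adduct_light, light_neutral, 1.0 - heavy_fraction),
                ("H", adduct_light + dm, light_neutral + dm, heavy_fraction),
            ):
                frags = theoretical_fragments(
                    pep.sequence, pep_site, adduct,
                    fragment_charges=(1,), precursor_charge=z, table=table,
                )
                mz = np.array([f.mz for f in frags])
                inten = np.full(len(frags), fragment_intensity)
                if intensity_jitter_sigma > 0:
                    inten = inten * rng.lognormal(0.0, intensity_jitter_sigma, len(frags))
                if noise_peaks > 0:
                    lo, hi = 100.0, max(1.05 * float(mz.max()), 200.0)
                    noise_mz = rng.uniform(lo, hi, noise_peaks)
                    noise_int = rng.exponential(noise_intensity, noise_peaks)
                    mz = np.concatenate([mz, noise_mz])
                    inten = np.concatenate([inten, noise_int])
                prec_mz = (neutral + z * PROTON_MASS) / z
                if mz_jitter_ppm > 0:
                    mz = mz * (1.0 + rng.normal(0.0, mz_jitter_ppm * 1e-6, len(mz)))
                    prec_mz *= 1.0 + rng.normal(0.0, mz_jitter_ppm * 1e-6)
                spec_id = f"{phase}_{pair_index:05d}_{tag}"
                specs[tag] = Spectrum(
                    id=spec_id,
                    precursor_mz=prec_mz,
                    charge=z,
                    mz=mz,
                    intensity=inten,
                    precursor_intensity=frac * pair_total,
                )
            spectra.extend([specs["L"], specs["H"]])
            rows.append(
                {
                    "light_id": specs["L"].id,
                    "heavy_id": specs["H"].id,
                    "protein_id": protein.id,
                    "peptide": pep.sequence,
                    "pep_start": pep.start,
                    "pep_end": pep.end,
                    "site": site.residue,
                    "composition": site.composition.key(),
                    "loss": site.loss,
                    "charge": z,
                    "phase": phase,
                }
            )
            pair_index += 1
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return SimulatedDataset(spectra=spectra, truth=truth, phase=phase)


def _site_key(s: CrosslinkSite) -> tuple:
    return (s.protein_id, s.residue, s.composition.key())


def simulate_two_phase(
    proteins: Sequence[SequenceRecord],
    shared_sites: Sequence[CrosslinkSite],
    phase_a_only: Sequence[CrosslinkSite] = (),
    phase_b_only: Sequence[CrosslinkSite] = (),
    phase_labels: tuple[str, str] = ("dispersed", "condensed"),
    seed: int = 0,
    **kwargs,
) -> tuple[SimulatedDataset, SimulatedDataset, pd.DataFrame]:
    """Two independent datasets whose truth sets intersect in shared_sites.

    Mirrors the two-sample (dispersed/condensed) design: both phases carry
    the shared sites, and each adds its own phase-specific ones.  The
    phase-only site sets must be disjoint from each other and from the
    shared set.
    """
    keys_shared = {_site_key(s) for s in shared_sites}
    keys_a = {_site_key(s) for s in phase_a_only}
    keys_b = {_site_key(s) for s in phase_b_only}
    overlap = (keys_a & keys_b) | (keys_shared & (keys_a | keys_b))
    if overlap:
        raise ValueError(f"phase-specific site sets overlap: {sorted(overlap)}")
    ds_a = simulate_dataset(
        proteins, list(shared_sites) + list(phase_a_only),
        seed=seed, phase=phase_labels[0], **kwargs,
    )
    ds_b = simulate_dataset(
        proteins, list(shared_sites) + list(phase_b_only),
        seed=seed + 1, phase=phase_labels[1], **kwargs,
    )
    merged = pd.concat([ds_a.truth, ds_b.truth], ignore_index=True)
    return ds_a, ds_b, merged


# ---------------------------------------------------------------------------
# Built-in scenario: a toy RNA-binding protein bound to a pyrimidine-repeat RNA
# ---------------------------------------------------------------------------

#: Toy RNA-binding protein (88 aa) with aromatic residues spread over
#: tryptic peptides of search-friendly lengths -- a stand-in for an
#: RRM-containing protein.  Synthetic sequence, not a database entry.
TOY_PROTEIN_SEQ = (
    "MKTAYEHAGELFRNDVSHQWKGIEHSLTPGYAKVLFHESNKAGYHWDLTRQPEFHVSGNKTYLDHAAGVRSEWFHTNQGKADHYLVSR"
)

#: Pyrimidine-repeat RNA: three UCUCU motifs separated by adenosines.
TOY_RNA_SEQ = "GGGAGAUCUCUAAAAAUCUCUAAAAAUCUCUAAAAA"


def toy_protein() -> SequenceRecord:
    return SequenceRecord(id="TOYRBP", kind="protein", sequence=TOY_PROTEIN_SEQ)


def toy_rna() -> SequenceRecord:
    return SequenceRecord(id="3xUCUCU", kind="rna", sequence=TOY_RNA_SEQ)


#: Cross-linked residues of the toy protein (aromatic/His positions inside
#: tryptic peptides) and the adduct compositions observed at each, drawn
#: from substrings of the repeat RNA (U- and UC-rich, as UV cross-linking
#: chemistry favors pyrimidines).
_TOY_SITES: tuple[tuple[int, str], ...] = (
    (5, "U1"),        # Y5
    (18, "C1U1"),     # H18
    (25, "C2U1"),     # H25
    (31, "U1"),       # Y31
    (37, "C1U2"),     # H37
    (44, "C1U1"),     # Y44
    (55, "U1"),       # H55
    (62, "A1U1"),     # Y62
    (65, "C1U2"),     # H65
    (74, "U1"),       # F74
    (83, "A2U1"),     # H83
    (84, "C1U1"),     # Y84
)


def _build_sites(
    pairs: Sequence[tuple[int, str]], n_pairs: int, protein_id: str = "TOYRBP"
) -> list[CrosslinkSite]:
    base, extra = divmod(n_pairs, len(pairs))
    sites = []
    for i, (residue, key) in enumerate(pairs):
        n = base + (1 if i < extra else 0)
        if n:
            sites.append(
                CrosslinkSite(
                    protein_id=protein_id,
                    residue=residue,
                    composition=OligoComposition.from_key(key),
                    n_spectra=n,
                )
            )
    return sites


def default_scenario(
    n_pairs: int = 200, seed: int = 0, **sim_kwargs
) -> tuple[list[SequenceRecord], SequenceRecord, SimulatedDataset]:
    """One-phase study: the toy protein/RNA pair with ``n_pairs`` doublets."""
    proteins = [toy_protein()]
    sites = _build_sites(_TOY_SITES, n_pairs)
    ds = simulate_dataset(proteins, sites, seed=seed, **sim_kwargs)
    return proteins, toy_rna(), ds


def two_phase_scenario(
    n_shared: int = 5,
    n_a_only: int = 2,
    n_b_only: int = 3,
    pairs_per_site: int = 8,
    seed: int = 0,
    **sim_kwargs,
) -> tuple[list[SequenceRecord], SequenceRecord, SimulatedDataset, SimulatedDataset, pd.DataFrame]:
    """Two-phase study with a constructed shared/phase-specific partition."""
    total = n_shared + n_a_only + n_b_only
    if total > len(_TOY_SITES):
        raise ValueError(f"at most {len(_TOY_SITES)} distinct sites available")
    chosen = _TOY_SITES[:total]

    def mk(pairs):
        return [
            CrosslinkSite(
                "TOYRBP", r, OligoComposition.from_key(k),
                n_spectra=pairs_per_site,
            )
            for r, k in pairs
        ]

    shared = mk(chosen[:n_shared])
    a_only = mk(chosen[n_shared : n_shared + n_a_only])
    b_only = mk(chosen[n_shared + n_a_only :])
    ds_a, ds_b, merged = simulate_two_phase(
        [toy_protein()], shared, a_only, b_only, seed=seed, **sim_kwargs
    )
    return [toy_protein()], toy_rna(), ds_a, ds_b, merged
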