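"""Doublet detection, precursor matching, site localization, and FDR control.

The identification engine.  Light/heavy precursor pairs whose neutral-mass
difference matches a labeling-scheme shift hypothesis are matched against
peptide + oligonucleotide candidates; the cross-linked residue is localized
by scoring every site hypothesis against the fragment spectrum; confidence
is controlled by a classical target-decoy procedure at the level of unique
(peptide, adduct mass, site) combinations.

The score is a surrogate for the (unpublished) scoring of dedicated search
engines: the number of matched theoretical fragments, each weighted by
1 + log10(1 + intensity).  It is monotone in evidence, cheap, and pluggable
-- pass a different ``peak_weight`` to change the weighting.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import DEFAULT_TABLE, LabelScheme, ResidueTable, label_shift
from .digest import OligoComposition, Peptide, PrecursorCandidate
from .spectra import Spectrum, theoretical_fragments

__all__ = [
    "DoubletMatch",
    "CsmIdentification",
    "FdrResult",
    "build_shift_hypotheses",
    "find_doublets",
    "match_precursor",
    "site_score_profile",
    "localize_and_score",
    "build_decoys",
    "search_spectra",
    "filter_fdr",
    "csms_to_frame",
]


@dataclass(frozen=True)
class DoubletMatch:
    """A light/heavy precursor pair separated by a plausible label shift."""

    light_id: str
    heavy_id: str
    charge: int
    light_mass: float  # neutral, Da
    observed_dm: float  # neutral-mass difference, Da
    hypotheses: tuple[str, ...]  # composition keys consistent with observed_dm


@dataclass(frozen=True)
class CsmIdentification:
    """One scored cross-link spectrum match (a doublet assigned to a site)."""

    light_id: str
    heavy_id: str
    charge: int
    peptide: Peptide
    site: int  # protein coordinates, 1-based
    composition: OligoComposition
    loss: str
    adduct_mass: float  # light adduct mass after the loss, Da
    dm: float
    score: float
    ambiguity: tuple[int, ...]  # protein-coordinate sites tied with the best
    is_decoy: bool
    phase: str = ""
    q_value: float = float("nan")

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be >= 0")
        if not self.peptide.start <= self.site <= self.peptide.end:
            raise ValueError("localized site outside the peptide's protein span")

    def unique_key(self) -> tuple:
        """Uniqueness level for FDR: peptide sequence, adduct mass, site."""
        return (self.peptide.sequence, round(self.adduct_mass, 3), self.site)


def build_shift_hypotheses(
    compositions: Sequence[OligoComposition],
    scheme: LabelScheme,
    table: ResidueTable = DEFAULT_TABLE,
) -> dict[float, tuple[str, ...]]:
    """Map each distinct label shift dm to the composition keys producing it."""
    groups: dict[float, set[str]] = {}
    for comp in compositions:
        dm = round(label_shift(comp.counts(), scheme, table), 6)
        groups.setdefault(dm, set()).add(comp.key())
    return {dm: tuple(sorted(keys)) for dm, keys in sorted(groups.items())}


def find_doublets(
    spectra: Sequence[Spectrum],
    shift_hypotheses: Mapping[float, Sequence[str]],
    ppm_tol: float = 10.0,
) -> list[DoubletMatch]:
    """Pairs of same-charge precursors separated by a hypothesized shift.

    The tolerance on the mass difference is ``2 x ppm_tol`` relative to the
    light neutral mass, since both members contribute measurement error.
    A spectrum may participate in several pairs (resolution is deferred to
    candidate matching and FDR).
    """
    shifts = sorted(shift_hypotheses)
    if not shifts:
        return []
    max_shift = max(shifts)
    by_charge: dict[int, list[Spectrum]] = {}
    for s in spectra:
        by_charge.setdefault(s.charge, []).append(s)
    matches = []
    for charge, group in sorted(by_charge.items()):
        group = sorted(group, key=lambda s: s.neutral_mass)
        masses = [s.neutral_mass for s in group]
        for i, light in enumerate(group):
            m_light = masses[i]
            tol = 2.0 * ppm_tol * 1e-6 * m_light
            hi = bisect_right(masses, m_light + max_shift + tol)
            for j in range(i + 1, hi):
                diff = masses[j] - m_light
                keys: list[str] = []
                for dm in shifts:
                    if abs(diff - dm) <= tol and dm > 0:
                        keys.extend(shift_hypotheses[dm])
                if keys:
                    matches.append(
                        DoubletMatch(
                            light_id=light.id,
                            heavy_id=group[j].id,
                            charge=charge,
                            light_mass=m_light,
                            observed_dm=diff,
                            hypotheses=tuple(sorted(set(keys))),
                        )
                    )
    return matches


def match_precursor(
    doublet: DoubletMatch,
    candidates: Sequence[PrecursorCandidate],
    ppm_tol: float = 10.0,
) -> list[PrecursorCandidate]:
    """Candidates consistent with both the light mass and the pair's dm."""
    out = []
    for cand in candidates:
        tol = ppm_tol * 1e-6 * cand.light_mass
        if abs(cand.light_mass - doublet.light_mass) <= tol and (
            abs(cand.dm - doublet.observed_dm) <= 2.0 * tol
        ):
            out.append(cand)
    return out


# ---------------------------------------------------------------------------
# Localization and scoring
# ---------------------------------------------------------------------------

def _default_peak_weight(intensity: float) -> float:
    return 1.0 + np.log10(1.0 + intensity)


def site_score_profile(
    spectrum: Spectrum,
    peptide: str,
    adduct_mass: float,
    frag_tol_ppm: float = 20.0,
    peak_weight: Callable[[float], float] = _default_peak_weight,
    table: ResidueTable = DEFAULT_TABLE,
) -> np.ndarray:
    """Score of every cross-link site hypothesis 1..len(peptide).

    Each theoretical fragment of the site hypothesis contributes the weight
    of the closest observed peak within the tolerance (once per fragment).
    """
    if len(spectrum) == 0:
        raise ValueError(f"spectrum {spectrum.id!r} has an empty peak list")
    mz = spectrum.mz
    inten = spectrum.intensity
    scores = np.zeros(len(peptide))
    for s in range(1, len(peptide) + 1):
        total = 0.0
        for frag in theoretical_fragments(
            peptide, s, adduct_mass, precursor_charge=spectrum.charge, table=table
        ):
            tol = frag_tol_ppm * 1e-6 * frag.mz
            lo = bisect_left(mz, frag.mz - tol)
            hi = bisect_right(mz, frag.mz + tol)
            if hi > lo:
                k = lo + int(np.argmin(np.abs(mz[lo:hi] - frag.mz)))
                total += peak_weight(float(inten[k]))
        scores[s - 1] = total
    return scores


def localize_and_score(
    spectrum: Spectrum,
    peptide: str,
    adduct_mass: float,
    frag_tol_ppm: float = 20.0,
    tie_tol: float = 1e-9,
    table: ResidueTable = DEFAULT_TABLE,
) -> tuple[int, float, tuple[int, ...]]:
    """Best cross-link site, its score, and the ambiguity set.

    Sites whose score lies within ``tie_tol`` of the maximum form the
    ambiguity set; the lowest position is reported as the primary site
    (deterministic tie-break).
    """
    profile = site_score_profile(
        spectrum, peptide, adduct_mass, frag_tol_ppm, table=table
    )
    best = float(profile.max())
    ambiguous = tuple(
        int(i) + 1 for i in np.flatnonzero(profile >= best - tie_tol)
    )
    return ambiguous[0], best, ambiguous


# ---------------------------------------------------------------------------
# Decoys
# ---------------------------------------------------------------------------

def build_decoys(peptides: Sequence[Peptide]) -> list[Peptide]:
    """Decoy peptides: sequence reversed with the C-terminal residue fixed.

    Reversal preserves the amino-acid multiset, so every decoy has exactly
    its target's mass -- decoys compete for the same precursors and differ
    only in fragmentation.  Peptides mapping to themselves (palindromic
    under the rule) are excluded with a warning.
    """
    decoys = []
    for pep in peptides:
        rev = pep.sequence[:-1][::-1] + pep.sequence[-1]
        if rev == pep.sequence:
            warnings.warn(
                f"peptide {pep.sequence!r} is its own decoy; excluded",
                stacklevel=2,
            )
            continue
        decoys.append(
            replace(pep, sequence=rev, protein_id=f"DECOY_{pep.protein_id}",
                    is_decoy=True)
        )
    return decoys


# ---------------------------------------------------------------------------
# Search driver
# ---------------------------------------------------------------------------

def search_spectra(
    spectra: Sequence[Spectrum],
    candidates: Sequence[PrecursorCandidate],
    scheme: LabelScheme,
    precursor_ppm: float = 10.0,
    fragment_ppm: float = 20.0,
    phase: str = "",
    table: ResidueTable = DEFAULT_TABLE,
) -> list[CsmIdentification]:
    """Doublet detection -> candidate matching -> localization, end to end.

    Light and heavy spectra are scored independently (the heavy fragment
    ladder carries the shifted adduct) and their site profiles summed, so a
    site must be supported by both members of the doublet.
    """
    compositions = {c.composition for c in candidates}
    hypotheses = build_shift_hypotheses(sorted(compositions), scheme, table)
    doublets = find_doublets(spectra, hypotheses, precursor_ppm)
    by_id = {s.id: s for s in spectra}
    csms = []
    for doublet in doublets:
        for cand in match_precursor(doublet, candidates, precursor_ppm):
            light = by_id[doublet.light_id]
            heavy = by_id[doublet.heavy_id]
            adduct = cand.adduct_mass()
            profile = site_score_profile(
                light, cand.peptide.sequence, adduct, fragment_ppm, table=table
            ) + site_score_profile(
                heavy, cand.peptide.sequence, adduct + cand.dm, fragment_ppm,
                table=table,
            )
            best = float(profile.max())
            if best <= 0.0:
                continue
            ambiguous = tuple(
                int(i) + 1 for i in np.flatnonzero(profile >= best - 1e-9)
            )
            pep_site = ambiguous[0]
            csms.append(
                CsmIdentification(
                    light_id=doublet.light_id,
                    heavy_id=doublet.heavy_id,
                    charge=doublet.charge,
                    peptide=cand.peptide,
                    site=cand.peptide.start + pep_site - 1,
                    composition=cand.composition,
                    loss=cand.loss.id,
                    adduct_mass=adduct,
                    dm=cand.dm,
                    score=best,
                    ambiguity=tuple(cand.peptide.start + a - 1 for a in ambiguous),
                    is_decoy=cand.is_decoy,
                    phase=phase,
                )
            )
    return csms


# ---------------------------------------------------------------------------
# Target-decoy FDR
# ---------------------------------------------------------------------------

@dataclass
class FdrResult:
    """Outcome of target-decoy filtering at the unique-combination level.

    ``unique`` has one row per unique (peptide, adduct mass, site) key with
    its best score, decoy flag, q-value and accept flag; ``accepted_csms``
    are all target spectrum matches whose key was accepted (the basis for
    spectral counting); ``estimated_fdr`` is the decoy estimate
    #decoys/#targets at the selected score threshold.
    """

    unique: pd.DataFrame
    accepted_csms: list[CsmIdentification]
    threshold_score: float
    estimated_fdr: float
    q_threshold: float


def filter_fdr(
    csms: Sequence[CsmIdentification],
    q_threshold: float = 0.01,
) -> FdrResult:
    """Collapse to unique combinations, estimate q-values, filter targets.

    The estimated FDR at score s is ``#decoy_keys(score >= s) /
    #target_keys(score >= s)``; q-values are the running minimum of that
    ratio from the bottom of the ranked list (monotone nonincreasing in
    score).  Targets with q <= ``q_threshold`` are accepted.  Raises if no
    decoy identifications are present (the estimate would be undefined).
    """
    if not any(c.is_decoy for c in csms):
        raise ValueError("no decoy identifications: FDR is undefined")
    best: dict[tuple, CsmIdentification] = {}
    for c in csms:
        key = (c.is_decoy,) + c.unique_key()
        if key not in best or c.score > best[key].score:
            best[key] = c
    ranked = sorted(best.values(), key=lambda c: (-c.score, c.is_decoy))
    n_targets = 0
    n_decoys = 0
    fdrs = []
    for c in ranked:
        if c.is_decoy:
            n_decoys += 1
        else:
            n_targets += 1
        fdrs.append(n_decoys / max(n_targets, 1))
    # monotonize from the bottom: q(s) = min FDR at any threshold <= s
    qs = np.minimum.accumulate(np.asarray(fdrs)[::-1])[::-1]
    accepted_keys = set()
    threshold_score = float("inf")
    est_fdr = 0.0
    for c, q in zip(ranked, qs):
        if not c.is_decoy and q <= q_threshold:
            accepted_keys.add(c.unique_key())
            threshold_score = min(threshold_score, c.score)
    if accepted_keys:
        n_t = sum(
            1 for c in ranked if not c.is_decoy and c.score >= threshold_score
        )
        n_d = sum(1 for c in ranked if c.is_decoy and c.score >= threshold_score)
        est_fdr = n_d / max(n_t, 1)
    unique = pd.DataFrame(
        {
            "peptide": [c.peptide.sequence for c in ranked],
            "protein_id": [c.peptide.protein_id for c in ranked],
            "site": [c.site for c in ranked],
            "composition": [c.composition.key() for c in ranked],
            "loss": [c.loss for c in ranked],
            "adduct_mass": [c.adduct_mass for c in ranked],
            "dm": [c.dm for c in ranked],
            "score": [c.score for c in ranked],
            "is_decoy": [c.is_decoy for c in ranked],
            "q_value": qs,
            "accepted": [
                (not c.is_decoy) and (c.unique_key() in accepted_keys)
                for c in ranked
            ],
        }
    )
    q_by_key = {c.unique_key(): float(q) for c, q in zip(ranked, qs) if not c.is_decoy}
    accepted_csms = [
        replace(c, q_value=q_by_key[c.unique_key()])
        for c in csms
        if not c.is_decoy and c.unique_key() in accepted_keys
    ]
    return FdrResult(
        unique=unique,
        accepted_csms=accepted_csms,
        threshold_score=threshold_score if accepted_keys else float("nan"),
        estimated_fdr=est_fdr,
        q_threshold=q_threshold,
    )


def csms_to_frame(csms: Sequence[CsmIdentification]) -> pd.DataFrame:
    """One row per spectrum match, ready for TSV export."""
    return pd.DataFrame(
        {
            "light_id": [c.light_id for c in csms],
            "heavy_id": [c.heavy_id for c in csms],
            "charge": [c.charge for c in csms],
            "protein_id": [c.peptide.protein_id for c in csms],
            "peptide": [c.peptide.sequence for c in csms],
            "pep_start": [c.peptide.start for c in csms],
            "pep_end": [c.peptide.end for c in csms],
            "site": [c.site for c in csms],
            "composition": [c.composition.key() for c in csms],
            "loss": [c.loss for c in csms],
            "adduct_mass": [c.adduct_mass for c in csms],
            "dm": [c.dm for c in csms],
            "score": [c.score for c in csms],
            "q_value": [c.q_value for c in csms],
            "ambiguity": [
                ";".join(str(a) for a in c.ambiguity) for c in csms
            ],
            "is_decoy": [c.is_decoy for c in csms],
            "phase": [c.phase for c in csms],
        }
    )
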