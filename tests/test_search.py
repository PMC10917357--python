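"""Doublet detection, localization, decoys, and target-decoy FDR."""

import numpy as np
import pytest

from clirms import chem, digest, search
from clirms.chem import PROTON_MASS, LabelScheme
from clirms.digest import OligoComposition, Peptide
from clirms.search import (
    CsmIdentification,
    build_decoys,
    build_shift_hypotheses,
    filter_fdr,
    find_doublets,
    localize_and_score,
    match_precursor,
    search_spectra,
)
from clirms.spectra import Spectrum, theoretical_fragments

U_SHIFT = chem.label_shift({"U": 1}, LabelScheme.full_13c15n())


def _precursor(spec_id, neutral, charge, peaks=((200.0, 10.0),)):
    mz = np.array([p[0] for p in peaks])
    inten = np.array([p[1] for p in peaks])
    return Spectrum(
        id=spec_id,
        precursor_mz=(neutral + charge * PROTON_MASS) / charge,
        charge=charge,
        mz=mz,
        intensity=inten,
    )


HYP = {round(U_SHIFT, 6): ("U1",)}


class TestFindDoublets:
    def test_u_shift_pair_found(self):
        spectra = [
            _precursor("L", 1000.0, 1),
            _precursor("H", 1000.0 + U_SHIFT, 1),
        ]
        [m] = find_doublets(spectra, HYP)
        assert (m.light_id, m.heavy_id) == ("L", "H")
        assert m.observed_dm == pytest.approx(U_SHIFT, abs=1e-9)
        assert m.hypotheses == ("U1",)

    def test_mz_spacing_scales_with_charge(self):
        spectra = [
            _precursor("L", 1000.0, 2),
            _precursor("H", 1000.0 + U_SHIFT, 2),
        ]
        [m] = find_doublets(spectra, HYP)
        by_id = {s.id: s for s in spectra}
        spacing = by_id["H"].precursor_mz - by_id["L"].precursor_mz
        assert spacing == pytest.approx(U_SHIFT / 2, abs=1e-9)

    def test_different_charges_never_pair(self):
        spectra = [
            _precursor("L", 1000.0, 1),
            _precursor("H", 1000.0 + U_SHIFT, 2),
        ]
        assert find_doublets(spectra, HYP) == []

    def test_single_spectrum_is_empty(self):
        assert find_doublets([_precursor("L", 1000.0, 1)], HYP) == []

    def test_off_hypothesis_spacing_is_empty(self):
        spectra = [
            _precursor("L", 1000.0, 1),
            _precursor("H", 1001.0, 1),
        ]
        assert find_doublets(spectra, HYP) == []


class TestMatchPrecursor:
    @pytest.fixture()
    def candidate(self, scheme):
        pep = Peptide("P", 1, 2, "GK")
        [cand] = digest.generate_candidates(
            [pep], [OligoComposition(u=1)], digest.DEFAULT_LOSSES[:1], scheme
        )
        return cand

    def test_exact_mass_matches(self, candidate):
        spectra = [
            _precursor("L", candidate.light_mass, 2),
            _precursor("H", candidate.heavy_mass, 2),
        ]
        [doublet] = find_doublets(spectra, HYP)
        assert match_precursor(doublet, [candidate]) == [candidate]

    def test_zero_tolerance_keeps_only_exact(self, candidate):
        exact = search.DoubletMatch(
            "L", "H", 2, candidate.light_mass, candidate.dm, ("U1",)
        )
        assert match_precursor(exact, [candidate], ppm_tol=0.0) == [candidate]
        off = search.DoubletMatch(
            "L", "H", 2, candidate.light_mass + 1e-6, candidate.dm, ("U1",)
        )
        assert match_precursor(off, [candidate], ppm_tol=0.0) == []

    def test_one_dalton_off_is_rejected_at_10ppm(self, candidate):
        spectra = [
            _precursor("L", candidate.light_mass + 1.0, 2),
            _precursor("H", candidate.heavy_mass + 1.0, 2),
        ]
        [doublet] = find_doublets(spectra, HYP)
        assert match_precursor(doublet, [candidate], ppm_tol=10.0) == []


class TestLocalization:
    def _spectrum_for(self, peptide, site, adduct):
        frags = theoretical_fragments(peptide, site, adduct, precursor_charge=2)
        mz = np.array(sorted(f.mz for f in frags))
        return Spectrum("s", 500.0, 2, mz, np.full(len(mz), 1000.0))

    @pytest.mark.parametrize("true_site", [1, 3, 6])
    def test_recovers_true_site_from_clean_ladder(self, true_site):
        adduct = chem.oligo_neutral_mass({"U": 1})
        spec = self._spectrum_for("GYHALK", true_site, adduct)
        site, score, ambiguity = localize_and_score(spec, "GYHALK", adduct)
        assert site == true_site
        assert ambiguity == (true_site,)
        assert score > 0

    def test_length_one_peptide_is_forced(self):
        spec = self._spectrum_for("K", 1, 324.0)
        site, _, ambiguity = localize_and_score(spec, "K", 324.0)
        assert (site, ambiguity) == (1, (1,))

    def test_uninformative_spectrum_has_full_ambiguity(self):
        # only the (always adduct-bearing) precursor species: no site information
        adduct = chem.oligo_neutral_mass({"U": 1})
        neutral = chem.peptide_neutral_mass("GAK") + adduct
        mz = np.array([(neutral + 2 * PROTON_MASS) / 2])
        spec = Spectrum("s", mz[0], 2, mz, np.array([1000.0]))
        site, _, ambiguity = localize_and_score(spec, "GAK", adduct)
        assert site == 1  # deterministic lowest-position tie-break
        assert len(ambiguity) == 3

    def test_empty_peak_list_errors(self):
        spec = Spectrum("s", 500.0, 2, np.array([]), np.array([]))
        with pytest.raises(ValueError):
            localize_and_score(spec, "GAK", 324.0)


class TestDecoys:
    def test_reversal_keeps_cterm(self):
        [decoy] = build_decoys([Peptide("P", 1, 4, "GASK")])
        assert decoy.sequence == "SAGK"
        assert decoy.is_decoy
        assert decoy.protein_id.startswith("DECOY_")

    def test_self_decoy_excluded_with_warning(self):
        peps = [Peptide("P", 1, 3, "AAK"), Peptide("P", 4, 7, "GASK")]
        with pytest.warns(UserWarning, match="own decoy"):
            decoys = build_decoys(peps)
        assert [d.sequence for d in decoys] == ["SAGK"]

    def test_decoy_mass_equals_target_mass(self, search_space):
        peptides, decoys, _ = search_space
        by_target = {p.sequence: p for p in peptides}
        for d in decoys:
            # reversal is an involution on the first n-1 residues
            target_seq = d.sequence[:-1][::-1] + d.sequence[-1]
            assert d.neutral_mass() == pytest.approx(
                by_target[target_seq].neutral_mass(), abs=1e-9
            )


def _csm(seq, site, score, is_decoy, adduct=324.0):
    pep = Peptide("P" if not is_decoy else "DECOY_P", 1, len(seq), seq,
                  is_decoy=is_decoy)
    return CsmIdentification(
        light_id=f"L_{seq}_{site}_{score}",
        heavy_id=f"H_{seq}_{site}_{score}",
        charge=2,
        peptide=pep,
        site=site,
        composition=OligoComposition(u=1),
        loss="none",
        adduct_mass=adduct,
        dm=U_SHIFT,
        score=score,
        ambiguity=(site,),
        is_decoy=is_decoy,
    )


AAS = "ACDEFGHIKLMNPQRSTVWY"


def _unique_targets(n, score_of):
    # n distinct peptide keys with prescribed scores
    out = []
    for i in range(n):
        seq = AAS[i % 20] + AAS[(i // 20) % 20] + "K"
        out.append(_csm(seq, 1 + (i % 3), score_of(i), False, adduct=300.0 + i))
    return out


class TestFdr:
    def test_separated_targets_all_pass_with_zero_fdr(self):
        csms = _unique_targets(100, lambda i: 100.0 + i) + [
            _csm("WWK", 1, 5.0, True)
        ]
        res = filter_fdr(csms)
        assert int(res.unique["accepted"].sum()) == 100
        assert res.estimated_fdr == 0.0

    def test_single_decoy_at_boundary_gives_one_percent(self):
        # one decoy outscores exactly the 100th (lowest) target: FDR = 1/100
        csms = _unique_targets(100, lambda i: 100.0 + i) + [
            _csm("WWK", 1, 100.5, True)
        ]
        res = filter_fdr(csms, q_threshold=0.01)
        assert int(res.unique["accepted"].sum()) == 100
        assert res.estimated_fdr == pytest.approx(0.01)

    def test_all_targets_below_decoys_yields_empty(self):
        csms = _unique_targets(10, lambda i: 1.0 + 0.01 * i) + [
            _csm("WWK", 1, 50.0, True),
            _csm("WYK", 1, 60.0, True),
        ]
        res = filter_fdr(csms)
        assert int(res.unique["accepted"].sum()) == 0
        assert res.accepted_csms == []

    def test_no_decoys_is_an_error(self):
        with pytest.raises(ValueError, match="decoy"):
            filter_fdr(_unique_targets(5, lambda i: 10.0 + i))

    def test_q_values_monotone_nonincreasing_in_score(self):
        rng = np.random.default_rng(5)
        csms = _unique_targets(60, lambda i: float(rng.uniform(0, 100))) + [
            _csm("W" + AAS[i % 20] + "K", 1, float(rng.uniform(0, 100)), True)
            for i in range(30)
        ]
        res = filter_fdr(csms)
        df = res.unique.sort_values("score", ascending=False)
        assert (np.diff(df["q_value"].to_numpy()) >= -1e-12).all()

    def test_collapse_keeps_best_score_per_key(self):
        csms = [
            _csm("GYK", 2, 10.0, False),
            _csm("GYK", 2, 30.0, False),
            _csm("WWK", 1, 1.0, True),
        ]
        res = filter_fdr(csms)
        target_rows = res.unique[~res.unique.is_decoy]
        assert len(target_rows) == 1
        assert target_rows.iloc[0]["score"] == 30.0
        # both spectrum matches of the accepted key are retained for counting
        assert len(res.accepted_csms) == 2


class TestRoundTrip:
    def test_noiseless_recovery_at_one_percent_fdr(
        self, noiseless_dataset, search_space, scheme
    ):
        """>=99% of ground-truth doublets recovered with correct peptide,
        composition and site after 1% FDR filtering."""
        _, _, ds = noiseless_dataset
        _, _, candidates = search_space
        csms = search_spectra(ds.spectra, candidates, scheme)
        res = filter_fdr(csms, q_threshold=0.01)
        accepted = {
            (c.light_id, c.heavy_id, c.peptide.sequence, c.composition.key(), c.site)
            for c in res.accepted_csms
        }
        truth = list(
            zip(
                ds.truth.light_id,
                ds.truth.heavy_id,
                ds.truth.peptide,
                ds.truth.composition,
                ds.truth.site,
            )
        )
        recovered = sum(1 for key in truth if key in accepted)
        assert recovered / len(truth) >= 0.99

    def test_noisy_realized_fdp_within_twice_estimate(self, search_space, scheme):
        """With moderate noise, the realized false-discovery proportion
        against ground truth stays within twice the 1% filtering level."""
        from clirms import simulate

        _, _, ds = simulate.default_scenario(
            n_pairs=60, seed=23, noise_peaks=25, intensity_jitter_sigma=0.3,
            mz_jitter_ppm=3.0,
        )
        _, _, candidates = search_space
        csms = search_spectra(ds.spectra, candidates, scheme)
        res = filter_fdr(csms, q_threshold=0.01)
        truth_keys = set(zip(ds.truth.peptide, ds.truth.composition, ds.truth.site))
        accepted_keys = {
            (c.peptide.sequence, c.composition.key(), c.site)
            for c in res.accepted_csms
        }
        assert accepted_keys, "no identifications survived filtering"
        false = {k for k in accepted_keys if k not in truth_keys}
        assert len(false) / len(accepted_keys) <= 2 * 0.01


def test_shift_hypotheses_group_compositions(scheme):
    comps = digest.enumerate_compositions(2)
    hyp = build_shift_hypotheses(comps, scheme)
    # A and G share C/N counts, so A1 and G1 share one dm hypothesis
    purine_dm = chem.label_shift({"A": 1}, scheme)
    assert hyp[round(purine_dm, 6)] == ("A1", "G1")
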