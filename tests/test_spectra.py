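"""Peak lists, MGF round trips, fragment ladders, and the simulator."""

import numpy as np
import pytest

from clirms import chem, simulate
from clirms.digest import OligoComposition
from clirms.spectra import (
    Spectrum,
    neutral_mass,
    read_mgf,
    theoretical_fragments,
    write_mgf,
)


def _random_spectra(n, rng):
    out = []
    for i in range(n):
        k = rng.integers(3, 30)
        mz = np.sort(rng.uniform(100, 1500, k))
        out.append(
            Spectrum(
                id=f"spec_{i}",
                precursor_mz=float(rng.uniform(300, 1200)),
                charge=int(rng.integers(1, 4)),
                mz=mz,
                intensity=rng.uniform(1, 1e4, k),
                precursor_intensity=float(rng.uniform(0, 1e5)),
            )
        )
    return out


class TestMgfIO:
    def test_round_trip(self, tmp_path):
        spectra = _random_spectra(5, np.random.default_rng(4))
        path = tmp_path / "t.mgf"
        write_mgf(spectra, path)
        back = read_mgf(path)
        assert len(back) == 5
        for a, b in zip(spectra, back):
            assert a.id == b.id
            assert a.charge == b.charge
            assert a.precursor_mz == pytest.approx(b.precursor_mz, abs=1e-4)
            np.testing.assert_allclose(a.mz, b.mz, atol=1e-4)
            np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-4)

    def test_missing_end_ions_errors(self, tmp_path):
        path = tmp_path / "bad.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=x\nPEPMASS=500.0\nCHARGE=2+\n100.0 1.0\n"
        )
        with pytest.raises(ValueError, match="END IONS"):
            read_mgf(path)

    def test_empty_file_is_empty_list(self, tmp_path):
        path = tmp_path / "empty.mgf"
        path.write_text("")
        assert read_mgf(path) == []

    def test_unsorted_peaks_are_sorted_on_construction(self):
        s = Spectrum("x", 500.0, 2, np.array([300.0, 100.0]), np.array([1.0, 2.0]))
        assert list(s.mz) == [100.0, 300.0]
        assert list(s.intensity) == [2.0, 1.0]


class TestFragments:
    def test_site_determines_adduct_carrier(self):
        umass = chem.oligo_neutral_mass({"U": 1})
        frags = {f.label: f.mz for f in theoretical_fragments("GK", 1, umass)}
        assert "b1+RNA" in frags and "y1" in frags
        assert "b1" not in frags and "y1+RNA" not in frags
        # b1+RNA = G residue + adduct + proton
        expected = chem.DEFAULT_TABLE.amino_mass("G") + umass + chem.PROTON_MASS
        assert frags["b1+RNA"] == pytest.approx(expected, abs=1e-6)

    def test_moving_site_swaps_carriers(self):
        umass = chem.oligo_neutral_mass({"U": 1})
        s1 = {f.label for f in theoretical_fragments("GK", 1, umass)}
        s2 = {f.label for f in theoretical_fragments("GK", 2, umass)}
        assert {"b1+RNA", "y1"} <= s1
        assert {"b1", "y1+RNA"} <= s2

    def test_length_one_peptide_has_only_adduct_species(self):
        frags = theoretical_fragments("K", 1, 324.0)
        assert [f.label for f in frags] == ["M+RNA"]

    def test_site_out_of_bounds(self):
        with pytest.raises(ValueError):
            theoretical_fragments("GK", 3, 324.0)

    def test_ladder_is_complete(self):
        frags = [f.label for f in theoretical_fragments("PEPTIDEK", 4, 324.0)]
        assert sum(l.startswith("b") for l in frags) == 7
        assert sum(l.startswith("y") for l in frags) == 7


class TestSimulator:
    def test_truth_rows_equal_doublet_pairs(self, noiseless_dataset):
        _, _, ds = noiseless_dataset
        assert len(ds.truth) == len(ds.spectra) / 2 == 48

    def test_doublet_spacing_equals_dm_over_charge(self, noiseless_dataset, scheme):
        _, _, ds = noiseless_dataset
        by_id = {s.id: s for s in ds.spectra}
        for row in ds.truth.itertuples():
            light, heavy = by_id[row.light_id], by_id[row.heavy_id]
            comp = OligoComposition.from_key(row.composition)
            dm = chem.label_shift(comp.counts(), scheme)
            assert heavy.precursor_mz - light.precursor_mz == pytest.approx(
                dm / light.charge, abs=1e-6
            )
            assert heavy.neutral_mass - light.neutral_mass == pytest.approx(
                dm, abs=1e-6
            )

    def test_noiseless_spectra_contain_full_theoretical_ladder(
        self, noiseless_dataset
    ):
        _, _, ds = noiseless_dataset
        by_id = {s.id: s for s in ds.spectra}
        for row in ds.truth.head(6).itertuples():
            comp = OligoComposition.from_key(row.composition)
            adduct = chem.oligo_neutral_mass(comp.counts())
            spec = by_id[row.light_id]
            site_in_pep = row.site - row.pep_start + 1
            for frag in theoretical_fragments(
                row.peptide, site_in_pep, adduct, precursor_charge=spec.charge
            ):
                assert np.min(np.abs(spec.mz - frag.mz)) < 1e-9

    @pytest.mark.parametrize("fraction", [0.25, 0.5, 0.75])
    def test_heavy_intensity_share_matches_input(self, toy_proteins, fraction):
        sites = [
            simulate.CrosslinkSite("TOYRBP", 5, OligoComposition(u=1), n_spectra=4)
        ]
        ds = simulate.simulate_dataset(
            toy_proteins, sites, heavy_fraction=fraction, seed=0
        )
        heavy = sum(
            s.precursor_intensity for s in ds.spectra if s.id.endswith("_H")
        )
        total = sum(s.precursor_intensity for s in ds.spectra)
        assert heavy / total == pytest.approx(fraction, abs=1e-12)

    def test_invalid_heavy_fraction(self, toy_proteins):
        sites = [simulate.CrosslinkSite("TOYRBP", 5, OligoComposition(u=1))]
        with pytest.raises(ValueError):
            simulate.simulate_dataset(toy_proteins, sites, heavy_fraction=1.0)

    def test_fixed_seed_is_byte_identical(self, toy_proteins, tmp_path):
        sites = [
            simulate.CrosslinkSite("TOYRBP", 18, OligoComposition(c=1, u=1), n_spectra=3)
        ]
        paths = []
        for name in ("a", "b"):
            ds = simulate.simulate_dataset(
                toy_proteins, sites, noise_peaks=15, intensity_jitter_sigma=0.3,
                mz_jitter_ppm=3.0, seed=42,
            )
            out = ds.write(tmp_path / name)
            paths.append(out["mgf"])
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_two_phase_truth_intersection_is_shared_set(self):
        _, _, ds_a, ds_b, merged = simulate.two_phase_scenario(
            n_shared=5, n_a_only=2, n_b_only=3, pairs_per_site=2, seed=7
        )
        keys = lambda df: set(zip(df.site, df.composition))
        shared = keys(ds_a.truth) & keys(ds_b.truth)
        assert len(shared) == 5
        assert len(keys(ds_a.truth) - shared) == 2
        assert len(keys(ds_b.truth) - shared) == 3
        assert len(merged) == len(ds_a.truth) + len(ds_b.truth)

    def test_overlapping_phase_only_sets_rejected(self, toy_proteins):
        site = simulate.CrosslinkSite("TOYRBP", 5, OligoComposition(u=1))
        with pytest.raises(ValueError):
            simulate.simulate_two_phase(
                toy_proteins, [], [site], [site]
            )


def test_neutral_mass_inverts_mz():
    m = 1500.0
    z = 2
    mz = (m + z * chem.PROTON_MASS) / z
    assert neutral_mass(mz, z) == pytest.approx(m, abs=1e-9)
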