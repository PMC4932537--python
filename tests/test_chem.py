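"""Molecular graph parsing, formulas and exact-mass arithmetic."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phoregen as pg
from phoregen.chem import ELECTRON_MASS, ISOTOPE_MASS, Formula, parse_formula
from phoregen.errors import (
    ParseError,
    UnsupportedChargeError,
    UnsupportedElementError,
)


class TestParseSmiles:
    def test_benzene_aromatic_carbocycle(self):
        mol = pg.parse_smiles("c1ccccc1")
        assert mol.num_atoms == 6
        assert all(sym == "C" and nh == 1 for sym, _q, nh in mol.atoms)
        assert all(order == 1.5 for _i, _j, order in mol.bonds)

    def test_aminomethylthiazole_fragment(self):
        # 2-amino-4-methylthiazole: ring perceived aromatic
        mol = pg.parse_smiles("CC1=CSC(=N1)N")
        syms = [a[0] for a in mol.atoms]
        assert sorted(syms) == ["C", "C", "C", "C", "N", "N", "S"]
        ring_aromatic = [
            a.GetIsAromatic() for a in mol.rdmol.GetAtoms() if a.IsInRing()
        ]
        assert ring_aromatic and all(ring_aromatic)

    def test_bis_cyclopropyl_connected(self):
        mol = pg.parse_smiles("C1CC1C1CC1")
        assert mol.num_atoms == 6
        assert len(mol.bonds) == 7  # 6 ring bonds + 1 linker

    @pytest.mark.parametrize("bad", ["C1CC", "C(", "not_smiles", ""])
    def test_malformed_raises_with_position(self, bad):
        with pytest.raises(ParseError, match="position"):
            pg.parse_smiles(bad)

    def test_unsupported_element(self):
        with pytest.raises(UnsupportedElementError):
            pg.parse_smiles("CC[Si](C)C")

    def test_multicomponent_rejected(self):
        with pytest.raises(ParseError):
            pg.parse_smiles("CC.CC")


class TestFormula:
    def test_methane(self):
        f = pg.molecular_formula(pg.parse_smiles("C"))
        assert f.hill() == "CH4"

    def test_compound12_formula(self, compound12):
        assert pg.molecular_formula(compound12).hill() == "C21H21ClFN5OS"

    def test_compound15_formula(self):
        mol = pg.paper_compounds()[14].molecule()
        assert pg.molecular_formula(mol).hill() == "C22H23ClFN5O"

    def test_hill_render_parse_idempotent(self, compound12):
        f = pg.molecular_formula(compound12)
        assert parse_formula(f.hill()).counts == f.counts
        assert parse_formula(str(f)).hill() == f.hill()

    def test_parse_cation_suffix(self):
        f = parse_formula("C20H30N5OS+")
        assert f.charge == 1 and f.counts["C"] == 20


class TestMasses:
    def test_water(self):
        assert pg.monoisotopic_mass(parse_formula("H2O")) == pytest.approx(
            18.01056, abs=1e-4
        )

    def test_carbon12_exact(self):
        assert pg.monoisotopic_mass(parse_formula("C")) == 12.0

    def test_cation_formula_mass(self):
        # electron mass subtracted for the +1 ion
        f = parse_formula("C20H30N5OS+")
        assert pg.monoisotopic_mass(f) == pytest.approx(388.2166, abs=5e-4)

    def test_protonated_mz_neutral_convention(self, compound12):
        f = pg.molecular_formula(compound12)
        assert pg.protonated_mz(f) == pytest.approx(446.1212, abs=5e-4)

    def test_protonated_mz_cation_convention(self):
        assert pg.protonated_mz(parse_formula("C24H28N5O2S+")) == pytest.approx(
            450.1958, abs=5e-4
        )

    def test_bare_proton(self):
        assert pg.protonated_mz(parse_formula("H+")) == pytest.approx(
            1.00728, abs=1e-5
        )

    def test_unsupported_charge(self):
        with pytest.raises(UnsupportedChargeError):
            pg.protonated_mz(Formula({"C": 1}, charge=2))

    def test_unknown_element_in_mass(self):
        with pytest.raises(UnsupportedElementError):
            pg.monoisotopic_mass(Formula({"Xx": 1}))

    @given(
        a=st.dictionaries(
            st.sampled_from(sorted(ISOTOPE_MASS)),
            st.integers(1, 40),
            min_size=1,
            max_size=5,
        ),
        b=st.dictionaries(
            st.sampled_from(sorted(ISOTOPE_MASS)),
            st.integers(1, 40),
            min_size=1,
            max_size=5,
        ),
    )
    @settings(max_examples=100, deadline=None)
    def test_mass_additivity(self, a, b):
        fa, fb = Formula(a), Formula(b)
        total = pg.monoisotopic_mass(fa.merge(fb))
        assert abs(total - pg.monoisotopic_mass(fa) - pg.monoisotopic_mass(fb)) < 1e-9

    def test_protonation_convention_consistency(self):
        """[M+H]+ of a neutral equals the mass of the cation with one
        extra H, exactly."""
        for c in pg.paper_compounds():
            f = pg.molecular_formula(c.molecule())
            counts = dict(f.counts)
            counts["H"] = counts.get("H", 0) + 1
            cation = Formula(counts, charge=1)
            assert abs(pg.protonated_mz(f) - pg.monoisotopic_mass(cation)) < 1e-9

    def test_electron_mass_matters_at_printed_precision(self):
        f = parse_formula("C20H30N5OS+")
        naive = pg.monoisotopic_mass(Formula(f.counts, 0))
        assert abs(naive - pg.monoisotopic_mass(f)) == pytest.approx(
            ELECTRON_MASS, abs=1e-12
        )


class TestLibraryIO:
    def test_smiles_round_trip_preserves_formulas(self, tmp_path):
        from phoregen.data import fixture_molecules

        mols = fixture_molecules()
        path = str(tmp_path / "lib.smi")
        pg.write_library(mols, path, "smiles")
        back = pg.read_library(path, "smiles")
        assert [m.id for m in back] == [m.id for m in mols]
        for a, b in zip(mols, back):
            assert pg.molecular_formula(a).hill() == pg.molecular_formula(b).hill()

    def test_sdf_round_trip_preserves_formulas(self, tmp_path):
        from phoregen.data import fixture_molecules

        mols = fixture_molecules()
        path = str(tmp_path / "lib.sdf")
        pg.write_library(mols, path, "sdf")
        back = pg.read_library(path, "sdf")
        assert len(back) == len(mols)
        for a, b in zip(mols, back):
            assert pg.molecular_formula(a).hill() == pg.molecular_formula(b).hill()

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.smi"
        path.write_text("")
        assert pg.read_library(str(path), "smiles") == []

    def test_malformed_second_sdf_record(self, tmp_path):
        good = str(tmp_path / "one.sdf")
        pg.write_library([pg.parse_smiles("CCO", "ethanol")], good, "sdf")
        text = open(good).read()
        block = text.split("$$$$\n")[0]
        lines = block.splitlines()
        lines[3] = " 99 99  0  0  0  0  0  0  0  0999 V2000"  # corrupt counts
        bad = block + "$$$$\n" + "\n".join(lines) + "\n$$$$\n"
        path = tmp_path / "two.sdf"
        path.write_text(bad)
        with pytest.raises(ParseError, match="record 2"):
            pg.read_library(str(path), "sdf")

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError):
            pg.read_library(str(tmp_path / "x.foo"), "foo")
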