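"""Peptide chemistry: masses, m/z, compositions, envelopes, fragments."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from pyteomics import mass as pyteomics_mass

from enamelsex import chem
from enamelsex.chem import (
    ElementalComposition,
    ModifiedPeptide,
    PeptideChemistryError,
    elemental_composition,
    fragment_ions,
    isotope_envelope,
    monoisotopic_mass,
    mz,
    neutral_mass,
)

peptides = st.text(alphabet=sorted(chem.RESIDUE_MASS), min_size=1, max_size=12)


class TestMonoisotopicMass:
    def test_glycine_free_molecule(self):
        assert monoisotopic_mass(ModifiedPeptide("G")) == pytest.approx(75.03203, abs=2e-5)

    def test_lrypyp_independent_summation(self):
        # frozen from an independent residue-table summation (L+R+Y+P+Y+P + H2O)
        assert monoisotopic_mass(ModifiedPeptide("LRYPYP")) == pytest.approx(
            807.4279, abs=5e-4)

    @given(peptides)
    def test_matches_pyteomics(self, seq):
        mine = monoisotopic_mass(ModifiedPeptide(seq))
        ref = pyteomics_mass.calculate_mass(sequence=seq)
        assert mine == pytest.approx(ref, abs=5e-4)

    @given(peptides, peptides)
    def test_mass_additivity_under_concatenation(self, a, b):
        m_ab = monoisotopic_mass(ModifiedPeptide(a + b))
        m_a = monoisotopic_mass(ModifiedPeptide(a))
        m_b = monoisotopic_mass(ModifiedPeptide(b))
        assert m_ab == pytest.approx(m_a + m_b - chem.WATER, abs=1e-9)

    def test_deamidation_delta(self):
        base = ModifiedPeptide("LNYPYP")
        mod = ModifiedPeptide("LNYPYP", ((2, "Deamidation"),))
        assert monoisotopic_mass(mod) - monoisotopic_mass(base) == pytest.approx(
            0.984016, abs=1e-5)

    def test_unknown_residue_rejected(self):
        with pytest.raises(PeptideChemistryError):
            ModifiedPeptide("LRXPYP")

    def test_modification_on_disallowed_residue_rejected(self):
        # no N/Q/R at position 1 (L) -> Deamidation must fail
        with pytest.raises(PeptideChemistryError):
            ModifiedPeptide("LRYPYP", ((1, "Deamidation"),))

    def test_modification_position_out_of_range(self):
        with pytest.raises(PeptideChemistryError):
            ModifiedPeptide("LR", ((7, "Oxidation"),))

    def test_duplicate_modification_rejected(self):
        with pytest.raises(PeptideChemistryError):
            ModifiedPeptide("LRYPYP", ((3, "Oxidation"), (3, "Oxidation")))

    def test_nterm_rules(self):
        # pyro-Glu from Gln requires an N-terminal Q
        ModifiedPeptide("QLR", (("N-term", "Gln->pyro-Glu"),))
        with pytest.raises(PeptideChemistryError):
            ModifiedPeptide("LQR", (("N-term", "Gln->pyro-Glu"),))
        with pytest.raises(PeptideChemistryError):
            ModifiedPeptide("QLR", ((1, "Acetyl"),))  # N-terminal-only mod


class TestMz:
    @pytest.mark.parametrize("seq,mods,z,expected", [
        ("LRYPYP", (), 2, 404.7212),
        ("LRYPYPSY", (), 2, 529.7689),
        ("SMIRHPYP", ((2, "Oxidation"),), 2, 508.7527),
        ("IRHPYPSY", (), 2, 516.7667),
    ])
    def test_printed_marker_mz(self, seq, mods, z, expected):
        mass = monoisotopic_mass(ModifiedPeptide(seq, mods))
        assert mz(mass, z) == pytest.approx(expected, abs=5e-4)

    def test_single_protonation(self):
        assert mz(100.0, 1) == pytest.approx(100.0 + 1.0072765, abs=1e-9)

    def test_nonpositive_charge_rejected(self):
        with pytest.raises(PeptideChemistryError):
            mz(100.0, 0)

    @given(st.floats(50.0, 5000.0), st.integers(1, 8))
    def test_roundtrip_exact(self, mass, z):
        assert neutral_mass(mz(mass, z), z) == pytest.approx(mass, abs=1e-9)


class TestElementalComposition:
    def test_glycine(self):
        assert elemental_composition(ModifiedPeptide("G")).as_dict() == {
            "C": 2, "H": 5, "N": 1, "O": 2}

    def test_condensation_removes_water(self):
        assert elemental_composition(ModifiedPeptide("GG")).as_dict() == {
            "C": 4, "H": 8, "N": 2, "O": 3}

    @given(peptides)
    def test_composition_mass_consistent(self, seq):
        pep = ModifiedPeptide(seq)
        assert elemental_composition(pep).mass() == pytest.approx(
            monoisotopic_mass(pep), abs=1e-3)

    def test_residue_table_consistency(self):
        for aa, m in chem.RESIDUE_MASS.items():
            comp = ElementalComposition(*chem.RESIDUE_FORMULA[aa])
            assert comp.mass() == pytest.approx(m, abs=1e-4), aa

    def test_registry_mass_composition_consistency(self, registry):
        for name in registry.names():
            mod = registry[name]
            assert mod.mass_delta == pytest.approx(
                mod.composition_delta.mass(), abs=1e-4), name


class TestIsotopeEnvelope:
    def test_single_carbon_is_element_abundance(self):
        env = isotope_envelope(ElementalComposition(C=1), 1, 2)
        ratio = env[1][1] / env[0][1]
        assert ratio == pytest.approx(0.0107 / 0.9893, rel=1e-9)

    def test_normalization_and_spacing(self):
        comp = elemental_composition(ModifiedPeptide("LRYPYP"))
        env = isotope_envelope(comp, 2, 4)
        assert sum(a for _, a in env) == pytest.approx(1.0, abs=1e-9)
        mzs = [m for m, _ in env]
        for a, b in zip(mzs, mzs[1:]):
            assert b - a == pytest.approx(chem.ISOTOPE_SPACING / 2, abs=1e-9)

    def test_matches_exhaustive_enumeration(self, envelope_oracle, random_compositions):
        for comp in random_compositions(30, seed=1):
            env = np.array([a for _, a in isotope_envelope(comp, 1, 4)])
            assert np.max(np.abs(env - envelope_oracle(comp, 4))) < 1e-10

    def test_empty_composition_rejected(self):
        with pytest.raises(PeptideChemistryError):
            isotope_envelope(ElementalComposition(), 1, 4)


class TestFragmentIons:
    def test_b_series_of_lr(self):
        frags = dict(fragment_ions(ModifiedPeptide("LR"), ("b",), 1))
        assert frags["b1"] == pytest.approx(113.08406 + 1.0072765, abs=1e-3)
        assert frags["b2"] == pytest.approx(270.1925, abs=1e-3)

    def test_y1_of_py(self):
        frags = dict(fragment_ions(ModifiedPeptide("PY"), ("y",), 1))
        assert frags["y1"] == pytest.approx(182.0812, abs=1e-3)

    @given(peptides.filter(lambda s: len(s) >= 2))
    def test_complementarity(self, seq):
        pep = ModifiedPeptide(seq)
        total = monoisotopic_mass(pep)
        frags = dict(fragment_ions(pep, ("b", "y"), 1))
        n = len(seq)
        for i in range(1, n):
            assert frags[f"b{i}"] + frags[f"y{n - i}"] == pytest.approx(
                total + 2 * chem.PROTON, abs=1e-6)

    def test_modification_travels_with_containing_fragment(self):
        plain = dict(fragment_ions(ModifiedPeptide("SMIRHPYP"), ("b", "y"), 1))
        oxed = dict(fragment_ions(
            ModifiedPeptide("SMIRHPYP", ((2, "Oxidation"),)), ("b", "y"), 1))
        assert oxed["b1"] == pytest.approx(plain["b1"], abs=1e-9)  # S only
        assert oxed["b2"] == pytest.approx(plain["b2"] + 15.994915, abs=1e-6)
        assert oxed["y6"] == pytest.approx(plain["y6"], abs=1e-9)  # IRHPYP
        assert oxed["y7"] == pytest.approx(plain["y7"] + 15.994915, abs=1e-6)

    def test_doubly_charged_series(self):
        pep = ModifiedPeptide("LRYPYP")
        frags = dict(fragment_ions(pep, ("b", "y"), 2))
        assert frags["y3^2"] == pytest.approx(
            (neutral_mass(frags["y3"], 1) + 2 * chem.PROTON) / 2, abs=1e-9)

    def test_errors(self):
        with pytest.raises(PeptideChemistryError):
            fragment_ions(ModifiedPeptide("LR"), (), 1)
        with pytest.raises(PeptideChemistryError):
            fragment_ions(ModifiedPeptide("L"), ("b",), 1)
        with pytest.raises(PeptideChemistryError):
            fragment_ions(ModifiedPeptide("LR"), ("a",), 1)
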