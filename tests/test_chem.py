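"""Peptide mass arithmetic, digestion and isotope envelopes."""

import itertools

import numpy as np
import pytest
from pyteomics import mass as pyt_mass
from pyteomics import parser as pyt_parser

from hismethyl import chem
from hismethyl.chem import ModifiedPeptide

from conftest import random_peptide


class TestNeutralMass:
    def test_free_glycine(self):
        # C2H5NO2 summed by hand from the atomic table
        assert chem.peptide_neutral_mass(ModifiedPeptide("G")) == pytest.approx(
            75.0320, abs=5e-5
        )

    def test_matches_independent_residue_summation(self, rng):
        """Masses agree with pyteomics' own residue summation to 1e-5 Da."""
        for _ in range(20):
            seq = random_peptide(rng)
            ours = chem.peptide_neutral_mass(ModifiedPeptide(seq))
            theirs = pyt_mass.calculate_mass(sequence=seq)
            assert ours == pytest.approx(theirs, abs=1e-5)

    def test_methyl_delta_is_peptide_independent(self, rng, mod_table):
        expected = chem.composition_mass({"C": 1, "H": 2})
        for _ in range(10):
            seq = "H" + random_peptide(rng)
            meth = chem.peptide_neutral_mass(
                ModifiedPeptide(seq, ((1, "methyl_his"),))
            )
            unmod = chem.peptide_neutral_mass(ModifiedPeptide(seq))
            assert meth - unmod == pytest.approx(expected, abs=1e-9)
        assert mod_table.delta("methyl_his") == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "bad",
        [
            lambda: ModifiedPeptide(""),
            lambda: ModifiedPeptide("GXG"),
            lambda: ModifiedPeptide("GAG", ((5, "methyl_his"),)),
            lambda: ModifiedPeptide("GAG", ((2, "methyl_his"),)),  # not on H
            lambda: ModifiedPeptide("HAG", ((1, "methyl_his"), (1, "phospho"))),
        ],
    )
    def test_invalid_peptides_rejected(self, bad):
        with pytest.raises(ValueError):
            bad()

    def test_unknown_mod_rejected(self):
        with pytest.raises(KeyError):
            chem.peptide_neutral_mass(ModifiedPeptide("HAG", ((1, "oxidation"),)))


class TestMz:
    def test_zero_mass_gives_proton(self):
        assert chem.mz_of(0.0, 1) == pytest.approx(chem.PROTON_MASS, abs=1e-12)

    def test_charge_state_algebra(self, rng):
        for m in rng.uniform(100, 5000, 10):
            assert 2 * chem.mz_of(m, 2) - chem.mz_of(m, 1) == pytest.approx(
                chem.PROTON_MASS, abs=1e-9
            )

    def test_doubly_charged_target_peptide(self):
        neutral = pyt_mass.calculate_mass(sequence="HTVIVYPGYR")
        assert chem.mz_of(
            chem.peptide_neutral_mass(ModifiedPeptide("HTVIVYPGYR")), 2
        ) == pytest.approx((neutral + 2 * chem.PROTON_MASS) / 2, abs=1e-5)

    def test_nonpositive_charge_rejected(self):
        with pytest.raises(ValueError):
            chem.mz_of(1000.0, 0)


class TestImmonium:
    def test_methyl_his_diagnostic_ion(self):
        assert round(chem.immonium_mz("H", "methyl_his"), 4) == 124.0869

    def test_difference_to_unmodified_equals_methyl_delta(self, mod_table):
        diff = chem.immonium_mz("H", "methyl_his") - chem.immonium_mz("H")
        assert diff == pytest.approx(mod_table.delta("methyl_his"), abs=1e-12)

    def test_illegal_mod_on_residue_rejected(self):
        with pytest.raises(ValueError):
            chem.immonium_mz("H", "phospho")


class TestFragmentIons:
    def test_complementarity_identity(self, rng):
        """b_i + y_{n-i} at 1+ sums to neutral mass + 2 protons."""
        for _ in range(10):
            seq = random_peptide(rng)
            p = ModifiedPeptide(seq)
            neutral = chem.peptide_neutral_mass(p)
            ions = {(i.series, i.index): i.mz for i in chem.fragment_ions(p)}
            n = len(seq)
            for i in range(1, n):
                total = ions[("b", i)] + ions[("y", n - i)]
                assert total == pytest.approx(
                    neutral + 2 * chem.PROTON_MASS, abs=1e-6
                )

    def test_nterm_methyl_shifts_all_b_no_y(self, mod_table):
        seq = "HTVIVYPGYR"
        meth = {
            (i.series, i.index): i
            for i in chem.fragment_ions(ModifiedPeptide(seq, ((1, "methyl_his"),)))
        }
        unmod = {
            (i.series, i.index): i.mz
            for i in chem.fragment_ions(ModifiedPeptide(seq))
        }
        delta = mod_table.delta("methyl_his")
        for key, ion in meth.items():
            series, _ = key
            if series == "b":
                assert ion.carries_mod
                assert ion.mz - unmod[key] == pytest.approx(delta, abs=1e-9)
            else:
                assert not ion.carries_mod
                assert ion.mz == pytest.approx(unmod[key], abs=1e-9)

    def test_dipeptide_yields_two_ions(self):
        ions = chem.fragment_ions(ModifiedPeptide("GH"), frozenset({1}))
        assert len(ions) == 2
        assert {(i.series, i.index) for i in ions} == {("b", 1), ("y", 1)}

    def test_empty_charge_set_rejected(self):
        with pytest.raises(ValueError):
            chem.fragment_ions(ModifiedPeptide("GH"), frozenset())


class TestDigest:
    def test_single_cleavage_site(self):
        peps = chem.digest("HTVIVYPGYRK", "trypsin_p", 0)
        assert [(p.sequence, p.start, p.end) for p in peps] == [
            ("HTVIVYPGYR", 1, 10),
            ("K", 11, 11),
        ]

    def test_missed_cleavage_enumeration(self):
        peps = {p.sequence for p in chem.digest("AKRG", "trypsin_p", 1)}
        assert peps == {"AK", "R", "G", "AKR", "RG"}

    @pytest.mark.parametrize("protease,rule", [("trypsin_p", "[KR]"), ("lysc", "K")])
    def test_matches_pyteomics_cleave(self, rng, protease, rule):
        """Peptide sets agree with pyteomics.parser.cleave for 0-2 missed."""
        for _ in range(10):
            seq = random_peptide(rng, 10, 40)
            for mc in (0, 1, 2):
                ours = {p.sequence for p in chem.digest(seq, protease, mc)}
                theirs = pyt_parser.cleave(seq, rule, missed_cleavages=mc)
                assert ours == theirs

    def test_zero_missed_concatenation_reconstructs_protein(self, rng):
        for _ in range(100):
            seq = random_peptide(rng, 5, 60)
            peps = chem.digest(seq, "trypsin_p", 0)
            assert "".join(p.sequence for p in peps) == seq

    def test_cleaves_before_proline(self):
        # the /P convention: K followed by P is still cleaved
        assert {p.sequence for p in chem.digest("AKPG", "trypsin_p", 0)} == {
            "AK",
            "PG",
        }

    def test_negative_missed_rejected(self):
        with pytest.raises(ValueError):
            chem.digest("AKRG", "trypsin_p", -1)


class TestTrimSignalPeptide:
    def test_exposes_his1(self):
        assert chem.trim_signal_peptide("MKFAHTVIVYPGYR", 4) == "HTVIVYPGYR"

    def test_zero_cleavage_is_identity(self):
        assert chem.trim_signal_peptide("HTVIVYPGYR", 0) == "HTVIVYPGYR"

    def test_empty_mature_protein_rejected(self):
        with pytest.raises(ValueError):
            chem.trim_signal_peptide("AB", 2)


class TestIsotopeEnvelope:
    @staticmethod
    def _brute_force(composition, n_peaks):
        """Enumerate isotope choices atom by atom and sum probabilities."""
        atoms = [el for el, n in composition.items() for _ in range(n)]
        dist = {0: 1.0}
        for el in atoms:
            new = {}
            for offset, prob in dist.items():
                for k, (_, abund) in enumerate(chem.ISOTOPES[el]):
                    if abund:
                        new[offset + k] = new.get(offset + k, 0.0) + prob * abund
            dist = new
        return [dist.get(i, 0.0) for i in range(n_peaks)]

    def test_glycine_matches_enumeration(self):
        p = ModifiedPeptide("G")
        comp = chem.peptide_composition(p)
        expected = self._brute_force(comp, 3)
        got = [a for _, a in chem.isotope_envelope(p, 3)]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_single_peak_is_lightest_isotope_product(self):
        p = ModifiedPeptide("HTVIVYPGYR")
        comp = chem.peptide_composition(p)
        expected = 1.0
        for el, n in comp.items():
            expected *= chem.ISOTOPES[el][0][1] ** n
        [(idx, abund)] = chem.isotope_envelope(p, 1)
        assert idx == 0
        assert abund == pytest.approx(expected, rel=1e-12)

    def test_positive_and_normalized(self, rng):
        for _ in range(5):
            p = ModifiedPeptide(random_peptide(rng, 10, 40))
            env = chem.isotope_envelope(p, 5)
            abundances = [a for _, a in env]
            assert all(a > 0 for a in abundances)
            assert sum(abundances) <= 1.0 + 1e-12

    def test_methylation_included_in_composition(self):
        unmod = chem.peptide_composition(ModifiedPeptide("HAG"))
        meth = chem.peptide_composition(
            ModifiedPeptide("HAG", ((1, "methyl_his"),))
        )
        assert meth["C"] == unmod["C"] + 1
        assert meth["H"] == unmod["H"] + 2
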