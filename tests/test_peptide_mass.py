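"""Peptide mass calculus, adducts, annotation and fragment ladders.

The independent oracle for neutral masses is an atomic-composition
calculation (element counts x isotope masses) via pyteomics, which is
never used by the implementation itself.
"""

import numpy as np
import pytest
from pyteomics import mass as ptmass

from maldiprof.errors import ValidationError
from maldiprof.peptide_mass import (
    DELTA_AMIDATION,
    DELTA_PYROGLUTAMATE,
    HYDROGEN_ATOM,
    Peptide,
    adduct_mz,
    confirm_identification,
    fragment_ions,
    load_reference_table,
    match_peaks,
    neutral_monoisotopic_mass,
    parse_sequence_notation,
    ppm_error,
)


def oracle_neutral(peptide: Peptide) -> float:
    """Atomic-composition oracle for the neutral monoisotopic mass."""
    m = ptmass.calculate_mass(sequence=peptide.sequence, monoisotopic=True)
    if peptide.amidated:
        m += ptmass.calculate_mass(formula="NH2") - ptmass.calculate_mass(formula="OH")
    if peptide.pyroglutamate:
        m -= ptmass.calculate_mass(formula="NH3")
    m += peptide.n_oxidations * ptmass.calculate_mass(formula="O")
    m += peptide.n_sulfations * ptmass.calculate_mass(formula="SO3")
    return m


class TestPeptideInvariants:
    def test_invalid_residue_rejected(self):
        with pytest.raises(ValidationError):
            Peptide("GB")

    def test_pyroglutamate_requires_nterm_gln(self):
        with pytest.raises(ValidationError):
            Peptide("AQTF", pyroglutamate=True)
        Peptide("QTF", pyroglutamate=True)  # valid

    def test_oxidation_count_bounded_by_met(self):
        with pytest.raises(ValidationError):
            Peptide("AMA", n_oxidations=2)


class TestNeutralMass:
    def test_glycine_composition_oracle(self):
        # C2H5NO2
        assert neutral_monoisotopic_mass(Peptide("G")) == pytest.approx(
            75.03203, abs=1e-4
        )

    def test_diglycine_is_two_residues_plus_water(self):
        assert neutral_monoisotopic_mass(Peptide("GG")) == pytest.approx(
            132.05349, abs=1e-4
        )

    def test_all_reference_peptides_match_composition_oracle(self):
        table = load_reference_table()
        for pep in table.peptides:
            assert neutral_monoisotopic_mass(pep) == pytest.approx(
                oracle_neutral(pep), abs=1e-4
            ), pep.name

    def test_modification_deltas_against_oracle(self):
        base = Peptide("QTFMYSRG")
        for mod in (
            Peptide("QTFMYSRG", amidated=True),
            Peptide("QTFMYSRG", pyroglutamate=True),
            Peptide("QTFMYSRG", n_oxidations=1),
            Peptide("QTFMYSRG", n_sulfations=1),
        ):
            assert neutral_monoisotopic_mass(mod) == pytest.approx(
                oracle_neutral(mod), abs=1e-4
            )


class TestAdducts:
    PDF = Peptide("NSELINSLLSLPKNMNDA", amidated=True)

    def test_pdf_protonated_matches_printed_value(self):
        mz = adduct_mz(neutral_monoisotopic_mass(self.PDF), "H")
        assert round(mz, 3) == 1972.017

    def test_pdf_potassiated_matches_printed_value(self):
        mz = adduct_mz(neutral_monoisotopic_mass(self.PDF), "K")
        assert round(mz, 3) == 2009.973

    def test_pdf_sodiated_matches_printed_value(self):
        mz = adduct_mz(neutral_monoisotopic_mass(self.PDF), "Na")
        assert round(mz, 1) == 1994.0

    def test_ion_convention_subtracts_electron(self):
        atom = adduct_mz(1000.0, "H", "atom")
        ion = adduct_mz(1000.0, "H", "ion")
        assert atom - ion == pytest.approx(0.000549, abs=1e-9)

    def test_unknown_adduct_rejected(self):
        with pytest.raises(ValidationError):
            adduct_mz(1000.0, "Li")

    def test_all_printed_calc_mz_reproduced(self):
        table = load_reference_table()
        for row in table.rows.itertuples(index=False):
            pep = parse_sequence_notation(row.notation)
            calc = adduct_mz(neutral_monoisotopic_mass(pep), row.adduct)
            assert calc == pytest.approx(row.printed_calc_mz, abs=0.002), row.notation


class TestPpmError:
    def test_definition(self):
        assert ppm_error(1000.001, 1000.000) == pytest.approx(1.0)
        assert ppm_error(5.0, 5.0) == 0.0

    def test_antisymmetric_up_to_scale(self):
        a, b = 1500.01, 1500.0
        assert ppm_error(a, b) * b == pytest.approx(-ppm_error(b, a) * a)

    def test_mean_confirmed_mass_error_rounds_to_four_ppm(self):
        table = load_reference_table()
        t1 = table.rows[table.rows["table"] == "T1"]
        errors = []
        for row in t1.itertuples(index=False):
            if row.name == "PDNFMRFamide":  # convolved peak, excluded
                continue
            pep = parse_sequence_notation(row.notation)
            calc = adduct_mz(neutral_monoisotopic_mass(pep), "H")
            errors.append(abs(ppm_error(row.observed_mz, calc)))
        assert len(errors) == 13
        assert round(float(np.mean(errors))) == 4


class TestNotationParsing:
    def test_flanks_amidation_pyroglutamate(self):
        p = parse_sequence_notation("R.NSELINSLLSLPKNMNDAa.G")
        assert p.sequence == "NSELINSLLSLPKNMNDA"
        assert p.amidated and not p.pyroglutamate
        q = parse_sequence_notation("G.pQTFQYSRGWTNa.G")
        assert q.sequence == "QTFQYSRGWTN"
        assert q.amidated and q.pyroglutamate
        r = parse_sequence_notation("R.NIATMARLQSAPSTHRDPK.R")
        assert not r.amidated and not r.pyroglutamate

    def test_garbage_rejected(self):
        with pytest.raises(ValidationError):
            parse_sequence_notation("not a peptide!")


class TestMatchPeaks:
    def test_pdf_annotated_within_one_ppm(self):
        table = load_reference_table()
        anns = match_peaks([1972.015], table, adducts=("H",), tol_ppm=25)
        assert anns
        best = anns[0]
        assert best.peptide.name == "Neuropeptide PDF"
        assert abs(best.ppm_error) < 2

    def test_convolved_peak_gets_two_annotations(self):
        table = load_reference_table()
        anns = match_peaks([925.481], table, adducts=("H",), tol_ppm=60)
        names = {a.peptide.name for a in anns}
        assert any("PDNFMRF" in n for n in names)
        assert any("Drostatin-3" in n for n in names)

    def test_zero_tolerance_matches_nothing(self):
        table = load_reference_table()
        assert match_peaks([1972.015], table, tol_ppm=0) == []

    def test_sorted_by_abs_ppm(self):
        table = load_reference_table()
        anns = match_peaks([1972.015, 925.481, 1653.907], table, tol_ppm=100)
        errs = [abs(a.ppm_error) for a in anns]
        assert errs == sorted(errs)


class TestFragments:
    def test_b2_y1_of_diglycine_match_composition_oracle(self):
        ions = dict(fragment_ions(Peptide("GG"), series=("b", "y")))
        # b2 = C4H7N2O2 (both residues, no water), atom convention
        b2_oracle = ptmass.calculate_mass(formula="C4H7N2O2")
        assert ions["b2"] == pytest.approx(b2_oracle, abs=1e-3)
        # y1 = glycine + water + proton
        y1_oracle = ptmass.calculate_mass(sequence="G", monoisotopic=True) + HYDROGEN_ATOM
        assert ions["y1"] == pytest.approx(y1_oracle, abs=1e-3)

    def test_complementarity_identity_for_all_unmodified_reference_peptides(self):
        table = load_reference_table()
        for pep in table.peptides:
            bare = Peptide(pep.sequence)  # strip modifications
            ions = dict(fragment_ions(bare, series=("b", "y")))
            n = len(bare.sequence)
            if n < 2:
                continue
            mh = adduct_mz(neutral_monoisotopic_mass(bare), "H")
            assert ions[f"b{n-1}"] + ions["y1"] - HYDROGEN_ATOM == pytest.approx(
                mh, abs=1e-9
            ), pep.name

    def test_a_ions_are_b_minus_co(self):
        ions = dict(fragment_ions(Peptide("PEPTIDE"), series=("a", "b")))
        for i in range(1, 7):
            assert ions[f"a{i}"] == pytest.approx(ions[f"b{i}"] - 27.994915)

    def test_terminal_mods_assigned_to_correct_series(self):
        plain = dict(fragment_ions(Peptide("QTFQYSRGWTN")))
        mod = dict(
            fragment_ions(Peptide("QTFQYSRGWTN", amidated=True, pyroglutamate=True))
        )
        assert mod["b2"] == pytest.approx(plain["b2"] + DELTA_PYROGLUTAMATE)
        assert mod["y3"] == pytest.approx(plain["y3"] + DELTA_AMIDATION)

    def test_positional_mods_rejected(self):
        with pytest.raises(ValidationError):
            fragment_ions(Peptide("AMA", n_oxidations=1))


class TestConfirmIdentification:
    CANDIDATE = Peptide("AYRKPPFNGSIF", amidated=True)

    def test_empty_observation_not_confirmed(self):
        confirmed, matched = confirm_identification([], self.CANDIDATE)
        assert not confirmed and matched == []

    def test_three_consecutive_y_ions_confirm(self):
        ions = dict(fragment_ions(self.CANDIDATE))
        obs = [ions["y3"], ions["y4"], ions["y5"]]
        confirmed, matched = confirm_identification(obs, self.CANDIDATE, tol=0.2)
        assert confirmed
        assert {m[0] for m in matched} >= {"y3", "y4", "y5"}

    def test_gap_in_series_breaks_the_run(self):
        ions = dict(fragment_ions(self.CANDIDATE))
        obs = [ions["y3"], ions["y5"], ions["y7"]]
        confirmed, _ = confirm_identification(obs, self.CANDIDATE, tol=0.2)
        assert not confirmed

    def test_mixed_series_do_not_combine(self):
        ions = dict(fragment_ions(self.CANDIDATE))
        obs = [ions["b2"], ions["y3"], ions["y4"]]
        confirmed, _ = confirm_identification(obs, self.CANDIDATE, tol=0.2)
        assert not confirmed
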