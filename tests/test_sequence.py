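"""Sequence-level analyses: parsing, charge, pI, diagram of states, profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idpchar.properties import get_pka_set, get_scale
from idpchar.sequence import (
    InvalidSequenceError,
    charge_profile,
    composition_summary,
    das_pappu_classify,
    disorder_propensity_profile,
    extinction_coefficient_214,
    find_tm_segments,
    hydropathy_profile,
    isoelectric_point,
    min_tm_segment_length,
    net_charge,
    parse_sequence,
)

from conftest import KEIF

sequences = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30)


class TestParsing:
    def test_reference_peptide_parses(self, keif):
        assert len(keif) == 33
        assert keif.residues == KEIF

    def test_whitespace_and_case_normalized(self):
        assert parse_sequence(" m f k\n").residues == "MFK"

    def test_fasta_header_becomes_name(self):
        seq = parse_sequence(">pep1 some description\nMFK\nEIF\n")
        assert seq.name == "pep1"
        assert seq.residues == "MFKEIF"

    def test_invalid_code_reports_position(self):
        with pytest.raises(InvalidSequenceError, match="position 4"):
            parse_sequence("MFKB")

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidSequenceError):
            parse_sequence("   ")


class TestComposition:
    def test_charged_residue_counts(self, keif):
        comp = composition_summary(keif)
        assert comp.n_positive == 5
        assert comp.n_negative == 2

    def test_molecular_weight_kda(self, keif):
        mw_kda = composition_summary(keif).molecular_weight / 1000.0
        assert mw_kda == pytest.approx(3.871, abs=0.001)

    def test_single_glycine(self):
        assert composition_summary(parse_sequence("G")).molecular_weight == pytest.approx(
            75.07, abs=0.01
        )


class TestCharge:
    def test_integer_net_charge_at_physiological_ph(self, keif):
        assert net_charge(keif, 7.4, "integer") == pytest.approx(3.0)

    def test_polyglycine_only_termini_contribute(self):
        prof = charge_profile(parse_sequence("GGGGG"), 7.0, "integer")
        assert all(c == 0.0 for c in prof.per_position_charge)
        assert prof.termini_charges == (1.0, -1.0)
        assert prof.net_charge == pytest.approx(0.0)

    def test_hh_mode_matches_term_by_term_summation(self, keif):
        """Brute-force oracle: sum the 9 ionizable groups independently."""
        pka = get_pka_set()
        pH = 7.0
        pos = lambda pk: 1.0 / (1.0 + 10.0 ** (pH - pk))
        neg = lambda pk: -1.0 / (1.0 + 10.0 ** (pk - pH))
        expected = pos(pka.nterm_pka("M")) + neg(pka.cterm_default)
        for aa in KEIF:
            if aa in "KRH":
                expected += pos(pka.sidechain[aa])
            elif aa in "DE":
                expected += neg(pka.sidechain[aa])
        assert net_charge(keif, pH, "henderson_hasselbalch") == pytest.approx(
            expected, abs=1e-12
        )

    def test_hh_net_charge_near_neutral_ph(self, keif):
        # the N-terminal Met amine (pKa 7.00) is half-titrated here, so the
        # HH value sits visibly below the integer-convention +3
        assert net_charge(keif, 7.4, "henderson_hasselbalch") == pytest.approx(
            2.357, abs=0.01
        )

    def test_ph_out_of_range(self, keif):
        with pytest.raises(ValueError):
            charge_profile(keif, pH=15.0)

    @settings(max_examples=40, derandomize=True)
    @given(seq=sequences, ph_pair=st.tuples(
        st.floats(0.0, 14.0), st.floats(0.0, 14.0)))
    def test_net_charge_monotone_in_ph(self, seq, ph_pair):
        lo, hi = sorted(ph_pair)
        s = parse_sequence(seq)
        assert net_charge(s, lo, "henderson_hasselbalch") >= net_charge(
            s, hi, "henderson_hasselbalch"
        ) - 1e-9


class TestIsoelectricPoint:
    def test_reference_peptide_pi(self, keif):
        assert isoelectric_point(keif) == pytest.approx(11.54, abs=0.005)

    def test_against_independent_calculator(self, keif):
        from Bio.SeqUtils.ProtParam import ProteinAnalysis

        assert isoelectric_point(keif) == pytest.approx(
            ProteinAnalysis(KEIF).isoelectric_point(), abs=0.01
        )

    def test_sign_ordering(self):
        assert isoelectric_point(parse_sequence("KK")) > 7 > isoelectric_point(
            parse_sequence("DD")
        )

    def test_fixed_point_definition(self, keif):
        pi = isoelectric_point(keif, decimals=6)
        assert abs(net_charge(keif, pi, "henderson_hasselbalch")) < 1e-3


class TestDasPappu:
    def test_reference_peptide_is_weak_polyampholyte(self, keif):
        res = das_pappu_classify(keif)
        assert res.f_plus == pytest.approx(5 / 33)
        assert res.f_minus == pytest.approx(2 / 33)
        assert res.region == "R1"

    def test_strong_polyelectrolyte_corner(self):
        res = das_pappu_classify(parse_sequence("E" * 30))
        assert res.f_minus == pytest.approx(1.0)
        assert res.region == "R4"

    def test_strong_polyampholyte(self):
        # f+ = f- = 0.3 -> FCR 0.6, NCPR 0 -> R3 by the threshold rules
        res = das_pappu_classify(parse_sequence("KKKDDDGGGG"))
        assert res.FCR == pytest.approx(0.6)
        assert res.NCPR == pytest.approx(0.0)
        assert res.region == "R3"

    @settings(max_examples=40, derandomize=True)
    @given(seq=sequences)
    def test_fraction_identities(self, seq):
        res = das_pappu_classify(parse_sequence(seq))
        assert res.FCR == pytest.approx(res.f_plus + res.f_minus)
        assert res.NCPR == pytest.approx(res.f_plus - res.f_minus)
        assert 0.0 <= res.FCR <= 1.0
        assert abs(res.NCPR) <= res.FCR + 1e-12


class TestDisorderProfile:
    def test_profile_covers_sequence(self, keif):
        prof = disorder_propensity_profile(keif)
        assert len(prof) == 33
        assert all(prof.defined)

    def test_cterminal_disorder_cluster(self, keif):
        """Residues 24-28 (Pro-24..Gln-28, 1-based) are disorder-promoting."""
        prof = disorder_propensity_profile(keif).as_array()
        assert prof[23:28].mean() > 0

    def test_polytryptophan_uniformly_order_promoting(self):
        prof = disorder_propensity_profile(parse_sequence("W" * 10))
        assert all(v < 0 for v in prof.values)


class TestHydropathy:
    def test_constant_sequence_gives_constant_profile(self):
        prof = hydropathy_profile(parse_sequence("L" * 9), window=5)
        val = get_scale("ww_octanol", "charged")["L"]
        defined = prof.as_array()[2:-2]
        assert np.allclose(defined, val)
        assert np.isnan(prof.values[0]) and np.isnan(prof.values[-1])

    def test_interior_value_is_window_mean(self, keif):
        table = get_scale("ww_octanol", "charged")
        prof = hydropathy_profile(keif, window=5)
        for center in (5, 16, 28):
            expected = np.mean([table[KEIF[i]] for i in range(center - 2, center + 3)])
            assert prof.values[center] == pytest.approx(expected)

    @settings(max_examples=30, derandomize=True)
    @given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=5, max_size=30))
    def test_profile_commutes_with_reversal(self, seq):
        fwd = hydropathy_profile(parse_sequence(seq)).as_array()
        rev = hydropathy_profile(parse_sequence(seq[::-1])).as_array()
        np.testing.assert_allclose(fwd, rev[::-1])

    def test_window_validation(self, keif):
        with pytest.raises(ValueError):
            hydropathy_profile(keif, window=4)
        with pytest.raises(ValueError):
            hydropathy_profile(parse_sequence("MFK"), window=5)


class TestTransmembrane:
    @pytest.mark.parametrize(
        "thickness,rise,expected", [(30.0, 1.5, 20), (30.0, 3.3, 9), (0.0, 1.5, 0)]
    )
    def test_min_segment_length(self, thickness, rise, expected):
        assert min_tm_segment_length(thickness, rise) == expected

    def test_nonpositive_rise_rejected(self):
        with pytest.raises(ValueError):
            min_tm_segment_length(30.0, 0.0)

    def test_reference_peptide_has_no_tm_segment(self, keif):
        prof = hydropathy_profile(keif)
        assert find_tm_segments(prof, min_length=min_tm_segment_length()) == []

    def test_polyleucine_spans_all_defined_positions(self):
        prof = hydropathy_profile(parse_sequence("L" * 30))
        segs = find_tm_segments(prof, min_length=20)
        assert segs == [(2, 28)]

    def test_nineteen_residue_stretch_below_helix_minimum(self):
        seq = parse_sequence("K" * 5 + "L" * 19 + "K" * 5)
        prof = hydropathy_profile(seq)
        assert find_tm_segments(prof, min_length=20) == []
        # sanity: the stretch is found once the length requirement drops
        assert find_tm_segments(prof, min_length=15) != []


def test_extinction_coefficient_matches_hand_sum(keif):
    scale = get_scale("epsilon214")
    expected = 32 * scale.extras["PEPTIDE_BOND"] + sum(scale[aa] for aa in KEIF)
    assert extinction_coefficient_214(keif) == pytest.approx(expected)


def test_extinction_coefficient_nterminal_proline():
    scale = get_scale("epsilon214")
    val = extinction_coefficient_214(parse_sequence("PG"))
    assert val == pytest.approx(scale.extras["PEPTIDE_BOND"] + scale.extras["P_NTERM"])
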