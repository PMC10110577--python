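"""Composition building, natural distributions, and labeled dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import binom

from isoturn import (
    DEFAULT_P_H,
    b_coefficient,
    c_coefficient,
    composition_from_sequence,
    labeled_isotopomer_rias,
    natural_isotope_distribution,
    oracle_labeled_distribution,
)
from isoturn.chem import IsotopomerVector, LabelingParameters, PeptideComposition

from conftest import brute_force_distribution


class TestComposition:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("G", {"C": 2, "H": 5, "N": 1, "O": 2}),
            ("GG", {"C": 4, "H": 8, "N": 2, "O": 3}),
        ],
    )
    def test_residue_formulas_plus_water(self, seq, expected):
        comp = composition_from_sequence(seq)
        assert {k: v for k, v in comp.element_counts.items() if v} == expected

    def test_neh_is_additive(self, neh_table):
        g = neh_table["G"]
        comp = composition_from_sequence("GG")
        assert comp.n_exchangeable == pytest.approx(2 * g)

    def test_concatenation_adds_residues_and_one_water(self):
        a = composition_from_sequence("ACDK")
        b = composition_from_sequence("MNPQ")
        ab = composition_from_sequence("ACDKMNPQ")
        for el in "CHNOS":
            expected = a.element_counts.get(el, 0) + b.element_counts.get(el, 0)
            if el == "H":
                expected -= 2
            if el == "O":
                expected -= 1
            assert ab.element_counts.get(el, 0) == expected
        assert ab.n_exchangeable == pytest.approx(
            a.n_exchangeable + b.n_exchangeable
        )

    def test_unknown_residue_named_with_position(self):
        with pytest.raises(ValueError, match=r"'B' at position 2"):
            composition_from_sequence("GGBG")

    def test_exchangeable_cannot_exceed_hydrogens(self):
        with pytest.raises(ValueError, match="exceeds hydrogen"):
            PeptideComposition("G", 1, {"C": 2, "H": 5, "N": 1, "O": 2}, 6.0)

    def test_labeling_parameters_ordering(self):
        with pytest.raises(ValueError):
            LabelingParameters(p_w=0.00005, p_h=DEFAULT_P_H)
        with pytest.raises(ValueError):
            LabelingParameters(p_w=0.046, time_points=(0.0, 3.0, 1.0))


class TestNaturalDistribution:
    def test_single_hydrogen(self, elements):
        comp = PeptideComposition("G", 1, {"H": 1}, 0.0)
        dist = natural_isotope_distribution(comp, elements=elements)
        assert dist[0] == pytest.approx(1 - DEFAULT_P_H)
        assert dist[1] == pytest.approx(DEFAULT_P_H)

    def test_empty_composition_is_identity(self, elements):
        comp = PeptideComposition("G", 1, {}, 0.0)
        dist = natural_isotope_distribution(comp, elements=elements)
        assert dist.values == pytest.approx([1, 0, 0, 0, 0, 0])

    def test_matches_exhaustive_enumeration_for_gg(self, elements):
        comp = composition_from_sequence("GG")
        dist = natural_isotope_distribution(comp, elements=elements)
        brute = brute_force_distribution(comp.element_counts, elements)
        assert np.max(np.abs(dist.values - brute)) < 1e-12


class TestCoefficients:
    def test_b_zero_enrichment_zero_natural(self):
        assert b_coefficient(1, 4.0, 0.0, 0.0) == 0.0

    def test_b_direct_substitution(self):
        p = 0.03
        assert b_coefficient(1, 1.0, p, 0.0) == pytest.approx(p / (1 - p))

    def test_b_hand_evaluation(self):
        expected = 45.0 * (0.020115 / 0.979885) ** 2
        assert b_coefficient(2, 10.0, 0.02, 0.000115) == pytest.approx(
            expected, rel=1e-12
        )

    def test_b_rejects_unphysical_domain(self):
        with pytest.raises(ValueError):
            b_coefficient(1, 4.0, 0.7, 0.4)

    def test_c_zero_natural_abundance(self):
        assert c_coefficient(1, 7.0, 0.0) == 0.0

    def test_c_direct_substitution(self):
        p_h = DEFAULT_P_H
        assert c_coefficient(1, 1.0, p_h) == pytest.approx(p_h / (1 - p_h))

    def test_c_hand_evaluation(self):
        p_h = DEFAULT_P_H
        expected = binom(7, 3) * (p_h / (1 - p_h)) ** 3
        assert c_coefficient(3, 5.0, p_h) == pytest.approx(expected, rel=1e-12)


class TestLabeledDynamics:
    def test_zero_enrichment_returns_natural(self, exemplar_natural, exemplar):
        out = labeled_isotopomer_rias(
            exemplar_natural, 0.0, exemplar.n_exchangeable
        )
        assert out.values == pytest.approx(exemplar_natural.values, abs=1e-15)

    def test_single_site_monoisotope_depletion(self, exemplar_natural):
        p_x = 0.02
        out = labeled_isotopomer_rias(exemplar_natural, p_x, 1.0)
        expected = exemplar_natural[0] * (1 - p_x / (1 - DEFAULT_P_H))
        assert out[0] == pytest.approx(expected, rel=1e-12)

    def test_matches_convolution_oracle(self, small_peptide):
        nat = natural_isotope_distribution(small_peptide)
        for p_x in [0.005, 0.02, 0.046]:
            ana = labeled_isotopomer_rias(nat, p_x, 10.0)
            orc = oracle_labeled_distribution(small_peptide, p_x)
            assert np.max(np.abs(ana.values - orc.values)) < 1e-9

    def test_oracle_refuses_fractional_sites(self, exemplar):
        with pytest.raises(ValueError, match="integer N_EH"):
            oracle_labeled_distribution(exemplar, 0.02)

    def test_oracle_two_exchangeable_hydrogens_binomial(self, elements):
        comp = PeptideComposition("G", 1, {"H": 2}, 2.0)
        p_x = 0.3
        out = oracle_labeled_distribution(comp, p_x, p_h=0.0, elements=elements)
        assert out.values[:3] == pytest.approx(
            [(1 - p_x) ** 2, 2 * p_x * (1 - p_x), p_x**2]
        )

    def test_oracle_matches_exhaustive_enumeration(self, elements, small_peptide):
        p_x = 0.03
        orc = oracle_labeled_distribution(small_peptide, p_x, elements=elements)
        brute = brute_force_distribution(
            small_peptide.element_counts, elements,
            n_heavy_sites=10, p_extra=p_x,
        )
        assert np.max(np.abs(orc.values - brute)) < 1e-12

    @settings(max_examples=25, deadline=None)
    @given(
        n_c=st.integers(5, 60),
        n_h=st.integers(20, 100),
        n_eh=st.integers(1, 19),
        n_s=st.integers(0, 2),
        p_x=st.floats(0.0, 0.06),
    )
    def test_oracle_equivalence_property(self, elements, n_c, n_h, n_eh, n_s, p_x):
        """Analytic dynamics equal first-principles convolution everywhere."""
        counts = {"C": n_c, "H": n_h, "N": max(n_c // 4, 1), "O": n_c // 2, "S": n_s}
        comp = PeptideComposition("G", 1, counts, float(n_eh))
        nat = natural_isotope_distribution(comp, elements=elements)
        ana = labeled_isotopomer_rias(nat, p_x, float(n_eh))
        orc = oracle_labeled_distribution(comp, p_x, elements=elements)
        assert np.max(np.abs(ana.values - orc.values)) < 1e-9

    def test_six_peak_truncation_coverage(self, elements, neh_table):
        # tryptic-scale peptides below ~1800 Da keep >= 99% of the natural
        # distribution within six isotopomers; at 5% enrichment the labeled
        # distribution spreads with N_EH, so >= 99% holds for peptides with
        # few exchangeable sites while heavily exchangeable ones shed a few
        # percent into the tail (compensated downstream by the
        # truncation-corrected full-profile inversion)
        for seq in ["GTTITSVLPKPALVASR", "SYELPDGQVITIGNER", "LVEALCAEHQINLIK"]:
            comp = composition_from_sequence(seq, 2, neh_table)
            nat = natural_isotope_distribution(comp, elements=elements)
            assert nat.values.sum() >= 0.99
        small = composition_from_sequence("GTTITSVLPK", 2, neh_table)
        nat = natural_isotope_distribution(small, elements=elements)
        lab = labeled_isotopomer_rias(nat, 0.05, small.n_exchangeable)
        assert lab.values.sum() >= 0.99
        big = composition_from_sequence("SYELPDGQVITIGNER", 2, neh_table)
        nat_b = natural_isotope_distribution(big, elements=elements)
        lab_b = labeled_isotopomer_rias(nat_b, 0.05, big.n_exchangeable)
        assert lab_b.values.sum() < lab.values.sum()  # tail grows with N_EH

    def test_monoisotope_strictly_decreasing_in_enrichment(self, exemplar, exemplar_natural):
        grid = np.linspace(0.0, 0.046, 30)
        i0 = [
            labeled_isotopomer_rias(exemplar_natural, p, exemplar.n_exchangeable)[0]
            for p in grid
        ]
        assert np.all(np.diff(i0) < 0)

    def test_first_ratios_strictly_increasing_in_enrichment(self, exemplar, exemplar_natural):
        grid = np.linspace(0.0, 0.046, 30)
        r10, r20 = [], []
        for p in grid:
            v = labeled_isotopomer_rias(exemplar_natural, p, exemplar.n_exchangeable)
            r10.append(v[1] / v[0])
            r20.append(v[2] / v[0])
        assert np.all(np.diff(r10) > 0)
        assert np.all(np.diff(r20) > 0)

    def test_continuity_at_zero_enrichment(self, exemplar, exemplar_natural):
        out = labeled_isotopomer_rias(
            exemplar_natural, 1e-12, exemplar.n_exchangeable
        )
        assert np.max(np.abs(out.values - exemplar_natural.values)) < 1e-9

    def test_vector_invariants(self):
        with pytest.raises(ValueError):
            IsotopomerVector(np.array([0.5, 0.7, 0, 0, 0, 0]), normalized=True)
        with pytest.raises(ValueError):
            IsotopomerVector(np.array([-0.1, 0.7, 0, 0, 0, 0]))
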