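"""Mass, buoyancy and concentration arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sedstoich import (
    BufferState,
    Component,
    Composition,
    InvalidInputError,
    buoyant_factor,
    composite_vbar,
    concentration_from_absorbance,
    molar_mass_from_sequence,
    vbar_percent_difference,
)


def comp(name, mass, vbar):
    return Component(name, mass, vbar, {}, "protein")


class TestCompositeVbar:
    def test_single_component_identity(self):
        c = comp("RecO", 27_000.0, 0.734)
        assert composite_vbar(Composition([(c, 1)])) == pytest.approx(0.734)
        assert composite_vbar(Composition([(c, 3)])) == pytest.approx(0.734)

    def test_equal_masses_give_arithmetic_mean(self):
        a = comp("a", 10_000.0, 0.734)
        b = comp("b", 10_000.0, 0.56)
        result = composite_vbar(Composition([(a, 1), (b, 1)]))
        assert result == pytest.approx(0.647, abs=1e-12)

    def test_protein_peptide_dna_complex(self):
        # hand-summed mass weights: (27000*0.734 + 1740*0.704 + 5100*0.56)
        # / 33840 = 0.70623
        entries = [
            (comp("RecO", 27_000.0, 0.734), 1),
            (comp("SSB-Ct", 1_740.0, 0.704), 1),
            (comp("Cy3-dT15", 5_100.0, 0.56), 1),
        ]
        assert composite_vbar(Composition(entries)) == pytest.approx(
            0.70623, abs=5e-4
        )

    def test_empty_composition_rejected(self):
        c = comp("x", 1000.0, 0.7)
        with pytest.raises(InvalidInputError):
            Composition([])
        with pytest.raises(InvalidInputError):
            Composition([(c, 0)])

    @given(
        data=st.lists(
            st.tuples(
                st.floats(1e3, 1e6),
                st.floats(0.45, 0.95),
                st.integers(1, 5),
            ),
            min_size=1,
            max_size=5,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_permutation_invariant(self, data):
        entries = [
            (comp(f"c{i}", m, v), n) for i, (m, v, n) in enumerate(data)
        ]
        value = composite_vbar(Composition(entries))
        vbars = [c.vbar for c, _ in entries]
        assert min(vbars) - 1e-12 <= value <= max(vbars) + 1e-12
        reversed_value = composite_vbar(Composition(entries[::-1]))
        assert value == pytest.approx(reversed_value, rel=1e-12)


class TestBuoyantFactor:
    def test_neutral_buoyancy_is_zero(self):
        assert buoyant_factor(50_000.0, 1.0 / 1.05, 1.05) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_arithmetic(self):
        assert buoyant_factor(1000.0, 0.5, 1.0) == pytest.approx(500.0)
        # 33800 * (1 - 0.706*1.05) = 8744.06
        assert buoyant_factor(33_800.0, 0.706, 1.05) == pytest.approx(
            8744.06, rel=1e-6
        )

    @given(
        m=st.floats(1e3, 1e6),
        v1=st.floats(0.45, 0.9),
        v2=st.floats(0.45, 0.9),
        rho=st.floats(0.95, 1.25),
    )
    @settings(max_examples=50, deadline=None)
    def test_linear_in_mass_and_decreasing_in_vbar(self, m, v1, v2, rho):
        assert buoyant_factor(2 * m, v1, rho) == pytest.approx(
            2 * buoyant_factor(m, v1, rho), rel=1e-12
        )
        lo, hi = sorted((v1, v2))
        if hi - lo > 1e-9:
            assert buoyant_factor(m, hi, rho) < buoyant_factor(m, lo, rho)


class TestVbarPercentDifference:
    @pytest.mark.parametrize(
        "measured, calculated, expected",
        [(0.734, 0.743, 1.2), (0.711, 0.731, 2.7), (0.7, 0.7, 0.0)],
    )
    def test_reported_percent_differences(self, measured, calculated, expected):
        assert vbar_percent_difference(measured, calculated) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(InvalidInputError):
            vbar_percent_difference(0.7, 0.0)


class TestSequenceMasses:
    def test_ssb_ct_peptide_mass(self):
        # independent hand summation over the documented average-mass table:
        # P+S+N+E+P+P+M+D+F+D+D+D+I+P+F = 1717.85, + H2O = 1735.87
        mass = molar_mass_from_sequence("PSNEPPMDFDDDIPF", "peptide")
        assert mass == pytest.approx(1735.87, abs=0.05)

    def test_cy3_dt15_mass(self):
        # 15 * 304.20 - 61.96 + 507.66 = 5008.70 by hand
        mass = molar_mass_from_sequence("T" * 15, "ssDNA", adducts=["Cy3"])
        assert mass == pytest.approx(5008.70, abs=0.05)
        assert mass == pytest.approx(5.1e3, rel=0.03)  # ~5.1 kDa labelled oligo

    def test_empty_and_bad_residue_rejected(self):
        with pytest.raises(InvalidInputError):
            molar_mass_from_sequence("", "peptide")
        with pytest.raises(InvalidInputError, match="Z"):
            molar_mass_from_sequence("PSZ", "peptide")
        with pytest.raises(InvalidInputError):
            molar_mass_from_sequence("TTT", "protein")

    @given(
        a=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=12),
        b=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=12),
    )
    @settings(max_examples=40, deadline=None)
    def test_additive_under_concatenation(self, a, b):
        # one terminal water is double-counted when chains are summed apart
        m_ab = molar_mass_from_sequence(a + b, "peptide")
        m_a = molar_mass_from_sequence(a, "peptide")
        m_b = molar_mass_from_sequence(b, "peptide")
        assert m_ab == pytest.approx(m_a + m_b - 18.02, abs=1e-9)


class TestBeerLambert:
    @pytest.mark.parametrize(
        "a, eps, path, expected",
        [
            (0.39, 390.0, 1.0, 1.0e-3),
            (0.0, 1e4, 1.2, 0.0),
            (0.244, 2.44e4, 1.2, 8.333e-6),
        ],
    )
    def test_concentration(self, a, eps, path, expected):
        assert concentration_from_absorbance(a, eps, path) == pytest.approx(
            expected, rel=1e-3
        )

    def test_negative_absorbance_rejected(self):
        with pytest.raises(InvalidInputError):
            concentration_from_absorbance(-0.1, 1e4, 1.2)


class TestDomainValidation:
    def test_component_invariants(self):
        with pytest.raises(InvalidInputError):
            Component("x", -5.0, 0.7)
        with pytest.raises(InvalidInputError):
            Component("x", 1e4, 1.2)
        with pytest.raises(InvalidInputError):
            Component("x", 1e4, 0.7, {280.0: -3.0})

    def test_buffer_invariants(self):
        with pytest.raises(InvalidInputError):
            BufferState(density=2.0)
        with pytest.raises(InvalidInputError):
            BufferState(viscosity=-1.0)
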