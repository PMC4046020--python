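"""Unit and property tests of the algebraic regulatory kernels."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemosim.regulation import (
    DEFAULT_GCSF_ON_CE,
    FILGRASTIM_CE_TRANSITION,
    PEGFILGRASTIM_CE_TRANSITION,
    ProliferativeFractionParams,
    RegulationParams,
    StemRegulationParams,
    bone_marrow_log_content,
    gcsf_erythroid_amplification_factor,
    gcsf_erythroid_transition_factor,
    proliferative_fraction,
    proliferative_fraction_from_x,
    receptor_competition_weight,
    self_renewal_probability,
    sigmoid_regulator,
)


@st.composite
def regulation_params(draw):
    """Random valid sigmoid regulators, either orientation."""
    a = draw(st.floats(0.01, 10.0))
    gap1 = draw(st.floats(0.01, 10.0))
    gap2 = draw(st.floats(0.01, 10.0))
    b = draw(st.floats(0.05, 5.0))
    increasing = draw(st.booleans())
    levels = (a, a + gap1, a + gap1 + gap2)
    if not increasing:
        levels = levels[::-1]
    return RegulationParams(y_min=levels[0], y_nor=levels[1], y_max=levels[2], b=b)


class TestSigmoidRegulator:
    @settings(deadline=None, max_examples=80)
    @given(regulation_params())
    def test_normalisation_at_unit_concentration(self, params):
        assert sigmoid_regulator(1.0, params) == pytest.approx(params.y_nor, rel=1e-12)

    @settings(deadline=None, max_examples=80)
    @given(regulation_params())
    def test_zero_concentration_gives_minimum(self, params):
        assert sigmoid_regulator(0.0, params) == pytest.approx(params.y_min, rel=1e-12)

    @settings(deadline=None, max_examples=80)
    @given(regulation_params(), st.floats(0.0, 50.0), st.floats(0.001, 10.0))
    def test_monotone_and_bounded(self, params, c, dc):
        lo, hi = sorted((params.y_min, params.y_max))
        y1, y2 = sigmoid_regulator(c, params), sigmoid_regulator(c + dc, params)
        eps = 1e-9 * (1.0 + abs(hi))  # floating rounding at the asymptotes
        assert lo - eps <= y1 <= hi + eps and lo - eps <= y2 <= hi + eps
        if params.y_min < params.y_max:
            assert y2 >= y1
        else:
            assert y2 <= y1

    def test_pegfilgrastim_normal_transition_factor(self):
        assert sigmoid_regulator(1.0, PEGFILGRASTIM_CE_TRANSITION) == pytest.approx(1.037)

    def test_filgrastim_asymptote(self):
        assert sigmoid_regulator(1e8, FILGRASTIM_CE_TRANSITION) == pytest.approx(
            98.37, rel=1e-3
        )

    def test_constant_branch_returns_normal_value(self):
        const = RegulationParams(2.0, 2.0, 2.0)
        for c in (0.0, 0.5, 1.0, 100.0):
            assert sigmoid_regulator(c, const) == 2.0

    @pytest.mark.parametrize(
        "levels", [(1.0, 3.0, 2.0), (2.0, 1.0, 3.0), (1.0, 1.0, 2.0)]
    )
    def test_invalid_level_ordering_rejected(self, levels):
        with pytest.raises(ValueError):
            RegulationParams(*levels)

    def test_negative_sensitivity_rejected(self):
        with pytest.raises(ValueError):
            RegulationParams(1.0, 2.0, 3.0, b=-1.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            sigmoid_regulator(-0.1, RegulationParams(1.0, 2.0, 3.0))


class TestSelfRenewal:
    def test_homeostatic_probability_is_half(self):
        p = self_renewal_probability(1.0, 1.0, 1.0, StemRegulationParams())
        assert p == 0.5

    def test_depleted_stem_pool_raises_probability(self):
        params = StemRegulationParams()
        p = self_renewal_probability(0.5, 1.0, 1.0, params)
        expected = 0.5 + params.p_delta * math.tanh(2.0 * 0.5**0.6 * 0.5)
        assert p == pytest.approx(expected, rel=1e-12)

    def test_granulopoietic_aplasia_limit(self):
        params = StemRegulationParams()
        p = self_renewal_probability(1.0, 1.0, 1e-12, params)
        # theta_G = -8: the argument tends to -8, tanh(-8) ~ -1
        assert p == pytest.approx(0.5 - params.p_delta * math.tanh(8.0), rel=1e-9)
        assert p > 0.5 - params.p_delta

    @settings(deadline=None, max_examples=80)
    @given(
        st.floats(0.01, 10.0), st.floats(0.01, 10.0), st.floats(0.01, 10.0),
        st.floats(0.01, 0.49),
    )
    def test_probability_bounded_by_half_range(self, cs, ce, cg, p_delta):
        params = StemRegulationParams(p_delta=p_delta)
        p = self_renewal_probability(cs, ce, cg, params)
        assert 0.5 - p_delta <= p <= 0.5 + p_delta

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(ValueError):
            self_renewal_probability(0.0, 1.0, 1.0, StemRegulationParams())

    def test_invalid_half_range_rejected(self):
        with pytest.raises(ValueError):
            StemRegulationParams(p_delta=0.6)


class TestProliferativeFraction:
    params = ProliferativeFractionParams(0.1, 0.25, 0.4, 0.9)

    def test_normal_marrow_gives_a_nor(self):
        a = proliferative_fraction(1.0, 1.0, 1.0, self.params)
        assert a == pytest.approx(self.params.a_nor, rel=1e-12)

    def test_intermediate_anchor_at_minus_log_two(self):
        a = proliferative_fraction_from_x(-math.log(2.0), self.params)
        assert a == pytest.approx(self.params.a_int, rel=1e-12)

    def test_empty_marrow_limit_is_a_max(self):
        assert proliferative_fraction_from_x(-60.0, self.params) == pytest.approx(
            self.params.a_max, rel=1e-9
        )

    @settings(deadline=None, max_examples=60)
    @given(st.floats(-20.0, 20.0), st.floats(0.001, 5.0))
    def test_monotone_non_increasing_in_x(self, x, dx):
        assert proliferative_fraction_from_x(
            x + dx, self.params
        ) <= proliferative_fraction_from_x(x, self.params) + 1e-12

    def test_stem_term_switches_from_log_to_linear(self):
        # continuous at cs_rel = 1 and linear above
        below = bone_marrow_log_content(0.999, 1.0, 1.0, self.params)
        above = bone_marrow_log_content(1.001, 1.0, 1.0, self.params)
        assert below == pytest.approx(math.log(0.999), abs=1e-12)
        assert above == pytest.approx(0.001, abs=1e-12)

    def test_constant_branch(self):
        const = ProliferativeFractionParams(0.3, 0.3, 0.3, 0.3)
        assert proliferative_fraction(0.2, 5.0, 0.7, const) == 0.3

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            ProliferativeFractionParams(0.5, 0.25, 0.4, 0.9)


class TestGcsfOnCe:
    def test_pure_filgrastim_at_normal_concentration(self):
        assert gcsf_erythroid_transition_factor(1.0, 0.0, w_p=0.0) == pytest.approx(1.0)

    def test_pure_pegfilgrastim_at_normal_concentration(self):
        assert gcsf_erythroid_transition_factor(0.0, 1.0, w_p=1.0) == pytest.approx(1.037)

    def test_equal_weighting_is_convex_combination(self):
        f = gcsf_erythroid_transition_factor(1.0, 1.0, w_p=0.5)
        assert f == pytest.approx((1.0 + 1.037) / 2.0, rel=1e-12)

    def test_pegfilgrastim_asymptote(self):
        f = gcsf_erythroid_transition_factor(0.0, 1e6, w_p=1.0)
        assert f == pytest.approx(2.787, rel=1e-3)

    def test_weight_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            gcsf_erythroid_transition_factor(1.0, 1.0, w_p=1.2)

    @settings(deadline=None, max_examples=40)
    @given(st.floats(0.0, 1e4), st.floats(0.0, 1e4), st.floats(0.0, 1.0))
    def test_amplification_factor_is_identically_one(self, c_fil, c_peg, w_p):
        assert gcsf_erythroid_amplification_factor(c_fil, c_peg, w_p) == 1.0

    def test_receptor_weight_is_pegfilgrastim_share(self):
        assert receptor_competition_weight(0.0, 0.0) == 0.0
        assert receptor_competition_weight(1.0, 1.0) == 0.5
        assert receptor_competition_weight(0.0, 3.0) == 1.0
        assert receptor_competition_weight(3.0, 1.0) == pytest.approx(0.25)

    def test_default_parameters_match_fitted_table(self):
        fil = DEFAULT_GCSF_ON_CE.filgrastim
        peg = DEFAULT_GCSF_ON_CE.pegfilgrastim
        assert (fil.y_min, fil.y_nor, fil.y_max, fil.b) == (0.9995, 1.0, 98.37, 0.930)
        assert (peg.y_min, peg.y_nor, peg.y_max, peg.b) == (1.0, 1.037, 2.787, 0.5660)
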