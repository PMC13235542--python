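"""δ15N arithmetic: fractionation, Rayleigh evolution, mixing, mass balance."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from cavenit.isotopes import (
    DegenerateEndmemberError,
    InfeasibleBalanceError,
    apply_fractionation,
    mix,
    mixing_fraction,
    rayleigh_remaining,
    trn_mass_balance,
    volatilization_chain,
)
from cavenit.samples import DomainError, FractionationSet

deltas = st.floats(-60.0, 60.0)
epsilons = st.floats(-50.0, 50.0)


class TestApplyFractionation:
    def test_stream_to_ammonia_prediction(self):
        # +3.3 permil stream ammonium, 30 permil equilibrium effect
        assert apply_fractionation(3.3, 30.0, "linear") == pytest.approx(-26.7)

    @pytest.mark.parametrize("mode", ["linear", "exact"])
    def test_zero_epsilon_identity(self, mode):
        assert apply_fractionation(3.3, 0.0, mode) == 3.3

    def test_exact_mode_hand_value(self):
        assert apply_fractionation(3.3, 30.0, "exact") == pytest.approx(
            1003.3 / 1.030 - 1000.0, rel=1e-12
        )

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(DomainError):
            apply_fractionation(0.0, -1000.0, "exact")

    @given(d=deltas, e=epsilons)
    @settings(max_examples=60, deadline=None)
    def test_modes_agree_to_first_order(self, d, e):
        # closed-form difference: eps*(eps - delta)/(1000*alpha)
        lin = apply_fractionation(d, e, "linear")
        exact = apply_fractionation(d, e, "exact")
        alpha = 1.0 + e / 1000.0
        assert abs(lin - exact) <= abs(e * (e - d)) / (1000.0 * alpha) + 1e-9

    @given(d=deltas, e=st.floats(0.1, 50.0))
    @settings(max_examples=40, deadline=None)
    def test_product_depleted_for_positive_epsilon(self, d, e):
        assert apply_fractionation(d, e, "linear") < d
        assert apply_fractionation(d, e, "exact") < d


class TestVolatilizationChain:
    def test_total_depletion_rounds_to_38(self, chain_defaults):
        chain = volatilization_chain(3.3, chain_defaults)
        assert chain.total_depletion_permil == pytest.approx(38.3)
        assert round(chain.total_depletion_permil) == 38
        assert chain.d15N_nh3_aq == pytest.approx(-26.7)

    def test_all_zero_epsilons_preserve_delta(self):
        fs = FractionationSet(0.0, 0.0, 0.0, 0.0)
        chain = volatilization_chain(3.3, fs)
        assert set(chain.as_dict().values()) == {3.3}

    def test_experimental_epsilon_set_sequential_oracle(self):
        # 32 then 8 permil, applied by sequential subtraction
        fs = FractionationSet(32.0, 8.0, 0.0, 0.0)
        chain = volatilization_chain(3.3, fs)
        assert chain.d15N_nh3_aq == pytest.approx(3.3 - 32.0)
        assert chain.d15N_nh3_g == pytest.approx(3.3 - 32.0 - 8.0)
        assert chain.d15N_nh4_trapped == pytest.approx(chain.d15N_nh3_g)

    @given(d=deltas, a=epsilons, b=epsilons, c=epsilons)
    @settings(max_examples=60, deadline=None)
    def test_linear_chain_is_order_independent(self, d, a, b, c):
        fwd = volatilization_chain(d, FractionationSet(a, b, c, 0.0))
        rev = volatilization_chain(d, FractionationSet(c, b, a, 0.0))
        assert fwd.d15N_nh4_trapped == pytest.approx(rev.d15N_nh4_trapped, abs=1e-9)
        assert fwd.total_depletion_permil == pytest.approx(a + b + c, abs=1e-9)

    def test_exact_chain_composes_alphas(self):
        # sequential exact steps are equivalent to one step with the
        # product of the alphas (hence commutative as well)
        fs = FractionationSet(30.0, 5.0, 0.0, 0.0, "exact")
        chain = volatilization_chain(10.0, fs)
        alpha_net = 1.030 * 1.005
        assert chain.d15N_nh4_trapped == pytest.approx(
            (10.0 + 1000.0) / alpha_net - 1000.0, rel=1e-12
        )


class TestRayleigh:
    def test_no_removal_identity(self):
        assert rayleigh_remaining(3.3, 38.3, 1.0) == 3.3

    def test_one_percent_removal_hand_value(self):
        got = rayleigh_remaining(3.3, 38.3, 0.99)
        assert got == pytest.approx(3.3 + 38.3 * (-math.log(0.99)), rel=1e-12)
        assert got == pytest.approx(3.684927863, rel=1e-9)

    def test_zero_epsilon_flat(self):
        for f in (0.01, 0.5, 1.0):
            assert rayleigh_remaining(3.3, 0.0, f) == 3.3

    @given(f=st.floats(0.01, 0.99))
    @settings(max_examples=40, deadline=None)
    def test_residual_enriched_as_pool_shrinks(self, f):
        assert rayleigh_remaining(0.0, 38.3, f) > rayleigh_remaining(
            0.0, 38.3, min(1.0, f + 0.01)
        )

    def test_nonpositive_fraction_rejected(self):
        with pytest.raises(DomainError):
            rayleigh_remaining(0.0, 38.3, 0.0)


class TestMixing:
    def test_pure_endmember(self):
        assert mixing_fraction(-27.3, -27.3, 15.0).f_A == pytest.approx(1.0)

    def test_midpoint(self):
        assert mixing_fraction(-6.15, -27.3, 15.0).f_A == pytest.approx(0.5)

    def test_mid_cave_air_sample_oracle(self):
        res = mixing_fraction(-10.0, -27.3, 15.0)
        assert res.f_A == pytest.approx((-10.0 - 15.0) / (-27.3 - 15.0), rel=1e-12)
        assert res.f_A == pytest.approx(0.5910165, rel=1e-6)
        assert res.in_hull

    def test_out_of_hull_flagged_not_clamped(self):
        res = mixing_fraction(20.0, -27.3, 15.0)
        assert not res.in_hull
        assert res.f_A < 0.0

    def test_degenerate_endmembers(self):
        with pytest.raises(DegenerateEndmemberError):
            mixing_fraction(1.0, 5.0, 5.0)

    @given(
        f=st.floats(0.0, 1.0),
        a=deltas,
        b=deltas,
    )
    @settings(max_examples=60, deadline=None)
    def test_forward_then_invert_recovers_fraction(self, f, a, b):
        if abs(a - b) <= 1e-6:
            b = a + 1.0
        sample = mix(f, a, b)
        assert mixing_fraction(sample, a, b).f_A == pytest.approx(f, abs=1e-9)


class TestTrnMassBalance:
    def test_no_nitrate_identity(self):
        assert trn_mass_balance(2.0, 100.0, 8.0, 0.0) == 2.0

    def test_hand_arithmetic(self):
        assert trn_mass_balance(2.0, 100.0, 8.0, 25.0) == pytest.approx(0.0)

    def test_uniform_pool_identity(self):
        assert trn_mass_balance(4.2, 120.0, 4.2, 30.0) == pytest.approx(4.2)

    def test_infeasible_balance(self):
        with pytest.raises(InfeasibleBalanceError):
            trn_mass_balance(2.0, 50.0, 8.0, 50.0)

    def test_negative_concentration(self):
        with pytest.raises(DomainError):
            trn_mass_balance(2.0, -1.0, 8.0, 0.0)

    @given(
        d_trn=deltas,
        d_no3=deltas,
        c_no3=st.floats(0.0, 99.0),
        c_tdn=st.floats(100.0, 500.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_remixing_conserves_mass(self, d_trn, d_no3, c_no3, c_tdn):
        c_trn = c_tdn - c_no3
        d_tdn = (d_trn * c_trn + d_no3 * c_no3) / c_tdn
        recovered = trn_mass_balance(d_tdn, c_tdn, d_no3, c_no3)
        assert recovered == pytest.approx(d_trn, rel=1e-10, abs=1e-10)
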