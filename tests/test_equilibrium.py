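"""NH4+/NH3 speciation and Henry's-law equilibrium.

Frozen expected values were computed by independent hand evaluation of the
van't Hoff and speciation expressions (see the inline oracles in the
property tests), not by running the module under test.
"""

import math

import pytest
from hypothesis import given, settings, strategies as st

from cavenit.config import Constants
from cavenit.equilibrium import (
    equilibrium_nh3_gas,
    henry_constant,
    pka_at_temperature,
    speciate_nhx,
)
from cavenit.samples import DomainError, MissingFieldError, WaterSample

R = 8.314462618


def oracle_pka(temp_C, pka_ref=9.25, dH_kJ=52.21):
    return pka_ref + dH_kJ * 1000 / (R * math.log(10)) * (
        1 / (temp_C + 273.15) - 1 / 298.15
    )


def oracle_kh(temp_C, kh_ref=59.0, B=4200.0):
    return kh_ref * math.exp(B * (1 / (temp_C + 273.15) - 1 / 298.15))


class TestPka:
    def test_reference_temperature_identity(self, constants):
        assert pka_at_temperature(25.0, constants) == pytest.approx(9.25, abs=1e-12)

    def test_zero_enthalpy_limit_is_flat(self):
        c = Constants(dH_dissoc_kJ_mol=0.0)
        assert {pka_at_temperature(t, c) for t in (0.0, 13.0, 25.0, 50.0)} == {9.25}

    def test_cold_stream_value(self, constants):
        # hand evaluation of the van't Hoff expression at 13 degC
        assert pka_at_temperature(13.0, constants) == pytest.approx(
            9.633580482912603, rel=1e-12
        )

    def test_monotone_decreasing_in_temperature(self, constants):
        vals = [pka_at_temperature(t, constants) for t in range(0, 51, 5)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("t", [-1.0, 50.1, 300.0])
    def test_out_of_range_temperature(self, t, constants):
        with pytest.raises(DomainError):
            pka_at_temperature(t, constants)


class TestSpeciation:
    def test_half_dissociated_at_pka(self, constants):
        s = speciate_nhx(100.0, pka_at_temperature(25.0), 25.0, constants)
        assert s.frac_nh3 == pytest.approx(0.5, abs=1e-12)

    def test_one_percent_at_stream_midpoint_ph(self, no_temp_correction):
        # midpoint of the circumneutral stream range, fixed pKa 9.25:
        # about 1% of NH_x is present as NH3(aq)
        s = speciate_nhx(100.0, 7.29, 25.0, no_temp_correction)
        assert s.frac_nh3 == pytest.approx(0.01, abs=2.5e-3)
        assert s.frac_nh3 == pytest.approx(0.010845859477, rel=1e-9)

    def test_cold_acid_stream_fraction(self, constants):
        s = speciate_nhx(80.7, 7.10, 13.0, constants)
        # 1/(1 + 10**(9.6335804829 - 7.10)) evaluated by hand
        assert s.frac_nh3 == pytest.approx(0.0029184361974, rel=1e-9)

    def test_partition_is_exact(self, constants):
        s = speciate_nhx(123.4, 7.3, 14.0, constants)
        assert s.nh3_aq_M + s.nh4_aq_M == pytest.approx(123.4e-6, rel=1e-12)
        assert s.frac_nh3 + s.frac_nh4 == pytest.approx(1.0, abs=1e-12)

    def test_negative_concentration_rejected(self, constants):
        with pytest.raises(DomainError):
            speciate_nhx(-1.0, 7.0, 25.0, constants)

    @given(
        ph=st.floats(0.5, 13.5),
        t=st.floats(0.0, 50.0),
        total=st.floats(0.1, 1e4),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_closed_form_oracle(self, ph, t, total):
        s = speciate_nhx(total, ph, t)
        expected = 1.0 / (1.0 + 10.0 ** (oracle_pka(t) - ph))
        assert s.frac_nh3 == pytest.approx(expected, rel=1e-9)

    @given(ph=st.floats(1.0, 13.0), t=st.floats(0.0, 49.0))
    @settings(max_examples=40, deadline=None)
    def test_fraction_increases_with_ph_and_temperature(self, ph, t):
        base = speciate_nhx(10.0, ph, t).frac_nh3
        assert speciate_nhx(10.0, ph + 0.5, t).frac_nh3 > base
        assert speciate_nhx(10.0, ph, t + 1.0).frac_nh3 > base

    def test_limits(self, constants):
        assert speciate_nhx(10.0, 0.0, 25.0, constants).frac_nh3 < 1e-8
        assert speciate_nhx(10.0, 14.0, 25.0, constants).frac_nh3 > 1.0 - 1e-4


class TestHenry:
    def test_reference_value(self, constants):
        assert henry_constant(25.0, constants) == 59.0

    def test_temperature_dependence_disabled(self):
        c = Constants(kh_vant_hoff_K=0.0)
        assert henry_constant(3.0, c) == henry_constant(47.0, c) == 59.0

    def test_cold_water_value(self, constants):
        # 59*exp(4200*(1/286.15 - 1/298.15)) evaluated by hand
        assert henry_constant(13.0, constants) == pytest.approx(
            106.514918258, rel=1e-9
        )

    def test_increases_as_temperature_drops(self, constants):
        assert henry_constant(5.0, constants) > henry_constant(35.0, constants)

    def test_out_of_range(self, constants):
        with pytest.raises(DomainError):
            henry_constant(-5.0, constants)


class TestGasEquilibrium:
    def test_zero_ammonium_gives_zero_gas(self, constants):
        s = WaterSample("x", pH=7.2, temp_C=13.0, nhx_uM=0.0)
        assert equilibrium_nh3_gas(s, constants).nh3_ppbv == 0.0

    def test_low_endmember_is_two_ppbv(self, constants):
        # the coolest, most acidic, most dilute printed stream condition
        s = WaterSample("low", pH=7.10, temp_C=13.0, nhx_uM=80.7)
        ppbv = equilibrium_nh3_gas(s, constants).nh3_ppbv
        assert float(f"{ppbv:.1g}") == 2.0

    def test_high_endmember_chained_oracle(self, constants):
        s = WaterSample("high", pH=7.48, temp_C=14.0, nhx_uM=158.0)
        frac = 1.0 / (1.0 + 10.0 ** (oracle_pka(14.0) - 7.48))
        expected = 158.0e-6 * frac / oracle_kh(14.0) * 1e9
        got = equilibrium_nh3_gas(s, constants).nh3_ppbv
        assert got == pytest.approx(expected, rel=1e-9)

    def test_missing_field_is_explicit(self, constants):
        with pytest.raises(MissingFieldError):
            equilibrium_nh3_gas(WaterSample("x", pH=7.1, temp_C=13.0), constants)

    @given(ph=st.floats(4.0, 10.0), t=st.floats(0.0, 50.0), c=st.floats(0.1, 1e4))
    @settings(max_examples=40, deadline=None)
    def test_roundtrip_through_henry(self, ph, t, c):
        s = WaterSample("x", pH=ph, temp_C=t, nhx_uM=c)
        gas = equilibrium_nh3_gas(s)
        back = gas.partial_pressure_atm * gas.kh_M_per_atm
        assert back == pytest.approx(speciate_nhx(c, ph, t).nh3_aq_M, rel=1e-10)

    @given(ph=st.floats(4.0, 10.0), t=st.floats(0.0, 50.0), c=st.floats(0.1, 5e3))
    @settings(max_examples=40, deadline=None)
    def test_ppbv_linear_in_total_ammonium(self, ph, t, c):
        one = equilibrium_nh3_gas(WaterSample("a", pH=ph, temp_C=t, nhx_uM=c))
        two = equilibrium_nh3_gas(WaterSample("a", pH=ph, temp_C=t, nhx_uM=2 * c))
        assert two.nh3_ppbv == pytest.approx(2 * one.nh3_ppbv, rel=1e-12)
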