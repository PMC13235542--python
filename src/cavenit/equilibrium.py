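"""NH4+/NH3 acid–base speciation and Henry's-law gas–water equilibrium.

The chemistry is deliberately minimal — one acid–base pair and one volatile
species. Activities are taken equal to concentrations (dilute
approximation); an optional activity-coefficient hook is provided for
waters where the ionic-strength correction matters, but the default is off
because sulfidic cave streams are dilute enough that the correction is
small against the order-of-magnitude questions asked here.

Temperature corrections use the van't Hoff relation about the 25 °C
reference values:

    pKa(T) = pKa(25 °C) + ΔH°/(R ln 10) · (1/T − 1/T₀)
    KH(T)  = KH(25 °C) · exp(B · (1/T − 1/T₀)),   B = −Δ_sol H / R

with ΔH° = 52.21 kJ/mol (NH4+ dissociation is endothermic, so cold water
holds relatively more NH4+) and B = 4200 K (NH3 is more soluble cold).
"""

from __future__ import annotations

import math
from typing import Callable

from cavenit.config import Constants, R_J_PER_MOL_K, T_REF_K
from cavenit.samples import (
    DomainError,
    GasEquilibrium,
    MissingFieldError,
    SpeciationResult,
    WaterSample,
)

_DEFAULT = Constants()


def _check_temp(temp_C: float) -> float:
    if not (0.0 <= temp_C <= 50.0):
        raise DomainError(f"temp_C={temp_C} outside [0, 50]")
    return temp_C + 273.15


def pka_at_temperature(temp_C: float, constants: Constants = _DEFAULT) -> float:
    """pKa of NH4+ at ``temp_C``, van't Hoff-corrected from 9.25 at 25 °C.

    Returns the reference pKa exactly at 25 °C and decreases monotonically
    with temperature for positive dissociation enthalpy.
    """
    T = _check_temp(temp_C)
    dH = constants.dH_dissoc_kJ_mol * 1000.0
    return constants.pka_ref + dH / (R_J_PER_MOL_K * math.log(10.0)) * (
        1.0 / T - 1.0 / T_REF_K
    )


def henry_constant(temp_C: float, constants: Constants = _DEFAULT) -> float:
    """Henry solubility constant of NH3 in M/atm at ``temp_C``.

    59 M/atm at 25 °C by default, increasing as temperature decreases;
    set ``kh_vant_hoff_K`` to 0 to disable the temperature dependence.
    """
    T = _check_temp(temp_C)
    return constants.kh_ref_M_atm * math.exp(
        constants.kh_vant_hoff_K * (1.0 / T - 1.0 / T_REF_K)
    )


def speciate_nhx(
    nhx_uM: float,
    pH: float,
    temp_C: float,
    constants: Constants = _DEFAULT,
    gamma_nh4: Callable[[float], float] | None = None,
) -> SpeciationResult:
    """Partition total NH_x between NH3(aq) and NH4+ at the given pH.

    frac_NH3 = 1 / (1 + 10^(pKa − pH)); the two concentrations sum to the
    total exactly. ``gamma_nh4`` optionally supplies an NH4+ activity
    coefficient as a function of temperature (ionic-strength hook); by
    default activities equal concentrations.
    """
    if nhx_uM < 0:
        raise DomainError(f"nhx_uM={nhx_uM} < 0")
    if not (0.0 <= pH <= 14.0):
        raise DomainError(f"pH={pH} outside [0, 14]")
    pka = pka_at_temperature(temp_C, constants)
    if gamma_nh4 is not None:
        # effective pKa shift: {NH4+} = gamma * [NH4+]
        pka = pka - math.log10(gamma_nh4(temp_C))
    frac = 1.0 / (1.0 + 10.0 ** (pka - pH))
    total_M = nhx_uM * 1e-6
    nh3 = frac * total_M
    return SpeciationResult(
        frac_nh3=frac,
        nh3_aq_M=nh3,
        nh4_aq_M=total_M - nh3,
        pKa_used=pka,
        temp_C=temp_C,
    )


def equilibrium_nh3_gas(
    sample: WaterSample, constants: Constants = _DEFAULT
) -> GasEquilibrium:
    """Predicted NH3(g) mixing ratio in equilibrium with a water sample.

    p_NH3 = [NH3(aq)] / KH(T); ppbv = p_NH3 × 1e9 at 1 atm total pressure
    and unit fugacity coefficient.
    """
    for field in ("pH", "temp_C", "nhx_uM"):
        if getattr(sample, field) is None:
            raise MissingFieldError(f"sample {sample.site_id}: {field} is missing")
    spec = speciate_nhx(sample.nhx_uM, sample.pH, sample.temp_C, constants)
    kh = henry_constant(sample.temp_C, constants)
    p_atm = spec.nh3_aq_M / kh
    return GasEquilibrium(
        nh3_ppbv=p_atm * 1e9, kh_M_per_atm=kh, partial_pressure_atm=p_atm
    )
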