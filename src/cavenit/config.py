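"""Physical constants and tunable model parameters.

All defaults live in ``data/constants.yaml`` shipped with the package; a
user file with the same structure overrides any subset of them. Values are
carried in SI-adjacent units conventional in aquatic chemistry: molar
concentrations, kJ/mol enthalpies, M/atm Henry constants, ‰ enrichment
factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path

import yaml

R_J_PER_MOL_K = 8.314462618
T_REF_K = 298.15  # 25 degC reference for pKa and Henry constant


@dataclass(frozen=True)
class Constants:
    """Model constants with temperature-correction parameters.

    Attributes
    ----------
    pka_ref : float
        pKa of NH4+ at 25 °C (9.25).
    dH_dissoc_kJ_mol : float
        Standard enthalpy of NH4+ dissociation, drives the van't Hoff
        temperature correction of the pKa. Set to 0 to disable.
    kh_ref_M_atm : float
        Henry solubility constant of NH3 at 25 °C, M/atm.
    kh_vant_hoff_K : float
        −Δ_sol H/R for NH3 dissolution, Kelvin. Set to 0 to disable the
        Henry-constant temperature dependence.
    eps_nh4_nh3aq_permil, eps_nh3aq_nh3g_permil, eps_transport_permil,
    eps_trap_permil : float
        Enrichment factors (‰) of the volatilization/trapping chain.
    stream_air_endmember_permil, surface_endmember_permil : float
        Two-endmember mixing poles for δ15N in cave air and droplets.
    """

    pka_ref: float = 9.25
    dH_dissoc_kJ_mol: float = 52.21
    kh_ref_M_atm: float = 59.0
    kh_vant_hoff_K: float = 4200.0
    eps_nh4_nh3aq_permil: float = 30.0
    eps_nh3aq_nh3g_permil: float = 8.3
    eps_transport_permil: float = 0.0
    eps_trap_permil: float = 0.0
    fractionation_mode: str = "linear"
    stream_air_endmember_permil: float = -27.3
    surface_endmember_permil: float = 15.0

    def with_overrides(self, **kwargs) -> "Constants":
        return replace(self, **kwargs)


def _package_defaults() -> dict:
    text = (resources.files("cavenit") / "data" / "constants.yaml").read_text()
    return yaml.safe_load(text)


def load_constants(path: str | Path | None = None) -> Constants:
    """Load constants from the packaged defaults, optionally overridden.

    Parameters
    ----------
    path : optional
        YAML file whose top-level keys override the packaged defaults.
        Unknown keys raise ``ValueError`` so typos do not pass silently.
    """
    data = _package_defaults()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(Constants)}
        unknown = set(user) - known
        if unknown:
            raise ValueError(f"unknown constants in {path}: {sorted(unknown)}")
        data.update(user)
    return Constants(**data)
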