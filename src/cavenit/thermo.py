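"""Gibbs-energy favorability of ammonia oxidation as a function of pH and NH4+.

Addresses whether chemolithotrophic ammonia oxidation — to nitrite (the
AOA/AOB step) or all the way to nitrate (comammox) — is exergonic in
extremely acidic cave-wall droplets. ΔG = ΔG° + RT·ln Q, with ΔG° assembled
from standard Gibbs energies of formation at 25 °C (Stumm & Morgan,
*Aquatic Chemistry*, 3rd ed., compilation; shipped in
``data/gibbs_formation.csv``) and Q built from the species activities of
the environment: H+ from pH, O2 as gas-phase partial pressure at unit
fugacity, vanishingly small product activities for NO2−/NO3−, and the
NH4+/NH3 reactant speciated at the ambient pH.

Reactions are written and normalized per mole of N oxidized, so grids are
directly comparable across pathways. Temperature is fixed at 25 °C; no
heat-capacity corrections are applied.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from cavenit.config import Constants, R_J_PER_MOL_K
from cavenit.equilibrium import speciate_nhx
from cavenit.samples import DomainError

_ELEMENTS = ("N", "H", "O")


class UnbalancedReactionError(ValueError):
    """Stoichiometry does not conserve elements or charge."""


def load_formation_energies() -> dict[str, dict]:
    """Species table: element composition, charge, ΔG°f (kJ/mol) at 25 °C."""
    text = (resources.files("cavenit") / "data" / "gibbs_formation.csv").read_text()
    table = {}
    for row in csv.DictReader(text.splitlines()):
        table[row["species"]] = {
            "phase": row["phase"],
            "composition": {el: int(row[el]) for el in _ELEMENTS},
            "charge": int(row["charge"]),
            "dG0f_kJ_mol": float(row["dG0f_kJ_mol"]),
        }
    return table


@dataclass(frozen=True)
class ReactionSpec:
    """A stoichiometric reaction with standard-state formation energies.

    ``stoichiometry`` maps species name to signed coefficient (products
    positive, reactants negative). Element and charge balance are checked
    at construction.
    """

    name: str
    stoichiometry: Mapping[str, float]
    dG0f_kJ_per_mol: Mapping[str, float]
    species_info: Mapping[str, dict] = field(default_factory=load_formation_energies)

    def __post_init__(self):
        for sp in self.stoichiometry:
            if sp not in self.dG0f_kJ_per_mol:
                raise UnbalancedReactionError(f"{self.name}: no ΔG°f for {sp}")
            if sp not in self.species_info:
                raise UnbalancedReactionError(f"{self.name}: unknown species {sp}")
        for el in _ELEMENTS:
            net = sum(
                coeff * self.species_info[sp]["composition"][el]
                for sp, coeff in self.stoichiometry.items()
            )
            if abs(net) > 1e-9:
                raise UnbalancedReactionError(f"{self.name}: {el} imbalance {net}")
        net_q = sum(
            coeff * self.species_info[sp]["charge"]
            for sp, coeff in self.stoichiometry.items()
        )
        if abs(net_q) > 1e-9:
            raise UnbalancedReactionError(f"{self.name}: charge imbalance {net_q}")

    @property
    def dG0_kJ_mol(self) -> float:
        """Standard reaction Gibbs energy: Σ ν_i ΔG°f,i."""
        return sum(
            coeff * self.dG0f_kJ_per_mol[sp]
            for sp, coeff in self.stoichiometry.items()
        )

    @property
    def reactant_n_species(self) -> str:
        """The nitrogen substrate species (NH4+ or NH3 form)."""
        for sp, coeff in self.stoichiometry.items():
            if coeff < 0 and self.species_info[sp]["composition"]["N"] > 0:
                return sp
        raise UnbalancedReactionError(f"{self.name}: no N-bearing reactant")


@dataclass(frozen=True)
class ThermoConditions:
    """Environmental conditions entering the reaction quotient."""

    pH: float
    nh4_total_M: float
    temp_C: float = 25.0
    pO2_atm: float = 0.209
    activity_no2: float = 1e-12
    activity_no3: float = 1e-12

    def __post_init__(self):
        if not (0.0 < self.pO2_atm <= 1.0):
            raise DomainError(f"pO2_atm={self.pO2_atm} outside (0, 1]")
        for name in ("activity_no2", "activity_no3"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")
        if self.nh4_total_M < 0:
            raise DomainError(f"nh4_total_M={self.nh4_total_M} < 0")


def _reaction(name, stoich, energies, info) -> ReactionSpec:
    return ReactionSpec(
        name=name,
        stoichiometry=stoich,
        dG0f_kJ_per_mol={sp: energies[sp]["dG0f_kJ_mol"] for sp in stoich},
        species_info=info,
    )


def ammonia_oxidation_reactions(reactant: str = "NH4+") -> dict[str, ReactionSpec]:
    """The three ammonia-oxidation reactions, per mole of N oxidized.

    ``reactant`` selects whether the quotient is written on the NH4+ or the
    NH3(aq) form of the substrate (both describe the same equilibrium once
    speciation is accounted for, but the proton stoichiometry differs).
    Returns ``to_nitrite`` (AOA/AOB), ``nitrite_to_nitrate``, and
    ``to_nitrate`` (comammox, the sum of the first two).
    """
    info = load_formation_energies()
    if reactant == "NH4+":
        to_no2 = {"NH4+": -1, "O2(g)": -1.5, "NO2-": 1, "H+": 2, "H2O(l)": 1}
        to_no3 = {"NH4+": -1, "O2(g)": -2.0, "NO3-": 1, "H+": 2, "H2O(l)": 1}
    elif reactant == "NH3":
        to_no2 = {"NH3(aq)": -1, "O2(g)": -1.5, "NO2-": 1, "H+": 1, "H2O(l)": 1}
        to_no3 = {"NH3(aq)": -1, "O2(g)": -2.0, "NO3-": 1, "H+": 1, "H2O(l)": 1}
    else:
        raise ValueError(f"reactant={reactant!r}, expected 'NH4+' or 'NH3'")
    no2_no3 = {"NO2-": -1, "O2(g)": -0.5, "NO3-": 1}
    return {
        "to_nitrite": _reaction("ammonia_to_nitrite", to_no2, info, info),
        "nitrite_to_nitrate": _reaction("nitrite_to_nitrate", no2_no3, info, info),
        "to_nitrate": _reaction("ammonia_to_nitrate", to_no3, info, info),
    }


def _activity(sp: str, cond: ThermoConditions, constants: Constants) -> float:
    """Species activity under the given conditions (dilute approximation)."""
    if sp == "H+":
        return 10.0 ** (-cond.pH)
    if sp == "H2O(l)":
        return 1.0
    if sp == "O2(g)":
        return cond.pO2_atm
    if sp == "NO2-":
        return cond.activity_no2
    if sp == "NO3-":
        return cond.activity_no3
    if sp in ("NH4+", "NH3(aq)"):
        spec = speciate_nhx(cond.nh4_total_M * 1e6, cond.pH, cond.temp_C, constants)
        return spec.nh4_aq_M if sp == "NH4+" else spec.nh3_aq_M
    raise DomainError(f"no activity rule for species {sp!r}")


def delta_g(
    reaction: ReactionSpec,
    cond: ThermoConditions,
    constants: Constants = Constants(),
) -> float:
    """ΔG in kJ per mole of N oxidized: ΔG° + RT·ln Q.

    Negative values mean the oxidation is exergonic under the stated
    conditions. The NH_x substrate is speciated at the ambient pH before
    entering Q with whichever form the reaction is written on.
    """
    T = cond.temp_C + 273.15
    ln_q = 0.0
    for sp, coeff in reaction.stoichiometry.items():
        a = _activity(sp, cond, constants)
        if a <= 0.0:
            raise DomainError(f"activity of {sp} is {a}; must be > 0")
        ln_q += coeff * np.log(a)
    return reaction.dG0_kJ_mol + R_J_PER_MOL_K * T * ln_q / 1000.0


def delta_g_grid(
    reaction: ReactionSpec,
    pH_values: Sequence[float],
    nh4_values_M: Sequence[float],
    cond: ThermoConditions | None = None,
    constants: Constants = Constants(),
) -> np.ndarray:
    """ΔG (kJ/mol N) over a pH × NH4+ grid; element [i, j] is (pH_i, nh4_j).

    ``cond`` supplies the non-gridded conditions (temperature, pO2, product
    activities); its pH and nh4_total are ignored in favor of the axes.
    """
    if len(pH_values) == 0 or len(nh4_values_M) == 0:
        raise ValueError("grid axes must be non-empty")
    base = cond or ThermoConditions(pH=7.0, nh4_total_M=1e-6)
    out = np.empty((len(pH_values), len(nh4_values_M)))
    for i, ph in enumerate(pH_values):
        for j, c in enumerate(nh4_values_M):
            cell = ThermoConditions(
                pH=ph,
                nh4_total_M=c,
                temp_C=base.temp_C,
                pO2_atm=base.pO2_atm,
                activity_no2=base.activity_no2,
                activity_no3=base.activity_no3,
            )
            out[i, j] = delta_g(reaction, cell, constants)
    return out
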