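"""δ15N arithmetic: fractionation chain, Rayleigh evolution, mixing, mass balance.

Sign convention, used everywhere in this package: ε ≡ (α − 1)·1000 with
α = R_substrate / R_product, so a positive ε means the instantaneous
product is depleted in 15N relative to its substrate. Two conventions for
applying an ε are supported:

* ``linear``: δ_product = δ_substrate − ε (the back-of-envelope form in
  which field arithmetic is usually printed);
* ``exact``:  δ_product = (δ_substrate + 1000)/α − 1000.

They agree to first order; the difference is exactly ε(ε − δ)/(1000·α) ‰,
i.e. of order ε²/1000 for δ near zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from cavenit.samples import DomainError, FractionationSet

CHAIN_STEPS = ("nh4_aq", "nh3_aq", "nh3_g", "nh3_transported", "nh4_trapped")


class DegenerateEndmemberError(ValueError):
    """Mixing endmembers coincide; the mixing fraction is undefined."""


class InfeasibleBalanceError(ValueError):
    """Mass balance requires a subtracted pool smaller than the total."""


def apply_fractionation(
    delta_substrate_permil: float, eps_permil: float, mode: str = "linear"
) -> float:
    """δ15N of the product of a single equilibrium fractionation step."""
    if not (math.isfinite(delta_substrate_permil) and math.isfinite(eps_permil)):
        raise DomainError("delta and eps must be finite")
    if mode not in ("linear", "exact"):
        raise DomainError(f"mode={mode!r}, expected 'linear' or 'exact'")
    if eps_permil == 0.0:
        return delta_substrate_permil
    if mode == "linear":
        return delta_substrate_permil - eps_permil
    alpha = 1.0 + eps_permil / 1000.0
    if alpha <= 0.0:
        raise DomainError(f"alpha={alpha} <= 0 (eps={eps_permil})")
    return (delta_substrate_permil + 1000.0) / alpha - 1000.0


@dataclass(frozen=True)
class ChainResult:
    """Per-step δ15N along NH4+(aq) → NH3(aq) → NH3(g) → transported → trapped."""

    d15N_nh4_aq: float
    d15N_nh3_aq: float
    d15N_nh3_g: float
    d15N_nh3_transported: float
    d15N_nh4_trapped: float

    @property
    def total_depletion_permil(self) -> float:
        """Source minus trapped δ15N; positive when the trap is depleted."""
        return self.d15N_nh4_aq - self.d15N_nh4_trapped

    def as_dict(self) -> dict[str, float]:
        return {
            "nh4_aq": self.d15N_nh4_aq,
            "nh3_aq": self.d15N_nh3_aq,
            "nh3_g": self.d15N_nh3_g,
            "nh3_transported": self.d15N_nh3_transported,
            "nh4_trapped": self.d15N_nh4_trapped,
        }


def volatilization_chain(
    delta_stream_nh4_permil: float, fs: FractionationSet
) -> ChainResult:
    """Sequential fractionation from stream NH4+ to acid-trapped NH4+.

    Applies, in physical order, the NH4+/NH3(aq) equilibrium, the
    air–water interface step, any transport fractionation, and the acid
    trap. In linear mode the total depletion is the sum of the four ε
    values; in exact mode the step alphas multiply (which is likewise
    commutative, so the fixed a→b→c→d order is physical bookkeeping, not
    a numerical choice).
    """
    deltas = [delta_stream_nh4_permil]
    for eps in fs.epsilons:
        deltas.append(apply_fractionation(deltas[-1], eps, fs.mode))
    return ChainResult(*deltas)


def rayleigh_remaining(
    delta0_permil: float, eps_net_permil: float, f_remaining: float
) -> float:
    """δ15N of the residual reservoir after removing a fraction with net ε.

    δ_remaining = δ0 − ε_net · ln(f): as isotopically light product is
    stripped away (ε_net > 0), the pool left behind grows heavier.
    """
    if not (0.0 < f_remaining <= 1.0):
        raise DomainError(f"f_remaining={f_remaining} outside (0, 1]")
    if not (math.isfinite(delta0_permil) and math.isfinite(eps_net_permil)):
        raise DomainError("delta0 and eps_net must be finite")
    return delta0_permil - eps_net_permil * math.log(f_remaining)


@dataclass(frozen=True)
class MixingResult:
    f_A: float
    in_hull: bool


def mixing_fraction(
    delta_sample_permil: float,
    delta_end_A_permil: float,
    delta_end_B_permil: float,
    min_separation_permil: float = 1e-9,
) -> MixingResult:
    """Fraction of endmember A in a two-endmember δ15N mixture.

    f_A = (δ_sample − δ_B)/(δ_A − δ_B). Values outside [0, 1] are returned
    as computed but flagged ``in_hull=False``, so samples inconsistent with
    the two-endmember model stay visible rather than being clamped away.
    """
    sep = delta_end_A_permil - delta_end_B_permil
    if abs(sep) <= min_separation_permil:
        raise DegenerateEndmemberError(
            f"endmembers {delta_end_A_permil} and {delta_end_B_permil} coincide"
        )
    f = (delta_sample_permil - delta_end_B_permil) / sep
    return MixingResult(f_A=f, in_hull=0.0 <= f <= 1.0)


def mix(f_A: float, delta_end_A_permil: float, delta_end_B_permil: float) -> float:
    """Forward two-endmember mixture: f·δ_A + (1 − f)·δ_B."""
    return f_A * delta_end_A_permil + (1.0 - f_A) * delta_end_B_permil


def trn_mass_balance(
    d15N_TDN_permil: float, c_TDN_uM: float, d15N_NO3_permil: float, c_NO3_uM: float
) -> float:
    """δ15N of total reduced N by subtracting nitrate from total dissolved N.

    δ_TRN = (δ_TDN·C_TDN − δ_NO3·C_NO3) / (C_TDN − C_NO3). Requires the
    nitrate pool to be strictly smaller than the total.
    """
    if c_TDN_uM < 0 or c_NO3_uM < 0:
        raise DomainError("concentrations must be non-negative")
    if c_NO3_uM >= c_TDN_uM:
        raise InfeasibleBalanceError(
            f"c_NO3={c_NO3_uM} uM >= c_TDN={c_TDN_uM} uM: no reduced N remains"
        )
    return (d15N_TDN_permil * c_TDN_uM - d15N_NO3_permil * c_NO3_uM) / (
        c_TDN_uM - c_NO3_uM
    )
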