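"""Domain records for field measurements and derived quantities.

Missing measurements are represented as ``None`` (``NaN`` in tables), never
as sentinel zeros: a stream with no nitrate datum is different from a stream
with zero nitrate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


class DomainError(ValueError):
    """An input lies outside the physically admissible domain."""


class MissingFieldError(ValueError):
    """A required measurement is absent from a sample."""


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not (lo <= value <= hi):
        raise DomainError(f"{name}={value!r} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class WaterSample:
    """One stream or drip-pool measurement (chemistry plus isotopes).

    Concentrations in μM, temperatures in °C, δ values in ‰ vs air N2.
    ``distance_m`` is 0 for the sulfidic stream itself.
    """

    site_id: str
    pH: float | None = None
    temp_C: float | None = None
    nhx_uM: float | None = None
    distance_m: float = 0.0
    no3_uM: float | None = None
    d15N_TDN_permil: float | None = None
    d15N_NO3_permil: float | None = None
    sulfide_uM: float | None = None

    def __post_init__(self):
        if self.pH is not None:
            _check_range("pH", self.pH, 0.0, 14.0)
        if self.temp_C is not None:
            _check_range("temp_C", self.temp_C, 0.0, 50.0)
        if self.nhx_uM is not None and self.nhx_uM < 0:
            raise DomainError(f"nhx_uM={self.nhx_uM} < 0")
        if self.no3_uM is not None and self.no3_uM < 0:
            raise DomainError(f"no3_uM={self.no3_uM} < 0")


@dataclass(frozen=True)
class DropletSample:
    """One acidic condensation-droplet measurement.

    ``droplet_type`` distinguishes droplets collected from spiderwebs from
    snottite (biofilm) drip tips; NH4+ in mM because droplet concentrations
    run three orders of magnitude above stream values.
    """

    site_id: str
    distance_m: float
    droplet_type: str
    pH: float
    nh4_mM: float
    d15N_nh4_permil: float

    def __post_init__(self):
        _check_range("pH", self.pH, 0.0, 14.0)
        if self.nh4_mM < 0:
            raise DomainError(f"nh4_mM={self.nh4_mM} < 0")
        if self.droplet_type not in ("spiderweb", "snottite"):
            raise DomainError(f"droplet_type={self.droplet_type!r}")


@dataclass(frozen=True)
class AirSample:
    """One passive or active air-sampler deployment.

    Passive samplers integrate NH3(g) without a flow measurement, so they
    carry no mixing ratio (``nh3_ppbv`` absent); drip-water-compromised
    deployments are flagged, not dropped.
    """

    site_id: str
    sampler: str
    distance_m: float
    d15N_permil: float | None = None
    nh3_ppbv: float | None = None
    quality_flag: str = "ok"

    def __post_init__(self):
        if self.sampler not in ("passive", "active"):
            raise DomainError(f"sampler={self.sampler!r}")
        if self.quality_flag not in ("ok", "compromised"):
            raise DomainError(f"quality_flag={self.quality_flag!r}")
        if self.nh3_ppbv is not None and self.nh3_ppbv < 0:
            raise DomainError(f"nh3_ppbv={self.nh3_ppbv} < 0")


@dataclass(frozen=True)
class SpeciationResult:
    """NH_x partitioned into NH3(aq) and NH4+ at a given pH and T."""

    frac_nh3: float
    nh3_aq_M: float
    nh4_aq_M: float
    pKa_used: float
    temp_C: float

    @property
    def frac_nh4(self) -> float:
        return 1.0 - self.frac_nh3


@dataclass(frozen=True)
class GasEquilibrium:
    """NH3(g) in Henry's-law equilibrium with a water sample.

    ppbv is mole fraction × 1e9 at 1 atm total pressure with a fugacity
    coefficient of 1.
    """

    nh3_ppbv: float
    kh_M_per_atm: float
    partial_pressure_atm: float


@dataclass(frozen=True)
class FractionationSet:
    """Enrichment factors of the volatilization/trapping chain.

    Steps, in physical order: (a) NH4+(aq) ↔ NH3(aq), (b) NH3(aq) ↔ NH3(g)
    across the air–water interface, (c) optional transport fractionation in
    cave air, (d) trapping as NH4+ in an acidic droplet. Positive ε depletes
    the product in 15N. ``mode`` selects the linear (δ − ε) or exact
    ((δ+1000)/α − 1000) convention.
    """

    eps_nh4_nh3aq_permil: float = 30.0
    eps_nh3aq_nh3g_permil: float = 8.3
    eps_transport_permil: float = 0.0
    eps_trap_permil: float = 0.0
    mode: str = "linear"

    def __post_init__(self):
        if self.mode not in ("linear", "exact"):
            raise DomainError(f"mode={self.mode!r}, expected 'linear' or 'exact'")
        for name in (
            "eps_nh4_nh3aq_permil",
            "eps_nh3aq_nh3g_permil",
            "eps_transport_permil",
            "eps_trap_permil",
        ):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise DomainError(f"{name}={v} is not finite")

    @property
    def epsilons(self) -> tuple[float, ...]:
        return (
            self.eps_nh4_nh3aq_permil,
            self.eps_nh3aq_nh3g_permil,
            self.eps_transport_permil,
            self.eps_trap_permil,
        )


# ---------------------------------------------------------------------------
# Delimited-table I/O. One row per sample, comma-separated, header row, UTF-8.

WATER_COLUMNS = [
    "site_id", "distance_m", "pH", "temp_C", "nhx_uM", "no3_uM",
    "d15N_TDN_permil", "d15N_NO3_permil", "sulfide_uM",
]
DROPLET_COLUMNS = [
    "site_id", "distance_m", "droplet_type", "pH", "nh4_mM", "d15N_nh4_permil",
]
AIR_COLUMNS = [
    "site_id", "sampler", "distance_m", "nh3_ppbv", "d15N_permil", "quality_flag",
]

_TABLE_SCHEMAS = {
    "water": (WaterSample, WATER_COLUMNS),
    "droplet": (DropletSample, DROPLET_COLUMNS),
    "air": (AirSample, AIR_COLUMNS),
}


def samples_to_frame(samples: Iterable) -> pd.DataFrame:
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample list; cannot infer schema")
    kind = {WaterSample: "water", DropletSample: "droplet", AirSample: "air"}[
        type(samples[0])
    ]
    _, cols = _TABLE_SCHEMAS[kind]
    return pd.DataFrame([asdict(s) for s in samples])[cols]


def write_table(samples: Sequence, path: str | Path) -> None:
    """Write samples as a CSV table with the canonical column order.

    Floats are written with 17 significant digits so a read-back
    round-trips bit-exactly.
    """
    samples_to_frame(samples).to_csv(path, index=False, float_format="%.17g")


def _row_to_sample(cls, row: pd.Series):
    kwargs = {}
    for key, value in row.items():
        if isinstance(value, float) and math.isnan(value):
            value = None
        kwargs[key] = value
    return cls(**kwargs)


def read_table(path: str | Path, kind: str) -> list:
    """Read a CSV table of ``kind`` 'water', 'droplet' or 'air'.

    Raises ``ValueError`` on missing columns; NaN cells become ``None``.
    """
    if kind not in _TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    cls, cols = _TABLE_SCHEMAS[kind]
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [_row_to_sample(cls, row) for _, row in df[cols].iterrows()]
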