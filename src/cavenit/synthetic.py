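"""Synthetic field-campaign generator.

Emits stream-water, condensation-droplet and air-sampler tables with the
statistical structure the analysis pipeline assumes, so every stage can be
exercised end-to-end without field data. The generative model is:

* Stream chemistry drawn uniformly within the observed circumneutral
  ranges (pH 7.10–7.48, 13–14 °C, 80.7–158.0 μM NH_x), stream δ15N_NHx
  Gaussian around +3.3 ‰.
* Droplet δ15N follows a two-endmember mixture between a stream-air pole
  (δ ≈ −27 ‰, volatilized NH3) and a surface pole (δ = +15 ‰, guano-derived
  N), with the stream-air mixing fraction decaying exponentially with
  distance from the stream — an explicitly synthetic transport convention,
  not a physical claim — plus Gaussian analytical noise (±0.3 ‰, 1σ).
* Droplet NH4+ is log-normal about a median that decays geometrically from
  the near-stream level (2.23 mM) to the distal level (0.018 mM).
* Droplets within the trapping zone are extremely acidic (pH < 1);
  beyond it they sit at pH 4 with distal concentrations.
* Air samples mix passive (no mixing ratio) and active (0.6–2.5 ppbv)
  deployments with δ15N from the same mixing law.

A single integer seed drives one ``SeedSequence``; per-table child streams
are spawned deterministically, so enlarging one table never perturbs the
others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from cavenit.isotopes import mix
from cavenit.samples import AirSample, DropletSample, WaterSample


class CampaignError(ValueError):
    """The campaign configuration is internally inconsistent."""


@dataclass(frozen=True)
class CampaignConfig:
    """Knobs of the synthetic campaign; defaults emulate the study system."""

    seed: int = 0
    n_streams: int = 8
    n_droplets: int = 40
    n_air: int = 12
    stream_pH_range: tuple[float, float] = (7.10, 7.48)
    stream_T_range: tuple[float, float] = (13.0, 14.0)
    stream_nhx_range: tuple[float, float] = (80.7, 158.0)
    stream_d15N_mean: float = 3.3
    stream_d15N_sd: float = 1.1
    distance_grid: tuple[float, ...] = (0.5, 1.0, 1.5, 7.5, 10.0, 12.5, 27.5)
    droplet_conc_near_mM: float = 2.23
    droplet_conc_far_mM: float = 0.018
    endmember_stream_air_permil: float = -27.3
    endmember_surface_permil: float = 15.0
    mixing_length_m: float = 34.0
    trapping_distance_m: float = 15.0
    trapping_pH_threshold: float = 2.0
    noise_sd_delta: float = 0.3
    noise_sd_conc_rel: float = 0.3

    def __post_init__(self):
        for name in ("stream_pH_range", "stream_T_range", "stream_nhx_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise CampaignError(f"{name} not ordered: {lo} > {hi}")
        for name in ("noise_sd_delta", "noise_sd_conc_rel", "stream_d15N_sd"):
            if getattr(self, name) < 0:
                raise CampaignError(f"{name} must be >= 0")
        for name in ("n_streams", "n_droplets", "n_air"):
            if getattr(self, name) < 1:
                raise CampaignError(f"{name} must be >= 1")
        if self.droplet_conc_far_mM <= 0 or self.droplet_conc_near_mM <= 0:
            raise CampaignError("droplet concentration levels must be > 0")
        if self.droplet_conc_far_mM >= self.droplet_conc_near_mM:
            raise CampaignError("far droplet level must be below the near level")
        if self.mixing_length_m <= 0:
            raise CampaignError("mixing_length_m must be > 0")
        if not self.distance_grid:
            raise CampaignError("distance_grid must be non-empty")

    # ---- closed-form expectations, used by tests and parameter recovery

    def stream_air_fraction(self, distance_m) -> np.ndarray:
        """Expected stream-air mixing fraction at a distance: exp(−d/L)."""
        return np.exp(-np.asarray(distance_m, dtype=float) / self.mixing_length_m)

    def expected_d15N(self, distance_m) -> np.ndarray:
        """Noise-free δ15N of trapped N at a distance, from the mixing law."""
        f = self.stream_air_fraction(distance_m)
        return f * self.endmember_stream_air_permil + (1.0 - f) * (
            self.endmember_surface_permil
        )

    def median_droplet_mM(self, distance_m) -> np.ndarray:
        """Median droplet NH4+ at a distance (geometric interpolation)."""
        d = np.asarray(distance_m, dtype=float)
        d_max = max(self.distance_grid)
        if d_max == 0:
            return np.broadcast_to(self.droplet_conc_near_mM, d.shape).copy()
        ratio = self.droplet_conc_far_mM / self.droplet_conc_near_mM
        return self.droplet_conc_near_mM * ratio ** (d / d_max)


class Campaign(NamedTuple):
    water: list[WaterSample]
    droplets: list[DropletSample]
    air: list[AirSample]


def _rngs(seed: int) -> tuple[np.random.Generator, ...]:
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def generate_campaign(cfg: CampaignConfig) -> Campaign:
    """Draw one synthetic campaign; deterministic under a fixed seed."""
    rng_w, rng_d, rng_a = _rngs(cfg.seed)

    water = []
    for i in range(cfg.n_streams):
        water.append(
            WaterSample(
                site_id=f"S{i:02d}",
                distance_m=0.0,
                pH=float(rng_w.uniform(*cfg.stream_pH_range)),
                temp_C=float(rng_w.uniform(*cfg.stream_T_range)),
                nhx_uM=float(rng_w.uniform(*cfg.stream_nhx_range)),
                d15N_TDN_permil=float(
                    rng_w.normal(cfg.stream_d15N_mean, cfg.stream_d15N_sd)
                ),
            )
        )

    droplets = []
    grid = np.asarray(cfg.distance_grid, dtype=float)
    for i in range(cfg.n_droplets):
        d = float(grid[i % len(grid)])
        trapping = d <= cfg.trapping_distance_m
        median = float(cfg.median_droplet_mM(d))
        conc = median * math.exp(float(rng_d.normal(0.0, cfg.noise_sd_conc_rel)))
        delta = float(cfg.expected_d15N(d) + rng_d.normal(0.0, cfg.noise_sd_delta))
        pH = float(rng_d.uniform(0.2, 1.0)) if trapping else 4.0
        droplets.append(
            DropletSample(
                site_id=f"D{i:03d}",
                distance_m=d,
                droplet_type="snottite" if i % 2 else "spiderweb",
                pH=pH,
                nh4_mM=conc,
                d15N_nh4_permil=delta,
            )
        )

    air = []
    for i in range(cfg.n_air):
        d = float(grid[i % len(grid)])
        sampler = "passive" if i % 3 == 0 else "active"
        delta = float(cfg.expected_d15N(d) + rng_a.normal(0.0, cfg.noise_sd_delta))
        ppbv = None if sampler == "passive" else float(rng_a.uniform(0.6, 2.5))
        air.append(
            AirSample(
                site_id=f"A{i:02d}",
                sampler=sampler,
                distance_m=d,
                nh3_ppbv=ppbv,
                d15N_permil=delta,
                quality_flag="ok",
            )
        )

    return Campaign(water=water, droplets=droplets, air=air)
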