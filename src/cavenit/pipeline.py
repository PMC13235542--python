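"""End-to-end analysis: tables in, structured report out.

``run_analysis`` chains the package's pieces the way the scientific
argument chains them: stream chemistry → predicted NH3(g) mixing ratios
and predicted δ15N along the volatilization chain; droplet and air δ15N →
two-endmember mixing fractions (stream-air vs surface N); nitrate-bearing
pools → TRN mass-balance correction; and a ΔG grid locating where ammonia
oxidation is exergonic. The analysis path contains no randomness; a report
is a plain JSON-serializable dict, bitwise reproducible for identical
inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from typing import Sequence

import numpy as np
import pandas as pd

from cavenit.config import Constants
from cavenit.equilibrium import equilibrium_nh3_gas
from cavenit.isotopes import (
    mixing_fraction,
    trn_mass_balance,
    volatilization_chain,
)
from cavenit.samples import (
    AirSample,
    DropletSample,
    FractionationSet,
    MissingFieldError,
    WaterSample,
    samples_to_frame,
)
from cavenit.thermo import ammonia_oxidation_reactions, delta_g_grid

REPORT_SCHEMA_VERSION = "1"

# Narrative distance bins: adjacent to streams, mid-cave, distal.
DEFAULT_DISTANCE_BINS_M = (1.5, 12.5)


def recover_endmembers(
    distance_m: Sequence[float],
    d15N_permil: Sequence[float],
    mixing_length_m: float,
) -> tuple[float, float]:
    """Invert the two-endmember mixing model by least squares.

    With the stream-air fraction f_i = exp(−d_i/L) known, each observation
    is δ_i = f_i·δ_air + (1 − f_i)·δ_surface; ordinary least squares on the
    design [f, 1 − f] recovers both endmembers. Returns
    (stream-air δ, surface δ).
    """
    d = np.asarray(distance_m, dtype=float)
    y = np.asarray(d15N_permil, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two observations to fit two endmembers")
    f = np.exp(-d / mixing_length_m)
    design = np.column_stack([f, 1.0 - f])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(coef[0]), float(coef[1])


def _sha256_of_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def _config_hash(constants: Constants) -> str:
    blob = json.dumps(asdict(constants), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _stream_block(sample: WaterSample, constants: Constants, fs: FractionationSet):
    entry: dict = {"site_id": sample.site_id}
    try:
        gas = equilibrium_nh3_gas(sample, constants)
    except MissingFieldError as exc:
        return None, str(exc)
    entry["nh3_ppbv"] = gas.nh3_ppbv
    entry["kh_M_per_atm"] = gas.kh_M_per_atm

    delta = sample.d15N_TDN_permil
    trn_applied = False
    if (
        delta is not None
        and sample.no3_uM is not None
        and sample.no3_uM > 0
        and sample.d15N_NO3_permil is not None
        and sample.no3_uM < sample.nhx_uM + sample.no3_uM
    ):
        # d15N_TDN spans the whole dissolved pool; strip the nitrate part
        total = sample.nhx_uM + sample.no3_uM
        delta = trn_mass_balance(delta, total, sample.d15N_NO3_permil, sample.no3_uM)
        trn_applied = True
    entry["trn_corrected"] = trn_applied
    if delta is None:
        entry["d15N_chain"] = None
    else:
        chain = volatilization_chain(delta, fs)
        entry["d15N_source_permil"] = delta
        entry["d15N_chain"] = chain.as_dict()
    return entry, None


def _mixing_block(delta: float | None, constants: Constants):
    if delta is None:
        return None
    res = mixing_fraction(
        delta,
        constants.stream_air_endmember_permil,
        constants.surface_endmember_permil,
    )
    return {"f_stream_air": res.f_A, "in_hull": res.in_hull}


def run_analysis(
    water: Sequence[WaterSample],
    droplets: Sequence[DropletSample],
    air: Sequence[AirSample],
    constants: Constants | None = None,
    seed: int | None = None,
    thermo_pH: Sequence[float] | None = None,
    thermo_nh4_M: Sequence[float] | None = None,
) -> dict:
    """Run the full analysis and assemble a versioned report.

    Rows whose required measurements are absent are reported as skipped
    with a per-row diagnostic, never silently dropped. An empty water
    table is a hard error: every downstream quantity is referenced to the
    stream endmember.
    """
    if not water:
        raise ValueError("water table is empty; the stream endmember is required")
    constants = constants or Constants()
    fs = FractionationSet(
        eps_nh4_nh3aq_permil=constants.eps_nh4_nh3aq_permil,
        eps_nh3aq_nh3g_permil=constants.eps_nh3aq_nh3g_permil,
        eps_transport_permil=constants.eps_transport_permil,
        eps_trap_permil=constants.eps_trap_permil,
        mode=constants.fractionation_mode,
    )

    streams, skipped_water = [], []
    for s in water:
        entry, err = _stream_block(s, constants, fs)
        if err is not None:
            skipped_water.append({"site_id": s.site_id, "reason": err})
        else:
            streams.append(entry)

    droplet_rows, skipped_droplets = [], []
    for d in droplets:
        block = _mixing_block(d.d15N_nh4_permil, constants)
        if block is None:
            skipped_droplets.append({"site_id": d.site_id, "reason": "no d15N"})
            continue
        droplet_rows.append(
            {
                "site_id": d.site_id,
                "distance_m": d.distance_m,
                "pH": d.pH,
                "nh4_mM": d.nh4_mM,
                "d15N_nh4_permil": d.d15N_nh4_permil,
                **block,
            }
        )

    air_rows, skipped_air = [], []
    for a in air:
        if a.quality_flag != "ok":
            skipped_air.append({"site_id": a.site_id, "reason": "compromised"})
            continue
        block = _mixing_block(a.d15N_permil, constants)
        if block is None:
            skipped_air.append({"site_id": a.site_id, "reason": "no d15N"})
            continue
        air_rows.append(
            {
                "site_id": a.site_id,
                "sampler": a.sampler,
                "distance_m": a.distance_m,
                "nh3_ppbv": a.nh3_ppbv,
                "d15N_permil": a.d15N_permil,
                **block,
            }
        )

    # Gibbs-energy favorability over a pH x NH4+ grid (25 degC, air O2,
    # trace products). Default grid spans the acidic droplet domain.
    pH_axis = list(thermo_pH) if thermo_pH is not None else [float(x) for x in np.linspace(0.0, 7.0, 15)]
    nh4_axis = (
        list(thermo_nh4_M)
        if thermo_nh4_M is not None
        else [float(x) for x in np.geomspace(1e-6, 1e-2, 13)]
    )
    reactions = ammonia_oxidation_reactions("NH4+")
    thermo_summary = {"reactant_species": "NH4+", "pathways": {}}
    for key in ("to_nitrite", "to_nitrate"):
        grid = delta_g_grid(reactions[key], pH_axis, nh4_axis, constants=constants)
        imin, jmin = np.unravel_index(int(np.argmin(grid)), grid.shape)
        thermo_summary["pathways"][key] = {
            "n_cells": int(grid.size),
            "n_favorable": int((grid < 0).sum()),
            "min_dG_kJ_mol": float(grid.min()),
            "min_at_pH": pH_axis[imin],
            "min_at_nh4_M": nh4_axis[jmin],
        }
    thermo_summary["pH_axis"] = pH_axis
    thermo_summary["nh4_axis_M"] = nh4_axis

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": {
            "config_hash": _config_hash(constants),
            "seed": seed,
            "input_checksums": {
                "water": _sha256_of_frame(samples_to_frame(water)),
                "droplets": _sha256_of_frame(samples_to_frame(droplets))
                if droplets
                else None,
                "air": _sha256_of_frame(samples_to_frame(air)) if air else None,
            },
        },
        "endmembers_permil": {
            "stream_air": constants.stream_air_endmember_permil,
            "surface": constants.surface_endmember_permil,
        },
        "fractionation": {
            "mode": fs.mode,
            "epsilons_permil": list(fs.epsilons),
        },
        "streams": streams,
        "droplets": droplet_rows,
        "air": air_rows,
        "thermodynamics": thermo_summary,
        "row_counts": {
            "water": {
                "total": len(water),
                "analyzed": len(streams),
                "skipped": len(skipped_water),
            },
            "droplets": {
                "total": len(droplets),
                "analyzed": len(droplet_rows),
                "skipped": len(skipped_droplets),
            },
            "air": {
                "total": len(air),
                "analyzed": len(air_rows),
                "skipped": len(skipped_air),
            },
        },
        "skipped": {
            "water": skipped_water,
            "droplets": skipped_droplets,
            "air": skipped_air,
        },
    }
    return report


def report_to_json(report: dict) -> str:
    """Canonical serialization (sorted keys) so identical runs are bitwise equal."""
    return json.dumps(report, sort_keys=True, indent=1)


def summarize_report(report: dict, bins_m: Sequence[float] = DEFAULT_DISTANCE_BINS_M) -> str:
    """Human-readable summary tables, binned by distance from the stream."""
    lines = [f"analysis report (schema v{report['schema_version']})", ""]
    if report["streams"]:
        df = pd.DataFrame(report["streams"])
        lines += ["stream equilibrium NH3(g) predictions:"]
        cols = [c for c in ("site_id", "nh3_ppbv", "d15N_source_permil") if c in df]
        lines += [df[cols].to_string(index=False, float_format=lambda v: f"{v:.2f}"), ""]
        chains = [s["d15N_chain"] for s in report["streams"] if s.get("d15N_chain")]
        if chains:
            cdf = pd.DataFrame(chains)
            lines += [
                "volatilization-chain d15N (permil), per stream:",
                cdf.to_string(index=False, float_format=lambda v: f"{v:.1f}"),
                "",
            ]
    edges = [-np.inf, *bins_m, np.inf]
    for table in ("droplets", "air"):
        rows = report[table]
        if not rows:
            continue
        df = pd.DataFrame(rows)
        df["bin"] = pd.cut(df["distance_m"], edges)
        grp = df.groupby("bin", observed=True).agg(
            n=("site_id", "size"),
            f_stream_air=("f_stream_air", "mean"),
            out_of_hull=("in_hull", lambda s: int((~s).sum())),
        )
        lines += [f"{table}: mean stream-air fraction by distance bin:"]
        lines += [grp.to_string(float_format=lambda v: f"{v:.3f}"), ""]
    th = report["thermodynamics"]
    lines += ["ammonia-oxidation favorability (dG < 0 cells / grid):"]
    for key, p in th["pathways"].items():
        lines.append(
            f"  {key}: {p['n_favorable']}/{p['n_cells']} cells exergonic;"
            f" min {p['min_dG_kJ_mol']:.1f} kJ/mol at pH {p['min_at_pH']:.2f},"
            f" NH4+ {p['min_at_nh4_M']:.2e} M"
        )
    rc = report["row_counts"]
    lines += ["", "rows analyzed/skipped: " + ", ".join(
        f"{k}={v['analyzed']}/{v['skipped']}" for k, v in rc.items()
    )]
    return "\n".join(lines) + "\n"
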