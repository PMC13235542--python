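"""Predict NH3(g) in equilibrium with cave-stream water.

Speciates NH_x at stream pH and temperature and divides the NH3(aq)
concentration by the temperature-corrected Henry constant. Run on the two
printed extreme stream conditions plus the synthetic campaign; the low
endmember (pH 7.10, 80.7 μM, 13 °C) lands at ≈2 ppbv, the lower bound of
the expected stream-equilibrium range.
"""

import argparse
from pathlib import Path

import pandas as pd

from cavenit.equilibrium import equilibrium_nh3_gas, speciate_nhx
from cavenit.samples import WaterSample, read_table

ENDMEMBERS = [
    WaterSample("printed_low", pH=7.10, temp_C=13.0, nhx_uM=80.7),
    WaterSample("printed_high", pH=7.48, temp_C=14.0, nhx_uM=158.0),
]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--campaign", default="results/campaign")
    ap.add_argument("--out", default="results/stream_equilibrium.csv")
    args = ap.parse_args()

    samples = list(ENDMEMBERS)
    water_csv = Path(args.campaign) / "water.csv"
    if water_csv.exists():
        samples += read_table(water_csv, "water")

    rows = []
    for s in samples:
        spec = speciate_nhx(s.nhx_uM, s.pH, s.temp_C)
        gas = equilibrium_nh3_gas(s)
        rows.append(
            {
                "site_id": s.site_id,
                "pH": s.pH,
                "temp_C": s.temp_C,
                "nhx_uM": s.nhx_uM,
                "pKa_used": spec.pKa_used,
                "frac_nh3": spec.frac_nh3,
                "kh_M_per_atm": gas.kh_M_per_atm,
                "nh3_ppbv": gas.nh3_ppbv,
            }
        )
    df = pd.DataFrame(rows)
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)
    low = df.loc[df.site_id == "printed_low", "nh3_ppbv"].iloc[0]
    print(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print(
        f"\nlow stream endmember: {low:.2f} ppbv "
        f"({float(f'{low:.1g}'):g} to one significant figure); "
        f"campaign range {df.nh3_ppbv.min():.1f}-{df.nh3_ppbv.max():.1f} ppbv"
    )


if __name__ == "__main__":
    main()
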