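"""Two-endmember mixing of droplet and air δ15N, and endmember recovery.

Each droplet and air sample is expressed as a mixture of the stream-air
pole (volatilized NH3, δ ≈ −27.3 ‰) and the surface pole (guano-derived N,
+15 ‰); out-of-hull samples are flagged rather than clamped. The script
then inverts the mixing model by least squares on the synthetic campaign
to show both endmembers are recoverable at the 0.3 ‰ analytical noise
level.
"""

import argparse
from pathlib import Path

import pandas as pd

from cavenit.config import Constants
from cavenit.isotopes import mixing_fraction
from cavenit.pipeline import recover_endmembers
from cavenit.samples import read_table
from cavenit.synthetic import CampaignConfig


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--campaign", default="results/campaign")
    ap.add_argument("--out", default="results/mixing_fractions.csv")
    args = ap.parse_args()

    c = Constants()
    droplets = read_table(Path(args.campaign) / "droplets.csv", "droplet")
    air = read_table(Path(args.campaign) / "air.csv", "air")

    rows = []
    for d in droplets:
        res = mixing_fraction(
            d.d15N_nh4_permil, c.stream_air_endmember_permil,
            c.surface_endmember_permil,
        )
        rows.append({"table": "droplet", "site_id": d.site_id,
                     "distance_m": d.distance_m, "d15N": d.d15N_nh4_permil,
                     "f_stream_air": res.f_A, "in_hull": res.in_hull})
    for a in air:
        if a.d15N_permil is None:
            continue
        res = mixing_fraction(
            a.d15N_permil, c.stream_air_endmember_permil,
            c.surface_endmember_permil,
        )
        rows.append({"table": "air", "site_id": a.site_id,
                     "distance_m": a.distance_m, "d15N": a.d15N_permil,
                     "f_stream_air": res.f_A, "in_hull": res.in_hull})
    df = pd.DataFrame(rows)
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)

    binned = df[df.table == "droplet"].groupby(
        pd.cut(df[df.table == "droplet"].distance_m, [0, 1.5, 12.5, 100]),
        observed=True,
    )["f_stream_air"].mean()
    print("mean droplet stream-air fraction by distance bin:")
    print(binned.to_string(float_format=lambda v: f"{v:.3f}"))
    print(f"out-of-hull samples: {int((~df.in_hull).sum())}/{len(df)}")

    cfg = CampaignConfig()  # recovery uses the configured decay length
    sub = df[df.table == "droplet"]
    est_air, est_surface = recover_endmembers(
        sub.distance_m, sub.d15N, cfg.mixing_length_m
    )
    print(
        f"recovered endmembers: stream-air {est_air:.2f} permil "
        f"(configured {cfg.endmember_stream_air_permil}), "
        f"surface {est_surface:.2f} permil "
        f"(configured {cfg.endmember_surface_permil})"
    )


if __name__ == "__main__":
    main()
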