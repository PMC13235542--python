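"""Gibbs-energy favorability of ammonia oxidation in acidic droplets.

Maps ΔG (kJ per mol N) for ammonia oxidation to nitrite (AOA/AOB) and to
nitrate (comammox) over pH 0–7 and 1 μM–10 mM total ammonium at 25 °C,
20.9% O2 and product activities of 1e-12. Both pathways stay exergonic
throughout — including the pH < 1, millimolar-NH4+ conditions of
condensation droplets — so the absence of ammonia oxidizers there is not
an energetic necessity.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cavenit.thermo import ammonia_oxidation_reactions, delta_g_grid


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", default="results/thermo")
    ap.add_argument("--n-ph", type=int, default=29)
    ap.add_argument("--n-nh4", type=int, default=25)
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    phs = np.linspace(0.0, 7.0, args.n_ph)
    concs = np.geomspace(1e-6, 1e-2, args.n_nh4)
    reactions = ammonia_oxidation_reactions("NH4+")

    for key in ("to_nitrite", "to_nitrate"):
        grid = delta_g_grid(reactions[key], phs, concs)
        df = pd.DataFrame(grid, index=phs,
                          columns=[f"{c:.3e}" for c in concs])
        df.index.name = "pH"
        df.to_csv(out / f"dG_{key}.csv")
        droplet = delta_g_grid(reactions[key], [0.8], [2.23e-3])[0, 0]
        print(
            f"{key}: dG0 = {reactions[key].dG0_kJ_mol:.2f} kJ/mol; "
            f"{int((grid < 0).sum())}/{grid.size} grid cells exergonic; "
            f"droplet conditions (pH 0.8, 2.23 mM): {droplet:.1f} kJ/mol N"
        )


if __name__ == "__main__":
    main()
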