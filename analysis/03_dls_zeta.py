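#!/usr/bin/env python
"""Hydrodynamic size and surface charge of the synthesis fractions.

Simulates DLS correlograms for the three sample presets (pellet,
supernatant, clodronate reference), runs the second-order cumulant
analysis on each, and aggregates synthetic replicate zeta series.
Writes results/dls_summary.csv and results/zeta_summary.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from lipoplex import dls, electrokinetics as ek, synth

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--replicates", type=int, default=10)
args = parser.parse_args()

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = []
for preset in synth.DLS_PRESETS:
    true_d, true_pdi = synth.dls_preset(preset)
    diams, pdis = [], []
    for i in range(args.replicates):
        trace, _ = synth.make_dls_dataset(
            preset, noise_sigma=0.005, seed=args.seed * 1000 + i
        )
        res = dls.cumulant_fit(trace)
        diams.append(res.hydrodynamic_diameter)
        pdis.append(res.pdi)
    rows.append(
        {
            "preset": preset,
            "true_diameter_nm": true_d,
            "true_pdi": true_pdi,
            "fitted_diameter_nm": np.mean(diams),
            "fitted_diameter_sd": np.std(diams, ddof=1),
            "fitted_pdi": np.mean(pdis),
        }
    )
dls_df = pd.DataFrame(rows)
dls_df.to_csv(OUT / "dls_summary.csv", index=False)

zrows = []
for preset in synth.ZETA_PRESETS:
    true_z, sigma, n = synth.zeta_preset(preset)
    values, _ = synth.make_zeta_replicates(true_z, sigma, n, seed=args.seed)
    s = ek.summarize_replicates(values)
    zrows.append(
        {
            "preset": preset,
            "true_zeta_mV": true_z,
            "mean_mV": s.mean,
            "sd_mV": s.sd,
            "n": s.n,
            "neutral": s.neutral,
        }
    )
zeta_df = pd.DataFrame(zrows)
zeta_df.to_csv(OUT / "zeta_summary.csv", index=False)

print(dls_df.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print()
print(zeta_df.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
print()
pellet = dls_df.set_index("preset").loc["pellet"]
print(
    f"Cumulant analysis recovers the pellet fraction at "
    f"{pellet.fitted_diameter_nm:.0f} nm (truth {pellet.true_diameter_nm:.0f} nm); "
    "the pellet zeta series is neutral while the supernatant carries the "
    "excess cationic-lipid charge."
)
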