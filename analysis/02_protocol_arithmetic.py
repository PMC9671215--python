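#!/usr/bin/env python
"""Synthesis-protocol solvent and formulation arithmetic.

Replays the two solvent-pooling steps of the protocol through the
mixing ledger, converts each composition to weight basis, classifies it
against the binodal, and reproduces the lipid-film formulation report.
Writes results/protocol_steps.csv and results/formulation_report.json.
"""

import json
from pathlib import Path

import pandas as pd

from lipoplex import formulation as f
from lipoplex import phase as ph

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

binodal = ph.load_default_binodal()

step1_adds = [(90, ph.PURE_WATER), (300, ph.PURE_METHANOL), (90, ph.PURE_CHLOROFORM)]
step2_adds = step1_adds + [(120, ph.PURE_CHLOROFORM), (120, ph.PURE_WATER)]

rows = []
for label, adds in [("step1_complexation", step1_adds), ("step2_compaction", step2_adds)]:
    vv = ph.mix(ph.MixtureLedger.from_pairs(adds))
    ww = ph.convert_basis(vv)
    rows.append(
        {
            "step": label,
            "total_volume_uL": sum(v for v, _ in adds),
            "water_vv": vv.water,
            "methanol_vv": vv.methanol,
            "chloroform_vv": vv.chloroform,
            "water_ww": ww.water,
            "methanol_ww": ww.methanol,
            "chloroform_ww": ww.chloroform,
            "phase": ph.classify_phase(vv, binodal).value,
        }
    )
steps = pd.DataFrame(rows)
steps.to_csv(OUT / "protocol_steps.csv", index=False)

rep = f.recipe_report(
    f.shell_lipid_recipe(),
    payload_monomer_umol=1.3,
    counterion_umol=3.0,
    payload_nmol=40.0,
    final_volume_uL=250.0,
    target_percent={"POPC": 60, "Chol": 30, "DSPE-PEG": 1, "DSPE-PEG-MAN": 9},
)
report = {
    "components": list(rep.names),
    "moles_nmol": list(rep.moles_nmol),
    "raw_mole_percent": list(rep.raw_percent),
    "report_mole_percent": list(rep.report_percent),
    "counterion_excess": rep.counterion_excess,
    "dose_nmol_per_uL": rep.dose_nmol_per_uL,
    "warnings": list(rep.warnings),
}
(OUT / "formulation_report.json").write_text(json.dumps(report, indent=2))

print(steps.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print()
print(
    "Shell lipid film:",
    " / ".join(f"{n} {p}%" for n, p in zip(rep.names, rep.report_percent)),
    f"(raw {', '.join(f'{p:.1f}' for p in rep.raw_percent)})",
)
print(
    f"Counterion excess {rep.counterion_excess:.2f}x stoichiometric demand; "
    f"payload dose {rep.dose_nmol_per_uL:.3f} nmol/uL in the final suspension."
)
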