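"""Dimension the centrifugation steps of the sample-preparation protocols.

Computes Stokes-law sedimentation distances for 20/40/60 nm anatase TiO2 at
2000 g over 30 min and 2 h spins, plus the time each size needs to clear the
1.75 cm liquid column of the centrifugation vial, and writes the protocol
presets.  A 2 h spin sediments even ~20-30 nm particles across most of the
column, which is why the sonication + 2 h protocol is the robust default.
"""

from pathlib import Path

import pandas as pd

from nanopartchar import protocol_design as pdn

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = []
for d_nm in (20, 40, 60):
    spec = pdn.SedimentationSpec(particle_diameter=d_nm)
    rows.append(
        {
            "diameter_nm": d_nm,
            "velocity_cm_per_h": round(pdn.stokes_velocity(spec), 3),
            "distance_30min_cm": pdn.sedimentation_distance(spec, 30),
            "distance_2h_cm": pdn.sedimentation_distance(spec, 120),
            "clearance_time_min_1p75cm": round(pdn.clearance_time(spec), 1),
        }
    )
table = pd.DataFrame(rows)
table.to_csv(OUT / "stokes_sedimentation.csv", index=False)

presets = pd.DataFrame([vars(pdn.protocol_preset(f"P{i}")) for i in range(1, 7)])
presets.to_csv(OUT / "protocol_presets.csv", index=False)

print(table.to_string(index=False))
print(f"\nwrote {OUT/'stokes_sedimentation.csv'} and {OUT/'protocol_presets.csv'}")
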