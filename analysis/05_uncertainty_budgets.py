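"""Uncertainty budgets of the spICP-MS measurands.

Combines the validation-study precision and trueness components into the
routine-conditions (three replicates, one day) combined and expanded
relative measurement uncertainties for the median ESD and the particle
mass and number concentrations.
"""

import math
from pathlib import Path

import pandas as pd

from nanopartchar import metrology as m
from nanopartchar.reference_data import SPICPMS_BUDGET_COMPONENTS

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = []
for measurand, comp in SPICPMS_BUDGET_COMPONENTS.items():
    s_d = (
        math.sqrt(comp["s_R"] ** 2 - comp["s_r"] ** 2)
        if "s_R" in comp
        else comp["between_day"]
    )
    budget = m.UncertaintyBudget(s_r=comp["s_r"], s_d=s_d, u_delta=comp["u_delta"],
                                 n_rep=3, n_days=1)
    rows.append({"measurand": measurand, **budget.display()})
table = pd.DataFrame(rows)
table.to_csv(OUT / "uncertainty_budgets.csv", index=False)
print(table.to_string(index=False))
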