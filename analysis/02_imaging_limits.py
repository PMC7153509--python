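"""Quantification windows of the TEM imaging configurations.

For each material's magnification/pixel size, derives the detection and
quantification limits (LLOD = pixel size, LLOQ = 10 x LLOD, ULOD = field
width, ULOQ = ULOD / 10) with a 4096-px camera.
"""

from pathlib import Path

import pandas as pd

from nanopartchar import tem_sizing as tem
from nanopartchar.reference_data import IMAGE_WIDTH_PX, IMAGING_CONDITIONS

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = []
for _, r in IMAGING_CONDITIONS.iterrows():
    cfg = tem.imaging_limits(r.pixel_nm, IMAGE_WIDTH_PX)
    rows.append(
        {
            "material": r.material,
            "magnification": r.magnification,
            "llod_nm": round(cfg.llod, 2),
            "lloq_nm": round(cfg.lloq, 1),
            "ulod_nm": round(cfg.ulod),
            "uloq_nm": round(cfg.uloq, 1),
            "analysis_mode": r.analysis_mode,
        }
    )
table = pd.DataFrame(rows)
table.to_csv(OUT / "imaging_limits.csv", index=False)
print(table.to_string(index=False))
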