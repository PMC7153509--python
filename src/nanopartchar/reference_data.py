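"""Published reference values used as worked-example inputs.

These are measured results for fifteen commercial E171 (food-grade TiO2)
materials and the validation-study precision/trueness components of the
spICP-MS method, kept here as plain literals so the classification and
uncertainty-budget stages can be exercised on real reported inputs.
"""

from __future__ import annotations

import pandas as pd

# Imaging conditions per material: magnification, pixel size (nm) and image
# analysis mode (4096-px camera).  Pixel sizes are the unrounded values
# consistent with the printed field widths (1.1548 nm -> 4730 nm, 0.8266 nm
# -> 3386 nm at 4096 px).
IMAGING_CONDITIONS = pd.DataFrame(
    [
        ("E171-01", 13000, 0.8266, "watershed"),
        ("E171-02", 9300, 1.1548, "ellipse"),
        ("E171-03", 9300, 1.1548, "ellipse"),
        ("E171-04", 9300, 1.1548, "ellipse"),
        ("E171-05", 13000, 0.8266, "watershed"),
        ("E171-06", 9300, 1.1548, "ellipse"),
        ("E171-07", 9300, 1.1548, "ellipse"),
        ("E171-08", 13000, 0.8266, "watershed"),
        ("E171-09", 9300, 1.1548, "ellipse"),
        ("E171-A", 9300, 1.1548, "ellipse"),
        ("E171-B", 9300, 1.1548, "ellipse"),
        ("E171-C", 9300, 1.1548, "ellipse"),
        ("E171-D", 9300, 1.1548, "ellipse"),
        ("E171-E", 9300, 1.1548, "ellipse"),
        ("E171-F", 9300, 1.1548, "ellipse"),
    ],
    columns=["material", "magnification", "pixel_nm", "analysis_mode"],
)
IMAGE_WIDTH_PX = 4096

# Median Fmin (nm) per material from quantitative TEM with the optimized
# preparation protocol: P1 for the three pearlescent pigments, P6 otherwise.
# Pearlescent pigments are rutile TiO2 on mica platelets with ~20-30 nm
# constituent particles; their uncertainty estimate comes from a small-
# particle reference material (9.2 % relative expanded uncertainty) versus
# 8.5 % for the ~100 nm materials.
TEM_MEDIAN_FMIN = pd.DataFrame(
    [
        ("E171-01", "pearlescent", 30.0),
        ("E171-02", "anatase", 79.0),
        ("E171-03", "anatase", 89.0),
        ("E171-04", "anatase", 86.0),
        ("E171-05", "pearlescent", 20.0),
        ("E171-06", "anatase", 88.0),
        ("E171-07", "anatase", 79.0),
        ("E171-08", "pearlescent", 17.0),
        ("E171-09", "anatase", 84.0),
        ("E171-A", "anatase", 110.0),
        ("E171-B", "anatase", 83.0),
        ("E171-C", "anatase", 94.0),
        ("E171-D", "anatase", 149.0),
        ("E171-E", "anatase", 86.0),
        ("E171-F", "rutile", 139.0),
    ],
    columns=["material", "structure", "median_fmin_nm"],
)

# Relative expanded uncertainties (k=2) of TEM medians from the validation
# study: keyed by descriptor and size regime.
TEM_RELATIVE_EXPANDED_UNCERTAINTY = {
    ("fmin", "large"): 0.085,
    ("fmin", "small"): 0.092,
    ("fmax", "large"): 0.091,
    ("fmax", "small"): 0.104,
    ("ar", "large"): 0.037,
    ("ar", "small"): 0.042,
}

# spICP-MS validation-study uncertainty components (relative %, from a
# 5-day x 3-replicate design on a ~100 nm TiO2 reference material) for the
# three measurands.  between_day for the concentration measurands follows
# the conservative convention (the full reproducibility SD).
SPICPMS_BUDGET_COMPONENTS = {
    "median_esd": {"s_r": 4.9, "s_R": 8.2, "u_delta": 5.1},
    "mass_concentration": {"s_r": 18.0, "between_day": 23.0, "u_delta": 11.0},
    "number_concentration": {"s_r": 17.0, "between_day": 13.0, "u_delta": 7.0},
}

# spICP-MS relative expanded uncertainties (k=2) applied to sample medians.
SPICPMS_RELATIVE_EXPANDED_UNCERTAINTY = {
    "median_esd": 0.18,
    "mass_concentration": 0.55,
    "number_concentration": 0.36,
}
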