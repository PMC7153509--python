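"""Measurement-uncertainty budgets for particle-characterization methods.

Precision is decomposed from a day × replicate validation design by one-way
analysis of variance into a repeatability (within-day) and a between-day
standard deviation.  Together with a trueness (bias) uncertainty these are
combined into the standard uncertainty of a routine result obtained as the
mean of ``n_rep`` replicates measured on ``n_days`` days::

    u_c = sqrt( s_r**2 / n_rep + s_d**2 / n_days + u_delta**2 )

and expanded with a coverage factor (k = 2 for ~95 % coverage).  All
components are handled as *relative* quantities in percent of the measurand.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PrecisionDesign",
    "UncertaintyBudget",
    "anova_precision",
    "combine_uncertainty",
    "expand_uncertainty",
    "apparent_trueness",
    "absolute_halfwidth",
    "round_half_away",
]


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round with ties going away from zero (display convention).

    Python's built-in ``round`` is banker's rounding; printed tables in
    metrology reports conventionally round 0.5 up.
    """
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class PrecisionDesign:
    """A day × replicate grid of measured values.

    Parameters
    ----------
    measurements:
        Tidy table with columns ``day``, ``replicate``, ``value``.  The grid
        may be unbalanced (unequal replicates per day); days with a single
        replicate contribute to the between-day estimate only.
    """

    measurements: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"day", "replicate", "value"}
        missing = required - set(self.measurements.columns)
        if missing:
            raise ValueError(f"precision design is missing columns: {sorted(missing)}")
        if self.measurements.empty:
            raise ValueError("precision design is empty")

    @property
    def n_days(self) -> int:
        return self.measurements["day"].nunique()

    @property
    def n_reps(self) -> int:
        return int(self.measurements.groupby("day")["value"].size().max())

    @classmethod
    def from_grid(cls, values: np.ndarray | Sequence[Sequence[float]]) -> "PrecisionDesign":
        """Build from a (n_days, n_reps) array."""
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2:
            raise ValueError("grid must be 2-D (days × replicates)")
        days, reps = np.meshgrid(np.arange(arr.shape[0]), np.arange(arr.shape[1]), indexing="ij")
        return cls(
            pd.DataFrame(
                {"day": days.ravel(), "replicate": reps.ravel(), "value": arr.ravel()}
            )
        )


@dataclass
class UncertaintyBudget:
    """Combined and expanded relative measurement uncertainty (percent)."""

    s_r: float
    s_d: float
    u_delta: float
    n_rep: int = 3
    n_days: int = 1
    k: float = 2.0
    u_c: float = field(init=False)
    U: float = field(init=False)

    def __post_init__(self) -> None:
        self.u_c = combine_uncertainty(
            self.s_r, self.s_d, self.u_delta, n_rep=self.n_rep, n_days=self.n_days
        )
        self.U = expand_uncertainty(self.u_c, k=self.k)

    def display(self) -> dict[str, float]:
        """Rounded values as printed in validation reports.

        u_c is shown to one decimal; the expanded uncertainty is the doubled
        *displayed* u_c, rounded to the nearest integer percent.
        """
        u_c_disp = round_half_away(self.u_c, 1)
        return {
            "repeatability_uncertainty_pct": round_half_away(self.s_r / math.sqrt(self.n_rep), 1),
            "between_day_uncertainty_pct": round_half_away(self.s_d / math.sqrt(self.n_days), 1),
            "trueness_uncertainty_pct": round_half_away(self.u_delta, 1),
            "combined_uncertainty_pct": u_c_disp,
            "expanded_uncertainty_pct": round_half_away(self.k * u_c_disp, 0),
        }


def anova_precision(design: PrecisionDesign) -> tuple[float, float, float]:
    """One-way ANOVA precision decomposition, in percent of the grand mean.

    Returns ``(s_r, s_d, s_R)``: repeatability, between-day and intermediate
    (reproducibility-like) relative standard deviations, with
    ``s_R**2 = s_r**2 + s_d**2``.

    The within-group mean square estimates the repeatability variance; the
    between-day variance component is ``max(0, (MS_between - MS_within) / n0)``
    where ``n0`` is the (average) number of replicates per day.  A negative
    component is clamped to zero with a warning.
    """
    df = design.measurements
    groups = df.groupby("day")["value"]
    n_days = groups.ngroups
    if n_days < 2:
        raise ValueError("between-day estimation needs at least 2 days")
    sizes = groups.size().to_numpy(dtype=float)
    if (sizes < 2).all():
        raise ValueError("at least one day needs >= 2 replicates")
    grand_mean = df["value"].mean()
    if grand_mean == 0:
        raise ValueError("grand mean is zero; relative SDs undefined")

    means = groups.mean().to_numpy()
    n_total = sizes.sum()
    ss_within = float(((df["value"] - df.groupby("day")["value"].transform("mean")) ** 2).sum())
    ms_within = ss_within / (n_total - n_days)
    ss_between = float((sizes * (means - grand_mean) ** 2).sum())
    ms_between = ss_between / (n_days - 1)
    # unbalanced-design effective group size (Searle's n0); equals n_reps when balanced
    n0 = (n_total - (sizes**2).sum() / n_total) / (n_days - 1)

    var_between = (ms_between - ms_within) / n0
    if var_between < 0:
        warnings.warn(
            "between-day variance component negative; clamped to zero", stacklevel=2
        )
        var_between = 0.0

    s_r = math.sqrt(ms_within) / abs(grand_mean) * 100.0
    s_d = math.sqrt(var_between) / abs(grand_mean) * 100.0
    s_R = math.hypot(s_r, s_d)
    return s_r, s_d, s_R


def combine_uncertainty(
    s_r: float, s_d: float, u_delta: float, n_rep: int = 3, n_days: int = 1
) -> float:
    """Combined standard uncertainty of an n_rep-replicate, n_days-day mean.

    u_c = sqrt(s_r²/n_rep + s_d²/n_days + u_Δ²), all in relative percent.
    """
    if min(s_r, s_d, u_delta) < 0:
        raise ValueError("uncertainty components must be non-negative")
    if n_rep < 1 or n_days < 1:
        raise ValueError("n_rep and n_days must be >= 1")
    return math.sqrt(s_r**2 / n_rep + s_d**2 / n_days + u_delta**2)


def expand_uncertainty(u_c: float, k: float = 2.0) -> float:
    """Expanded uncertainty U = k · u_c (k = 2 for ~95 % coverage)."""
    if u_c < 0:
        raise ValueError("u_c must be non-negative")
    return k * u_c


def apparent_trueness(measured_median: float, reference_median: float) -> float:
    """Recovery in percent of a reference value (e.g. spICP-MS median ESD
    against the TEM median Fmin of a representative test material)."""
    if reference_median == 0:
        raise ValueError("reference median must be non-zero")
    return 100.0 * measured_median / reference_median


def absolute_halfwidth(
    median: float, relative_expanded_uncertainty: float, decimals: int = 0
) -> float:
    """± half-width of an expanded-uncertainty interval in the median's units.

    ``median × relU`` rounded to the display precision of the median
    (integer nm for sizes, two decimals for aspect ratios).
    """
    if median <= 0 or relative_expanded_uncertainty <= 0:
        raise ValueError("median and relative uncertainty must be positive")
    return round_half_away(median * relative_expanded_uncertainty, decimals)
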