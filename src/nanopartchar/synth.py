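"""Synthetic ground-truth inputs for every pipeline stage.

Generates spICP-MS time traces (Poisson baseline plus particle plumes from a
lognormal size population), rasterized particle images for the TEM sizing
stage, and day × replicate precision tables — each paired with an exact
truth table so that estimator recovery can be checked against known values.

The default populations emulate the food-additive TiO2 materials the
pipeline targets: right-skewed lognormal diameters with medians around
60–125 nm, near-spherical projections (aspect ratios just above 1), TiO2
bulk density 4.23 g/cm³.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrology import PrecisionDesign
from .spicpms import (
    AcquisitionConfig,
    AnalyteSpec,
    TIO2_ANALYTE,
    TimeTrace,
    esd_to_mass,
)

__all__ = [
    "PopulationSpec",
    "TraceSimConfig",
    "sample_population",
    "simulate_trace",
    "render_particle_image",
    "simulate_precision_study",
]


@dataclass(frozen=True)
class PopulationSpec:
    """A lognormal particle population with near-spherical shape.

    size_median in nm, size_gsd the geometric SD (>= 1); the aspect-ratio
    distribution is lognormal shifted to [1, inf) via AR = exp(|N(ln m, ln g)|)
    truncation-free parameterization: draws below 1 are reflected.
    """

    size_median: float = 90.0
    size_gsd: float = 1.3
    ar_median: float = 1.16
    ar_gsd: float = 1.08
    density: float = 4.23
    number_concentration_per_L: float = 2.5e7  # diluted to the single-particle regime

    def __post_init__(self) -> None:
        if self.size_median <= 0 or self.ar_median < 1:
            raise ValueError("size median must be > 0 and AR median >= 1")
        if self.size_gsd < 1 or self.ar_gsd < 1:
            raise ValueError("geometric SDs must be >= 1")
        if self.density <= 0 or self.number_concentration_per_L < 0:
            raise ValueError("density must be positive, concentration non-negative")


@dataclass(frozen=True)
class TraceSimConfig:
    """Instrument model for trace simulation."""

    background_mean: float = 1.0      # counts/dwell
    sensitivity: float = 200.0        # counts per fg analyte
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    seed: int = 0
    split_fraction: float = 0.0       # fraction of plumes split over 2 dwells

    def __post_init__(self) -> None:
        if self.background_mean < 0 or self.sensitivity <= 0:
            raise ValueError("background_mean >= 0 and sensitivity > 0 required")
        if not 0 <= self.split_fraction <= 1:
            raise ValueError("split_fraction in [0, 1]")


def sample_population(
    pop: PopulationSpec, n: int, seed: int
) -> pd.DataFrame:
    """Draw ``n`` particles (esd_nm, ar) reproducibly from the population."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    esd = pop.size_median * np.exp(rng.normal(0.0, math.log(pop.size_gsd), n))
    ar_raw = pop.ar_median * np.exp(rng.normal(0.0, math.log(pop.ar_gsd), n))
    ar = np.maximum(ar_raw, 2.0 - ar_raw)  # reflect below-1 draws about 1
    ar = np.maximum(ar, 1.0)
    return pd.DataFrame({"esd_nm": esd, "ar": ar})


def simulate_trace(
    pop: PopulationSpec,
    cfg: TraceSimConfig,
    analyte: AnalyteSpec = TIO2_ANALYTE,
    n_dwells: int | None = None,
) -> tuple[TimeTrace, pd.DataFrame]:
    """Simulate a counts-per-dwell trace plus an exact particle truth table.

    Per dwell the baseline is Poisson(background_mean) and particle arrivals
    are Poisson(lambda) with lambda = number concentration × transport
    efficiency × flow × dwell time.  Each arriving particle draws its ESD
    from the population, is converted to analyte mass, and contributes
    Poisson-distributed counts with mean sensitivity × mass.  The
    single-particle regime requires lambda < 0.1; denser dispersions must be
    diluted (coincidence would merge particles).
    """
    acq = cfg.acquisition
    if n_dwells is None:
        n_dwells = int(round(acq.duration / acq.dwell_time))
    lam = (
        pop.number_concentration_per_L
        * acq.transport_efficiency
        * (acq.flow_rate / 1000.0 / 60.0)
        * acq.dwell_time
    )
    if lam >= 0.1:
        raise ValueError(
            f"coincidence regime: {lam:.3g} expected particles/dwell >= 0.1; dilute the sample"
        )
    rng = np.random.default_rng(cfg.seed)
    counts = rng.poisson(cfg.background_mean, n_dwells).astype(float)

    n_particles = rng.poisson(lam * n_dwells)
    truth_rows: list[dict] = []
    if n_particles > 0:
        dwell_idx = rng.integers(0, n_dwells, n_particles)
        particles = sample_population(pop, n_particles, seed=int(rng.integers(0, 2**31 - 1)))
        esds = particles["esd_nm"].to_numpy()
        masses_particle = esd_to_mass(esds, pop.density)
        masses_analyte = (
            masses_particle
            / analyte.mass_fraction_particle_to_analyte
            * analyte.ionization_efficiency
        )
        mean_counts = cfg.sensitivity * masses_analyte
        signal = rng.poisson(mean_counts).astype(float)
        split = rng.random(n_particles) < cfg.split_fraction
        for i in range(n_particles):
            idx = int(dwell_idx[i])
            if split[i] and idx + 1 < n_dwells:
                first = rng.binomial(int(signal[i]), 0.6)
                counts[idx] += first
                counts[idx + 1] += signal[i] - first
            else:
                counts[idx] += signal[i]
            truth_rows.append(
                {
                    "dwell_index": idx,
                    "esd_nm": float(esds[i]),
                    "mass_particle_fg": float(masses_particle[i]),
                    "signal_counts": float(signal[i]),
                    "split": bool(split[i] and idx + 1 < n_dwells),
                }
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=["dwell_index", "esd_nm", "mass_particle_fg", "signal_counts", "split"],
    )
    trace = TimeTrace(
        readings=counts,
        dwell_time=acq.dwell_time,
        sample_id=f"synthetic-seed{cfg.seed}",
        dilution_factor=acq.dilution_factor,
    )
    return trace, truth


def render_particle_image(
    particles: pd.DataFrame,
    canvas_px: int,
    pixel_nm: float,
    agglomeration_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Rasterize a particle sample as filled ellipses on a binary canvas.

    ``particles`` needs columns esd_nm and ar; each particle becomes an
    ellipse of equal projected area with the given aspect ratio, at a random
    position and orientation.  With ``agglomeration_fraction`` > 0 that
    share of particles is placed touching a previously placed one.  Returns
    the binary image and a truth table (center, axes, orientation in
    pixels/radians).
    """
    from skimage.draw import ellipse as draw_ellipse

    if not 0 <= agglomeration_fraction <= 1:
        raise ValueError("agglomeration_fraction in [0, 1]")
    rng = np.random.default_rng(seed)
    img = np.zeros((canvas_px, canvas_px), dtype=bool)
    rows: list[dict] = []
    placed: list[tuple[float, float, float]] = []  # (r, c, mean radius px)

    for _, p in particles.iterrows():
        esd_px = p["esd_nm"] / pixel_nm
        ar = max(float(p["ar"]), 1.0)
        # equal projected area: major*minor = esd^2, major/minor = ar
        minor = esd_px / math.sqrt(ar)
        major = esd_px * math.sqrt(ar)
        a, b = major / 2.0, minor / 2.0
        if major >= canvas_px / 2:
            raise ValueError("particle overflows the canvas; enlarge canvas_px")
        theta = rng.uniform(0, math.pi)
        margin = a + 2
        agglomerate = placed and rng.random() < agglomeration_fraction
        for _attempt in range(200):
            if agglomerate:
                pr, pc, prad = placed[rng.integers(0, len(placed))]
                phi = rng.uniform(0, 2 * math.pi)
                dist = prad + min(a, b) * 0.9  # touching/slightly overlapping
                r0, c0 = pr + dist * math.sin(phi), pc + dist * math.cos(phi)
            else:
                r0 = rng.uniform(margin, canvas_px - margin)
                c0 = rng.uniform(margin, canvas_px - margin)
            if not (margin <= r0 <= canvas_px - margin and margin <= c0 <= canvas_px - margin):
                continue
            rr, cc = draw_ellipse(r0, c0, a, b, shape=img.shape, rotation=theta)
            if agglomerate:
                break
            # forbid contact, not just overlap: check a 2-px-padded footprint
            rr_pad, cc_pad = draw_ellipse(r0, c0, a + 2, b + 2, shape=img.shape, rotation=theta)
            if not img[rr_pad, cc_pad].any():
                break
        else:
            raise ValueError("could not place particle without contact; canvas too crowded")
        img[rr, cc] = True
        placed.append((r0, c0, (a + b) / 2.0))
        rows.append(
            {
                "row_px": r0,
                "col_px": c0,
                "major_px": major,
                "minor_px": minor,
                "orientation_rad": theta,
                "esd_nm": float(p["esd_nm"]),
                "ar": ar,
                "agglomerated": bool(agglomerate),
            }
        )
    return img, pd.DataFrame(rows)


def simulate_precision_study(
    true_value: float,
    sigma_within_rel: float,
    sigma_between_rel: float,
    n_days: int = 5,
    n_reps: int = 3,
    seed: int = 0,
) -> PrecisionDesign:
    """Day × replicate table with known within/between-day relative SDs.

    value(day, rep) = true × (1 + delta_day + eps_rep) with independent
    normal effects; relative sigmas are fractions (0.049 for 4.9 %).
    """
    if sigma_within_rel < 0 or sigma_between_rel < 0:
        raise ValueError("sigmas must be >= 0")
    rng = np.random.default_rng(seed)
    day_eff = rng.normal(0.0, sigma_between_rel, n_days)
    rep_eff = rng.normal(0.0, sigma_within_rel, (n_days, n_reps))
    values = true_value * (1.0 + day_eff[:, None] + rep_eff)
    return PrecisionDesign.from_grid(values)
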