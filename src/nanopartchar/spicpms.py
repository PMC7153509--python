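"""Single-particle ICP-MS trace processing.

In time-resolved single-particle ICP-MS a dilute particle dispersion is
nebulized into the plasma and the detector signal is read out in short dwell
windows (milliseconds).  Dissolved analyte and instrument background produce
a low, stationary baseline; each particle that reaches the plasma produces a
short ion plume, seen as an isolated spike.  This module covers the full
chain from raw counts-per-dwell traces to particle size distributions:

1.  iterative mean + k·sigma outlier detection separates particle events
    from the baseline;
2.  an ionic (dissolved-standard) calibration plus the transport efficiency
    converts net event counts to analyte mass per particle;
3.  particle mass is converted to an equivalent spherical diameter (ESD)
    through the bulk density;
4.  event counts and masses over the effectively analyzed sample volume
    yield number and mass concentrations, and the background statistics give
    size detection/quantification limits.

Units are explicit throughout: counts per dwell, mL/min flow, fg mass, nm
diameter, g/cm³ density.  A femtogram of a solid with density rho g/cm³ has
volume 1e-15/rho cm³; diameters follow from the spherical mass–size relation
m = (pi/6)·rho·d³.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "TimeTrace",
    "AcquisitionConfig",
    "AnalyteSpec",
    "IonicCalibration",
    "ParticleEventSet",
    "ParticleResult",
    "DilutionCheckReport",
    "detect_events",
    "fit_ionic_calibration",
    "sensitivity_from_calibration",
    "transport_efficiency_frequency",
    "event_mass",
    "mass_to_esd",
    "esd_to_mass",
    "size_limits",
    "concentrations",
    "check_dilution_series",
    "summarize_spicpms",
    "TIO2_ANALYTE",
]

MergePolicy = Literal["merge", "drop", "keep"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TimeTrace:
    """Ordered counts-per-dwell readings with acquisition metadata."""

    readings: np.ndarray
    dwell_time: float  # seconds
    sample_id: str = ""
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        self.readings = np.asarray(self.readings, dtype=float)
        if self.readings.ndim != 1 or self.readings.size == 0:
            raise ValueError("trace must be a non-empty 1-D array of readings")
        if np.any(self.readings < 0):
            raise ValueError("counts must be non-negative")
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")

    @property
    def duration(self) -> float:
        """Total acquisition time in seconds."""
        return self.readings.size * self.dwell_time


@dataclass(frozen=True)
class AcquisitionConfig:
    """Instrument acquisition parameters.

    flow_rate in mL/min, transport_efficiency as a fraction in (0, 1],
    dwell_time and duration in seconds.
    """

    flow_rate: float = 0.47
    transport_efficiency: float = 0.048
    dwell_time: float = 0.003
    duration: float = 60.0
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if min(self.flow_rate, self.transport_efficiency, self.dwell_time, self.duration) <= 0:
            raise ValueError("acquisition parameters must be positive")
        if self.transport_efficiency > 1:
            raise ValueError("transport_efficiency is a fraction <= 1")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class AnalyteSpec:
    """Element/particle bookkeeping for mass conversion.

    mass_fraction_particle_to_analyte is the compound-to-element mass ratio
    (1.67 for TiO2/Ti); ionization_efficiency the detected fraction of
    analyte atoms (1.0 here).
    """

    element: str
    particle_density: float  # g/cm^3 of the particle compound
    mass_fraction_particle_to_analyte: float = 1.0
    ionization_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.particle_density <= 0:
            raise ValueError("particle density must be positive")
        if self.mass_fraction_particle_to_analyte < 1:
            raise ValueError("particle/analyte mass fraction must be >= 1")
        if not 0 < self.ionization_efficiency <= 1:
            raise ValueError("ionization efficiency must be in (0, 1]")


TIO2_ANALYTE = AnalyteSpec(
    element="Ti",
    particle_density=4.23,
    mass_fraction_particle_to_analyte=1.67,
    ionization_efficiency=1.0,
)


@dataclass
class IonicCalibration:
    """Ordinary least-squares ionic calibration line.

    slope in counts/dwell per (µg analyte / L), intercept in counts/dwell.
    """

    standards: list[tuple[float, float]]
    slope: float
    intercept: float
    r_squared: float


@dataclass
class ParticleEventSet:
    """Result of iterative baseline/event discrimination."""

    background_mean: float
    background_sd: float
    threshold: float
    events: np.ndarray  # net counts per event
    n_iterations: int
    sigma_multiplier: float = 5.0
    n_readings: int = 0

    @property
    def n_events(self) -> int:
        return int(self.events.size)


@dataclass
class ParticleResult:
    """Per-sample summary of an spICP-MS measurement."""

    masses_fg: np.ndarray
    esds_nm: np.ndarray
    median_esd_nm: float
    fraction_below_100nm: float
    number_concentration_per_L: float
    mass_concentration_g_per_L: float
    size_lod_nm: float
    size_loq_nm: float
    n_events: int
    number_concentration_per_kg_powder: Optional[float] = None
    mass_concentration_kg_per_kg_powder: Optional[float] = None
    low_size_peak_flag: bool = False
    eventset: Optional[ParticleEventSet] = None


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def detect_events(
    trace: TimeTrace,
    sigma_multiplier: float = 5.0,
    merge_policy: MergePolicy = "merge",
    max_iterations: int = 1000,
) -> ParticleEventSet:
    """Separate particle events from the baseline by iterative mean + k·sigma.

    Starting from all readings, the mean and SD (n-1 denominator) of the
    current inlier set define a threshold mu + k·sigma; readings above it are
    moved to the outlier (particle-candidate) set and the statistics are
    recomputed, until the inlier set is stable.  Runs of consecutive
    above-threshold dwells — ion plumes split over two dwell windows — are
    handled per ``merge_policy``:

    - ``merge`` (default): summed into one event (conserves particle mass);
    - ``drop``: multi-dwell runs discarded as incomplete events;
    - ``keep``: every dwell counted as its own event.
    """
    if sigma_multiplier <= 0:
        raise ValueError("sigma_multiplier must be positive")
    readings = trace.readings
    inlier = np.ones(readings.size, dtype=bool)
    mu = float(readings.mean())
    sd = float(readings.std(ddof=1)) if readings.size > 1 else 0.0
    threshold = mu + sigma_multiplier * sd
    n_iter = 0
    for n_iter in range(1, max_iterations + 1):
        new_inlier = readings <= threshold
        if np.array_equal(new_inlier, inlier):
            break
        inlier = new_inlier
        if not inlier.any():
            raise RuntimeError("event detection removed all readings; no baseline left")
        sub = readings[inlier]
        mu = float(sub.mean())
        sd = float(sub.std(ddof=1)) if sub.size > 1 else 0.0
        threshold = mu + sigma_multiplier * sd
    else:
        raise RuntimeError(
            f"event detection did not converge in {max_iterations} iterations "
            f"(last threshold {threshold:.3g}, {int((~inlier).sum())} outliers)"
        )

    outlier_idx = np.flatnonzero(~inlier)
    events: list[float] = []
    if outlier_idx.size:
        # split outlier indices into runs of consecutive dwells
        breaks = np.flatnonzero(np.diff(outlier_idx) > 1)
        runs = np.split(outlier_idx, breaks + 1)
        for run in runs:
            if len(run) == 1:
                events.append(float(readings[run[0]] - mu))
            elif merge_policy == "merge":
                events.append(float(readings[run].sum() - mu * len(run)))
            elif merge_policy == "keep":
                events.extend(float(readings[i] - mu) for i in run)
            # drop: multi-dwell runs discarded

    return ParticleEventSet(
        background_mean=mu,
        background_sd=sd,
        threshold=threshold,
        events=np.asarray(events, dtype=float),
        n_iterations=n_iter,
        sigma_multiplier=sigma_multiplier,
        n_readings=readings.size,
    )


# ---------------------------------------------------------------------------
# calibration and mass conversion
# ---------------------------------------------------------------------------

def fit_ionic_calibration(standards: Sequence[tuple[float, float]]) -> IonicCalibration:
    """OLS fit of mean intensity (counts/dwell) vs ionic concentration (µg/L)."""
    pts = [(float(c), float(i)) for c, i in standards]
    conc = np.array([p[0] for p in pts])
    inten = np.array([p[1] for p in pts])
    if conc.size < 2 or np.unique(conc).size < 2:
        raise ValueError("calibration needs >= 2 distinct concentrations")
    A = np.vstack([conc, np.ones_like(conc)]).T
    (slope, intercept), res, *_ = np.linalg.lstsq(A, inten, rcond=None)
    ss_tot = float(((inten - inten.mean()) ** 2).sum())
    ss_res = float(res[0]) if res.size else float(((inten - A @ [slope, intercept]) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return IonicCalibration(standards=pts, slope=float(slope), intercept=float(intercept), r_squared=r2)


def sensitivity_from_calibration(cal: IonicCalibration, acq: AcquisitionConfig) -> float:
    """Counts per fg of analyte reaching the plasma, per dwell.

    A standard at 1 µg/L (= 1e6 fg/mL) delivers
    ``W_unit = eta * (q/60 mL/s) * t_dwell * 1e6`` fg of analyte to the
    plasma per dwell; the sensitivity is the calibration slope divided by
    this unit mass flux.
    """
    if cal.slope <= 0:
        raise ValueError("calibration slope must be positive")
    w_unit_fg = (
        acq.transport_efficiency * (acq.flow_rate / 60.0) * acq.dwell_time * 1e6
    )
    return cal.slope / w_unit_fg


def transport_efficiency_frequency(
    n_detected: int,
    acq: AcquisitionConfig,
    reference_diameter_nm: float,
    reference_density: float,
    reference_mass_concentration_ng_L: float,
) -> float:
    """Transport efficiency by the particle-frequency method.

    A reference dispersion of monodisperse particles of known size, density
    and mass concentration (e.g. 30 nm gold at 12.5 ng/L) is measured; the
    ratio of detected events to the number of particles nebulized during the
    run is the transport efficiency.
    """
    if n_detected < 0:
        raise ValueError("n_detected must be >= 0")
    single_mass_g = esd_to_mass(reference_diameter_nm, reference_density) * 1e-15
    number_conc_per_L = reference_mass_concentration_ng_L * 1e-9 / single_mass_g
    nebulized = number_conc_per_L * (acq.flow_rate / 1000.0 / 60.0) * acq.duration
    if nebulized <= 0:
        raise ValueError("expected particle count is zero; check the reference spec")
    eta = n_detected / nebulized
    if eta == 0:
        warnings.warn("no particles detected; transport efficiency is 0", stacklevel=2)
    return eta


def event_mass(net_counts: float | np.ndarray, sensitivity: float, analyte: AnalyteSpec):
    """Particle-compound mass (fg) from net event counts.

    m_analyte = counts / S; m_particle = m_analyte × (compound/analyte mass
    ratio) / ionization efficiency.
    """
    if sensitivity <= 0:
        raise ValueError("sensitivity must be positive")
    counts = np.asarray(net_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("net counts must be non-negative")
    mass = counts / sensitivity * analyte.mass_fraction_particle_to_analyte / analyte.ionization_efficiency
    return float(mass) if np.isscalar(net_counts) else mass


def mass_to_esd(mass_fg: float | np.ndarray, density: float):
    """Equivalent spherical diameter (nm) of a particle of given mass (fg).

    d = (6 m / (pi rho))^(1/3); 1 fg of material at rho g/cm³ occupies
    1e-15/rho cm³ and 1 cm = 1e7 nm.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    mass = np.asarray(mass_fg, dtype=float)
    if np.any(mass < 0):
        raise ValueError("mass must be non-negative")
    d_cm = np.cbrt(6.0 * mass * 1e-15 / (math.pi * density))
    d_nm = d_cm * 1e7
    return float(d_nm) if np.isscalar(mass_fg) else d_nm


def esd_to_mass(diameter_nm: float | np.ndarray, density: float):
    """Inverse of :func:`mass_to_esd`: spherical particle mass in fg."""
    if density <= 0:
        raise ValueError("density must be positive")
    d_cm = np.asarray(diameter_nm, dtype=float) * 1e-7
    mass_fg = math.pi / 6.0 * density * d_cm**3 * 1e15
    return float(mass_fg) if np.isscalar(diameter_nm) else mass_fg


# ---------------------------------------------------------------------------
# limits and concentrations
# ---------------------------------------------------------------------------

def size_limits(
    eventset: ParticleEventSet,
    sensitivity: float,
    analyte: AnalyteSpec,
    floor_counts: float = 4.0,
    lod_sigma_multiplier: float = 3.0,
    loq_sigma_multiplier: float = 10.0,
) -> tuple[float, float]:
    """Size detection and quantification limits (nm).

    The LOD intensity is mean + 3·sigma of the background, but never below a
    hard counting floor (4 counts by default — with very clean backgrounds
    the statistical limit falls below what a single ion plume can reliably
    produce).  The LOQ uses a 10·sigma multiplier, same floor.  Both are
    converted to diameters through the mass calibration.
    """
    if sensitivity <= 0:
        raise ValueError("sensitivity must be positive")
    mu, sd = eventset.background_mean, eventset.background_sd
    lod_counts = max(mu + lod_sigma_multiplier * sd, floor_counts)
    loq_counts = max(mu + loq_sigma_multiplier * sd, floor_counts)
    lod_nm = mass_to_esd(event_mass(lod_counts, sensitivity, analyte), analyte.particle_density)
    loq_nm = mass_to_esd(event_mass(loq_counts, sensitivity, analyte), analyte.particle_density)
    return lod_nm, loq_nm


def concentrations(
    eventset: ParticleEventSet,
    masses_fg: np.ndarray,
    acq: AcquisitionConfig,
    powder_loading_g_per_L: Optional[float] = None,
) -> dict[str, float]:
    """Number and mass concentrations in the undiluted dispersion.

    The effective analyzed volume is ``V_eff = eta · q · t`` (the fraction of
    the nebulized volume that reached the plasma).  Dispersion
    concentrations are dilution-corrected; when the powder loading of the
    dispersion is given, per-kg-of-powder values are added.
    """
    v_eff_mL = acq.transport_efficiency * acq.flow_rate * acq.duration / 60.0
    if v_eff_mL <= 0:
        raise ValueError("effective analyzed volume is zero")
    v_eff_L = v_eff_mL / 1000.0
    n = eventset.n_events
    number_conc = n / v_eff_L * acq.dilution_factor
    mass_conc_g_L = float(np.sum(masses_fg)) * 1e-15 / v_eff_L * acq.dilution_factor
    out = {
        "number_concentration_per_L": number_conc,
        "mass_concentration_g_per_L": mass_conc_g_L,
    }
    if powder_loading_g_per_L is not None:
        if powder_loading_g_per_L <= 0:
            raise ValueError("powder loading must be positive")
        out["number_concentration_per_kg_powder"] = number_conc / (powder_loading_g_per_L / 1000.0)
        out["mass_concentration_kg_per_kg_powder"] = mass_conc_g_L / powder_loading_g_per_L
    return out


@dataclass
class DilutionCheckReport:
    """Quality flags for a dilution series."""

    proportionality_pass: bool
    size_consistency_pass: bool
    count_range_pass: bool
    corrected_counts: list[float]
    details: str = ""

    @property
    def all_pass(self) -> bool:
        return self.proportionality_pass and self.size_consistency_pass and self.count_range_pass


def check_dilution_series(
    results: Sequence[tuple[float, int, float]],
    count_rtol: float = 0.20,
    size_rtol: float = 0.10,
    count_range: tuple[int, int] = (200, 2200),
) -> DilutionCheckReport:
    """Validate a dilution series of (dilution_factor, n_events, median_esd).

    A well-behaved series shows dilution-corrected event counts equal within
    ``count_rtol``, constant median size within ``size_rtol``, and every raw
    count inside the workable range (defaults 200–2200 detected particles).
    """
    if len(results) < 2:
        raise ValueError("dilution check needs >= 2 dilution levels")
    corrected = [df * n for df, n, _ in results]
    sizes = [s for _, _, s in results]
    counts = [n for _, n, _ in results]
    ref_c = float(np.mean(corrected))
    prop_ok = all(abs(c - ref_c) <= count_rtol * ref_c for c in corrected)
    ref_s = float(np.mean(sizes))
    size_ok = all(abs(s - ref_s) <= size_rtol * ref_s for s in sizes)
    range_ok = all(count_range[0] <= n <= count_range[1] for n in counts)
    return DilutionCheckReport(
        proportionality_pass=prop_ok,
        size_consistency_pass=size_ok,
        count_range_pass=range_ok,
        corrected_counts=corrected,
        details=f"corrected counts {corrected}, sizes {sizes}",
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def summarize_spicpms(
    trace: TimeTrace,
    calibration: IonicCalibration,
    acq: AcquisitionConfig,
    analyte: AnalyteSpec = TIO2_ANALYTE,
    powder_loading_g_per_L: Optional[float] = None,
    sigma_multiplier: float = 5.0,
    merge_policy: MergePolicy = "merge",
) -> ParticleResult:
    """Full trace-to-report pipeline.

    Composes event detection, mass calibration, size conversion, limits and
    concentrations into a per-sample summary.  The low-size-peak flag marks
    size distributions whose mode sits in the first decile above the LOD — a
    programmatic stand-in for the visual check that event discrimination did
    not truncate into the baseline.
    """
    eventset = detect_events(trace, sigma_multiplier=sigma_multiplier, merge_policy=merge_policy)
    sensitivity = sensitivity_from_calibration(calibration, acq)
    masses = event_mass(eventset.events, sensitivity, analyte) if eventset.n_events else np.array([])
    esds = mass_to_esd(masses, analyte.particle_density) if eventset.n_events else np.array([])
    lod_nm, loq_nm = size_limits(eventset, sensitivity, analyte)
    conc = concentrations(eventset, masses, acq, powder_loading_g_per_L)

    if eventset.n_events:
        median_esd = float(np.median(esds))
        frac_below = float(np.mean(esds < 100.0))
        # low-size peak: histogram mode within 10% above the detection limit
        hist, edges = np.histogram(esds, bins=32)
        mode_center = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        low_peak = mode_center <= lod_nm * 1.1
    else:
        median_esd = math.nan
        frac_below = math.nan
        low_peak = False

    return ParticleResult(
        masses_fg=masses,
        esds_nm=esds,
        median_esd_nm=median_esd,
        fraction_below_100nm=frac_below,
        number_concentration_per_L=conc["number_concentration_per_L"],
        mass_concentration_g_per_L=conc["mass_concentration_g_per_L"],
        size_lod_nm=lod_nm,
        size_loq_nm=loq_nm,
        n_events=eventset.n_events,
        number_concentration_per_kg_powder=conc.get("number_concentration_per_kg_powder"),
        mass_concentration_kg_per_kg_powder=conc.get("mass_concentration_kg_per_kg_powder"),
        low_size_peak_flag=low_peak,
        eventset=eventset,
    )
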