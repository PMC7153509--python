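"""TEM particle-size-distribution analysis of constituent particles.

Electron micrographs of a particulate material are reduced to per-particle
shape descriptors — the maximum and minimum Feret (caliper) diameters and
their ratio — and then to number-weighted distribution statistics following
ISO 9276 conventions.  Descriptors outside the quantifiable window of the
imaging setup are excluded: the pixel size sets the lower limit of detection
(LLOD), ten pixels the lower limit of quantification (Merkus criterion), and
one tenth of the field of view the upper limit of quantification.

The EC recommendation classifies a material as a nanomaterial when the
median minimal external dimension of its constituent particles (assessed as
the median Fmin) is below 100 nm; a stricter call adds the expanded
measurement uncertainty before comparing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.stats import gaussian_kde
from skimage import measure, segmentation
from skimage.feature import peak_local_max

__all__ = [
    "ImagingConfig",
    "ParticleProjection",
    "SizeDistributionSummary",
    "imaging_limits",
    "feret_extents",
    "ellipse_fit",
    "segment_particles",
    "apply_quantification_limits",
    "distribution_summary",
    "classify_ec_nanomaterial",
    "default_relative_expanded_uncertainty",
]


@dataclass(frozen=True)
class ImagingConfig:
    """Imaging magnification window and the derived quantification limits (nm)."""

    pixel_size: float     # nm/pixel = LLOD
    image_width: int      # pixels
    llod: float
    lloq: float
    ulod: float
    uloq: float


def imaging_limits(pixel_size: float, image_width: int) -> ImagingConfig:
    """Detection/quantification limits of a TEM imaging configuration.

    LLOD = pixel size; LLOQ = 10 × LLOD; ULOD = field width; ULOQ = ULOD/10.
    """
    if pixel_size <= 0 or image_width <= 0:
        raise ValueError("pixel_size and image_width must be positive")
    llod = pixel_size
    ulod = pixel_size * image_width
    return ImagingConfig(
        pixel_size=pixel_size,
        image_width=image_width,
        llod=llod,
        lloq=10.0 * llod,
        ulod=ulod,
        uloq=ulod / 10.0,
    )


@dataclass
class ParticleProjection:
    """2-D particle projection descriptors (nm).

    For ellipse-fit mode the full major/minor axes stand in for Fmax/Fmin.
    """

    fmin: float
    fmax: float
    outline: Optional[np.ndarray] = None
    ellipse_major: Optional[float] = None
    ellipse_minor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.fmin > self.fmax:
            raise ValueError("Fmin cannot exceed Fmax")

    @property
    def ar(self) -> float:
        return self.fmax / self.fmin

    @classmethod
    def from_outline(cls, outline: np.ndarray) -> "ParticleProjection":
        fmin, fmax = feret_extents(outline)
        return cls(fmin=fmin, fmax=fmax, outline=np.asarray(outline, dtype=float))

    @classmethod
    def from_ellipse(cls, major: float, minor: float) -> "ParticleProjection":
        return cls(fmin=minor, fmax=major, ellipse_major=major, ellipse_minor=minor)


def feret_extents(outline: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Minimum and maximum Feret (caliper) diameters of a planar outline.

    Rotating calipers on the convex hull: the maximum Feret diameter is the
    hull diameter (max vertex-pair distance); the minimum Feret diameter is
    the smallest width over directions perpendicular to hull edges (the
    minimum width of a convex polygon is always attained flush with an edge).
    """
    pts = np.asarray(outline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("outline must be an (n >= 3, 2) vertex array")
    try:
        hull = ConvexHull(pts)
    except Exception as exc:  # qhull raises on collinear input
        raise ValueError("degenerate (collinear) outline") from exc
    hp = pts[hull.vertices]

    diffs = hp[:, None, :] - hp[None, :, :]
    fmax = float(np.sqrt((diffs**2).sum(-1)).max())

    edges = np.roll(hp, -1, axis=0) - hp
    lengths = np.linalg.norm(edges, axis=1)
    normals = np.stack([-edges[:, 1], edges[:, 0]], axis=1) / lengths[:, None]
    # width along each edge normal = spread of vertex projections
    proj = hp @ normals.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    fmin = float(widths.min())
    return fmin, fmax


def ellipse_fit(mask: np.ndarray, pixel_size: float = 1.0) -> tuple[float, float]:
    """Full axes (nm) of the moments-equivalent ellipse of a binary mask.

    4·sqrt(eigenvalues) of the central second-moment matrix — the ellipse
    with the same normalized second moments as the region.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    major = props.axis_major_length * pixel_size
    minor = props.axis_minor_length * pixel_size
    return float(major), float(minor)


def segment_particles(
    binary_image: np.ndarray, mode: str = "components", min_distance: int = 5
) -> list[np.ndarray]:
    """Split a binary particle image into per-particle boolean masks.

    ``components`` labels 8-connected foreground regions; ``watershed_split``
    additionally splits touching convex blobs by a distance-transform
    watershed seeded at distance-map maxima.
    """
    img = np.asarray(binary_image)
    uniq = np.unique(img)
    if not np.all(np.isin(uniq, [0, 1])) and img.dtype != bool:
        raise ValueError("input image must be binary")
    img = img.astype(bool)
    if not img.any():
        return []

    if mode == "components":
        labels, _ = ndimage.label(img, structure=np.ones((3, 3), dtype=int))
    elif mode == "watershed_split":
        dist = ndimage.distance_transform_edt(img)
        coords = peak_local_max(dist, labels=img, min_distance=min_distance, exclude_border=False)
        markers = np.zeros_like(img, dtype=np.int32)
        for i, (r, c) in enumerate(coords, start=1):
            markers[r, c] = i
        if markers.max() == 0:
            labels, _ = ndimage.label(img, structure=np.ones((3, 3), dtype=int))
        else:
            labels = segmentation.watershed(-dist, markers, mask=img)
    else:
        raise ValueError(f"unknown segmentation mode {mode!r}")

    return [labels == lab for lab in range(1, labels.max() + 1) if np.any(labels == lab)]


def apply_quantification_limits(
    values_nm: Sequence[float], config: ImagingConfig
) -> tuple[np.ndarray, float, float]:
    """Strictly exclude measurements outside [LLOQ, ULOQ].

    Returns the retained values plus the excluded fractions below and above.
    """
    v = np.asarray(values_nm, dtype=float)
    if v.size == 0:
        return v, 0.0, 0.0
    below = v < config.lloq
    above = v > config.uloq
    retained = v[~below & ~above]
    return retained, float(below.mean()), float(above.mean())


@dataclass
class SizeDistributionSummary:
    """Number-weighted distribution statistics of one descriptor."""

    n: int
    median: float
    mode: float
    q25: float
    q75: float
    fraction_below_100nm: float
    hist_edges: np.ndarray
    hist_density: np.ndarray
    kde_grid: np.ndarray
    kde_density: np.ndarray


def distribution_summary(
    values: Sequence[float],
    kde_bandwidth: str | float = "silverman",
    n_bins: int = 64,
    grid_points: int = 512,
    hist_range: Optional[tuple[float, float]] = None,
) -> SizeDistributionSummary:
    """ISO 9276-style number-weighted summary of a descriptor sample.

    Quantiles use linear interpolation between order statistics.  The mode
    is taken from a Gaussian-kernel KDE (Silverman bandwidth by default)
    evaluated on a ``grid_points``-point grid spanning the data range ± 3
    bandwidths; histogram densities are normalized so that density × bin
    width sums to one.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    frac_below = float(np.mean(v < 100.0))

    lo, hi = hist_range if hist_range is not None else (v.min(), v.max())
    if hi - lo <= max(abs(lo), 1.0) * 1e-9:  # (near-)degenerate range
        hi = lo + 1.0
    hist_density, hist_edges = np.histogram(v, bins=n_bins, range=(lo, hi), density=True)

    if np.ptp(v) == 0 or v.size < 2:
        # degenerate: KDE undefined; the distribution is a point mass
        grid = np.linspace(v[0] - 1, v[0] + 1, grid_points)
        dens = np.zeros(grid_points)
        dens[np.argmin(np.abs(grid - v[0]))] = 1.0
        mode = float(v[0])
    else:
        kde = gaussian_kde(v, bw_method=kde_bandwidth)
        h = kde.factor * v.std(ddof=1)
        grid = np.linspace(v.min() - 3 * h, v.max() + 3 * h, grid_points)
        dens = kde(grid)
        mode = float(grid[np.argmax(dens)])  # argmax takes the first (smallest) tie

    return SizeDistributionSummary(
        n=int(v.size),
        median=float(med),
        mode=mode,
        q25=float(q25),
        q75=float(q75),
        fraction_below_100nm=frac_below,
        hist_edges=hist_edges,
        hist_density=hist_density,
        kde_grid=grid,
        kde_density=dens,
    )


def default_relative_expanded_uncertainty(median_nm: float, switch_nm: float = 50.0) -> float:
    """Size-regime default for the relative expanded uncertainty (k = 2) of a
    median Fmin: 9.2 % for small-particle materials (validated on a ~25 nm
    TiO2 reference), 8.5 % for ~100 nm materials."""
    return 0.092 if median_nm < switch_nm else 0.085


def classify_ec_nanomaterial(
    median_fmin_nm: float, relative_expanded_uncertainty: float
) -> dict[str, bool]:
    """EC nanomaterial classification from the median minimal external dimension.

    ``is_nanomaterial``: median Fmin < 100 nm.  ``significantly_below_100``:
    still below 100 nm after adding the expanded uncertainty
    (median × (1 + relU) < 100).
    """
    if median_fmin_nm <= 0 or relative_expanded_uncertainty <= 0:
        raise ValueError("median and uncertainty must be positive")
    return {
        "is_nanomaterial": median_fmin_nm < 100.0,
        "significantly_below_100": median_fmin_nm * (1.0 + relative_expanded_uncertainty) < 100.0,
    }
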