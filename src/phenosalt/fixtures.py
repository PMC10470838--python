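"""Seeded synthetic data generators with analytic ground truth.

Everything downstream is testable offline: hyperspectral scenes with a known
vegetation mask and a stress-severity knob, canopy point clouds with
closed-form height/footprint/hull-volume truth and labelled outliers, and
trait matrices with a planted latent tolerance ordering.

All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from phenosalt.fce import TraitMatrix
from phenosalt.spectral import INDEX_NAMES, HyperCube, VegetationMask
from phenosalt.structural import PointCloud

__all__ = [
    "SceneSpec",
    "CanopySpec",
    "CohortSpec",
    "make_scene",
    "make_canopy",
    "make_cohort",
    "vegetation_spectrum",
    "background_spectrum",
    "CPT_TRAIT_NAMES",
]

#: Canonical 19-trait naming: 3 structural + 16 spectral.
CPT_TRAIT_NAMES: tuple[str, ...] = ("Height", "Leaf-area", "Volume") + INDEX_NAMES


# ---------------------------------------------------------------------------
# Hyperspectral scenes


@dataclass(frozen=True)
class SceneSpec:
    rows: int = 48
    cols: int = 48
    band_start: float = 400.0
    band_end: float = 1000.0
    band_step: float = 5.0
    stress: float = 0.0
    #: (row, col, radius) circles of vegetation, in pixels
    vegetation_blobs: tuple[tuple[float, float, float], ...] = ((24.0, 24.0, 14.0),)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.stress <= 1.0:
            raise ValueError("stress must be in [0, 1]")
        if self.band_start > 400.0 or self.band_end < 1000.0:
            raise ValueError("band range must cover 400-1000 nm")
        if self.band_step <= 0:
            raise ValueError("band_step must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def vegetation_spectrum(wavelengths: np.ndarray, stress: float = 0.0) -> np.ndarray:
    """Smooth parametric leaf-like reflectance over 400-1000 nm.

    Green peak near 550 nm, red absorption near 670 nm, logistic red edge to
    a NIR plateau, and a water absorption dip near 970 nm. Raising ``stress``
    monotonically raises red reflectance, lowers the NIR plateau and
    shallows the water dip.
    """
    wl = np.asarray(wavelengths, dtype=float)
    base = 0.03
    green = 0.10 * _gauss(wl, 550.0, 25.0)
    plateau = 0.50 - 0.22 * stress
    red_edge = plateau / (1.0 + np.exp(-(wl - 715.0) / 12.0))
    red_boost = 0.14 * stress * _gauss(wl, 670.0, 35.0)
    water_dip = 0.10 * (1.0 - 0.6 * stress) * _gauss(wl, 970.0, 22.0)
    water_dip = water_dip * (wl > 850.0)  # confine the dip to the NIR
    refl = base + green + red_edge + red_boost - water_dip
    return np.clip(refl, 0.005, 1.0)


def background_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Featureless soil-like ramp, brightening toward longer wavelengths."""
    wl = np.asarray(wavelengths, dtype=float)
    return 0.15 + 0.17 * (wl - 400.0) / 600.0


def make_scene(spec: SceneSpec) -> tuple[HyperCube, VegetationMask]:
    """Synthetic reflectance cube plus its true vegetation mask."""
    rng = np.random.default_rng(spec.seed)
    n_bands = int(round((spec.band_end - spec.band_start) / spec.band_step)) + 1
    wavelengths = spec.band_start + spec.band_step * np.arange(n_bands)

    rr, cc = np.meshgrid(
        np.arange(spec.rows), np.arange(spec.cols), indexing="ij"
    )
    mask = np.zeros((spec.rows, spec.cols), dtype=bool)
    for r0, c0, radius in spec.vegetation_blobs:
        mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2

    veg = vegetation_spectrum(wavelengths, spec.stress)
    soil = background_spectrum(wavelengths)
    cube = np.where(mask[:, :, None], veg, soil)
    if spec.noise_sd > 0:
        cube = cube + rng.normal(0.0, spec.noise_sd, size=cube.shape)
    cube = np.clip(cube, 1e-4, 1.2)
    return (
        HyperCube(reflectance=cube, wavelengths=wavelengths),
        VegetationMask(mask=mask, threshold_used=float("nan")),
    )


# ---------------------------------------------------------------------------
# Canopy point clouds


@dataclass(frozen=True)
class CanopySpec:
    shape: str = "box"  # box | hemisphere | ellipsoid
    #: box: (length, width, height); hemisphere: (radius,);
    #: ellipsoid: (a, b, c) semi-axes of a ground-standing dome
    dimensions: tuple[float, ...] = (20.0, 20.0, 15.0)
    point_density: float = 4.0  # points per cm^2 of surface
    outlier_count: int = 0
    jitter_sd: float = 0.0  # cm
    seed: int = 0

    def __post_init__(self) -> None:
        expected = {"box": 3, "hemisphere": 1, "ellipsoid": 3}
        if self.shape not in expected:
            raise ValueError(f"unknown canopy shape {self.shape!r}")
        if len(self.dimensions) != expected[self.shape]:
            raise ValueError(
                f"{self.shape} needs {expected[self.shape]} dimension(s)"
            )
        if any(d <= 0 for d in self.dimensions):
            raise ValueError("dimensions must be positive")
        if self.point_density <= 0:
            raise ValueError("point_density must be positive")
        if self.outlier_count < 0 or self.jitter_sd < 0:
            raise ValueError("outlier_count and jitter_sd must be non-negative")


@dataclass
class CanopyTruth:
    """Closed-form trait values for a generated canopy.

    ``height`` is the continuous limit of the grid-mean height rule (for the
    curved shapes the mean of the surface height over the footprint),
    ``footprint_area`` the analytic footprint, ``volume`` the solid volume.
    """

    height: float
    footprint_area: float
    volume: float


def _centers(length: float, step: float) -> np.ndarray:
    n = max(1, int(round(length / step)))
    return step / 2 + step * np.arange(n)


def _sample_box(dims: tuple[float, ...], density: float) -> np.ndarray:
    """Scan-like lattice sampling of a box canopy.

    Top and bottom faces share one x-y lattice (so occupied grid cells are
    well defined at the nominal density); side walls sit a quarter-step
    inside the bounding planes so they never spill into an extra grid column.
    """
    L, W, H = dims
    s = 1.0 / np.sqrt(density)
    xs, ys, zs = _centers(L, s), _centers(W, s), _centers(H, s)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    top = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, H)])
    bottom = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    zlev = np.concatenate([[0.0], zs, [H]])
    parts = [top, bottom]
    for x0 in (s / 4, L - s / 4):
        gy2, gz2 = np.meshgrid(ys, zlev, indexing="ij")
        parts.append(
            np.column_stack([np.full(gy2.size, x0), gy2.ravel(), gz2.ravel()])
        )
    for y0 in (s / 4, W - s / 4):
        gx2, gz2 = np.meshgrid(xs, zlev, indexing="ij")
        parts.append(
            np.column_stack([gx2.ravel(), np.full(gx2.size, y0), gz2.ravel()])
        )
    return np.vstack(parts)


def _sample_dome(abc: tuple[float, float, float], density: float) -> np.ndarray:
    """Scan-like lattice sampling of a ground-standing half-ellipsoid.

    The dome surface and its base are sampled on the same footprint lattice,
    so the base closes the hull without occupying extra grid cells.
    """
    a, b, c = abc
    s = 1.0 / np.sqrt(density)
    xs = _centers(2 * a, s) - a
    ys = _centers(2 * b, s) - b
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    rho = (gx / a) ** 2 + (gy / b) ** 2
    inside = rho < 1.0
    x, y = gx[inside], gy[inside]
    z = c * np.sqrt(1.0 - rho[inside])
    surface = np.column_stack([x, y, z])
    base = np.column_stack([x, y, np.zeros_like(x)])
    return np.vstack([surface, base])


def make_canopy(
    spec: CanopySpec,
) -> tuple[PointCloud, CanopyTruth, np.ndarray]:
    """Canopy cloud, closed-form truth, and a boolean outlier label array.

    Outliers are sampled in an inflated shell around the canopy bounding
    box (outside 1.3x, inside 2x the box half-extent, centred on it) so the
    default statistical filter can remove exactly them.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.shape == "box":
        L, W, H = spec.dimensions
        surface = _sample_box(spec.dimensions, spec.point_density)
        truth = CanopyTruth(height=H, footprint_area=L * W, volume=L * W * H)
    elif spec.shape == "hemisphere":
        (R,) = spec.dimensions
        surface = _sample_dome((R, R, R), spec.point_density)
        truth = CanopyTruth(
            height=2 * R / 3,
            footprint_area=np.pi * R**2,
            volume=2 * np.pi * R**3 / 3,
        )
    else:  # ellipsoid dome
        a, b, c = spec.dimensions
        surface = _sample_dome((a, b, c), spec.point_density)
        truth = CanopyTruth(
            height=2 * c / 3,
            footprint_area=np.pi * a * b,
            volume=2 * np.pi * a * b * c / 3,
        )
    if spec.jitter_sd > 0:
        surface = surface + rng.normal(0.0, spec.jitter_sd, size=surface.shape)

    lo = surface.min(axis=0)
    hi = surface.max(axis=0)
    center = (lo + hi) / 2
    half = (hi - lo) / 2
    outliers = np.empty((0, 3))
    if spec.outlier_count > 0:
        draws = []
        while sum(len(d) for d in draws) < spec.outlier_count:
            cand = center + rng.uniform(-2.0, 2.0, size=(spec.outlier_count * 4, 3)) * half
            rel = np.abs(cand - center) / half
            outside = rel.max(axis=1) > 1.3  # clear of the canopy bounding box
            draws.append(cand[outside])
        outliers = np.vstack(draws)[: spec.outlier_count]
    points = np.vstack([surface, outliers])
    labels = np.zeros(points.shape[0], dtype=bool)
    labels[surface.shape[0]:] = True
    cloud = PointCloud(points=points, sample_id=f"{spec.shape}-canopy")
    return cloud, truth, labels


# ---------------------------------------------------------------------------
# Trait cohorts


@dataclass(frozen=True)
class CohortSpec:
    n_samples: int = 12
    m_traits: int = 19
    #: latent tolerance per sample in [0, 1]; evenly spaced when omitted
    latent_tolerance: tuple[float, ...] | None = None
    #: per-trait (intercept, slope); slope sign defines the trait polarity
    loadings: tuple[tuple[float, float], ...] | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.m_traits < 1:
            raise ValueError("need at least 1 trait")
        if self.latent_tolerance is not None and len(self.latent_tolerance) != self.n_samples:
            raise ValueError("latent_tolerance length must equal n_samples")
        if self.loadings is not None:
            if len(self.loadings) != self.m_traits:
                raise ValueError("loadings length must equal m_traits")
            if any(b == 0 for _, b in self.loadings):
                raise ValueError("loading slopes must be nonzero")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def make_cohort(spec: CohortSpec) -> tuple[TraitMatrix, np.ndarray]:
    """Trait matrix with a planted tolerance ordering.

    Trait j of sample i is a_j + b_j * tolerance_i + noise; the declared
    polarity matches the sign of b_j. Returns the matrix and the latent
    tolerance vector (the recovery target).
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.m_traits
    if spec.latent_tolerance is not None:
        latent = np.asarray(spec.latent_tolerance, dtype=float)
    else:
        latent = np.linspace(0.05, 0.95, n)
    if spec.loadings is not None:
        intercepts = np.array([a for a, _ in spec.loadings])
        slopes = np.array([b for _, b in spec.loadings])
    else:
        intercepts = rng.uniform(0.5, 5.0, m)
        slopes = rng.uniform(0.8, 2.0, m)
        flip = np.arange(m) % 5 == 4  # every fifth trait is a negative indicator
        slopes[flip] *= -1.0
    values = intercepts[None, :] + latent[:, None] * slopes[None, :]
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    if m == len(CPT_TRAIT_NAMES):
        names = list(CPT_TRAIT_NAMES)
    else:
        names = [f"trait{j + 1}" for j in range(m)]
    matrix = TraitMatrix(
        sample_ids=[f"sample{i + 1}" for i in range(n)],
        trait_names=names,
        values=values,
        polarity=["positive" if b > 0 else "negative" for b in slopes],
    )
    return matrix, latent
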