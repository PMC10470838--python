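"""Canopy structural traits from 3-D point clouds.

Preprocessing chain: statistical outlier removal, voxel downsampling of the
sub-canopy points, moving-least-squares surface smoothing, then re-basing to
the canopy bottom. Extractors: grid-averaged plant height, occupied-cell
canopy leaf area, and convex-hull volume. Coordinates are centimetres
throughout.
"""

from __future__ import annotations

import os
import struct
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

__all__ = [
    "PointCloud",
    "FilterConfig",
    "StructuralTraits",
    "DEFAULT_GRID_CELL",
    "load_points",
    "save_points",
    "remove_outliers",
    "voxel_filter_below_canopy",
    "mls_smooth",
    "base_to_ground",
    "grid_height",
    "canopy_leaf_area",
    "convex_hull_volume",
    "monte_carlo_hull_volume",
    "extract_structural_traits",
]

DEFAULT_GRID_CELL = 0.5  # cm


@dataclass
class PointCloud:
    """3-D canopy points (cm) with a sample identifier."""

    points: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if self.points.shape[0] == 0:
            raise ValueError("point cloud is empty")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return self.points.shape[0]

    def replace(self, points: np.ndarray) -> "PointCloud":
        return PointCloud(points=points, sample_id=self.sample_id)


@dataclass(frozen=True)
class FilterConfig:
    """Preprocessing parameters; defaults recover the synthetic fixtures."""

    knn: int = 16
    std_multiplier: float = 2.0
    voxel_size: float = 0.25  # cm
    canopy_fraction: float = 0.5
    mls_radius: float = 1.0  # cm

    def __post_init__(self) -> None:
        if self.knn < 1:
            raise ValueError("knn must be >= 1")
        if self.std_multiplier <= 0:
            raise ValueError("std_multiplier must be positive")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not 0.0 < self.canopy_fraction < 1.0:
            raise ValueError("canopy_fraction must be in (0, 1)")
        if self.mls_radius <= 0:
            raise ValueError("mls_radius must be positive")


@dataclass
class StructuralTraits:
    sample_id: str
    height: float  # cm
    canopy_leaf_area: float  # cm^2
    volume: float  # cm^3

    def __post_init__(self) -> None:
        if not (self.height > 0 and self.canopy_leaf_area > 0 and self.volume > 0):
            raise ValueError("structural traits of a valid canopy must be positive")


# ---------------------------------------------------------------------------
# IO: ascii/binary PLY, whitespace XYZ, and a minimal LAS reader (no LAS
# library ships in this environment).


def _read_ply(path: str) -> np.ndarray:
    with open(path, "rb") as fh:
        if fh.readline().strip() != b"ply":
            raise ValueError(f"{path}: not a PLY file")
        fmt = None
        n_vertices = None
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertices = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                props.append((tokens[1], tokens[2]))
            elif tokens[0] == "end_header":
                break
        if n_vertices is None:
            raise ValueError(f"{path}: PLY has no vertex element")
        names = [p[1] for p in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise ValueError(f"{path}: PLY vertex lacks {axis} property")
        if fmt == "ascii":
            rows = []
            for _ in range(n_vertices):
                rows.append([float(t) for t in fh.readline().split()])
            data = np.asarray(rows, dtype=float)
        elif fmt in ("binary_little_endian", "binary_big_endian"):
            endian = "<" if fmt == "binary_little_endian" else ">"
            type_map = {
                "float": "f4",
                "float32": "f4",
                "double": "f8",
                "float64": "f8",
                "int": "i4",
                "int32": "i4",
                "uint": "u4",
                "uint32": "u4",
                "short": "i2",
                "ushort": "u2",
                "char": "i1",
                "uchar": "u1",
                "int8": "i1",
                "uint8": "u1",
            }
            dtype = np.dtype([(nm, endian + type_map[tp]) for tp, nm in props])
            rec = np.frombuffer(fh.read(dtype.itemsize * n_vertices), dtype=dtype)
            data = np.column_stack([rec[nm].astype(float) for nm in names])
        else:
            raise ValueError(f"{path}: unsupported PLY format {fmt!r}")
        cols = [names.index(a) for a in ("x", "y", "z")]
        return data[:, cols]


def _write_ply(points: np.ndarray, path: str, binary: bool = False) -> None:
    n = points.shape[0]
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"element vertex {n}\n"
        "property float x\n"
        "property float y\n"
        "property float z\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(points.astype("<f4").tobytes())
        else:
            for x, y, z in points:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n".encode("ascii"))


def _read_las(path: str) -> np.ndarray:
    with open(path, "rb") as fh:
        header = fh.read(227)
        if len(header) < 227 or header[:4] != b"LASF":
            raise ValueError(f"{path}: not a LAS file")
        offset_to_points = struct.unpack_from("<I", header, 96)[0]
        record_length = struct.unpack_from("<H", header, 105)[0]
        n_points = struct.unpack_from("<I", header, 107)[0]
        sx, sy, sz, ox, oy, oz = struct.unpack_from("<6d", header, 131)
        fh.seek(offset_to_points)
        raw = fh.read(n_points * record_length)
    if len(raw) < n_points * record_length:
        raise ValueError(f"{path}: truncated LAS point data")
    rec = np.frombuffer(raw, dtype=np.uint8).reshape(n_points, record_length)
    xyz_int = rec[:, :12].copy().view("<i4").reshape(n_points, 3)
    return xyz_int * np.array([sx, sy, sz]) + np.array([ox, oy, oz])


def _write_las(points: np.ndarray, path: str) -> None:
    """Minimal LAS 1.2, point format 0 writer (for fixtures/round-trips)."""
    n = points.shape[0]
    scale = 1e-4
    offset = points.min(axis=0)
    xyz_int = np.round((points - offset) / scale).astype("<i4")
    header = bytearray(227)
    header[0:4] = b"LASF"
    struct.pack_into("<BB", header, 24, 1, 2)  # version 1.2
    struct.pack_into("<H", header, 94, 227)  # header size
    struct.pack_into("<I", header, 96, 227)  # offset to point data
    struct.pack_into("<B", header, 104, 0)  # point data format 0
    struct.pack_into("<H", header, 105, 20)  # point record length
    struct.pack_into("<I", header, 107, n)
    struct.pack_into(
        "<6d", header, 131, scale, scale, scale, offset[0], offset[1], offset[2]
    )
    struct.pack_into(
        "<6d",
        header,
        179,
        points[:, 0].max(),
        points[:, 0].min(),
        points[:, 1].max(),
        points[:, 1].min(),
        points[:, 2].max(),
        points[:, 2].min(),
    )
    records = np.zeros((n, 20), dtype=np.uint8)
    records[:, :12] = xyz_int.view(np.uint8).reshape(n, 12)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(records.tobytes())


def load_points(
    path: str, format: str | None = None, sample_id: str = "", unit_scale: float = 1.0
) -> PointCloud:
    """Load a point cloud from PLY, whitespace XYZ text, or LAS.

    ``unit_scale`` multiplies coordinates into centimetres (e.g. 100 for a
    file in metres). The format is inferred from the extension when omitted.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"point cloud file not found: {path}")
    if format is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        format = ext if ext in ("ply", "xyz", "las") else "xyz"
    if format == "ply":
        pts = _read_ply(path)
    elif format == "las":
        pts = _read_las(path)
    elif format == "xyz":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # empty file warns before we error
                pts = np.loadtxt(path, dtype=float, ndmin=2)
        except ValueError as e:
            raise ValueError(f"{path}: unparseable XYZ text ({e})") from None
        if pts.size == 0:
            raise ValueError(f"{path}: empty point cloud file")
        if pts.shape[1] < 3:
            raise ValueError(f"{path}: XYZ rows need at least 3 columns")
        pts = pts[:, :3]
    else:
        raise ValueError(f"unknown point cloud format {format!r}")
    if pts.shape[0] < 4:
        raise ValueError(f"{path}: need at least 4 points, found {pts.shape[0]}")
    return PointCloud(points=pts * float(unit_scale), sample_id=sample_id)


def save_points(cloud: PointCloud, path: str, format: str | None = None) -> None:
    if format is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        format = ext if ext in ("ply", "xyz", "las") else "xyz"
    if format == "ply":
        _write_ply(cloud.points, path)
    elif format == "las":
        _write_las(cloud.points, path)
    elif format == "xyz":
        np.savetxt(path, cloud.points, fmt="%.6f")
    else:
        raise ValueError(f"unknown point cloud format {format!r}")


# ---------------------------------------------------------------------------
# Filters


def mean_knn_distance(points: np.ndarray, knn: int) -> np.ndarray:
    """Per-point mean distance to its ``knn`` nearest neighbours."""
    tree = cKDTree(points)
    dist, _ = tree.query(points, k=knn + 1)
    return dist[:, 1:].mean(axis=1)


def remove_outliers(
    cloud: PointCloud, knn: int = 16, std_multiplier: float = 2.0
) -> PointCloud:
    """Statistical outlier removal on the mean k-nearest-neighbour distance.

    A point is removed when its mean distance to the ``knn`` nearest
    neighbours exceeds the global mean plus ``std_multiplier`` standard
    deviations of that statistic.
    """
    if knn < 1:
        raise ValueError("knn must be >= 1")
    if len(cloud) <= knn:
        raise ValueError(f"cloud has {len(cloud)} points, need more than knn={knn}")
    stat = mean_knn_distance(cloud.points, knn)
    threshold = stat.mean() + std_multiplier * stat.std()
    keep = stat <= threshold
    if not keep.any():
        raise ValueError("outlier filter would remove every point")
    return cloud.replace(cloud.points[keep])


def voxel_filter_below_canopy(
    cloud: PointCloud, voxel_size: float = 0.25, canopy_fraction: float = 0.5
) -> PointCloud:
    """Voxel-downsample only the sub-canopy points.

    Points with z below ``canopy_fraction`` of the z range (above the cloud
    minimum) are replaced by one centroid per occupied voxel; points at or
    above that height pass through unchanged.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    pts = cloud.points
    z_min, z_max = pts[:, 2].min(), pts[:, 2].max()
    cut = z_min + canopy_fraction * (z_max - z_min)
    low = pts[:, 2] < cut
    if not low.any():
        return cloud.replace(pts.copy())
    low_pts = pts[low]
    keys = np.floor((low_pts - low_pts.min(axis=0)) / voxel_size).astype(np.int64)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    inverse = inverse.ravel()
    n_voxels = inverse.max() + 1
    sums = np.zeros((n_voxels, 3))
    np.add.at(sums, inverse, low_pts)
    counts = np.bincount(inverse, minlength=n_voxels).astype(float)
    centroids = sums / counts[:, None]
    return cloud.replace(np.vstack([centroids, pts[~low]]))


def mls_smooth(cloud: PointCloud, radius: float = 1.0) -> PointCloud:
    """Moving-least-squares smoothing: project points to a local surface fit.

    For each point a local frame is built from the PCA of its neighbourhood
    within ``radius``; a quadric (or plane, when neighbours are scarce) is
    fitted to the neighbour heights in that frame and the point is projected
    onto it along the local normal. Points with fewer than 3 neighbours pass
    through unchanged. Point count is preserved.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pts = cloud.points
    tree = cKDTree(pts)
    neighbour_lists = tree.query_ball_point(pts, r=radius)
    out = pts.copy()
    for i, idx in enumerate(neighbour_lists):
        if len(idx) < 4:  # point itself plus < 3 neighbours
            continue
        nb = pts[idx]
        centroid = nb.mean(axis=0)
        centered = nb - centroid
        cov = centered.T @ centered
        eigvals, eigvecs = np.linalg.eigh(cov)
        normal = eigvecs[:, 0]
        e1, e2 = eigvecs[:, 2], eigvecs[:, 1]
        u = centered @ e1
        v = centered @ e2
        w = centered @ normal
        d = pts[i] - centroid
        ui, vi = d @ e1, d @ e2
        if len(idx) >= 7:
            A = np.column_stack([np.ones_like(u), u, v, u * u, u * v, v * v])
            coef, *_ = np.linalg.lstsq(A, w, rcond=None)
            wi = coef @ np.array([1.0, ui, vi, ui * ui, ui * vi, vi * vi])
        else:
            wi = 0.0  # plane through the centroid
        out[i] = centroid + ui * e1 + vi * e2 + wi * normal
    return cloud.replace(out)


def base_to_ground(cloud: PointCloud) -> PointCloud:
    """Shift z so the cloud bottom sits at z = 0."""
    pts = cloud.points.copy()
    pts[:, 2] -= pts[:, 2].min()
    return cloud.replace(pts)


# ---------------------------------------------------------------------------
# Extractors


def _cell_indices(pts: np.ndarray, cell: float) -> np.ndarray:
    if cell <= 0:
        raise ValueError("cell must be positive")
    origin = pts[:, :2].min(axis=0)
    return np.floor((pts[:, :2] - origin) / cell).astype(np.int64)


def grid_height(cloud: PointCloud, cell: float = DEFAULT_GRID_CELL) -> float:
    """Mean over occupied grid cells of the per-cell maximum z.

    The x-y plane is partitioned into ``cell`` x ``cell`` squares anchored at
    (min x, min y); only occupied cells contribute.
    """
    pts = cloud.points
    ij = _cell_indices(pts, cell)
    _, inverse = np.unique(ij, axis=0, return_inverse=True)
    inverse = inverse.ravel()
    n_cells = inverse.max() + 1
    cell_max = np.full(n_cells, -np.inf)
    np.maximum.at(cell_max, inverse, pts[:, 2])
    return float(cell_max.mean())


def canopy_leaf_area(cloud: PointCloud, cell: float = DEFAULT_GRID_CELL) -> float:
    """Occupied-cell count times cell area (cm^2)."""
    ij = _cell_indices(cloud.points, cell)
    n_occupied = np.unique(ij, axis=0).shape[0]
    return float(n_occupied * cell * cell)


def convex_hull_volume(cloud: PointCloud) -> float:
    """Volume (cm^3) of the 3-D convex hull of the points."""
    if len(cloud) < 4:
        raise ValueError("degenerate hull: need at least 4 points")
    try:
        hull = ConvexHull(cloud.points)
    except QhullError as e:
        raise ValueError(f"degenerate hull: {e}") from None
    return float(hull.volume)


def monte_carlo_hull_volume(
    cloud: PointCloud, n_samples: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo estimate of the convex-hull volume and its standard error.

    Uniform samples in the bounding box are classified against the hull's
    facet half-spaces (in chunks, to bound memory). Useful as an independent
    check on :func:`convex_hull_volume`.
    """
    try:
        hull = ConvexHull(cloud.points)
    except QhullError as e:
        raise ValueError(f"degenerate hull: {e}") from None
    rng = np.random.default_rng(seed)
    lo = cloud.points.min(axis=0)
    hi = cloud.points.max(axis=0)
    box_volume = float(np.prod(hi - lo))
    normals = hull.equations[:, :3]
    offsets = hull.equations[:, 3]
    n_inside = 0
    chunk = max(1, min(n_samples, 10_000_000 // max(1, len(offsets))))
    remaining = n_samples
    while remaining > 0:
        m = min(chunk, remaining)
        pts = rng.uniform(lo, hi, size=(m, 3))
        inside = (pts @ normals.T + offsets <= 1e-9).all(axis=1)
        n_inside += int(inside.sum())
        remaining -= m
    p = n_inside / n_samples
    volume = p * box_volume
    se = box_volume * np.sqrt(p * (1.0 - p) / n_samples)
    return volume, se


def extract_structural_traits(
    cloud: PointCloud,
    config: FilterConfig | None = None,
    cell: float = DEFAULT_GRID_CELL,
) -> StructuralTraits:
    """Full chain: outlier removal, sub-canopy voxel filter, MLS smoothing,
    re-basing, then the three extractors."""
    if config is None:
        config = FilterConfig()
    c = remove_outliers(cloud, knn=config.knn, std_multiplier=config.std_multiplier)
    c = voxel_filter_below_canopy(
        c, voxel_size=config.voxel_size, canopy_fraction=config.canopy_fraction
    )
    c = mls_smooth(c, radius=config.mls_radius)
    c = base_to_ground(c)
    return StructuralTraits(
        sample_id=cloud.sample_id,
        height=grid_height(c, cell),
        canopy_leaf_area=canopy_leaf_area(c, cell),
        volume=convex_hull_volume(c),
    )
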