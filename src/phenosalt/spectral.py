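"""Hyperspectral trait extraction.

Reads calibrated reflectance cubes (ENVI or GeoTIFF), segments vegetation by
thresholding the triangular vegetation index, evaluates 16 built-in
narrow-band vegetation indices per pixel and reduces each to a masked mean
per sample.
"""

from __future__ import annotations

import json
import os
import re
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "HyperCube",
    "IndexDefinition",
    "VegetationMask",
    "SpectralTraitVector",
    "INDEX_DEFINITIONS",
    "DEFAULT_TVI_THRESHOLD",
    "load_cube",
    "save_envi",
    "save_geotiff",
    "nearest_band",
    "compute_index",
    "segment_vegetation",
    "extract_spectral_traits",
]

DEFAULT_TVI_THRESHOLD = 10.6
DEFAULT_BAND_TOLERANCE = 10.0  # nm


class CubeFormatError(ValueError):
    """The cube file is unreadable or its wavelength metadata is missing."""


@dataclass
class HyperCube:
    """A calibrated reflectance image: rows x cols x bands plus wavelengths (nm)."""

    reflectance: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.reflectance.ndim != 3:
            raise ValueError("reflectance must be rows x cols x bands")
        rows, cols, bands = self.reflectance.shape
        if rows < 1 or cols < 1:
            raise ValueError("spatial dimensions must be positive")
        if self.wavelengths.shape != (bands,):
            raise ValueError(
                f"wavelength count {self.wavelengths.size} != band count {bands}"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.reflectance.shape

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[2]

    def band(self, index: int) -> np.ndarray:
        return self.reflectance[:, :, index]


@dataclass(frozen=True)
class IndexDefinition:
    """A named vegetation index over reflectances at fixed wavelengths.

    ``formula`` receives a mapping wavelength (nm) -> 2-D reflectance grid for
    every entry of ``required_wavelengths`` and returns the per-pixel index.
    """

    name: str
    category: str
    required_wavelengths: tuple[float, ...]
    formula: Callable[[Mapping[float, np.ndarray]], np.ndarray]


def _defs() -> tuple[IndexDefinition, ...]:
    d = []

    def add(name, category, wl, fn):
        d.append(IndexDefinition(name, category, tuple(float(w) for w in wl), fn))

    add("SR680", "chlorophyll", (800, 680), lambda R: R[800] / R[680])
    add("PSSRb", "chlorophyll", (800, 635), lambda R: R[800] / R[635])
    add(
        "Datt",
        "chlorophyll",
        (850, 710, 680),
        lambda R: (R[850] - R[710]) / (R[850] - R[680]),
    )
    add(
        "mNDVI",
        "chlorophyll",
        (750, 705, 445),
        lambda R: (R[750] - R[705]) / (R[750] + R[705] - 2 * R[445]),
    )
    add("BN", "chlorophyll", (800, 550), lambda R: np.log10(R[800] / R[550]))
    add("ARI", "anthocyanin", (550, 700), lambda R: 1 / R[550] - 1 / R[700])
    add("CRI", "carotenol", (510, 550), lambda R: 1 / R[510] - 1 / R[550])
    add("Srapa", "LAI", (900, 680), lambda R: R[900] / R[680])
    add(
        "TVI",
        "LAI",
        (750, 550, 670),
        lambda R: 0.5 * (120 * (R[750] - R[550]) - 200 * (R[670] - R[550])),
    )
    add("WI", "water", (900, 970), lambda R: R[900] / R[970])
    add(
        "SWSI",
        "water",
        (803, 681, 905, 972),
        lambda R: (R[803] - R[681]) / np.sqrt(R[905] + R[972]),
    )
    add("SRVI", "stress", (830, 660), lambda R: R[830] / R[660])
    add("CTR", "stress", (695, 420), lambda R: R[695] / R[420])
    add(
        "NDVIlut",
        "stress",
        (913, 711),
        lambda R: (R[913] - R[711]) / (R[913] + R[711]),
    )
    add(
        "NDRI",
        "stress",
        (790, 720),
        lambda R: (R[790] - R[720]) / (R[790] + R[720]),
    )
    add(
        "NDVI",
        "biomass",
        (800, 670),
        lambda R: (R[800] - R[670]) / (R[800] + R[670]),
    )
    return tuple(d)


#: The 16 built-in vegetation index definitions, in canonical order.
INDEX_DEFINITIONS: tuple[IndexDefinition, ...] = _defs()

INDEX_NAMES: tuple[str, ...] = tuple(d.name for d in INDEX_DEFINITIONS)
_INDEX_BY_NAME = {d.name: d for d in INDEX_DEFINITIONS}


def get_index_definition(name: str) -> IndexDefinition:
    try:
        return _INDEX_BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown vegetation index {name!r}") from None


@dataclass
class VegetationMask:
    """Boolean vegetation mask with the threshold that produced it."""

    mask: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("no vegetation pixels")


@dataclass
class SpectralTraitVector:
    """Masked-mean value of each of the 16 indices for one sample."""

    sample_id: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.values) != set(INDEX_NAMES):
            missing = set(INDEX_NAMES) - set(self.values)
            extra = set(self.values) - set(INDEX_NAMES)
            raise ValueError(
                f"trait vector must contain exactly the 16 built-in indices; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        for name, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"trait {name} is not finite")


# ---------------------------------------------------------------------------
# Cube IO. ENVI is a text header next to a raw binary; no maintained reader
# for it ships in this environment, so a minimal one lives here. GeoTIFF goes
# through tifffile with wavelengths stored as JSON in the image description.

_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}


def _parse_envi_header(path: str) -> dict:
    with open(path, "r") as fh:
        text = fh.read()
    if not text.lstrip().upper().startswith("ENVI"):
        raise CubeFormatError(f"{path}: not an ENVI header")
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values
    body = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in body.splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def _envi_list(raw: str) -> list[float]:
    inner = raw.strip().strip("{}").strip()
    return [float(tok) for tok in inner.split(",") if tok.strip()]


def _read_envi(path: str) -> HyperCube:
    if path.endswith(".hdr"):
        hdr_path = path
        data_path = path[:-4]
    else:
        hdr_path = path + ".hdr"
        data_path = path
    if not os.path.exists(hdr_path):
        raise CubeFormatError(f"ENVI header not found for {path}")
    if not os.path.exists(data_path):
        # ENVI convention: header "foo.hdr" may accompany "foo.img"
        alt = os.path.splitext(hdr_path)[0] + ".img"
        if os.path.exists(alt):
            data_path = alt
        else:
            raise CubeFormatError(f"ENVI data file not found for {hdr_path}")
    h = _parse_envi_header(hdr_path)
    try:
        samples = int(h["samples"])
        lines = int(h["lines"])
        bands = int(h["bands"])
        dtype_code = int(h["data type"])
    except KeyError as e:
        raise CubeFormatError(f"{hdr_path}: missing required ENVI field {e}") from None
    if "wavelength" not in h:
        raise CubeFormatError(f"{hdr_path}: header has no wavelength field")
    try:
        wavelengths = _envi_list(h["wavelength"])
    except ValueError:
        raise CubeFormatError(f"{hdr_path}: garbled wavelength field") from None
    if len(wavelengths) != bands:
        raise CubeFormatError(
            f"{hdr_path}: {len(wavelengths)} wavelengths for {bands} bands"
        )
    if dtype_code not in _ENVI_DTYPES:
        raise CubeFormatError(f"{hdr_path}: unsupported data type {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(h.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = h.get("interleave", "bsq").lower()
    offset = int(h.get("header offset", "0"))
    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    expected = samples * lines * bands
    if raw.size != expected:
        raise CubeFormatError(
            f"{data_path}: expected {expected} values, found {raw.size}"
        )
    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(lines, samples, bands)
    else:
        raise CubeFormatError(f"{hdr_path}: unknown interleave {interleave!r}")
    return HyperCube(reflectance=cube.astype(float), wavelengths=np.array(wavelengths))


def save_envi(cube: HyperCube, path: str, interleave: str = "bsq") -> None:
    """Write a cube as float32 ENVI (``path`` + ``path``.hdr)."""
    if interleave != "bsq":
        raise ValueError("only bsq interleave is written")
    rows, cols, bands = cube.shape
    data = cube.reflectance.transpose(2, 0, 1).astype(np.float32)
    data.tofile(path)
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(path + ".hdr", "w") as fh:
        fh.write(hdr)


def _read_geotiff(path: str) -> HyperCube:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description or ""
    wavelengths = None
    try:
        meta = json.loads(desc)
        if isinstance(meta, dict) and "wavelength" in meta:
            wavelengths = [float(w) for w in meta["wavelength"]]
    except (json.JSONDecodeError, TypeError, ValueError):
        pass
    if wavelengths is None:
        raise CubeFormatError(
            f"{path}: no per-band wavelength metadata in the image description"
        )
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise CubeFormatError(f"{path}: expected a 3-D image, got shape {arr.shape}")
    # tifffile yields bands-first for multi-page stacks
    cube = np.moveaxis(arr, 0, -1)
    if cube.shape[2] != len(wavelengths):
        raise CubeFormatError(
            f"{path}: {len(wavelengths)} wavelengths for {cube.shape[2]} bands"
        )
    return HyperCube(reflectance=cube.astype(float), wavelengths=np.array(wavelengths))


def save_geotiff(cube: HyperCube, path: str) -> None:
    """Write a cube as a multi-page float32 TIFF with wavelength metadata."""
    import tifffile

    data = cube.reflectance.transpose(2, 0, 1).astype(np.float32)
    desc = json.dumps({"wavelength": [float(w) for w in cube.wavelengths]})
    tifffile.imwrite(path, data, description=desc)


def load_cube(path: str, format: str | None = None) -> HyperCube:
    """Load a reflectance cube from ENVI or GeoTIFF.

    ``format`` is ``"envi"`` or ``"geotiff"``; when omitted it is inferred
    from the file extension (.tif/.tiff -> geotiff, otherwise envi).
    """
    if not os.path.exists(path) and not os.path.exists(path + ".hdr"):
        raise FileNotFoundError(f"cube file not found: {path}")
    if format is None:
        format = "geotiff" if path.lower().endswith((".tif", ".tiff")) else "envi"
    if format == "envi":
        return _read_envi(path)
    if format == "geotiff":
        return _read_geotiff(path)
    raise ValueError(f"unknown cube format {format!r}")


# ---------------------------------------------------------------------------
# Trait computation


def nearest_band(
    cube: HyperCube, wavelength: float, tolerance: float = DEFAULT_BAND_TOLERANCE
) -> int:
    """Index of the band whose center is closest to ``wavelength``.

    Ties resolve toward the shorter wavelength. Raises if the best match is
    farther than ``tolerance`` nm.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    dist = np.abs(cube.wavelengths - wavelength)
    idx = int(np.argmin(dist))  # first minimum = shorter wavelength on ties
    if dist[idx] > tolerance:
        raise ValueError(
            f"no band within {tolerance} nm of {wavelength} nm "
            f"(closest: {cube.wavelengths[idx]} nm)"
        )
    return idx


def compute_index(cube: HyperCube, definition: IndexDefinition | str) -> np.ndarray:
    """Per-pixel value grid of a vegetation index; NaN where undefined."""
    if isinstance(definition, str):
        definition = get_index_definition(definition)
    bands = {
        wl: cube.band(nearest_band(cube, wl)) for wl in definition.required_wavelengths
    }
    with np.errstate(divide="ignore", invalid="ignore"):
        grid = np.asarray(definition.formula(bands), dtype=float)
    grid[~np.isfinite(grid)] = np.nan
    return grid


def segment_vegetation(
    tvi_grid: np.ndarray, threshold: float = DEFAULT_TVI_THRESHOLD
) -> VegetationMask:
    """Threshold a TVI grid: vegetation is strictly greater than ``threshold``."""
    grid = np.asarray(tvi_grid, dtype=float)
    if not np.all(np.isfinite(grid)):
        raise ValueError("TVI grid must be finite")
    mask = grid > threshold
    if not mask.any():
        raise ValueError("no vegetation pixels")
    return VegetationMask(mask=mask, threshold_used=float(threshold))


def extract_spectral_traits(
    cube: HyperCube, mask: VegetationMask, sample_id: str
) -> SpectralTraitVector:
    """Masked mean of every built-in index over vegetation pixels."""
    m = mask.mask
    if m.shape != cube.reflectance.shape[:2]:
        raise ValueError(
            f"mask shape {m.shape} does not match cube spatial shape "
            f"{cube.reflectance.shape[:2]}"
        )
    values: dict[str, float] = {}
    for definition in INDEX_DEFINITIONS:
        grid = compute_index(cube, definition)
        vals = grid[m]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(
                f"index {definition.name} is undefined at every vegetation pixel"
            )
        values[definition.name] = float(vals.mean())
    return SpectralTraitVector(sample_id=sample_id, values=values)
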