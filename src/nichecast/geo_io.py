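"""Grids, raster I/O, and occurrence tables.

Every other module works on three containers defined here: a
:class:`GridGeometry` (a regular lon/lat grid with cell-center
registration), an :class:`EnvStack` (co-registered named predictor
layers sharing one intersection nodata mask), and an
:class:`OccurrenceSet` (point records).  Rasters are read and written
as single-band GeoTIFF (via :mod:`tifffile`, with standard GeoTIFF
georeferencing tags) or ESRI ASCII grids.

Conventions
-----------
* Plain geographic lon/lat coordinates (WGS84 assumed); no projections.
* Row 0 is the northernmost row; ``origin_lon, origin_lat`` is the
  top-left *corner* of the grid.
* Cell membership is half-open: ``[west, east)`` in longitude and
  ``(south, north]`` in latitude, so a point on a shared edge belongs
  to the cell to its east / south.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GridGeometry",
    "EnvStack",
    "OccurrenceSet",
    "SuitabilityMap",
    "AlignmentError",
    "OccurrenceFormatError",
    "OUT_OF_GRID",
    "cell_index",
    "cell_indices",
    "read_env_stack",
    "write_env_stack",
    "read_raster",
    "write_raster",
    "read_occurrences",
]

#: Sentinel returned by :func:`cell_index` for a point beyond the grid extent.
OUT_OF_GRID = None

# GeoTIFF / GDAL tag codes used for georeferencing single-band rasters.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

_ASCII_NODATA = -9999.0


class AlignmentError(ValueError):
    """Rasters that should share a grid do not."""


class OccurrenceFormatError(ValueError):
    """An occurrence CSV is malformed (columns or coordinate bounds)."""


@dataclass(eq=False)
class GridGeometry:
    """A regular lon/lat grid, row 0 at the north edge.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape.
    cell_size_deg
        Square cell size in decimal degrees (2.5 arc-minutes is
        ``2.5 / 60``).
    origin_lon, origin_lat
        Top-left corner of the grid (west edge of column 0, north edge
        of row 0).
    nodata_mask
        Boolean array, ``True`` where a cell carries no data.  ``None``
        means all cells are valid.
    """

    n_rows: int
    n_cols: int
    cell_size_deg: float
    origin_lon: float
    origin_lat: float
    nodata_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.cell_size_deg > 0:
            raise ValueError("cell_size_deg must be positive")
        if self.nodata_mask is not None:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != (self.n_rows, self.n_cols):
                raise ValueError("nodata_mask shape does not match grid shape")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def valid_mask(self) -> np.ndarray:
        if self.nodata_mask is None:
            return np.ones(self.shape, dtype=bool)
        return ~self.nodata_mask

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def same_grid(self, other: "GridGeometry", tol: float = 1e-9) -> bool:
        """True if shapes and geotransforms agree (masks are not compared)."""
        return (
            self.shape == other.shape
            and abs(self.cell_size_deg - other.cell_size_deg) <= tol
            and abs(self.origin_lon - other.origin_lon) <= tol
            and abs(self.origin_lat - other.origin_lat) <= tol
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell ``(row, col)``."""
        lon = self.origin_lon + (col + 0.5) * self.cell_size_deg
        lat = self.origin_lat - (row + 0.5) * self.cell_size_deg
        return lon, lat

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays of shape ``(n_rows, n_cols)`` of center lon and lat."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        lon = self.origin_lon + (cols + 0.5) * self.cell_size_deg
        lat = self.origin_lat - (rows + 0.5) * self.cell_size_deg
        return np.broadcast_to(lon, self.shape).copy(), np.broadcast_to(
            lat[:, None], self.shape
        ).copy()

    def with_mask(self, nodata_mask: np.ndarray | None) -> "GridGeometry":
        return replace(self, nodata_mask=nodata_mask)


def cell_index(
    geometry: GridGeometry, lon: float, lat: float
) -> tuple[int, int] | None:
    """Grid cell containing a point, or :data:`OUT_OF_GRID`.

    Membership is half-open: a point exactly on a shared edge belongs
    to the cell to its east (longitude) or south (latitude).
    """
    col = math.floor((lon - geometry.origin_lon) / geometry.cell_size_deg)
    row = math.floor((geometry.origin_lat - lat) / geometry.cell_size_deg)
    if 0 <= row < geometry.n_rows and 0 <= col < geometry.n_cols:
        return row, col
    return OUT_OF_GRID


def cell_indices(
    geometry: GridGeometry, lon: np.ndarray, lat: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`cell_index`.

    Returns ``(rows, cols, inside)`` where ``inside`` is a boolean mask;
    rows/cols are only meaningful where ``inside`` is True.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    cols = np.floor((lon - geometry.origin_lon) / geometry.cell_size_deg).astype(int)
    rows = np.floor((geometry.origin_lat - lat) / geometry.cell_size_deg).astype(int)
    inside = (
        (rows >= 0)
        & (rows < geometry.n_rows)
        & (cols >= 0)
        & (cols < geometry.n_cols)
    )
    return rows, cols, inside


class EnvStack:
    """Co-registered named predictor layers on one grid.

    A cell is valid only if it is valid in *every* layer (intersection
    mask); invalid cells are stored as NaN in every layer and flagged
    in ``geometry.nodata_mask``.
    """

    def __init__(self, geometry: GridGeometry, layers: dict[str, np.ndarray]):
        if not layers:
            raise ValueError("EnvStack needs at least one layer")
        nodata = ~geometry.valid_mask
        arrays: dict[str, np.ndarray] = {}
        for name, arr in layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != geometry.shape:
                raise AlignmentError(
                    f"layer {name!r} shape {arr.shape} does not match grid "
                    f"{geometry.shape}"
                )
            arrays[name] = arr.copy()
            nodata = nodata | ~np.isfinite(arr)
        for arr in arrays.values():
            arr[nodata] = np.nan
        self.geometry = geometry.with_mask(nodata)
        self.layers = arrays

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_vars(self) -> int:
        return len(self.layers)

    @property
    def valid_mask(self) -> np.ndarray:
        return self.geometry.valid_mask

    def table(self) -> pd.DataFrame:
        """Valid-cell values, one row per valid cell, one column per layer."""
        mask = self.valid_mask
        return pd.DataFrame({name: arr[mask] for name, arr in self.layers.items()})

    def valid_rowcol(self) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.valid_mask)

    def values_at(self, rows: np.ndarray, cols: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {name: arr[rows, cols] for name, arr in self.layers.items()}
        )

    def subset(self, names: Sequence[str]) -> "EnvStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"variables not in stack: {missing}")
        return EnvStack(self.geometry, {n: self.layers[n] for n in names})


@dataclass(eq=False)
class SuitabilityMap:
    """Per-cell suitability on an :class:`EnvStack` grid (NaN = nodata)."""

    geometry: GridGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise AlignmentError("suitability shape does not match grid")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.geometry.valid_mask & np.isfinite(self.values)

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]


class OccurrenceSet:
    """Point records (lon, lat) with a species label and provenance tag."""

    COLUMNS = ("species", "longitude", "latitude", "source")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        for col in ("species", "longitude", "latitude"):
            if col not in frame.columns:
                raise OccurrenceFormatError(f"missing required column {col!r}")
        if "source" not in frame.columns:
            frame["source"] = ""
        bad_lon = ~frame["longitude"].between(-180.0, 180.0)
        bad_lat = ~frame["latitude"].between(-90.0, 90.0)
        bad = bad_lon | bad_lat
        if bad.any():
            rows = [int(i) for i in frame.index[bad][:10]]
            raise OccurrenceFormatError(
                f"coordinates out of range in rows {rows} "
                "(longitude must be in [-180, 180], latitude in [-90, 90])"
            )
        self.frame = frame[list(self.COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, OccurrenceSet) and self.frame.equals(other.frame)

    @property
    def lon(self) -> np.ndarray:
        return self.frame["longitude"].to_numpy(dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return self.frame["latitude"].to_numpy(dtype=float)

    @classmethod
    def from_points(
        cls,
        lon: Iterable[float],
        lat: Iterable[float],
        species: str = "species",
        source: str = "",
    ) -> "OccurrenceSet":
        lon = list(lon)
        lat = list(lat)
        return cls(
            pd.DataFrame(
                {
                    "species": species,
                    "longitude": lon,
                    "latitude": lat,
                    "source": source,
                }
            )
        )

    def select(self, index: Iterable[int]) -> "OccurrenceSet":
        return OccurrenceSet(self.frame.iloc[list(index)])

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def read_occurrences(path: str | Path) -> OccurrenceSet:
    """Read an occurrence CSV with header ``species,longitude,latitude[,source]``.

    Rows with unparseable coordinates raise a row-level error; an empty
    file (header only) yields an empty set with a logged warning.
    """
    frame = pd.read_csv(path)
    required = {"species", "longitude", "latitude"}
    missing = required - set(frame.columns)
    if missing:
        raise OccurrenceFormatError(
            f"{path}: missing required columns {sorted(missing)}"
        )
    for col in ("longitude", "latitude"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(frame.index[bad][0]) + 2  # 1-based, counting the header
            raise OccurrenceFormatError(
                f"{path}: unparseable {col} value at line {row}"
            )
        frame[col] = coerced
    if frame[["longitude", "latitude"]].isna().any().any():
        bad = frame[["longitude", "latitude"]].isna().any(axis=1)
        row = int(frame.index[bad][0]) + 2
        raise OccurrenceFormatError(f"{path}: missing coordinate at line {row}")
    if frame.empty:
        log.warning("occurrence file %s contains a header but no records", path)
    try:
        return OccurrenceSet(frame)
    except OccurrenceFormatError as exc:
        raise OccurrenceFormatError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# raster I/O


def _geometry_from_header(
    data: np.ndarray, cell: float, origin_lon: float, origin_lat: float
) -> GridGeometry:
    nodata = ~np.isfinite(data)
    return GridGeometry(
        n_rows=data.shape[0],
        n_cols=data.shape[1],
        cell_size_deg=cell,
        origin_lon=origin_lon,
        origin_lat=origin_lat,
        nodata_mask=nodata if nodata.any() else None,
    )


def write_raster(
    path: str | Path, data: np.ndarray, geometry: GridGeometry
) -> None:
    """Write one layer as GeoTIFF (``.tif``/``.tiff``) or ESRI ASCII grid."""
    path = Path(path)
    data = np.asarray(data, dtype=float).copy()
    data[~geometry.valid_mask] = np.nan
    if path.suffix.lower() in (".tif", ".tiff"):
        _write_geotiff(path, data, geometry)
    else:
        _write_ascii_grid(path, data, geometry)


def read_raster(path: str | Path) -> tuple[np.ndarray, GridGeometry]:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_geotiff(path)
    return _read_ascii_grid(path)


def _write_geotiff(path: Path, data: np.ndarray, geometry: GridGeometry) -> None:
    import tifffile

    out = data.astype(np.float32)
    cs = geometry.cell_size_deg
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (
            _TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, geometry.origin_lon, geometry.origin_lat, 0.0),
        ),
        (_TAG_GDAL_NODATA, "s", 0, "nan"),
    ]
    tifffile.imwrite(path, out, extratags=extratags)


def _read_geotiff(path: Path) -> tuple[np.ndarray, GridGeometry]:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            data = page.asarray().astype(float)
            tags = page.tags
            if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
                raise IOError(f"{path}: missing GeoTIFF georeferencing tags")
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value
            tie = tags[_TAG_MODEL_TIEPOINT].value
            nodata_txt = (
                str(tags[_TAG_GDAL_NODATA].value).strip("\x00 ")
                if _TAG_GDAL_NODATA in tags
                else "nan"
            )
    except IOError:
        raise
    except Exception as exc:  # pragma: no cover - corrupt file path
        raise IOError(f"cannot read raster {path}: {exc}") from exc
    sx, sy = scale[:2]
    if abs(sx - sy) > 1e-9:
        raise AlignmentError(f"{path}: non-square cells ({sx} x {sy}) unsupported")
    origin_lon = tie[3] - tie[0] * sx
    origin_lat = tie[4] + tie[1] * sy
    if nodata_txt and nodata_txt.lower() != "nan":
        data[data == float(nodata_txt)] = np.nan
    return data, _geometry_from_header(data, float(sx), origin_lon, origin_lat)


def _write_ascii_grid(path: Path, data: np.ndarray, geometry: GridGeometry) -> None:
    cs = geometry.cell_size_deg
    yll = geometry.origin_lat - geometry.n_rows * cs
    out = np.where(np.isfinite(data), data, _ASCII_NODATA)
    header = (
        f"ncols {geometry.n_cols}\n"
        f"nrows {geometry.n_rows}\n"
        f"xllcorner {geometry.origin_lon:.10f}\n"
        f"yllcorner {yll:.10f}\n"
        f"cellsize {cs:.10f}\n"
        f"NODATA_value {_ASCII_NODATA:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6f")


def _read_ascii_grid(path: Path) -> tuple[np.ndarray, GridGeometry]:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not parts[0][0].isalpha():
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        data = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise IOError(f"{path}: ASCII grid header missing {key}")
    nodata = header.get("nodata_value", _ASCII_NODATA)
    data[data == nodata] = np.nan
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    if data.shape != (n_rows, n_cols):
        raise IOError(
            f"{path}: data shape {data.shape} disagrees with header "
            f"({n_rows}, {n_cols})"
        )
    cs = header["cellsize"]
    origin_lat = header["yllcorner"] + n_rows * cs
    return data, _geometry_from_header(data, cs, header["xllcorner"], origin_lat)


def read_env_stack(
    paths: Sequence[str | Path], names: Sequence[str] | None = None
) -> EnvStack:
    """Read co-registered single-band rasters into one stack.

    Variable order follows the input order.  All rasters must share the
    grid shape and geotransform; the stack's nodata mask is the
    intersection of per-layer validity.
    """
    if names is None:
        names = [Path(p).stem for p in paths]
    if len(names) != len(paths):
        raise ValueError("paths and names must have equal length")
    layers: dict[str, np.ndarray] = {}
    geometry: GridGeometry | None = None
    for path, name in zip(paths, names):
        data, geom = read_raster(path)
        if geometry is None:
            geometry = geom
        elif not geometry.same_grid(geom):
            raise AlignmentError(
                f"raster {path} does not align with the first raster "
                f"(shape {geom.shape} vs {geometry.shape}, or differing geotransform)"
            )
        layers[name] = data
    assert geometry is not None
    # per-layer masks are folded into the intersection inside EnvStack
    return EnvStack(geometry.with_mask(None), layers)


def write_env_stack(
    stack: EnvStack, out_dir: str | Path, fmt: str = "tif"
) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in stack.layers.items():
        path = out_dir / f"{name}.{fmt.lstrip('.')}"
        write_raster(path, arr, stack.geometry)
        paths.append(path)
    return paths
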