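"""Raster and sample-table data model shared by every pipeline stage.

Grids are plain north-up rasters in geographic coordinates: a 2-D value
array plus an affine transform described by the top-left corner and the
cell size. Missing cells are held as NaN in memory and encoded with a
nodata sentinel on disk. GeoTIFF files are written with the standard
GeoTIFF tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory and the
GDAL nodata tag) so they open in any GIS.

Sample tables are pandas DataFrames with one row per feather record
(id, coordinates, tissue d2H in permil VSMOW, taxonomy metadata).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "GeoGrid",
    "GridStack",
    "CovariateMatrix",
    "GridError",
    "read_geotiff",
    "write_geotiff",
    "read_samples_csv",
    "validate_samples",
    "descriptive_stats",
    "extract_at_points",
]

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

#: columns every sample table must provide
REQUIRED_SAMPLE_COLUMNS = ("sample_id", "lon", "lat", "d2h_f")
#: optional metadata columns carried through when present
OPTIONAL_SAMPLE_COLUMNS = ("species", "subfamily", "feather_type", "biome", "year")

DEFAULT_NODATA = -9999.0


class GridError(ValueError):
    """Raised for malformed grids, misaligned stacks or unreadable files."""


@dataclass
class GeoGrid:
    """One georeferenced raster layer.

    Parameters
    ----------
    values
        2-D array, row 0 is the northernmost row. Missing cells are NaN.
    origin_x, origin_y
        Map coordinates of the top-left corner of the top-left cell.
    cell_size_x, cell_size_y
        Cell width/height in map units; both positive, rows descend
        southward.
    crs_id
        Coordinate reference identifier, ``"EPSG:4326"`` by default.
    nodata
        Sentinel used when the grid is written to disk.
    """

    values: np.ndarray
    origin_x: float
    origin_y: float
    cell_size_x: float
    cell_size_y: float
    crs_id: str = "EPSG:4326"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise GridError(f"grid values must be 2-D, got shape {arr.shape}")
        if self.cell_size_x <= 0 or self.cell_size_y <= 0:
            raise GridError("cell sizes must be positive")
        self.values = arr

    # -- geometry ---------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer grid edge."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size_y,
            self.origin_x + self.n_cols * self.cell_size_x,
            self.origin_y,
        )

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size_x

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size_y

    def cell_index(self, x, y):
        """Row/col of the cell containing each point (nearest-cell rule).

        Returns integer arrays ``(row, col)`` and a boolean ``inside``
        mask; indices are only meaningful where ``inside`` is True.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size_x).astype(int)
        row = np.floor((self.origin_y - y) / self.cell_size_y).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return row, col, inside

    def value_at(self, x: float, y: float) -> float:
        row, col, inside = self.cell_index(x, y)
        if not bool(inside):
            raise GridError(f"point ({x}, {y}) is outside the grid extent {self.extent}")
        return float(self.values[int(row), int(col)])

    def same_geometry(self, other: "GeoGrid", rtol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.origin_x, other.origin_x, rel_tol=rtol, abs_tol=1e-9)
            and math.isclose(self.origin_y, other.origin_y, rel_tol=rtol, abs_tol=1e-9)
            and math.isclose(self.cell_size_x, other.cell_size_x, rel_tol=rtol)
            and math.isclose(self.cell_size_y, other.cell_size_y, rel_tol=rtol)
        )

    def with_values(self, values: np.ndarray) -> "GeoGrid":
        return replace(self, values=np.asarray(values, dtype=float))


class GridStack:
    """An ordered, name-addressed set of layers on one common grid."""

    def __init__(self, layers: Mapping[str, GeoGrid] | None = None):
        self._layers: dict[str, GeoGrid] = {}
        if layers:
            for name, grid in layers.items():
                self.add(name, grid)

    def add(self, name: str, grid: GeoGrid) -> None:
        if name in self._layers:
            raise GridError(f"duplicate layer name {name!r}")
        if self._layers:
            ref = next(iter(self._layers.values()))
            if not ref.same_geometry(grid):
                raise GridError(
                    f"layer {name!r} is not aligned with the stack "
                    f"(shape {grid.values.shape} vs {ref.values.shape})"
                )
        self._layers[name] = grid

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __getitem__(self, name: str) -> GeoGrid:
        try:
            return self._layers[name]
        except KeyError:
            raise GridError(f"no layer named {name!r} in stack") from None

    def __iter__(self):
        return iter(self._layers.items())

    def __len__(self) -> int:
        return len(self._layers)

    def subset(self, names: Iterable[str]) -> "GridStack":
        return GridStack({n: self[n] for n in names})

    @property
    def reference(self) -> GeoGrid:
        if not self._layers:
            raise GridError("empty stack has no reference grid")
        return next(iter(self._layers.values()))


@dataclass
class CovariateMatrix:
    """Samples x covariates, aligned with the response, ready to model.

    ``data`` holds one numeric column per covariate indexed by sample_id;
    ``response`` is the feather d2H (permil). Rows with any missing
    covariate were dropped at extraction; their ids are retained in
    ``dropped_nodata``/``out_of_extent`` for reporting.
    """

    data: pd.DataFrame
    response: pd.Series
    out_of_extent: list = field(default_factory=list)
    dropped_nodata: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.response.index):
            raise GridError("covariate rows and response are not aligned")
        if len(set(self.data.columns)) != len(self.data.columns):
            raise GridError("covariate column names must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def n_covariates(self) -> int:
        return self.data.shape[1]

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.response.to_numpy(dtype=float)

    def subset_columns(self, names: Iterable[str]) -> "CovariateMatrix":
        return CovariateMatrix(
            self.data[list(names)].copy(),
            self.response.copy(),
            list(self.out_of_extent),
            list(self.dropped_nodata),
        )

    def subset_rows(self, ids: Iterable) -> "CovariateMatrix":
        ids = list(ids)
        return CovariateMatrix(self.data.loc[ids].copy(), self.response.loc[ids].copy())


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def _epsg_code(crs_id: str) -> int:
    try:
        return int(str(crs_id).upper().replace("EPSG:", ""))
    except ValueError:
        return 4326


def write_geotiff(grid: GeoGrid, path) -> None:
    """Write a grid as a single-band float32 GeoTIFF."""
    path = Path(path)
    vals = grid.values.astype(np.float32).copy()
    vals[~np.isfinite(vals)] = np.float32(grid.nodata)
    epsg = _epsg_code(grid.crs_id)
    # minimal GeoKey directory: geographic model, area rasters, named CRS
    geokeys = (
        1, 1, 0, 3,
        1024, 0, 1, 2,
        1025, 0, 1, 1,
        2048, 0, 1, epsg,
    )
    nodata_ascii = f"{grid.nodata:.10g}"
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(grid.cell_size_x), float(grid.cell_size_y), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(grid.origin_x), float(grid.origin_y), 0.0)),
        (_TAG_GEO_KEYS, "H", len(geokeys), geokeys),
        (_TAG_GDAL_NODATA, "s", len(nodata_ascii) + 1, nodata_ascii),
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


def read_geotiff(path) -> GeoGrid:
    """Read a single-band GeoTIFF written by :func:`write_geotiff` (or GDAL)."""
    path = Path(path)
    if not path.exists():
        raise GridError(f"raster file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            vals = page.asarray().astype(float)
            tags = {tag.code: tag.value for tag in page.tags.values()}
    except Exception as exc:  # malformed TIFF
        raise GridError(f"unreadable raster file {path}: {exc}") from exc
    if vals.ndim != 2:
        raise GridError(f"{path}: expected a single-band raster, got shape {vals.shape}")
    if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise GridError(f"{path}: missing georeferencing tags (not a GeoTIFF?)")
    sx, sy, _ = tags[_TAG_PIXEL_SCALE]
    tie = tags[_TAG_TIEPOINT]
    # tiepoint maps raster (i, j, k) -> model (x, y, z)
    origin_x = tie[3] - tie[0] * sx
    origin_y = tie[4] + tie[1] * sy
    crs_id = "EPSG:4326"
    if _TAG_GEO_KEYS in tags:
        keys = tags[_TAG_GEO_KEYS]
        for i in range(4, len(keys), 4):
            if keys[i] == 2048:
                crs_id = f"EPSG:{keys[i + 3]}"
    nodata = DEFAULT_NODATA
    if _TAG_GDAL_NODATA in tags:
        try:
            nodata = float(str(tags[_TAG_GDAL_NODATA]).strip("\x00 "))
        except ValueError:
            pass
    vals[np.isclose(vals, nodata, rtol=0, atol=1e-6 * max(1.0, abs(nodata)))] = np.nan
    return GeoGrid(vals, float(origin_x), float(origin_y), float(sx), float(sy), crs_id, nodata)


# ---------------------------------------------------------------------------
# Sample tables
# ---------------------------------------------------------------------------

def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, coordinate ranges and id uniqueness."""
    for col in REQUIRED_SAMPLE_COLUMNS:
        if col not in samples.columns:
            raise GridError(f"sample table is missing required column {col!r}")
    bad = samples[~np.isfinite(pd.to_numeric(samples["d2h_f"], errors="coerce"))]
    if len(bad):
        raise GridError(
            f"non-numeric or missing d2h_f for sample id(s) {bad['sample_id'].tolist()[:5]}"
        )
    lon = samples["lon"].astype(float)
    lat = samples["lat"].astype(float)
    if (lon.abs() > 180).any() or (lat.abs() > 90).any():
        off = samples.loc[(lon.abs() > 180) | (lat.abs() > 90), "sample_id"].tolist()[:5]
        raise GridError(f"coordinates out of range for sample id(s) {off}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()[:5]
        raise GridError(f"duplicate sample_id(s) {dup}")
    out = samples.copy()
    out["lon"] = lon
    out["lat"] = lat
    out["d2h_f"] = out["d2h_f"].astype(float)
    return out


def read_samples_csv(path) -> pd.DataFrame:
    """Read and validate a georeferenced feather-sample table (CSV)."""
    path = Path(path)
    if not path.exists():
        raise GridError(f"sample file not found: {path}")
    return validate_samples(pd.read_csv(path))


def descriptive_stats(samples: pd.DataFrame) -> dict:
    """Headline summary of a sample table.

    Reports the sample count, number of distinct collection locations
    (unique lon/lat pairs), number of species, and the range/mean of the
    feather d2H values.
    """
    samples = validate_samples(samples)
    d2h = samples["d2h_f"].to_numpy(dtype=float)
    stats = {
        "n_samples": int(len(samples)),
        "n_unique_locations": int(samples[["lon", "lat"]].drop_duplicates().shape[0]),
        "d2h_min": float(np.min(d2h)),
        "d2h_max": float(np.max(d2h)),
        "d2h_mean": float(np.mean(d2h)),
    }
    if "species" in samples.columns:
        stats["n_species"] = int(samples["species"].nunique())
    return stats


# ---------------------------------------------------------------------------
# Point extraction
# ---------------------------------------------------------------------------

def extract_at_points(stack: GridStack, samples: pd.DataFrame) -> CovariateMatrix:
    """Extract every stack layer at the sample coordinates.

    Uses the nearest-cell rule (the value of the cell containing the
    point). Samples outside the grid extent are flagged
    ``out_of_extent``; samples hitting nodata in any layer are dropped
    from the matrix and listed in ``dropped_nodata``.
    """
    samples = validate_samples(samples)
    ref = stack.reference
    row, col, inside = ref.cell_index(samples["lon"].to_numpy(), samples["lat"].to_numpy())
    ids = samples["sample_id"].to_numpy()
    out_ids = [str(i) for i in ids[~inside]]

    cols = {}
    for name, grid in stack:
        vals = np.full(len(samples), np.nan)
        vals[inside] = grid.values[row[inside], col[inside]]
        cols[name] = vals
    frame = pd.DataFrame(cols, index=pd.Index(ids, name="sample_id"))
    frame = frame.loc[inside]
    response = pd.Series(
        samples["d2h_f"].to_numpy()[inside], index=frame.index, name="d2h_f"
    )
    has_nodata = frame.isna().any(axis=1)
    dropped = [str(i) for i in frame.index[has_nodata]]
    return CovariateMatrix(
        frame.loc[~has_nodata],
        response.loc[~has_nodata],
        out_of_extent=out_ids,
        dropped_nodata=dropped,
    )
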