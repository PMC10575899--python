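"""Georeferenced grids, city masks, and plain-text raster I/O.

Conventions: row-major, north-up, pixel-area semantics with pixel-center
registration for point-in-polygon tests; row 0 is the northernmost row.
Missing cells are NaN in memory and ``-9999`` on disk (ESRI ASCII grid).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from shapely import contains_xy
from shapely.geometry import Polygon, shape

NODATA = -9999.0


@dataclass(frozen=True)
class Georef:
    """Affine placement of a north-up grid.

    ``x_origin``/``y_origin`` are the coordinates of the grid's upper-left
    corner (not cell center); ``cell_size`` is in meters.
    """

    x_origin: float
    y_origin: float
    cell_size: float

    def cell_centers(self, n_rows: int, n_cols: int) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates as 2-D arrays of shape (n_rows, n_cols)."""
        xs = self.x_origin + (np.arange(n_cols) + 0.5) * self.cell_size
        ys = self.y_origin - (np.arange(n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def compatible(self, other: "Georef") -> bool:
        return (
            np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
            and np.isclose(self.cell_size, other.cell_size)
        )


@dataclass
class Raster:
    """Single-band grid with NaN for missing cells."""

    data: np.ndarray  # 2-D float array
    georef: Georef
    year: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Raster data must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "Raster":
        return Raster(self.data.copy(), self.georef, self.year)


@dataclass
class CityMask:
    """Boolean in-city grid plus the polygon it was rasterized from."""

    mask: np.ndarray  # 2-D bool
    georef: Georef
    polygon: Polygon | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("CityMask is empty: no in-city cells")

    @property
    def area_km2(self) -> float:
        cell_area_km2 = (self.georef.cell_size / 1000.0) ** 2
        return float(self.mask.sum()) * cell_area_km2

    def on_georef(self, georef: Georef, shape: tuple[int, int]) -> "CityMask":
        """Re-rasterize the source polygon onto another grid."""
        if self.polygon is None:
            raise ValueError("mask has no polygon provenance to re-rasterize")
        return rasterize_polygon(self.polygon, georef, shape)


def rasterize_polygon(poly: Polygon, georef: Georef, shape: tuple[int, int]) -> CityMask:
    """Mark cells whose centers fall inside the polygon (all-touched=false)."""
    xs, ys = georef.cell_centers(*shape)
    mask = contains_xy(poly, xs, ys)
    return CityMask(mask=mask, georef=georef, polygon=poly)


# ---------------------------------------------------------------------------
# plain-text raster / vector I/O


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write a grid as an ESRI ASCII raster (text, nodata -9999)."""
    rows, cols = raster.shape
    g = raster.georef
    y_ll = g.y_origin - rows * g.cell_size
    data = np.where(np.isfinite(raster.data), raster.data, NODATA)
    header = (
        f"ncols {cols}\nnrows {rows}\n"
        f"xllcorner {g.x_origin:.6f}\nyllcorner {y_ll:.6f}\n"
        f"cellsize {g.cell_size:.6f}\nNODATA_value {NODATA:.1f}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.8g")


def read_ascii_grid(path: str | Path, year: int | None = None) -> Raster:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        data = np.loadtxt(fh)
    rows, cols = int(hdr["nrows"]), int(hdr["ncols"])
    data = data.reshape(rows, cols)
    nodata = hdr.get("nodata_value", NODATA)
    data[data == nodata] = np.nan
    georef = Georef(
        x_origin=hdr["xllcorner"],
        y_origin=hdr["yllcorner"] + rows * hdr["cellsize"],
        cell_size=hdr["cellsize"],
    )
    return Raster(data, georef, year)


def write_boundary_geojson(poly: Polygon, path: str | Path) -> None:
    feature = {
        "type": "Feature",
        "properties": {},
        "geometry": poly.__geo_interface__,
    }
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": [feature]}, fh)


def read_boundary_geojson(path: str | Path) -> Polygon:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geom = gj["features"][0]["geometry"]
    elif gj.get("type") == "Feature":
        geom = gj["geometry"]
    else:
        geom = gj
    return shape(geom)


def block_aggregate(values: np.ndarray, factor: int) -> np.ndarray:
    """Mean over non-missing cells of each factor x factor block.

    All-missing blocks stay NaN. Grid dimensions must be multiples of factor.
    """
    rows, cols = values.shape
    if rows % factor or cols % factor:
        raise ValueError(f"grid shape {values.shape} not divisible by {factor}")
    blocks = values.reshape(rows // factor, factor, cols // factor, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(rows // factor, cols // factor, -1)
    with np.errstate(invalid="ignore"):
        return np.nanmean(blocks, axis=2)
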