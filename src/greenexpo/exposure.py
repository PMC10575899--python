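"""Buffered greenness and population-weighted greenspace exposure.

Exposure at the city level is GE^d = sum_i P_i G_i^d / sum_i P_i, where
G_i^d is the mean greenspace fraction within Euclidean distance d of pixel
i's center (the pixel itself included) and P_i is the pixel's population.
The per-pixel (G^d, P) pairs form the individual-exposure distribution that
the inequality indices and the coefficient of variation are computed on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve

from .grids import CityMask, Raster


class ZeroPopulationError(ValueError):
    pass


@dataclass
class BufferedGreenness:
    """Grid of G^d values together with the buffer distance used."""

    raster: Raster
    d_m: float

    @property
    def data(self) -> np.ndarray:
        return self.raster.data


def disk_kernel(d_m: float, cell_size_m: float) -> np.ndarray:
    """Boolean footprint of cells whose centers lie within the open disk of
    radius d around the focal center.

    The strict inequality makes d equal to one cell size reduce to the
    focal cell alone (the buffered mean then equals the raw fraction).
    """
    r = int(d_m // cell_size_m)
    di, dj = np.mgrid[-r : r + 1, -r : r + 1]
    return (di**2 + dj**2) * cell_size_m**2 < d_m**2


def buffered_greenness(fraction: Raster, d_m: float = 500.0) -> BufferedGreenness:
    """Mean fraction over the disk of radius d around each cell center.

    Missing cells are excluded from the mean; edge pixels use the window
    truncated at the grid boundary (no padding).
    """
    cs = fraction.georef.cell_size
    if d_m < cs:
        raise ValueError(f"buffer distance {d_m} m smaller than cell size {cs} m")
    kernel = disk_kernel(d_m, cs).astype(float)
    valid = np.isfinite(fraction.data)
    vals = np.where(valid, fraction.data, 0.0)
    sums = convolve(vals, kernel, mode="constant", cval=0.0)
    counts = convolve(valid.astype(float), kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(counts > 0, sums / np.maximum(counts, 1e-300), np.nan)
    g = np.clip(g, 0.0, 1.0)
    g[counts == 0] = np.nan
    return BufferedGreenness(Raster(g, fraction.georef, fraction.year), d_m)


def _aligned_arrays(g: BufferedGreenness, p: Raster, mask: CityMask):
    if g.raster.shape != p.shape or g.raster.shape != mask.mask.shape:
        raise ValueError("greenness, population, and mask grids are not aligned")
    if not (g.raster.georef.compatible(p.georef) and g.raster.georef.compatible(mask.georef)):
        raise ValueError("greenness, population, and mask georeferences differ")
    sel = mask.mask & np.isfinite(g.data) & np.isfinite(p.data)
    return g.data[sel], p.data[sel]


@dataclass
class ExposureDistribution:
    """Population-weighted sample of individual buffered-greenness values."""

    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.values.shape != self.weights.shape or self.values.ndim != 1:
            raise ValueError("values and weights must be matching 1-D arrays")
        if len(self.values) == 0:
            raise ValueError("empty exposure distribution")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be strictly positive")

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    @property
    def weighted_mean(self) -> float:
        return float(np.average(self.values, weights=self.weights))

    @property
    def weighted_cv(self) -> float:
        """Population-weighted coefficient of variation, sd/mean with
        sd = sqrt(sum w (x - mu)^2 / sum w)."""
        mu = self.weighted_mean
        if mu == 0:
            raise ZeroDivisionError("CV undefined for zero mean exposure")
        var = np.average((self.values - mu) ** 2, weights=self.weights)
        return float(np.sqrt(var) / mu)


def population_weighted_exposure(
    g: BufferedGreenness, p: Raster, mask: CityMask
) -> float:
    """City-level exposure GE^d: population-weighted mean of G^d in the city."""
    vals, w = _aligned_arrays(g, p, mask)
    total = w.sum()
    if total <= 0:
        raise ZeroPopulationError(
            f"zero total in-city population (year {p.year})"
        )
    return float((w * vals).sum() / total)


def exposure_distribution(
    g: BufferedGreenness, p: Raster, mask: CityMask
) -> ExposureDistribution:
    """One (G^d, persons) pair per in-city pixel with positive population."""
    vals, w = _aligned_arrays(g, p, mask)
    keep = w > 0
    if not keep.any():
        raise ZeroPopulationError(
            f"zero total in-city population (year {p.year})"
        )
    return ExposureDistribution(values=vals[keep], weights=w[keep])
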