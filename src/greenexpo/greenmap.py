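"""From reflectance stacks to smoothed annual fraction maps and coverage.

The chain mirrors a standard optical-archive workflow: optional cross-sensor
harmonization (per-band affine), per-year maximum-NDVI compositing over
QA-clear observations, temporally stable endmember selection, fully
constrained linear spectral unmixing of the six-component signature
(blue, green, red, nir, NDVI, NDWI), Savitzky-Golay smoothing of the
per-pixel fraction time series, aggregation to the population lattice, and
city-level coverage statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from scipy.stats import pearsonr

from .grids import CityMask, Georef, Raster, block_aggregate
from .scene import ObservationStack
from .spectra import EndmemberSet, SpectralSignature, ndvi as _ndvi, ndwi as _ndwi


class EndmemberSelectionError(ValueError):
    """No temporally stable candidate pixels for an endmember class."""

    def __init__(self, klass: str):
        self.klass = klass
        super().__init__(f"no temporally stable candidate pixels for class '{klass}'")


@dataclass
class AnnualComposite:
    """Per-pixel signature of the greenest clear observation of one year.

    ``signature`` is (6, rows, cols) in component order blue, green, red,
    nir, ndvi, ndwi; all-contaminated pixel-years are NaN across components.
    """

    signature: np.ndarray
    year: int
    georef: Georef

    @property
    def shape(self) -> tuple[int, int]:
        return self.signature.shape[1:]

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.signature[0])


def harmonize(stack: ObservationStack, coeffs) -> ObservationStack:
    """Apply a per-band affine transform gain*b + offset, clipped to [0, 1].

    ``coeffs`` is a (4, 2) array-like of (gain, offset) rows in band order
    blue, green, red, nir. QA flags are unchanged. Identity is
    ``[(1, 0)] * 4``.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (4, 2) or not np.all(np.isfinite(coeffs)):
        raise ValueError("coeffs must be a finite (4, 2) array of (gain, offset)")
    gains = coeffs[:, 0][None, :, None, None]
    offsets = coeffs[:, 1][None, :, None, None]
    refl = np.clip(stack.reflectance * gains + offsets, 0.0, 1.0)
    return ObservationStack(
        year=stack.year,
        dates=stack.dates,
        reflectance=refl,
        clear=stack.clear,
        georef=stack.georef,
    )


IDENTITY_COEFFS = ((1.0, 0.0),) * 4


def max_value_composite(stack: ObservationStack) -> AnnualComposite:
    """Keep, per pixel, the clear observation with maximal NDVI.

    The winning observation's full band set plus its NDWI are recorded.
    Ties in NDVI go to the earliest observation date. Pixels with no clear
    observation are missing.
    """
    blue, green, red, nir = (stack.reflectance[:, b] for b in range(4))
    obs_ndvi = _ndvi(nir, red)
    masked = np.where(stack.clear, obs_ndvi, -np.inf)
    best = np.argmax(masked, axis=0)  # first occurrence wins ties
    any_clear = stack.clear.any(axis=0)

    rows, cols = stack.shape
    ii, jj = np.ogrid[0:rows, 0:cols]
    sig = np.empty((6, rows, cols))
    for b, band in enumerate((blue, green, red, nir)):
        sig[b] = band[best, ii, jj]
    sig[4] = _ndvi(sig[3], sig[2])
    sig[5] = _ndwi(sig[1], sig[3])
    sig[:, ~any_clear] = np.nan
    return AnnualComposite(signature=sig, year=stack.year, georef=stack.georef)


def select_endmembers(composites: list[AnnualComposite]) -> EndmemberSet:
    """Temporally stable endmember selection over all composited years.

    A pixel is a vegetation candidate if NDVI > 0.8 in every year,
    impervious if NDVI < 0.2 (and NDWI <= 0, to keep open water out of the
    impervious pool) in every year, water if NDWI > 0 in every year.
    Pixels missing in any year, or with a zero index denominator in any
    year, are not candidates. Each endmember signature is the per-component
    mean over its candidates' all-year signatures.
    """
    if len(composites) < 2:
        raise ValueError("need composites from at least 2 years")
    sigs = np.stack([c.signature for c in composites])  # (Y, 6, R, C)
    finite = np.isfinite(sigs[:, 0]).all(axis=0)
    usable = finite & ((sigs[:, 3] + sigs[:, 2]) > 0).all(axis=0)
    usable &= ((sigs[:, 1] + sigs[:, 3]) > 0).all(axis=0)
    ndvi_all, ndwi_all = sigs[:, 4], sigs[:, 5]
    cand = {
        "vegetation": usable & (ndvi_all > 0.8).all(axis=0),
        "impervious": usable & (ndvi_all < 0.2).all(axis=0) & (ndwi_all <= 0).all(axis=0),
        "water": usable & (ndwi_all > 0).all(axis=0),
    }
    means = {}
    for klass, sel in cand.items():
        if not sel.any():
            raise EndmemberSelectionError(klass)
        means[klass] = sigs[:, :, sel].mean(axis=(0, 2))  # (6,)
    def sig(v):
        return SpectralSignature(
            blue=v[0], green=v[1], red=v[2], nir=v[3], ndvi=v[4], ndwi=v[5]
        )
    return EndmemberSet(
        vegetation=sig(means["vegetation"]),
        impervious=sig(means["impervious"]),
        water=sig(means["water"]),
    )


# ---------------------------------------------------------------------------
# constrained unmixing


def _unmix_matrix(R: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fully constrained least squares on the 2-simplex for many pixels.

    Minimizes ||R - C f||^2 subject to sum(f) = 1, f >= 0, by exact
    enumeration of the simplex faces (interior, three edges, three
    vertices). ``R`` is (6, N), ``C`` is (6, 3). Returns (f (3, N),
    residual norm (N,)). Candidates are scanned interior-first with strict
    improvement, so exact ties resolve to the largest support and then the
    lowest endmember indices.
    """
    n = R.shape[1]
    best_f = np.zeros((3, n))
    best_r2 = np.full(n, np.inf)

    def consider(f_cand: np.ndarray, feasible: np.ndarray) -> None:
        resid = R - C @ f_cand
        r2 = np.einsum("ij,ij->j", resid, resid)
        better = feasible & (r2 < best_r2 - 0.0)
        best_r2[better] = r2[better]
        best_f[:, better] = f_cand[:, better]

    # interior: f3 eliminated via the sum-to-one constraint
    D = C[:, :2] - C[:, 2:3]  # (6, 2)
    G = D.T @ D
    rhs = D.T @ (R - C[:, 2:3])  # (2, N)
    f12 = np.linalg.solve(G, rhs)
    f_int = np.vstack([f12, 1.0 - f12.sum(axis=0)])
    consider(f_int, (f_int >= 0).all(axis=0))

    # edges (a, b): f_a = t, f_b = 1 - t
    for a, b in ((0, 1), (0, 2), (1, 2)):
        d = C[:, a] - C[:, b]
        t = d @ (R - C[:, b : b + 1]) / (d @ d)
        f_edge = np.zeros((3, n))
        f_edge[a] = t
        f_edge[b] = 1.0 - t
        consider(f_edge, (t >= 0) & (t <= 1))

    # vertices
    for k in range(3):
        f_vert = np.zeros((3, n))
        f_vert[k] = 1.0
        consider(f_vert, np.ones(n, dtype=bool))

    return best_f, np.sqrt(best_r2)


def unmix_pixel(
    signature: SpectralSignature, endmembers: EndmemberSet
) -> tuple[np.ndarray, float]:
    """Constrained fractions (f_veg, f_imp, f_wat) and residual norm."""
    vec = signature.as_vector()
    if not np.all(np.isfinite(vec)):
        raise ValueError("signature has non-finite components")
    f, r = _unmix_matrix(vec[:, None], endmembers.matrix())
    return f[:, 0], float(r[0])


def unmix_map(
    composite: AnnualComposite, endmembers: EndmemberSet
) -> tuple[Raster, Raster]:
    """Vegetation FractionMap and residual grid; missing propagates."""
    sig = composite.signature
    valid = ~composite.missing
    frac = np.full(composite.shape, np.nan)
    resid = np.full(composite.shape, np.nan)
    if valid.any():
        R = sig[:, valid]
        f, r = _unmix_matrix(R, endmembers.matrix())
        frac[valid] = f[0]
        resid[valid] = r
    return (
        Raster(frac, composite.georef, composite.year),
        Raster(resid, composite.georef, composite.year),
    )


# ---------------------------------------------------------------------------
# temporal smoothing and spatial aggregation


def sg_smooth(
    series: list[Raster], window: int = 5, polyorder: int = 2
) -> list[Raster]:
    """Savitzky-Golay filter each pixel's fraction time series.

    Missing years are linearly interpolated (constant extension at the
    ends) before filtering and re-flagged missing afterwards. Output is
    clipped to [0, 1].
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if len(series) < window:
        raise ValueError(f"series length {len(series)} shorter than window {window}")
    cube = np.stack([r.data for r in series])  # (Y, R, C)
    missing = ~np.isfinite(cube)
    filled = cube.copy()
    if missing.any():
        yidx = np.arange(len(series), dtype=float)
        bad_px = np.argwhere(missing.any(axis=0) & ~missing.all(axis=0))
        for i, j in bad_px:
            col = filled[:, i, j]
            ok = np.isfinite(col)
            filled[:, i, j] = np.interp(yidx, yidx[ok], col[ok])
        all_missing = missing.all(axis=0)
        filled[:, all_missing] = 0.0  # placeholder; re-flagged below
    smooth = savgol_filter(filled, window_length=window, polyorder=polyorder, axis=0, mode="interp")
    smooth = np.clip(smooth, 0.0, 1.0)
    smooth[missing] = np.nan
    return [
        Raster(smooth[k], series[k].georef, series[k].year)
        for k in range(len(series))
    ]


def aggregate_to_grid(fine: Raster, target_cell_size_m: float) -> Raster:
    """Nearest-neighbour resample to a common fine lattice, then block-mean.

    The common lattice step is gcd(source, target) in meters; integer
    refinement makes the nearest-neighbour step an exact replication.
    Raises if the grid extent does not tile the target cell size.
    """
    cs = fine.georef.cell_size
    g = math.gcd(round(cs), round(target_cell_size_m))
    if g == 0 or abs(cs - round(cs)) > 1e-9 or abs(target_cell_size_m - round(target_cell_size_m)) > 1e-9:
        raise ValueError("cell sizes must be whole meters")
    refine = round(cs) // g
    tf = round(target_cell_size_m) // g
    rows, cols = fine.shape
    if (rows * refine) % tf or (cols * refine) % tf:
        raise ValueError(
            f"extent {rows}x{cols} @ {cs} m does not tile {target_cell_size_m} m cells"
        )
    dense = np.repeat(np.repeat(fine.data, refine, axis=0), refine, axis=1)
    coarse = block_aggregate(dense, tf)
    georef = Georef(fine.georef.x_origin, fine.georef.y_origin, float(target_cell_size_m))
    return Raster(coarse, georef, fine.year)


def threshold_classify(fraction: Raster, tau: float) -> Raster:
    """Binary greenspace map: 1 where fraction >= tau (missing preserved)."""
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    data = np.where(np.isfinite(fraction.data), (fraction.data >= tau).astype(float), np.nan)
    return Raster(data, fraction.georef, fraction.year)


def city_coverage(fraction: Raster, mask: CityMask) -> float:
    """Unweighted mean fraction over non-missing in-city pixels."""
    if fraction.shape != mask.mask.shape or not fraction.georef.compatible(mask.georef):
        raise ValueError("fraction map and mask are not aligned")
    sel = mask.mask & np.isfinite(fraction.data)
    if not sel.any():
        raise ValueError("no valid pixels inside the city mask")
    return float(fraction.data[sel].mean())


def fraction_agreement(a, b) -> float:
    """Pearson correlation between two paired city-level series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need equal-length 1-D series of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(pearsonr(a, b).statistic)
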