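"""Synthetic city scenes with known ground truth.

A scene is a small monocentric city observed like a satellite archive:
multi-date four-band reflectance per year with cloud-contaminated
observations flagged in a QA layer, truth fraction maps of three land
covers (vegetation / impervious / water), a city boundary polygon, and a
population surface growing multiplicatively year over year.

Layout: a calibration strip along the northern edge holds spectrally pure,
temporally stable patches (park, pavement, lake) that feed endmember
selection; it lies outside the city polygon, so every in-city pixel is a
vegetation/impervious mixture that carries exactly the configured
vegetation-fraction trend. Within a year, greenness follows a single-peak
phenology curve so that the maximum-NDVI composite recovers the peak-season
(truth) spectrum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .grids import CityMask, Georef, Raster, rasterize_polygon, write_ascii_grid, write_boundary_geojson
from .spectra import EndmemberSet, SpectralSignature, ndvi as _ndvi

#: bright, spectrally flat target that contaminated observations are pulled toward
CLOUD_SPECTRUM = np.array([0.75, 0.78, 0.80, 0.82])

#: nominal endmember reflectances (blue, green, red, nir); jittered per seed.
#: impervious is constructed to share vegetation's nir+red and green+nir band
#: sums, which makes NDVI and NDWI mix exactly linearly for the
#: vegetation/impervious mixtures that city pixels are made of.
NOMINAL_VEGETATION = np.array([0.02, 0.05, 0.02, 0.62])  # NDVI ~ 0.94
NOMINAL_WATER = np.array([0.08, 0.11, 0.06, 0.04])  # NDWI ~ 0.47
NOMINAL_IMPERVIOUS_BLUE = 0.22
NOMINAL_IMPERVIOUS_NIR_SHARE = 0.5625  # of vegetation's nir+red sum; NDVI ~ 0.125


@dataclass
class SceneConfig:
    """Full parameterization of one synthetic city.

    ``veg_trend_per_year`` is either a single slope (fraction/yr) or a
    ``(before, after)`` pair split at ``turning_year``. ``trend_gradient``
    spatially modulates the slope by the (mean-centred, max-normalised)
    population kernel, so positive values concentrate greening where people
    live; a scalar applies to both phases, a pair is per phase. The
    city-mean slope is unaffected by the gradient.
    """

    grid_rows: int = 60
    grid_cols: int = 60
    cell_size_m: float = 30.0
    pop_cell_size_m: float = 100.0
    years: tuple[int, ...] = tuple(range(2000, 2019))
    obs_per_year: int = 8
    cloud_prob: float = 0.3
    noise_sd: float = 0.01
    veg_trend_per_year: float | tuple[float, float] = 0.003
    turning_year: int = 2011
    trend_gradient: float | tuple[float, float] = 0.0
    pop_center: tuple[float, float] | None = None  # (row, col) in 30-m cells
    pop_growth_rate: float = 0.02
    pop_total_start: float = 100_000.0
    pop_sigma_m: float = 450.0
    pop_sigma_trend_per_year: float = 0.0  # fractional change of sigma per year
    strip_rows: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing")
        self.years = years
        if not 0.0 <= self.cloud_prob < 1.0:
            raise ValueError(
                "cloud_prob must be in [0, 1): with cloud_prob >= 1 a pixel-year "
                "has zero expected clear observations"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.obs_per_year < 1:
            raise ValueError("obs_per_year must be >= 1")
        if self.grid_rows <= self.strip_rows + 4 or self.grid_cols < 9:
            raise ValueError("grid too small for calibration strip plus city")
        if self.pop_center is None:
            city_mid = (self.strip_rows + self.grid_rows) / 2.0
            self.pop_center = (city_mid, self.grid_cols / 2.0)

    # -- trend helpers -----------------------------------------------------

    def _phases(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """((slope_pre, grad_pre), (slope_post, grad_post))."""
        s = self.veg_trend_per_year
        pre, post = (s, s) if np.isscalar(s) else (s[0], s[1])
        g = self.trend_gradient
        gpre, gpost = (g, g) if np.isscalar(g) else (g[0], g[1])
        return (float(pre), float(gpre)), (float(post), float(gpost))

    def cumulative_trend(self, year: int) -> tuple[float, float]:
        """Cumulative (uniform, gradient) fraction change from the first year."""
        (pre, gpre), (post, gpost) = self._phases()
        y0 = self.years[0]
        t_pre = min(year, self.turning_year) - y0
        t_post = max(0, year - max(self.turning_year, y0))
        if self.turning_year <= y0:
            t_pre, t_post = 0, year - y0
        return pre * t_pre + post * t_post, gpre * t_pre + gpost * t_post

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        for k in ("years", "pop_center", "veg_trend_per_year", "trend_gradient"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class ObservationStack:
    """All observations of one year: (n_obs, 4, rows, cols) reflectance."""

    year: int
    dates: np.ndarray  # ordinal within-year date index, strictly increasing
    reflectance: np.ndarray  # (n_obs, 4, rows, cols), band order blue/green/red/nir
    clear: np.ndarray  # (n_obs, rows, cols) bool QA; False = contaminated
    georef: Georef

    @property
    def shape(self) -> tuple[int, int]:
        return self.reflectance.shape[2:]


@dataclass
class TruthBundle:
    """Ground truth the pipeline is measured against."""

    true_fraction_maps: dict[int, Raster]  # vegetation fraction per year
    true_coverage_series: dict[int, float]
    endmembers: EndmemberSet
    population_series: dict[int, Raster]
    fraction_simplex: dict[int, np.ndarray]  # (3, rows, cols) per year


def generate_endmembers(seed: int) -> EndmemberSet:
    """Draw a per-seed endmember basis around the nominal spectra.

    Multiplicative jitter of up to ~8% per band; the class index
    constraints (vegetation NDVI > 0.8, impervious NDVI < 0.2, water
    NDWI > 0) hold by construction for any seed because the nominal
    spectra carry wide margins.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    vb, vg, vr, vn = NOMINAL_VEGETATION * (1.0 + rng.uniform(-0.05, 0.05, size=4))
    veg = SpectralSignature(blue=vb, green=vg, red=vr, nir=vn)

    # impervious shares vegetation's nir+red and green+nir sums (see note
    # at NOMINAL_VEGETATION), so band-ratio indices mix linearly
    s_vis = vn + vr
    imp_nir = s_vis * NOMINAL_IMPERVIOUS_NIR_SHARE * (1.0 + rng.uniform(-0.03, 0.03))
    imp = SpectralSignature(
        blue=NOMINAL_IMPERVIOUS_BLUE * (1.0 + rng.uniform(-0.05, 0.05)),
        green=(vg + vn) - imp_nir,
        red=s_vis - imp_nir,
        nir=imp_nir,
    )
    wb, wg, wr, wn = NOMINAL_WATER * (1.0 + rng.uniform(-0.05, 0.05, size=4))
    water = SpectralSignature(blue=wb, green=wg, red=wr, nir=wn)
    return EndmemberSet(vegetation=veg, impervious=imp, water=water)


def season_curve(n_obs: int) -> np.ndarray:
    """Within-year effective greenness: a single peak of 1.0 mid-season.

    Off-peak values decay toward 0.9 — the modest seasonal NDVI amplitude
    of urban vegetation (evergreen trees plus senescing ground cover), so
    pure-vegetation pixels keep NDVI well above 0.8 year-round while the
    maximum-NDVI composite still has a unique noiseless winner.
    """
    t = np.arange(n_obs)
    c = (n_obs - 1) // 2
    return 0.9 + 0.1 * 0.4 ** np.abs(t - c)


def _base_vegetation_field(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth base vegetation fraction, greener toward the city edge."""
    rows, cols = config.grid_rows, config.grid_cols
    rr, cc = np.mgrid[0:rows, 0:cols]
    r0, c0 = config.pop_center
    dist = np.hypot(rr - r0, cc - c0)
    radial = dist / dist.max()
    noise = gaussian_filter(rng.standard_normal((rows, cols)), sigma=6.0)
    noise /= max(np.abs(noise).max(), 1e-12)
    return 0.32 + 0.30 * radial + 0.04 * noise


def _population_kernel(config: SceneConfig, georef: Georef, shape: tuple[int, int], sigma_m: float) -> np.ndarray:
    xs, ys = georef.cell_centers(*shape)
    r0, c0 = config.pop_center
    cx = georef.x_origin + c0 * config.cell_size_m
    cy = georef.y_origin  # same top edge for both lattices
    cy = cy - r0 * config.cell_size_m
    d2 = (xs - cx) ** 2 + (ys - cy) ** 2
    return np.exp(-d2 / (2.0 * sigma_m**2)) + 0.02


def city_polygon(config: SceneConfig, georef: Georef):
    """City boundary: everything south of the calibration strip."""
    rows, cols = config.grid_rows, config.grid_cols
    x0, y0, cs = georef.x_origin, georef.y_origin, config.cell_size_m
    return box(x0, y0 - rows * cs, x0 + cols * cs, y0 - config.strip_rows * cs)


def generate_city_scene(
    config: SceneConfig,
) -> tuple[dict[int, ObservationStack], TruthBundle, CityMask]:
    """Build observation stacks, ground truth, and the city mask.

    Raises ValueError if the configured trend would push any pixel's
    vegetation fraction outside (0, 1) (clipping would break the constructed
    linear-trend guarantee).
    """
    ss = np.random.SeedSequence(int(config.seed))
    child = ss.spawn(3 + len(config.years))
    rng_field = np.random.default_rng(child[0])

    rows, cols = config.grid_rows, config.grid_cols
    georef = Georef(x_origin=0.0, y_origin=rows * config.cell_size_m, cell_size=config.cell_size_m)
    endmembers = generate_endmembers(config.seed)
    C_bands = endmembers.band_matrix()  # (4, 3)

    poly = city_polygon(config, georef)
    mask30 = rasterize_polygon(poly, georef, (rows, cols))

    # calibration strip: thirds of pure vegetation / impervious / water
    strip = config.strip_rows
    third = cols // 3
    pure = np.zeros((3, rows, cols))
    pure[0, :strip, :third] = 1.0
    pure[1, :strip, third : 2 * third] = 1.0
    pure[2, :strip, 2 * third :] = 1.0

    base = _base_vegetation_field(config, rng_field)

    # normalized population kernel drives the spatial trend modulation
    kern30 = _population_kernel(config, georef, (rows, cols), config.pop_sigma_m)
    kern30 = kern30 / kern30.max()
    k_centered = kern30 - kern30[mask30.mask].mean()

    season = season_curve(config.obs_per_year)

    # population lattice (may be coarser than the reflectance lattice)
    pcs = config.pop_cell_size_m
    prows = int(rows * config.cell_size_m // pcs)
    pcols = int(cols * config.cell_size_m // pcs)
    pop_georef = Georef(x_origin=0.0, y_origin=georef.y_origin, cell_size=pcs)
    mask_pop = rasterize_polygon(poly, pop_georef, (prows, pcols))

    y0 = config.years[0]
    stacks: dict[int, ObservationStack] = {}
    truth_maps: dict[int, Raster] = {}
    coverage: dict[int, float] = {}
    pop_series: dict[int, Raster] = {}
    simplex: dict[int, np.ndarray] = {}

    for yi, year in enumerate(config.years):
        rng = np.random.default_rng(child[3 + yi])
        d_uniform, d_grad = config.cumulative_trend(year)
        f_veg = base + d_uniform + d_grad * k_centered
        interior = ~(pure.sum(axis=0) > 0)
        if np.any((f_veg[interior] <= 0.005) | (f_veg[interior] >= 0.995)):
            raise ValueError(
                f"vegetation trend pushes fractions out of (0,1) in year {year}; "
                "reduce the trend magnitude or gradient"
            )
        fractions = np.zeros((3, rows, cols))
        fractions[0] = np.where(interior, f_veg, pure[0])
        fractions[1] = np.where(interior, 1.0 - f_veg, pure[1])
        fractions[2] = pure[2]

        n_obs = config.obs_per_year
        refl = np.empty((n_obs, 4, rows, cols))
        for t in range(n_obs):
            s = season[t]
            eff = fractions.copy()
            eff[0] = fractions[0] * s
            eff[1] = fractions[1] + fractions[0] * (1.0 - s)
            refl[t] = np.einsum("bk,krc->brc", C_bands, eff)
        clear = rng.random((n_obs, rows, cols)) >= config.cloud_prob
        cloudy = ~clear
        if cloudy.any():
            blend = 0.45 * refl + 0.55 * CLOUD_SPECTRUM[None, :, None, None]
            refl = np.where(cloudy[:, None, :, :], blend, refl)
        if config.noise_sd > 0:
            refl = refl + rng.normal(0.0, config.noise_sd, size=refl.shape)
        refl = np.clip(refl, 0.0, 1.0)

        stacks[year] = ObservationStack(
            year=year,
            dates=np.arange(1, n_obs + 1),
            reflectance=refl,
            clear=clear,
            georef=georef,
        )
        truth_maps[year] = Raster(fractions[0].copy(), georef, year)
        coverage[year] = float(fractions[0][mask30.mask].mean())
        simplex[year] = fractions

        sigma = config.pop_sigma_m * (1.0 + config.pop_sigma_trend_per_year) ** (year - y0)
        kern = _population_kernel(config, pop_georef, (prows, pcols), sigma)
        total = config.pop_total_start * (1.0 + config.pop_growth_rate) ** (year - y0)
        pop = kern * (total / kern[mask_pop.mask].sum())
        pop_series[year] = Raster(pop, pop_georef, year)

    truth = TruthBundle(
        true_fraction_maps=truth_maps,
        true_coverage_series=coverage,
        endmembers=endmembers,
        population_series=pop_series,
        fraction_simplex=simplex,
    )
    return stacks, truth, mask30


# ---------------------------------------------------------------------------
# scenario presets: the two qualitative regimes exercised by the pipeline


def south_like_config(seed: int = 0, **overrides) -> SceneConfig:
    """Rapidly urbanizing city: greenspace loss to 2011, then regreening
    concentrated where people live, with strong population growth."""
    params = dict(
        veg_trend_per_year=(-0.008, 0.016),
        trend_gradient=(0.008, 0.06),
        turning_year=2011,
        pop_growth_rate=0.035,
        pop_sigma_trend_per_year=-0.002,
        seed=seed,
    )
    params.update(overrides)
    return SceneConfig(**params)


def north_like_config(seed: int = 0, **overrides) -> SceneConfig:
    """Mature city: monotone, slightly centre-weighted greening and slow
    population growth."""
    params = dict(
        veg_trend_per_year=0.0025,
        trend_gradient=0.001,
        pop_growth_rate=0.008,
        pop_sigma_trend_per_year=0.001,
        seed=seed,
    )
    params.update(overrides)
    return SceneConfig(**params)


def write_scene(outdir: str | Path, truth: TruthBundle, mask: CityMask, config: SceneConfig) -> None:
    """Persist truth rasters, population, boundary, and config as text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for year, r in truth.true_fraction_maps.items():
        write_ascii_grid(r, outdir / f"true_fraction_{year}.asc")
    for year, r in truth.population_series.items():
        write_ascii_grid(r, outdir / f"population_{year}.asc")
    write_boundary_geojson(mask.polygon, outdir / "boundary.geojson")
    config.to_yaml(outdir / "scene.yaml")
    import csv

    with open(outdir / "true_coverage.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["year", "true_coverage"])
        for year, gc in truth.true_coverage_series.items():
            w.writerow([year, f"{gc:.10g}"])
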