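"""End-to-end city analysis: simulate -> unmix -> expose -> inequality ->
trends -> attribute, with deterministic text outputs and a run manifest.

Each stage writes its CSV as soon as it completes, so a failure in a later
stage (e.g. too few years for the trend tests) leaves the upstream products
on disk. The manifest records the configuration, its hash, and a checksum
per output file; identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import ComparativeResult, VennStep, comparative_contribution, venn_series
from .exposure import BufferedGreenness, buffered_greenness, exposure_distribution, population_weighted_exposure
from .greenmap import (
    IDENTITY_COEFFS,
    aggregate_to_grid,
    city_coverage,
    harmonize,
    max_value_composite,
    select_endmembers,
    sg_smooth,
    threshold_classify,
    unmix_map,
)
from .grids import CityMask, Raster
from .inequality import compute_metric
from .scene import SceneConfig, generate_city_scene
from .trends import analyze_series

log = logging.getLogger("greenexpo")

CSV_FLOAT_FORMAT = "%.10g"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and context."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {detail}")


@dataclass
class RunConfig:
    """Everything needed to reproduce one city analysis."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    city_id: str = "city"
    d_m: float = 500.0
    sg_window: int = 5
    sg_order: int = 2
    thresholds: tuple[float, ...] = (0.3, 0.4, 0.5)
    metrics: tuple[str, ...] = ("gini", "atkinson", "theil")
    epsilon: float = 0.5
    theil_normalized: bool = True
    alpha: float = 0.05
    baseline_year: int | None = None
    both_orders: bool = False
    harmonization: tuple = IDENTITY_COEFFS

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scene"] = self.scene.to_dict()
        for k in ("thresholds", "metrics"):
            d[k] = list(d[k])
        d["harmonization"] = [list(c) for c in self.harmonization]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["scene"] = SceneConfig.from_dict(d.get("scene", {}))
        for k in ("thresholds", "metrics"):
            if k in d:
                d[k] = tuple(d[k])
        if "harmonization" in d:
            d["harmonization"] = tuple(tuple(c) for c in d["harmonization"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class CityResults:
    config: RunConfig
    coverage: pd.DataFrame
    exposure: pd.DataFrame
    inequality: pd.DataFrame
    trends: pd.DataFrame
    venn: pd.DataFrame
    attribution: pd.DataFrame
    fraction_maps_100m: dict[int, Raster]
    greenness: dict[int, BufferedGreenness]
    population: dict[int, Raster]
    mask_pop: CityMask
    manifest: dict


def _metric_params(cfg: RunConfig, metric: str) -> dict:
    if metric == "atkinson":
        return {"epsilon": cfg.epsilon}
    if metric == "theil":
        return {"normalized": cfg.theil_normalized}
    return {}


def _write(df: pd.DataFrame, outdir: Path | None, name: str, manifest: dict) -> None:
    if outdir is None:
        return
    path = outdir / name
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)
    manifest["checksums"][name] = hashlib.sha256(path.read_bytes()).hexdigest()


def run_city_analysis(config: RunConfig, outdir: str | Path | None = None) -> CityResults:
    """Run the full chain for one synthetic city; see module docstring."""
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
    manifest: dict = {
        "city_id": config.city_id,
        "seed": config.scene.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages": {},
        "checksums": {},
    }
    cid = config.city_id

    def stage(name):
        def wrap(fn, *a, **kw):
            try:
                return fn(*a, **kw)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, f"{cid}: {exc}") from exc
        return wrap

    # -- simulate ----------------------------------------------------------
    stacks, truth, mask30 = stage("simulate")(generate_city_scene, config.scene)
    years = list(config.scene.years)
    manifest["stages"]["simulate"] = {"years": len(years), "pixels": int(np.prod(mask30.mask.shape))}

    # -- unmix: harmonize, composite, endmembers, unmix, smooth, aggregate -
    def unmix_stage():
        composites = []
        for y in years:
            stack = harmonize(stacks[y], config.harmonization)
            composites.append(max_value_composite(stack))
        endmembers = select_endmembers(composites)
        fractions30 = []
        n_missing = 0
        for comp in composites:
            frac, _resid = unmix_map(comp, endmembers)
            n_missing += int(np.sum(~np.isfinite(frac.data)))
            fractions30.append(frac)
        if len(fractions30) >= config.sg_window:
            fractions30 = sg_smooth(fractions30, config.sg_window, config.sg_order)
            smoothed = True
        else:
            smoothed = False
            log.warning("series shorter than SG window; smoothing skipped")
        pop_cell = config.scene.pop_cell_size_m
        maps100 = {f.year: aggregate_to_grid(f, pop_cell) for f in fractions30}
        manifest["stages"]["unmix"] = {
            "missing_pixel_years": n_missing,
            "smoothed": smoothed,
            "endmember_ndvi": {
                "vegetation": endmembers.vegetation.ndvi,
                "impervious": endmembers.impervious.ndvi,
            },
        }
        return maps100

    maps100 = stage("unmix")(unmix_stage)
    mask_pop = mask30.on_georef(
        next(iter(maps100.values())).georef, next(iter(maps100.values())).shape
    )

    def coverage_stage():
        rows = []
        for y in years:
            rec = {"city_id": cid, "year": y, "GC": city_coverage(maps100[y], mask_pop)}
            for tau in config.thresholds:
                binary = threshold_classify(maps100[y], tau)
                rec[f"GC_tau_{tau:g}"] = city_coverage(binary, mask_pop)
            rows.append(rec)
        return pd.DataFrame(rows)

    coverage_df = stage("unmix")(coverage_stage)
    _write(coverage_df, outdir, "coverage.csv", manifest)

    # -- expose ------------------------------------------------------------
    def expose_stage():
        greenness = {y: buffered_greenness(maps100[y], config.d_m) for y in years}
        pop = truth.population_series
        rows = []
        for y in years:
            dist = exposure_distribution(greenness[y], pop[y], mask_pop)
            rows.append(
                {
                    "city_id": cid,
                    "year": y,
                    "GE": population_weighted_exposure(greenness[y], pop[y], mask_pop),
                    "CV": dist.weighted_cv,
                    "d_m": config.d_m,
                }
            )
        return greenness, pd.DataFrame(rows)

    greenness, exposure_df = stage("expose")(expose_stage)
    _write(exposure_df, outdir, "exposure.csv", manifest)
    manifest["stages"]["expose"] = {"d_m": config.d_m}

    # -- inequality --------------------------------------------------------
    def inequality_stage():
        rows = []
        for y in years:
            dist = exposure_distribution(greenness[y], truth.population_series[y], mask_pop)
            for metric in config.metrics:
                params = _metric_params(config, metric)
                res = compute_metric(dist, metric, **params)
                rows.append(
                    {
                        "city_id": cid,
                        "year": y,
                        "metric": metric,
                        "value": res.value,
                        "params": json.dumps(res.params, sort_keys=True),
                    }
                )
        return pd.DataFrame(rows)

    inequality_df = stage("inequality")(inequality_stage)
    _write(inequality_df, outdir, "inequality.csv", manifest)

    # -- trends ------------------------------------------------------------
    def trends_stage():
        rows = []
        series = {"GC": coverage_df.set_index("year")["GC"], "GE": exposure_df.set_index("year")["GE"]}
        for metric in config.metrics:
            sub = inequality_df[inequality_df.metric == metric].set_index("year")["value"]
            series[metric] = sub
        for name, s in series.items():
            tr = analyze_series(s.index.to_numpy(), s.to_numpy(), config.alpha)
            rows.append(
                {
                    "city_id": cid,
                    "variable": name,
                    "slope": tr.slope,
                    "slope_milli_per_yr": tr.slope * 1000.0,
                    "intercept": tr.intercept,
                    "S": tr.mk_s,
                    "var_S": tr.mk_var,
                    "z": tr.z,
                    "p": tr.p,
                    "significant": tr.significant,
                    "class": tr.klass,
                }
            )
        return pd.DataFrame(rows)

    trends_df = stage("trends")(trends_stage)
    _write(trends_df, outdir, "trends.csv", manifest)

    # -- attribute ---------------------------------------------------------
    def attribute_stage():
        pop = truth.population_series
        steps = venn_series(greenness, pop, mask_pop, metric="gini")
        venn_df = pd.DataFrame(
            [
                {
                    "city_id": cid,
                    "year": s.year,
                    "dGini_green": s.d_green,
                    "dGini_pop": s.d_pop,
                    "dGini_all": s.d_all,
                    "region_I": s.region_i,
                    "region_II": s.region_ii,
                    "region_III": s.region_iii,
                }
                for s in steps
            ]
        )
        orders = ("green", "pop") if config.both_orders else ("green",)
        comp_rows = []
        for direct in orders:
            res = comparative_contribution(
                greenness, pop, mask_pop, metric="gini", direct=direct,
                baseline_year=config.baseline_year,
            )
            comp_rows.append(
                {
                    "city_id": cid,
                    "direct_factor": res.direct,
                    "beta_expo": res.beta_expo,
                    "beta_green": res.beta_green,
                    "beta_pop": res.beta_pop,
                    "CC": res.cc if res.cc is not None else float("nan"),
                }
            )
        return venn_df, pd.DataFrame(comp_rows)

    venn_df, attribution_df = stage("attribute")(attribute_stage)
    _write(venn_df, outdir, "venn.csv", manifest)
    _write(attribution_df, outdir, "attribution.csv", manifest)

    if outdir is not None:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return CityResults(
        config=config,
        coverage=coverage_df,
        exposure=exposure_df,
        inequality=inequality_df,
        trends=trends_df,
        venn=venn_df,
        attribution=attribution_df,
        fraction_maps_100m=maps100,
        greenness=greenness,
        population=truth.population_series,
        mask_pop=mask_pop,
        manifest=manifest,
    )
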