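"""Attribution of inequality change to greenspace vs. population.

Two devices:

* a Venn (inclusion-exclusion) decomposition of each year-over-year change
  of the exposure-inequality index into a greenspace-only region (I), a
  population-only region (III), and their joint region (II), built from
  three counterfactual index evaluations
  (dG_green = Gini(g_{i+1}, p_i) - Gini(g_i, p_i),
   dG_pop   = Gini(g_i, p_{i+1}) - Gini(g_i, p_i),
   dG_all   = Gini(g_{i+1}, p_{i+1}) - Gini(g_i, p_i));

* a comparative-contribution trend approach: the factual inequality trend
  beta_expo, a counterfactual trend with one factor frozen at the baseline
  year, the other factor's trend by subtraction, and
  CC = (|beta_pop| - |beta_green|) / |beta_expo| (negative values mean the
  greenspace contribution dominates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exposure import BufferedGreenness, exposure_distribution
from .grids import CityMask, Raster
from .inequality import compute_metric
from .trends import theil_sen


@dataclass(frozen=True)
class VennStep:
    """Decomposition of one year-over-year inequality change."""

    year: int
    d_green: float  # regions I + II
    d_pop: float  # regions II + III
    d_all: float  # regions I + II + III
    region_i: float
    region_ii: float
    region_iii: float


@dataclass(frozen=True)
class ComparativeResult:
    beta_expo: float
    beta_green: float
    beta_pop: float
    cc: float | None  # None when beta_expo == 0 (undefined)
    direct: str


def _index(g: BufferedGreenness | Raster, p: Raster, mask: CityMask, metric: str, label: str, **params) -> float:
    gb = g if isinstance(g, BufferedGreenness) else BufferedGreenness(g, d_m=float("nan"))
    try:
        dist = exposure_distribution(gb, p, mask)
        return compute_metric(dist, metric, **params).value
    except Exception as exc:
        raise type(exc)(f"{exc} [counterfactual pair {label}]") from exc


def venn_step(
    g_i: BufferedGreenness,
    g_i1: BufferedGreenness,
    p_i: Raster,
    p_i1: Raster,
    mask: CityMask,
    metric: str = "gini",
    year: int | None = None,
    **metric_params,
) -> VennStep:
    """Inclusion-exclusion decomposition of one inequality step."""
    base = _index(g_i, p_i, mask, metric, "(g_i, p_i)", **metric_params)
    d_green = _index(g_i1, p_i, mask, metric, "(g_i+1, p_i)", **metric_params) - base
    d_pop = _index(g_i, p_i1, mask, metric, "(g_i, p_i+1)", **metric_params) - base
    d_all = _index(g_i1, p_i1, mask, metric, "(g_i+1, p_i+1)", **metric_params) - base
    return VennStep(
        year=year if year is not None else (p_i1.year or 0),
        d_green=d_green,
        d_pop=d_pop,
        d_all=d_all,
        region_i=d_all - d_pop,
        region_ii=d_green + d_pop - d_all,
        region_iii=d_all - d_green,
    )


def venn_series(
    g_by_year: dict[int, BufferedGreenness],
    p_by_year: dict[int, Raster],
    mask: CityMask,
    metric: str = "gini",
    **metric_params,
) -> list[VennStep]:
    """One VennStep per consecutive year pair, labeled by the later year."""
    years = sorted(g_by_year)
    if years != sorted(p_by_year):
        raise ValueError("greenness and population series have different year axes")
    if len(years) < 2:
        raise ValueError("need at least 2 years")
    return [
        venn_step(
            g_by_year[a], g_by_year[b], p_by_year[a], p_by_year[b],
            mask, metric, year=b, **metric_params,
        )
        for a, b in zip(years, years[1:])
    ]


def comparative_contribution(
    g_by_year: dict[int, BufferedGreenness],
    p_by_year: dict[int, Raster],
    mask: CityMask,
    metric: str = "gini",
    direct: str = "green",
    baseline_year: int | None = None,
    **metric_params,
) -> ComparativeResult:
    """Trend-based comparative contribution CC of population vs. greenspace.

    ``direct`` names the factor varied directly against the frozen baseline
    ("green" or "pop"); the other factor's trend is obtained by
    subtraction, so beta_green + beta_pop = beta_expo exactly.
    """
    years = sorted(g_by_year)
    if years != sorted(p_by_year):
        raise ValueError("greenness and population series have different year axes")
    if len(years) < 4:
        raise ValueError("need at least 4 years for the trend statistics")
    if direct not in ("green", "pop"):
        raise ValueError("direct must be 'green' or 'pop'")
    base_year = years[0] if baseline_year is None else baseline_year
    if base_year not in g_by_year:
        raise ValueError(f"baseline year {base_year} not in series")

    factual = [
        _index(g_by_year[y], p_by_year[y], mask, metric, f"(g_{y}, p_{y})", **metric_params)
        for y in years
    ]
    beta_expo, _ = theil_sen(years, factual)

    if direct == "green":
        counter = [
            _index(g_by_year[y], p_by_year[base_year], mask, metric,
                   f"(g_{y}, p_{base_year})", **metric_params)
            for y in years
        ]
        beta_green, _ = theil_sen(years, counter)
        beta_pop = beta_expo - beta_green
    else:
        counter = [
            _index(g_by_year[base_year], p_by_year[y], mask, metric,
                   f"(g_{base_year}, p_{y})", **metric_params)
            for y in years
        ]
        beta_pop, _ = theil_sen(years, counter)
        beta_green = beta_expo - beta_pop

    cc = None
    if beta_expo != 0:
        cc = (abs(beta_pop) - abs(beta_green)) / abs(beta_expo)
    return ComparativeResult(
        beta_expo=beta_expo,
        beta_green=beta_green,
        beta_pop=beta_pop,
        cc=cc,
        direct=direct,
    )
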