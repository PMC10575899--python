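"""Population-weighted exposure and inequality over one city-year.

Exposure per person is the mean greenspace fraction within 500 m of their
pixel (buffered greenness G^d); the city-level exposure GE^d is the
population-weighted mean of G^d, and the Gini/Atkinson/Theil indices
quantify how unevenly G^d is spread over people.
"""

from greenexpo import SceneConfig, generate_city_scene
from greenexpo.exposure import buffered_greenness, exposure_distribution, population_weighted_exposure
from greenexpo.greenmap import aggregate_to_grid, city_coverage
from greenexpo.inequality import atkinson, gini, theil

cfg = SceneConfig(seed=7)
_stacks, truth, mask30 = generate_city_scene(cfg)
year = cfg.years[-1]

f100 = aggregate_to_grid(truth.true_fraction_maps[year], cfg.pop_cell_size_m)
mask = mask30.on_georef(f100.georef, f100.shape)
g = buffered_greenness(f100, d_m=500.0)
pop = truth.population_series[year]

gc = city_coverage(f100, mask)
ge = population_weighted_exposure(g, pop, mask)
dist = exposure_distribution(g, pop, mask)

print(f"year {year}: coverage GC={gc:.4f}, exposure GE(500m)={ge:.4f}")
print(f"exposure distribution: {len(dist.values)} populated pixels, "
      f"{dist.total_weight:,.0f} persons, CV={dist.weighted_cv:.4f}")
print(f"Gini     = {gini(dist).value:.4f}")
print(f"Atkinson = {atkinson(dist, 0.5).value:.4f} (epsilon=0.5)")
print(f"Theil    = {theil(dist).value:.4f} (normalized)")
# GE below GC means people live in the less green part of the city;
# all three indices are 0 for perfectly equal exposure.
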