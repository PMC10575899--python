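# greenexpo

Urban greenspace is unevenly supplied and unevenly experienced. `greenexpo`
is a Python library for quantifying that gap over time: it maps fractional
greenspace from multi-date satellite-style reflectance, converts it into
population-weighted exposure, measures exposure inequality, detects
long-term trends, and attributes inequality change to greenspace versus
population dynamics. It is aimed at environmental-exposure and urban-equity
researchers who want a tested, fully reproducible desk-scale pipeline:
every stage runs on synthetic cities with known ground truth, so each
operation can be validated against closed forms and brute-force oracles.

## The quantities it computes

**Fractional greenspace.** Each pixel's signature
R = (blue, green, red, nir, NDVI, NDWI) is modeled as a linear mixture of
n = 3 endmembers (vegetation, impervious, water):

    R_i = Σ_k f_ik · C_k + ε_i,   with  Σ_k f_ik = 1,  f_ik ≥ 0

solved per pixel by fully constrained least squares (exact enumeration of
the simplex faces). Signatures come from an annual maximum-NDVI composite
of QA-clear observations; endmembers are pixels that satisfy their class
constraint (vegetation NDVI > 0.8, impervious NDVI < 0.2, water NDWI > 0)
in *every* year. Fraction time series are Savitzky–Golay smoothed and
aggregated to the 100 m population lattice. City coverage GC is the
unweighted in-boundary mean.

**Exposure.** With P_i the population of pixel i and G_i^d the mean
fraction within distance d (default 500 m) of pixel i,

    GE^d = Σ_i P_i · G_i^d / Σ_i P_i

is the population-weighted exposure; the per-pixel (G^d, P) pairs form the
individual-exposure distribution.

**Inequality.** Population-weighted Gini
(G = Σ_ij w_i w_j |x_i − x_j| / (2 W² μ), computed via the sorted Lorenz
form), Atkinson (ε = 0.5 by default), and Theil-T (normalized by ln of the
number of units so it shares the 0–1 range).

**Trends.** Theil–Sen slope plus the Mann–Kendall test (tie-corrected
variance, continuity correction, α = 0.05), classified into
significant/insignificant increase/decrease.

**Attribution.** For each year pair, three counterfactual Gini evaluations
decompose the inequality change into a greenspace-only region I, a
population-only region III, and a joint region II
(ΔGini_green = Gini(g_{i+1}, p_i) − Gini(g_i, p_i), etc., with
I + II + III = ΔGini_all exactly). A trend-based comparative contribution
CC = (|β_pop| − |β_green|) / |β_expo| is negative when greenspace dominates.

## Worked example

```bash
python examples/05_attribution_run_all.py
```

prints (abridged):

```
--- south-like ---
    GC: -1.38 x0.001/yr (insig_decrease)
    GE: +1.23 x0.001/yr (insig_increase)
  gini: -0.66 x0.001/yr (sig_decrease)
  attribution: beta_green=-0.607, beta_pop=-0.053, CC=-0.84
  |region I| > |region III| in 100% of steps
--- north-like ---
    GC: +2.51 x0.001/yr (sig_increase)
    GE: +2.58 x0.001/yr (sig_increase)
  gini: -0.35 x0.001/yr (sig_decrease)
  attribution: beta_green=-0.369, beta_pop=+0.020, CC=-1.00
```

The south-like city loses greenspace overall (GC trend −1.4 × 0.001 yr⁻¹)
yet per-person exposure holds steady-to-rising (GE +1.2 × 0.001 yr⁻¹)
because post-2011 regreening concentrates where people live; exposure
inequality falls (Gini −0.66 × 0.001 yr⁻¹), and attribution shows the
change is driven by greenspace, not population (CC < 0, region I dominant).
The north-like city greens monotonically with a smaller inequality decline.

The other examples walk the individual stages: scene generation (`01`),
unmixing and coverage (`02`), exposure and inequality (`03`), trend
statistics (`04`).

A thin CLI wraps the same pipeline:

```bash
greenexpo run-all --out out/demo --preset south --seed 0
greenexpo simulate --out out/scene --preset north --seed 1
```

All outputs carry a config hash and per-file checksums in `manifest.json`;
identical config + seed gives byte-identical products.

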