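# Methods

## Pipeline model

The package implements a desk-scale version of a satellite-era urban
greenspace exposure analysis. One city-year is processed as:

1. **Harmonization** — optional per-band affine transform
   (gain · band + offset, clipped to [0, 1]) to place sensors on a common
   radiometric baseline. Identity by default; coefficients are
   configuration, never estimated here.
2. **Maximum-NDVI compositing** — per pixel, the QA-clear observation with
   the highest NDVI is kept with its full band set and NDWI. Ties go to
   the earliest date; pixel-years with no clear observation become
   missing. The composite targets peak-season greenness and suppresses
   residual cloud contamination.
3. **Endmember selection** — candidate pixels must satisfy their class
   constraint in *every* composited year: vegetation NDVI > 0.8,
   impervious NDVI < 0.2 (and NDWI ≤ 0, to keep open water out of the
   impervious pool), water NDWI > 0. Pixels with a zero index denominator
   in any year are excluded. The endmember signature is the per-component
   mean over all candidate-year signatures. A class with no stable
   candidate raises an error naming the class.
4. **Constrained unmixing** — the six-component signature (blue, green,
   red, nir, NDVI, NDWI; unweighted) is decomposed over the three
   endmembers under Σf = 1, f ≥ 0. The solver enumerates the seven faces
   of the 2-simplex (interior via the sum-to-one-eliminated normal
   equations, three edges, three vertices), keeps the feasible candidate
   with the smallest residual, and breaks exact ties toward the larger
   support and then the lower endmember index. This is exact, deterministic,
   and vectorized over pixels.
5. **Temporal smoothing** — per-pixel Savitzky–Golay filtering of the
   annual fraction series (window 5, polyorder 2 by default: the shortest
   window that smooths a 19-point series without erasing a mid-series
   turning point). Missing years are linearly interpolated (constant
   extension at the ends) for filtering and re-flagged missing afterwards;
   output is clipped to [0, 1].
6. **Aggregation** — nearest-neighbour resampling onto the
   gcd(source, target) lattice (exact replication for integer refinement)
   followed by a block mean onto the 100 m population grid; missing
   subcells are excluded from block means.
7. **Exposure** — buffered greenness G^d is the mean fraction over cells
   whose centers lie in the *open* Euclidean disk of radius d (default
   500 m) around the focal center, focal cell included, truncated at the
   grid edge (no padding, which would bias boundary exposure downward).
   The open disk makes d = one cell size reduce exactly to the raw map.
   GE^d is the population-weighted mean of G^d over in-boundary pixels;
   pixels with zero population feed their neighbours' buffers but carry no
   weight.
8. **Inequality** — population-weighted Gini (pairwise definition,
   computed by the sorted-Lorenz O(n log n) form), Atkinson (generalized
   mean of order 1 − ε over the arithmetic mean; ε default 0.5; geometric
   limit at ε = 1), and Theil-T. The Theil index is reported normalized by
   ln(number of units) by default so that all three indices share the 0–1
   range; the unit count defaults to pixels, with persons available, and
   the choice is recorded in the result parameters. Tiny negative values
   from floating-point cancellation in Gini/Atkinson are clamped to 0.
9. **Trends** — Theil–Sen slope (median pairwise slope; intercept
   median(y − slope·t)) and the Mann–Kendall normal approximation with
   tie-corrected variance and ±1 continuity correction (both switchable),
   two-sided p, α = 0.05, and a four-class label; slope 0 classifies with
   the increase branch by convention. Output tables also report slopes in
   the ×0.001 yr⁻¹ convention.
10. **Attribution** — three counterfactual inequality evaluations per year
    pair give ΔGini_green, ΔGini_pop, ΔGini_all; regions solve the
    inclusion–exclusion system (I = all − pop, III = all − green,
    II = green + pop − all), so I + II + III = ΔGini_all holds to machine
    precision by construction. Counterfactuals operate on buffered
    greenness grids, since the index is defined over individual exposure.
    The comparative contribution freezes one factor at the baseline year
    (default: the first year; the directly varied factor defaults to
    greenspace), obtains the other's trend by subtraction (so
    β_green + β_pop = β_expo exactly), and reports
    CC = (|β_pop| − |β_green|)/|β_expo| as printed — CC can leave [−1, 1]
    when the two β's oppose in sign; it is reported, never clipped, and a
    zero β_expo yields an explicit "undefined", not a silent NaN.

## Synthetic study conditions

The scene generator defines the conditions every test runs under; its
defaults are fixed, not tuning knobs.

* **Geometry** — 60 × 60 cells at 30 m reflectance resolution
  (64 × 64 for the accuracy benchmark), population on a 100 m lattice,
  years 2000–2018, 8 observations per year, cloud probability 0.3,
  reflectance noise sd 0.01. A six-row calibration strip along the
  northern edge holds pure, temporally stable park / pavement / lake
  patches; the city polygon excludes it, so every in-city pixel is a
  vegetation/impervious mixture whose fraction carries exactly the
  configured trend (the truth coverage series is exactly linear in the
  uniform-trend case).
* **Spectra** — nominal endmembers: vegetation (0.02, 0.05, 0.02, 0.62;
  NDVI ≈ 0.94), water (0.08, 0.11, 0.06, 0.04; NDWI ≈ 0.47), and an
  impervious spectrum constructed to share vegetation's nir+red and
  green+nir band sums (NDVI ≈ 0.125). The shared sums make NDVI and NDWI
  *exactly linear* over vegetation/impervious mixtures, so the
  six-component mixing model is exactly invertible in the noiseless case —
  for general endmembers a ratio index of mixed bands is not the mixture
  of pure indices, and the residual ε absorbs the mismatch. Per-seed
  multiplicative jitter (±5%, ±3% on the impervious nir share) preserves
  the class-constraint margins by construction.
* **Phenology** — within-year effective greenness follows a single-peak
  curve 0.9 + 0.1·0.4^|t − c|. The unique peak makes the noiseless
  composite recover truth exactly; the modest amplitude (urban vegetation
  retains high NDVI off-peak) keeps pure-vegetation pixels above the 0.8
  stability screen even when the peak date is cloudy.
* **Clouds** — i.i.d. Bernoulli(0.3) per pixel-observation; contaminated
  reflectance is blended toward a bright flat spectrum and flagged in QA.
  The pipeline consumes QA flags; it does not detect clouds.
* **Population** — a Gaussian monocentric kernel (σ = 450 m, plus a 0.02
  floor) scaled so the in-boundary total equals
  pop_total_start·(1 + g)^(y − y₀) exactly (float-valued counts, as in
  gridded population products). The kernel width can drift
  (densification/sprawl) via a fractional per-year σ trend.
* **Trends** — the vegetation-fraction slope may be piecewise (turning
  year default 2011) and spatially modulated by the mean-centred
  population kernel ("gradient"), which concentrates greening where
  people live without changing the city-mean slope. The generator rejects
  configurations whose cumulative trend would clip any pixel's fraction.
* **Scenario presets** — *south-like*: pre-2011 loss (−0.008 yr⁻¹, mild
  gradient 0.008: peripheral-heavy conversion), post-2011 centre-weighted
  regreening (+0.016 yr⁻¹, gradient 0.06), population +3.5 %/yr with a
  −0.2 %/yr σ trend. *north-like*: monotone greening (+0.0025 yr⁻¹,
  gradient 0.001), population +0.8 %/yr. These phase parameters were set
  by a design calculation on the generator's closed-form truth surfaces
  (pairwise-slope counting for the Theil–Sen median of the V-shaped
  exposure series, and an overshoot bound for the centre's catch-up), so
  that the two presets realize the intended qualitative regimes — loss
  with steady-or-rising exposure and falling inequality versus monotone
  greening with a smaller inequality decline — robustly across seeds.

### What the generator does not emulate

No atmospheric or directional-reflectance physics, no spatially correlated
cloud systems, no mixed water pixels or shoreline dynamics, no seasonal
population movement, and no error structure in the population surface
(it is treated as exact). Passing tests therefore demonstrate the
correctness and calibration of the *method chain* under controlled
conditions, not the accuracy of any real-archive product.

### Known biases, by design

Maximum-NDVI compositing selects on noisy NDVI, so composited signatures
of phenology-flat surfaces carry a positive NDVI selection bias of order
the index noise (≈ 5 × 10⁻³ per band at noise sd 0.01). This is a
well-known property of maximum-value composites, visible here in the
endmember means of the impervious and water classes; the single-peak
vegetation phenology avoids it for the vegetation class, and the
end-to-end fraction RMSE (≤ 0.02 at noise sd 0.01) already includes it.
Under clouds, a missed peak date yields a composite from a lower
phenology tier (up to ~10% relative greenness deficit); the
Savitzky–Golay stage and the robust trend statistics absorb these dips.

## Numerical choices

* Composite ties: earliest date. Unmixing ties: larger support, then lower
  endmember index. Zero index denominators: index set to 0 and the pixel
  barred from endmember candidacy.
* Georeference: row-major, north-up, pixel-centre registration for
  point-in-polygon tests (all-touched = false); grids compared with exact
  shape and near-exact origin/cell-size checks.
* Rasters on disk: ESRI ASCII grid, nodata −9999; boundaries GeoJSON;
  tables CSV with `%.10g` floats (byte-stable for checksumming); configs
  YAML; the run manifest records a config hash and per-file SHA-256.
* One integer seed drives all randomness through `SeedSequence` spawning;
  per-year substreams make scenes byte-identical across runs.
* Degenerate inputs raise: empty masks, zero in-city population (with the
  year named), constant series in the correlation, duplicate years,
  Mann–Kendall below n = 4, inequality metrics on non-positive means or
  (for Theil/Atkinson ε ≥ 1) non-positive values.

## Problem sizes

The test suite and the acceptance script use 60 × 60 (scenarios) and
64 × 64 (accuracy benchmark) scenes over 19 years, 10,000 null series for
the Mann–Kendall calibration, 1,000 replicates for slope recovery, and
100-instance oracle sweeps; the full suite runs in well under a minute.
These sizes were chosen so every check is exhaustive at desk scale while
the whole pipeline stays interactive.

## Limitations

Single-city, single-sensor abstraction; three fixed endmember classes; no
uncertainty propagation onto exposure or attribution outputs (point
decompositions only, matching the method's standard usage); no
between-group equity decomposition (the indices measure equality of
exposure, not demographic equity); no mobility or time-activity weighting
of exposure.
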