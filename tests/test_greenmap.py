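import itertools

import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from greenexpo import (
    Georef,
    Raster,
    aggregate_to_grid,
    city_coverage,
    fraction_agreement,
    harmonize,
    max_value_composite,
    select_endmembers,
    sg_smooth,
    threshold_classify,
    unmix_map,
    unmix_pixel,
)
from greenexpo.greenmap import AnnualComposite, EndmemberSelectionError, IDENTITY_COEFFS
from greenexpo.grids import CityMask
from greenexpo.scene import ObservationStack, generate_endmembers
from greenexpo.spectra import SpectralSignature, ndvi, ndwi

GEOREF30 = Georef(0.0, 90.0, 30.0)


def stack_from_bands(bands, clear=None):
    """bands: (n_obs, 4, rows, cols) array-like."""
    refl = np.asarray(bands, dtype=float)
    if clear is None:
        clear = np.ones(refl.shape[:1] + refl.shape[2:], dtype=bool)
    return ObservationStack(
        year=2000,
        dates=np.arange(1, refl.shape[0] + 1),
        reflectance=refl,
        clear=np.asarray(clear, bool),
        georef=Georef(0.0, refl.shape[2] * 30.0, 30.0),
    )


def obs_with_ndvi(target_ndvi):
    """A 4-band spectrum whose NDVI equals target (nir+red fixed at 0.5)."""
    nir = 0.25 * (1 + target_ndvi)
    red = 0.5 - nir
    return [0.1, 0.2, red, nir]


# ---------------------------------------------------------------------------
# harmonization


class TestHarmonize:
    def test_identity_is_a_no_op(self, rng):
        stack = stack_from_bands(rng.random((3, 4, 2, 2)))
        out = harmonize(stack, IDENTITY_COEFFS)
        np.testing.assert_array_equal(out.reflectance, stack.reflectance)
        np.testing.assert_array_equal(out.clear, stack.clear)

    def test_affine_fixed_point(self):
        stack = stack_from_bands(np.full((1, 4, 1, 1), 0.5))
        out = harmonize(stack, [(0.5, 0.25)] * 4)
        np.testing.assert_allclose(out.reflectance, 0.5)

    def test_gain_clips_to_unit_interval(self):
        stack = stack_from_bands(np.full((1, 4, 1, 1), 0.8))
        out = harmonize(stack, [(2.0, 0.0)] * 4)
        np.testing.assert_allclose(out.reflectance, 1.0)

    def test_non_finite_coefficients_rejected(self, rng):
        stack = stack_from_bands(rng.random((1, 4, 1, 1)))
        with pytest.raises(ValueError):
            harmonize(stack, [(1.0, np.nan)] * 4)


# ---------------------------------------------------------------------------
# maximum-NDVI compositing


class TestMaxValueComposite:
    def test_contaminated_observations_excluded(self):
        bands = np.array(
            [[[v] for v in obs_with_ndvi(x)] for x in (0.3, 0.5, 0.7)]
        ).reshape(3, 4, 1, 1)
        clear = np.array([1, 1, 0], bool).reshape(3, 1, 1)
        comp = max_value_composite(stack_from_bands(bands, clear))
        assert comp.signature[4, 0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_single_clear_observation_is_kept_verbatim(self, rng):
        bands = rng.random((1, 4, 3, 3))
        comp = max_value_composite(stack_from_bands(bands))
        np.testing.assert_array_equal(comp.signature[:4], bands[0])
        np.testing.assert_allclose(comp.signature[4], ndvi(bands[0, 3], bands[0, 2]))
        np.testing.assert_allclose(comp.signature[5], ndwi(bands[0, 1], bands[0, 3]))

    def test_all_contaminated_pixel_year_yields_missing(self, rng):
        bands = rng.random((2, 4, 2, 2))
        clear = np.ones((2, 2, 2), bool)
        clear[:, 0, 0] = False
        comp = max_value_composite(stack_from_bands(bands, clear))
        assert comp.missing[0, 0] and not comp.missing[1, 1]

    def test_matches_brute_force_argmax_with_earliest_date_tie_rule(self, rng):
        n_obs, rows, cols = 5, 4, 4
        bands = rng.random((n_obs, 4, rows, cols))
        bands[3] = bands[1]  # manufacture exact NDVI ties
        clear = rng.random((n_obs, rows, cols)) > 0.3
        comp = max_value_composite(stack_from_bands(bands, clear))
        for i, j in itertools.product(range(rows), range(cols)):
            cand = [
                (t, ndvi(bands[t, 3, i, j], bands[t, 2, i, j]))
                for t in range(n_obs)
                if clear[t, i, j]
            ]
            if not cand:
                assert comp.missing[i, j]
                continue
            best_ndvi = max(v for _, v in cand)
            t_best = min(t for t, v in cand if v == best_ndvi)  # earliest wins
            np.testing.assert_array_equal(comp.signature[:4, i, j], bands[t_best, :, i, j])


# ---------------------------------------------------------------------------
# endmember selection


def composite_from_signatures(sig_grid, year=2000):
    """sig_grid: (6, rows, cols)."""
    sig = np.asarray(sig_grid, dtype=float)
    return AnnualComposite(sig, year, Georef(0.0, sig.shape[1] * 30.0, 30.0))


def pure_composites(em, years=3):
    """Composites whose three pixels are the pure endmember signatures."""
    sig = np.stack([m.as_vector() for m in em.members], axis=1).reshape(6, 1, 3)
    return [composite_from_signatures(sig, 2000 + k) for k in range(years)]


class TestSelectEndmembers:
    def test_exact_recovery_from_pure_stable_pixels(self):
        em = generate_endmembers(3)
        out = select_endmembers(pure_composites(em))
        np.testing.assert_allclose(out.matrix(), em.matrix(), atol=1e-14)

    def test_pixel_failing_the_constraint_in_one_year_is_excluded(self):
        em = generate_endmembers(3)
        comps = pure_composites(em)
        # second vegetation-like pixel: NDVI 0.85 in all years but 0.6 once
        good = em.vegetation.as_vector()
        wobbly = good.copy()
        sig = np.concatenate([c.signature for c in comps]).reshape(3, 6, 1, 3)
        sig = np.concatenate([sig, np.zeros((3, 6, 1, 1))], axis=3)
        for k in range(3):
            sig[k, :, 0, 3] = wobbly
        sig[1, 4, 0, 3] = 0.6  # dips below 0.8 in year 2
        sig[1, 3, 0, 3] = 0.4  # keep bands consistent-ish
        comps2 = [composite_from_signatures(sig[k], 2000 + k) for k in range(3)]
        out = select_endmembers(comps2)
        # mean must equal the single stable pixel, not include the wobbly one
        np.testing.assert_allclose(
            out.vegetation.as_vector(), em.vegetation.as_vector(), atol=1e-14
        )

    def test_missing_class_raises_named_error(self):
        em = generate_endmembers(3)
        comps = pure_composites(em)
        for c in comps:  # destroy all water candidates
            c.signature[5] = -0.5
        with pytest.raises(EndmemberSelectionError, match="water"):
            select_endmembers(comps)

    def test_noisy_recovery_within_standard_error(self, rng):
        # unbiased noisy composites of pure pixels: the recovered signature
        # is a mean of ~N noisy samples, so it must sit within 3 standard
        # errors of truth per band
        em = generate_endmembers(6)
        years, npix = 19, 300  # pixels per class
        sd = 0.01
        truth_bands = em.band_matrix()  # (4, 3)
        comps = []
        for k in range(years):
            bands = np.repeat(truth_bands, npix, axis=1)  # (4, 3*npix)
            bands = np.clip(bands + rng.normal(0, sd, bands.shape), 0, 1)
            sig = np.empty((6, 1, 3 * npix))
            sig[:4, 0] = bands
            sig[4, 0] = ndvi(bands[3], bands[2])
            sig[5, 0] = ndwi(bands[1], bands[3])
            comps.append(composite_from_signatures(sig, 2000 + k))
        est = select_endmembers(comps)
        tol = 3 * sd / np.sqrt(npix * years)
        diff = np.abs(est.band_matrix() - truth_bands)
        assert diff.max() < tol


# ---------------------------------------------------------------------------
# constrained unmixing


def simplex_grid_search(vec, em, step=1e-3):
    """Dense search over the 2-simplex, locally refined; independent oracle."""
    C = em.matrix()

    def cost(f):
        r = vec - C @ f
        return float(r @ r)

    best, best_c = None, np.inf
    fs = np.arange(0.0, 1.0 + step / 2, step)
    for f1 in fs:
        for f2 in np.arange(0.0, 1.0 - f1 + step / 2, step):
            f = np.array([f1, f2, 1.0 - f1 - f2])
            c = cost(f)
            if c < best_c:
                best, best_c = f, c
    for _ in range(4):  # local refinement down to 1e-7 steps
        step /= 10
        improved = True
        while improved:  # walk the lattice until locally optimal
            improved = False
            f0 = best
            for d1 in range(-10, 11):
                for d2 in range(-10, 11):
                    f = f0 + np.array([d1 * step, d2 * step, -(d1 + d2) * step])
                    if (f >= 0).all():
                        c = cost(f)
                        if c < best_c:
                            best, best_c, improved = f, c, True
    return best


@pytest.fixture(scope="module")
def em():
    return generate_endmembers(2)


class TestUnmixPixel:
    def test_exact_interior_mixture_recovered_with_zero_residual(self, em):
        vec = 0.6 * em.vegetation.as_vector() + 0.4 * em.impervious.as_vector()
        sig = SpectralSignature(*vec)
        f, resid = unmix_pixel(sig, em)
        np.testing.assert_allclose(f, [0.6, 0.4, 0.0], atol=1e-10)
        assert resid == pytest.approx(0.0, abs=1e-10)

    def test_pure_water_vertex(self, em):
        f, resid = unmix_pixel(em.water, em)
        np.testing.assert_allclose(f, [0.0, 0.0, 1.0], atol=1e-12)
        assert resid == pytest.approx(0.0, abs=1e-12)

    def test_noisy_signatures_match_simplex_grid_search(self, em, rng):
        for _ in range(5):
            f_true = rng.dirichlet([2, 2, 1])
            vec = em.matrix() @ f_true + rng.normal(0, 0.02, 6)
            vec = np.clip(vec, -1, 1)
            sig = SpectralSignature(*np.clip(vec[:4], 0, 1), ndvi=vec[4], ndwi=vec[5])
            f, _ = unmix_pixel(sig, em)
            f_oracle = simplex_grid_search(sig.as_vector(), em)
            np.testing.assert_allclose(f, f_oracle, atol=1e-6)

    def test_non_finite_signature_rejected(self, em):
        sig = SpectralSignature(0.1, 0.2, 0.3, 0.4, ndvi=np.nan, ndwi=0.0)
        with pytest.raises(ValueError):
            unmix_pixel(sig, em)


class TestUnmixMap:
    def test_agrees_with_per_pixel_loop(self, rng):
        em = generate_endmembers(4)
        rows, cols = 5, 6
        f_true = rng.dirichlet([3, 3, 1], size=rows * cols).T.reshape(3, rows, cols)
        sig = np.einsum("ck,krc->crc".replace("rc", "xy"), em.matrix(), f_true)
        sig += rng.normal(0, 0.01, sig.shape)
        comp = composite_from_signatures(sig)
        comp.signature[:, 0, 0] = np.nan  # a missing pixel propagates
        fmap, resid = unmix_map(comp, em)
        assert np.isnan(fmap.data[0, 0]) and np.isnan(resid.data[0, 0])
        for i, j in itertools.product(range(rows), range(cols)):
            if i == j == 0:
                continue
            v = comp.signature[:, i, j]
            s = SpectralSignature(*np.clip(v[:4], 0, 1), ndvi=v[4], ndwi=v[5])
            f, r = unmix_pixel(s, em)
            assert fmap.data[i, j] == pytest.approx(f[0], abs=1e-12)
            assert resid.data[i, j] == pytest.approx(r, abs=1e-12)

    def test_pure_vegetation_composite_gives_unit_fractions(self):
        em = generate_endmembers(1)
        sig = np.tile(em.vegetation.as_vector()[:, None, None], (1, 3, 3))
        fmap, _ = unmix_map(composite_from_signatures(sig), em)
        np.testing.assert_allclose(fmap.data, 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# temporal smoothing


def series_of(values, rows=2, cols=2):
    return [
        Raster(np.full((rows, cols), v), Georef(0, rows * 100.0, 100.0), 2000 + i)
        for i, v in enumerate(values)
    ]


class TestSgSmooth:
    def test_constant_series_unchanged(self):
        out = sg_smooth(series_of([0.4] * 9))
        for r in out:
            np.testing.assert_allclose(r.data, 0.4, atol=1e-12)

    def test_linear_series_reproduced(self):
        vals = 0.1 + 0.02 * np.arange(11)
        out = sg_smooth(series_of(vals))
        got = [r.data[0, 0] for r in out]
        np.testing.assert_allclose(got, vals, atol=1e-12)

    def test_interior_matches_analytic_savitzky_golay_coefficients(self, rng):
        vals = rng.random(15)
        out = sg_smooth(series_of(vals), window=5, polyorder=2)
        coeffs = savgol_coeffs(5, 2)[::-1]
        for k in range(2, 13):
            want = np.clip(coeffs @ vals[k - 2 : k + 3], 0, 1)
            assert out[k].data[1, 1] == pytest.approx(want, abs=1e-12)

    def test_missing_years_interpolated_then_reflagged(self):
        vals = list(0.2 + 0.05 * np.arange(9))
        series = series_of(vals)
        series[4].data[0, 0] = np.nan
        out = sg_smooth(series)
        assert np.isnan(out[4].data[0, 0])  # re-flagged missing
        # linear gap fill means the linear series is still reproduced nearby
        assert out[3].data[0, 0] == pytest.approx(vals[3], abs=1e-12)
        assert out[4].data[1, 1] == pytest.approx(vals[4], abs=1e-12)

    def test_output_stays_in_unit_interval(self, rng):
        vals = np.clip(rng.random(9) * 1.4 - 0.2, 0, 1)
        out = sg_smooth(series_of(vals))
        for r in out:
            assert ((r.data >= 0) & (r.data <= 1)).all()

    @pytest.mark.parametrize(
        "kwargs", [{"window": 4}, {"window": 5, "polyorder": 5}]
    )
    def test_invalid_filter_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sg_smooth(series_of([0.1] * 9), **kwargs)

    def test_series_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            sg_smooth(series_of([0.1] * 3), window=5)


# ---------------------------------------------------------------------------
# aggregation, classification, coverage, agreement


class TestAggregateToGrid:
    def test_constant_map_invariant(self):
        r = Raster(np.full((10, 10), 0.7), Georef(0, 300.0, 30.0), 2000)
        out = aggregate_to_grid(r, 100.0)
        assert out.shape == (3, 3)
        np.testing.assert_allclose(out.data, 0.7, atol=1e-12)

    def test_two_by_two_block_mean(self):
        r = Raster(np.array([[1.0, 0.0], [0.0, 1.0]]), Georef(0, 60.0, 30.0), 2000)
        out = aggregate_to_grid(r, 60.0)
        assert out.data.shape == (1, 1)
        assert out.data[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_matches_naive_subcell_loop(self, rng):
        rows = cols = 10
        r = Raster(rng.random((rows, cols)), Georef(0, rows * 30.0, 30.0), 2000)
        out = aggregate_to_grid(r, 100.0)
        # 10-m common lattice: source cell of subcell (a, b) is (a//3, b//3)
        dense = np.empty((rows * 3, cols * 3))
        for a in range(rows * 3):
            for b in range(cols * 3):
                dense[a, b] = r.data[a // 3, b // 3]
        for i in range(3):
            for j in range(3):
                want = dense[10 * i : 10 * i + 10, 10 * j : 10 * j + 10].mean()
                assert out.data[i, j] == pytest.approx(want, abs=1e-12)

    def test_incompatible_extent_rejected(self, rng):
        r = Raster(rng.random((7, 7)), Georef(0, 210.0, 30.0), 2000)
        with pytest.raises(ValueError, match="tile"):
            aggregate_to_grid(r, 100.0)


class TestThresholdClassify:
    def test_boundary_is_inclusive(self, raster_factory):
        r = raster_factory([[0.25, 0.3, 0.45]])
        out = threshold_classify(r, 0.3)
        np.testing.assert_array_equal(out.data, [[0.0, 1.0, 1.0]])

    def test_all_below_gives_zeros(self, raster_factory):
        out = threshold_classify(raster_factory([[0.1, 0.49]]), 0.5)
        np.testing.assert_array_equal(out.data, [[0.0, 0.0]])

    def test_coverage_non_increasing_in_threshold(self, raster_factory, mask_factory, rng):
        for _ in range(10):
            r = raster_factory(rng.random((6, 6)))
            m = mask_factory(r)
            covs = [city_coverage(threshold_classify(r, t), m) for t in (0.3, 0.4, 0.5)]
            assert covs[0] >= covs[1] >= covs[2]

    def test_tau_outside_open_interval_rejected(self, raster_factory):
        with pytest.raises(ValueError):
            threshold_classify(raster_factory([[0.5]]), 1.0)


class TestCityCoverage:
    def test_constant_inside_mask(self, raster_factory, mask_factory):
        r = raster_factory(np.full((4, 4), 0.3))
        assert city_coverage(r, mask_factory(r)) == pytest.approx(0.3)

    def test_two_pixel_mean(self, raster_factory):
        r = raster_factory([[0.2, 0.6], [0.9, 0.9]])
        mask = CityMask(np.array([[True, True], [False, False]]), r.georef)
        assert city_coverage(r, mask) == pytest.approx(0.4)

    def test_matches_masked_loop(self, raster_factory, rng):
        data = rng.random((8, 8))
        data[rng.random((8, 8)) < 0.1] = np.nan
        r = raster_factory(data)
        m = CityMask(rng.random((8, 8)) < 0.6, r.georef)
        tot, n = 0.0, 0
        for i in range(8):
            for j in range(8):
                if m.mask[i, j] and np.isfinite(data[i, j]):
                    tot += data[i, j]
                    n += 1
        assert city_coverage(r, m) == pytest.approx(tot / n, abs=1e-12)

    def test_empty_intersection_rejected(self, raster_factory):
        r = raster_factory(np.full((2, 2), np.nan))
        with pytest.raises(ValueError):
            city_coverage(r, CityMask(np.ones((2, 2), bool), r.georef))


class TestFractionAgreement:
    def test_identical_series_is_one(self):
        assert fraction_agreement([0.1, 0.5, 0.3], [0.1, 0.5, 0.3]) == pytest.approx(1.0)

    def test_negated_series_is_minus_one(self):
        a = np.array([0.1, 0.4, 0.2, 0.8])
        assert fraction_agreement(a, -a + 1.0) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        a, b = rng.random(10), rng.random(10)
        num = ((a - a.mean()) * (b - b.mean())).sum()
        den = np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        assert fraction_agreement(a, b) == pytest.approx(num / den, abs=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            fraction_agreement([0.2, 0.2, 0.2], [0.1, 0.5, 0.3])
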