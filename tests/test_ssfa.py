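"""Scale-sensitive fractal analysis: leveling, relative area, Asfc, epLsar, HAsfc."""

import numpy as np
import pytest

from dentoproxy.errors import LevelingError
from dentoproxy.ssfa import (
    asfc_smc,
    eplsar,
    extract_region,
    hasfc,
    level,
    relative_area,
    relative_area_curve,
    texture_direction,
)
from dentoproxy.surfaces import HeightMap
from dentoproxy.synthetic import fractal_background


def exhaustive_asfc_oracle(curve, window=5):
    """Naive steepest-window search with explicit least-squares slope."""
    pts = sorted(curve)
    best = (np.inf, None)
    for s in range(len(pts) - window + 1):
        xs = [np.log(p[0]) for p in pts[s : s + window]]
        ys = [np.log(p[1]) for p in pts[s : s + window]]
        n = len(xs)
        mx, my = sum(xs) / n, sum(ys) / n
        slope = sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / sum((x - mx) ** 2 for x in xs)
        if slope < best[0] - 1e-15:
            best = (slope, pts[s][0])
    return -1000.0 * min(best[0], 0.0), best[1]


def ridge_map(theta_deg, n=128, sp=0.83, wavelength=8.0, amp=0.8):
    x, y = np.meshgrid(np.arange(n) * sp, (n - 1 - np.arange(n)) * sp)
    th = np.radians(theta_deg)
    phase = -np.sin(th) * x + np.cos(th) * y
    return HeightMap(amp * np.sin(2 * np.pi * phase / wavelength), sp, sp)


class TestLevel:
    def test_plane_removed_entirely(self, plane_map):
        out = level(plane_map)
        assert np.abs(out.heights).max() < 1e-9

    def test_idempotent(self, rng):
        hm = HeightMap(rng.normal(size=(30, 30)), 1, 1)
        once = level(hm)
        twice = level(once)
        assert np.abs(twice.heights - once.heights).max() < 1e-9

    def test_residual_uncorrelated_with_coordinates(self, rng):
        x, y = np.meshgrid(np.arange(50.0), np.arange(50.0))
        hm = HeightMap(1.5 * x - 0.5 * y + rng.normal(size=x.shape), 1, 1)
        out = level(hm)
        r = out.heights.ravel()
        assert abs(r.mean()) < 1e-9
        # OLS normal equations: residual orthogonal to both regressors
        assert abs(np.dot(r, x.ravel()) / len(r)) < 1e-8
        assert abs(np.dot(r, y.ravel()) / len(r)) < 1e-8

    def test_collinear_support_rejected(self):
        z = np.full((1, 5), np.nan)
        hm = HeightMap(np.vstack([np.arange(5.0), z, z]), 1, 1)
        with pytest.raises(LevelingError):
            level(hm)


class TestExtractRegion:
    def test_centered_crop_offsets_floored(self):
        hm = HeightMap(np.arange(768 * 576, dtype=float).reshape(576, 768), 0.83, 0.83)
        crop = extract_region(hm, 500)
        assert crop.shape == (500, 500)
        # offsets: (576-500)//2 = 38 rows, (768-500)//2 = 134 cols
        assert crop.heights[0, 0] == hm.heights[38, 134]

    def test_full_size_is_identity(self, rng):
        hm = HeightMap(rng.normal(size=(16, 16)), 1, 1)
        assert np.array_equal(extract_region(hm, 16).heights, hm.heights)

    def test_small_arithmetic(self):
        hm = HeightMap(np.arange(100, dtype=float).reshape(10, 10), 1, 1)
        crop = extract_region(hm, 4)
        assert np.array_equal(crop.heights, hm.heights[3:7, 3:7])

    def test_oversize_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_region(HeightMap(rng.normal(size=(8, 8)), 1, 1), 9)


class TestRelativeArea:
    def test_plane_exactly_one_at_all_scales(self, flat_map):
        for k in (1, 2, 5, 16):
            _, ratio = relative_area(flat_map, k)
            assert ratio == 1.0

    def test_45_degree_incline_sqrt2(self):
        x, _ = np.meshgrid(np.arange(64, dtype=float), np.arange(64, dtype=float))
        hm = HeightMap(x, 1.0, 1.0)  # z = x, unleveled on purpose
        for k in (1, 2, 8):
            _, ratio = relative_area(hm, k)
            assert ratio == pytest.approx(np.sqrt(2), rel=1e-12)

    def test_ratio_at_least_one(self, rng):
        hm = HeightMap(fractal_background(64, 0.5, 0.5, rng), 0.83, 0.83)
        for s, ratio in relative_area_curve(hm):
            assert ratio >= 1.0

    def test_self_affine_fine_above_coarse(self, rng):
        """Direct triangulation at two well-separated scales: the fine scale
        measures at least as much area as the coarse scale."""
        for _ in range(5):
            hm = HeightMap(fractal_background(96, 0.5, 0.5, rng), 0.83, 0.83)
            _, fine = relative_area(hm, 2)
            _, coarse = relative_area(hm, 32)
            assert fine >= coarse - 1e-9

    def test_out_of_range_scale_rejected(self, flat_map):
        with pytest.raises(ValueError):
            relative_area(flat_map, 0)
        with pytest.raises(ValueError):
            relative_area(flat_map, 10_000)


class TestAsfcSmc:
    def test_plane_zero_complexity(self, flat_map):
        curve = relative_area_curve(flat_map)
        a, _ = asfc_smc(curve)
        assert a == 0.0

    def test_analytic_loglog_slope(self):
        scales = 2.0 ** np.arange(12)
        rel = np.exp(-0.002 * np.log(scales) + 0.1)
        a, smc = asfc_smc(list(zip(scales, rel)))
        assert a == pytest.approx(2.0, rel=1e-9)
        assert smc == scales[0]

    def test_matches_exhaustive_window_oracle(self, rng):
        for _ in range(10):
            hm = HeightMap(fractal_background(128, rng.uniform(0.3, 0.9), 0.5, rng), 0.83, 0.83)
            curve = relative_area_curve(hm)
            a, smc = asfc_smc(curve)
            oa, osmc = exhaustive_asfc_oracle(curve)
            assert a == pytest.approx(oa, rel=1e-9)
            assert smc == osmc

    def test_too_few_scales_rejected(self):
        with pytest.raises(ValueError):
            asfc_smc([(1.0, 1.0), (2.0, 1.0)], window=5)


class TestEplsar:
    def test_plane_perfectly_isotropic(self, flat_map):
        ep, _, rose = eplsar(flat_map)
        assert ep < 1e-12
        props = np.array(list(rose.values()))
        assert props.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(props, props[0])

    @pytest.mark.parametrize("theta", [0, 30, 77, 120])
    def test_ridge_orientation_recovered(self, theta):
        ep, direction, _ = eplsar(ridge_map(theta))
        recovered = texture_direction(direction)
        delta = min(abs(recovered - theta), 180 - abs(recovered - theta))
        assert delta <= 5.0
        assert ep > 1e-3

    def test_isotropic_noise_below_permutation_null(self, rng):
        hm = HeightMap(rng.normal(scale=0.3, size=(96, 96)), 0.83, 0.83)
        ep, _, rose = eplsar(hm)
        props = np.array(list(rose.values()))
        thetas = np.radians(2 * np.array(list(rose.keys())))
        null = []
        for _ in range(199):
            p = rng.permutation(props)
            null.append(np.hypot((p * np.cos(thetas)).sum(), (p * np.sin(thetas)).sum()))
        assert ep <= np.quantile(null, 0.95)

    def test_rose_sums_to_one(self, rng):
        hm = HeightMap(fractal_background(64, 0.5, 0.3, rng), 0.83, 0.83)
        _, _, rose = eplsar(hm)
        assert sum(rose.values()) == pytest.approx(1.0, abs=1e-12)


class TestHasfc:
    def test_tiled_identical_patches_zero(self, rng):
        patch = fractal_background(16, 0.5, 0.5, rng)
        hm = HeightMap(np.tile(patch, (9, 9)), 0.83, 0.83)
        assert hasfc(hm) == 0.0

    def test_plane_zero_by_convention(self):
        assert hasfc(HeightMap(np.zeros((144, 144)), 1, 1)) == 0.0

    def test_heterogeneous_exceeds_homogeneous(self, rng):
        base = fractal_background(144, 0.7, 0.2, rng)
        hetero = base.copy()
        hetero[:72, :72] += fractal_background(72, 0.3, 1.5, rng)
        h_hom = hasfc(HeightMap(base, 0.83, 0.83))
        h_het = hasfc(HeightMap(hetero, 0.83, 0.83))
        assert h_het > h_hom

    def test_degenerate_cell_named(self):
        with pytest.raises(ValueError, match=r"cell"):
            hasfc(HeightMap(np.zeros((12, 12)), 1, 1))


class TestInvariances:
    def test_asfc_invariant_under_added_plane(self, rng):
        z = fractal_background(96, 0.5, 0.5, rng)
        x, y = np.meshgrid(np.arange(96.0), np.arange(96.0))
        a0, _ = asfc_smc(relative_area_curve(level(HeightMap(z, 1, 1))))
        a1, _ = asfc_smc(relative_area_curve(level(HeightMap(z + 3 * x - 2 * y + 10, 1, 1))))
        assert a1 == pytest.approx(a0, rel=1e-6)

    def test_vertical_rescale_does_not_decrease_asfc(self, rng):
        for _ in range(5):
            z = fractal_background(96, rng.uniform(0.3, 0.9), 0.5, rng)
            a1, _ = asfc_smc(relative_area_curve(HeightMap(z, 1, 1)))
            a2, _ = asfc_smc(relative_area_curve(HeightMap(2.5 * z, 1, 1)))
            assert a2 >= a1 - 1e-12

    def test_eplsar_equivariant_under_90_degree_rotation(self):
        hm = ridge_map(30)
        rot = HeightMap(np.rot90(hm.heights).copy(), hm.dx, hm.dy)
        _, d0, _ = eplsar(hm)
        _, d1, _ = eplsar(rot)
        delta = abs((d1 - d0) % 180)
        assert min(delta, 180 - delta) == pytest.approx(90.0, abs=5.0)
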