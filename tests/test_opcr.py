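"""Orientation patch counting: rasterization, aspect binning, patches."""

import numpy as np
import pytest

from dentoproxy.opcr import (
    FLAT,
    GridSpec,
    OrientationGrid,
    count_patches,
    opcr,
    orientation_bins,
    rasterize_crown,
)
from dentoproxy.surfaces import CrownMesh, HeightMap
from dentoproxy.synthetic import SyntheticCrownSpec, make_crown

from conftest import brute_force_patch_count, ray_heights


def tilted_plane_map(n=40, gx=0.3, gy=0.7):
    x, y = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
    return HeightMap(gx * x + gy * y, 1.0, 1.0)


class TestRasterize:
    def test_hemisphere_apex_height(self):
        crown, _, _ = make_crown(SyntheticCrownSpec(shape="hemisphere", radius=1.0, sections=128))
        hm = rasterize_crown(crown, GridSpec(rpt=50))
        ny, nx = hm.shape
        assert hm.heights[ny // 2, nx // 2] == pytest.approx(1.0, abs=0.01)

    def test_tilted_plane_rasterizes_linearly(self):
        v = np.array([[0, 0, 0], [4, 0, 2], [0, 6, 3], [4, 6, 5]], float)
        f = np.array([[0, 1, 3], [0, 3, 2]])
        hm = rasterize_crown(CrownMesh(v, f), GridSpec(rpt=12))
        X, Y = hm.cell_xy()
        assert np.nanmax(np.abs(hm.heights - (0.5 * X + 0.5 * Y))) < 1e-12

    def test_overhang_records_top_surface(self):
        # mushroom: narrow column under a wide cap; max-z must see the cap
        import trimesh

        stem = trimesh.creation.box((1, 1, 4))
        stem.apply_translation((0, 0, 2))
        cap = trimesh.creation.box((4, 4, 1))
        cap.apply_translation((0, 0, 4.5))
        mush = trimesh.util.concatenate([stem, cap])
        mesh = CrownMesh(np.asarray(mush.vertices), np.asarray(mush.faces))
        hm = rasterize_crown(mesh, GridSpec(rpt=10))
        X, Y = hm.cell_xy()
        oracle = ray_heights(mesh, X.ravel(), Y.ravel()).reshape(hm.shape)
        both = hm.mask & np.isfinite(oracle)
        assert both.sum() > 50
        assert np.abs(hm.heights[both] - oracle[both]).max() < 1e-9
        # every cap-covered cell records the cap top, not the stem
        assert hm.heights[both].max() == pytest.approx(5.0, abs=1e-12)

    def test_empty_footprint_rejected(self):
        v = np.array([[0, 0, 0], [0, 0, 1], [0, 1, 0]], float)
        with pytest.raises(ValueError):
            rasterize_crown(CrownMesh(v, np.array([[0, 1, 2]])), GridSpec(rpt=4))


class TestOrientationBins:
    def test_uniform_dip_single_bin(self):
        # plane dipping due north: downhill aspect 90° everywhere -> one bin
        n = 20
        _, rows = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
        # row 0 is the max-y (northern) edge, so z = row index falls northward
        hm = HeightMap(rows, 1.0, 1.0)
        grid = orientation_bins(hm)
        assert len(np.unique(grid.bins)) == 1
        assert np.unique(grid.bins)[0] == 2  # aspect 90° -> bin [90, 135)

    def test_horizontal_plane_all_flat(self):
        grid = orientation_bins(HeightMap(np.zeros((15, 15)), 1, 1))
        assert (grid.bins == FLAT).all()

    def test_eggcrate_matches_brute_force_aspect(self):
        n = 64
        x, y = np.meshgrid(
            np.linspace(0, 2 * np.pi, n), np.linspace(2 * np.pi, 0, n)  # row 0 = max y
        )
        hm = HeightMap(np.sin(x) * np.sin(y), x[0, 1] - x[0, 0], x[0, 1] - x[0, 0])
        grid = orientation_bins(hm, rotation_offset=10.0)
        # independent per-cell aspect: central differences on interior cells
        z = hm.heights
        gx = (z[1:-1, 2:] - z[1:-1, :-2]) / (2 * hm.dx)
        gy = -(z[2:, 1:-1] - z[:-2, 1:-1]) / (2 * hm.dy)
        aspect = np.degrees(np.arctan2(-gy, -gx)) % 360
        expect = np.floor(((aspect - 10.0) % 360) / 45).astype(int)
        slope = np.hypot(gx, gy)
        interior = grid.bins[1:-1, 1:-1]
        nonflat = slope > 0
        assert np.array_equal(interior[nonflat], expect[nonflat])


class TestCountPatches:
    @staticmethod
    def _grid(bins):
        bins = np.asarray(bins)
        return OrientationGrid(bins=bins, rotation_offset=0.0, footprint=bins >= 0)

    def test_uniform_grid_single_patch(self):
        total, per_bin = count_patches(self._grid(np.full((6, 6), 3)), min_patch_size=3)
        assert total == 1
        assert per_bin[3] == 1

    def test_checkerboard_all_below_min_size(self):
        bins = np.indices((8, 8)).sum(axis=0) % 2
        total, _ = count_patches(self._grid(bins), min_patch_size=3)
        assert total == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_maps_match_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        bins = rng.integers(0, 8, (20, 20))
        for mps in (1, 3, 5):
            total, per_bin = count_patches(self._grid(bins), min_patch_size=mps)
            o_total, o_bin = brute_force_patch_count(bins, mps)
            assert total == o_total
            assert per_bin == o_bin

    def test_counts_non_increasing_in_min_patch_size(self, rng):
        bins = rng.integers(0, 8, (30, 30))
        totals = [count_patches(self._grid(bins), m)[0] for m in range(1, 8)]
        assert all(a >= b for a, b in zip(totals, totals[1:]))


class TestOPCR:
    def test_tilted_plane_opcr_exactly_one(self):
        res = opcr(tilted_plane_map())
        assert res.opcr == 1.0
        assert res.per_rotation_counts == [1] * 8

    def test_opcr_equals_mean_of_rotations(self, rng):
        z = rng.normal(size=(40, 40)).cumsum(axis=0).cumsum(axis=1)
        res = opcr(HeightMap(z, 1.0, 1.0))
        assert res.opcr == np.mean(res.per_rotation_counts)

    def test_monotone_surface_invariant_to_rpt_and_rotations(self):
        for n, rots in ((24, 4), (60, 8), (100, 16)):
            res = opcr(tilted_plane_map(n=n), n_rotations=rots)
            assert res.opcr == 1.0

    def test_radial_surface_invariant_under_45_degree_bin_shift(self):
        # downhill cone z = -r covers all aspects uniformly; shifting the
        # bin boundaries by a full bin must reproduce the patch count
        n = 41
        x, y = np.meshgrid(np.arange(n) - n // 2, np.arange(n) - n // 2)
        hm = HeightMap(-np.hypot(x, y).astype(float), 1.0, 1.0)
        g0 = orientation_bins(hm, rotation_offset=0.0)
        g45 = orientation_bins(hm, rotation_offset=45.0)
        assert count_patches(g0)[0] == count_patches(g45)[0]

    def test_full_pipeline_on_eggcrate_matches_oracle(self):
        n = 60
        x, y = np.meshgrid(np.linspace(0, 6 * np.pi, n), np.linspace(6 * np.pi, 0, n))
        hm = HeightMap(np.sin(x) * np.sin(y), x[0, 1] - x[0, 0], x[0, 1] - x[0, 0])
        res = opcr(hm, min_patch_size=3, n_rotations=8)
        for k in range(8):
            grid = orientation_bins(hm, rotation_offset=k * 45.0 / 8)
            o_total, _ = brute_force_patch_count(
                np.where(grid.footprint, grid.bins, -2), 3
            )
            assert res.per_rotation_counts[k] == o_total

    def test_crown_mesh_end_to_end(self):
        crown, _, _ = make_crown(
            SyntheticCrownSpec(shape="cone", radius=3, height=8, sections=64)
        )
        res = opcr(crown, GridSpec(rpt=25))
        assert res.opcr >= 1.0
        assert res.rpt_used == 25
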