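import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import oracles
from firescape.raster_core import (
    Grid,
    distance_to_class,
    fractal_index,
    hex_aggregate,
    label_patches,
    read_ascii_grid,
    read_geotiff,
    remove_single_pixels,
    resample_majority,
    write_ascii_grid,
    write_geotiff,
)


class TestGrid:
    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            Grid(np.empty((0, 3)))

    def test_rejects_nonpositive_resolution(self):
        with pytest.raises(ValueError):
            Grid(np.zeros((2, 2)), resolution_m=0)

    def test_pixel_area(self):
        assert Grid(np.zeros((2, 2)), resolution_m=10).pixel_area_ha == 0.01
        assert Grid(np.zeros((2, 2)), resolution_m=30).pixel_area_ha == 0.09


class TestLabelPatches:
    def test_singleton(self, grid_10m):
        g = grid_10m([[0, 0], [0, 1]])
        patches = label_patches(g, 1)
        assert len(patches) == 1
        assert patches[0].area_ha == pytest.approx(10**2 / 1e4)
        assert patches[0].pixels == ((1, 1),)

    def test_diagonal_connectivity(self, grid_10m):
        g = grid_10m([[1, 0], [0, 1]])
        assert len(label_patches(g, 1, connectivity=8)) == 1
        assert len(label_patches(g, 1, connectivity=4)) == 2

    def test_checkerboard_4conn(self, grid_10m):
        vals = np.indices((4, 4)).sum(axis=0) % 2
        g = grid_10m(vals)
        patches = label_patches(g, 1, connectivity=4)
        # oracle: flood-fill enumeration
        comps = oracles.components(vals == 1, connectivity=4)
        assert len(comps) == 8
        assert len(patches) == len(comps)
        assert {frozenset(p.pixels) for p in patches} == {
            frozenset(c) for c in comps
        }

    def test_conservation(self, rng, grid_10m):
        vals = rng.integers(0, 3, size=(20, 20))
        g = grid_10m(vals)
        for cls in (0, 1, 2):
            patches = label_patches(g, cls)
            assert sum(len(p) for p in patches) == int((vals == cls).sum())
            total = sum(p.area_ha for p in patches)
            assert total == pytest.approx((vals == cls).sum() * g.pixel_area_ha)

    def test_perimeter_matches_edge_count(self, rng, grid_10m):
        vals = (rng.random((15, 15)) < 0.4).astype(int)
        g = grid_10m(vals)
        for p in label_patches(g, 1):
            assert p.perimeter_m == oracles.perimeter_m(set(p.pixels), 10.0)
            assert p.perimeter_m % g.resolution_m == 0

    def test_nodata_class_rejected(self, grid_10m):
        g = grid_10m([[0, 0], [0, 0]], nodata=-1)
        with pytest.raises(ValueError):
            label_patches(g, -1)


class TestFractalIndex:
    @pytest.mark.parametrize("side", [2, 3, 5, 8])
    def test_square_is_exactly_one(self, side, grid_30m):
        vals = np.zeros((side + 2, side + 2), dtype=int)
        vals[1 : 1 + side, 1 : 1 + side] = 1
        (patch,) = label_patches(grid_30m(vals), 1)
        assert fractal_index(patch) == pytest.approx(1.0, abs=1e-12)

    def test_strip_1x3(self, grid_30m):
        vals = np.zeros((3, 5), dtype=int)
        vals[1, 1:4] = 1
        (patch,) = label_patches(grid_30m(vals), 1)
        # P = 240 m, A = 2700 m^2 -> 2 ln 60 / ln 2700
        expected = 2 * math.log(60.0) / math.log(2700.0)
        assert expected == pytest.approx(1.0364, abs=5e-4)
        assert fractal_index(patch) == pytest.approx(expected, rel=1e-12)

    def test_l_shape_matches_oracle(self, grid_30m):
        vals = np.zeros((4, 4), dtype=int)
        for r, c in [(0, 0), (1, 0), (1, 1)]:
            vals[r, c] = 1
        (patch,) = label_patches(grid_30m(vals), 1)
        expected = oracles.fractal_from_pixels({(0, 0), (1, 0), (1, 1)}, 30.0)
        assert fractal_index(patch) == pytest.approx(expected, rel=1e-12)

    def test_translation_and_rotation_invariance(self, rng, grid_30m):
        base = np.zeros((20, 20), dtype=int)
        blob = [(5, 5), (5, 6), (6, 5), (6, 6), (7, 6), (7, 7), (8, 7)]
        for r, c in blob:
            base[r, c] = 1
        (p0,) = label_patches(grid_30m(base), 1)
        shifted = np.roll(base, (3, -2), axis=(0, 1))
        (p1,) = label_patches(grid_30m(shifted), 1)
        rotated = np.rot90(base)
        (p2,) = label_patches(grid_30m(rotated), 1)
        f = fractal_index(p0)
        assert fractal_index(p1) == pytest.approx(f, rel=1e-12)
        assert fractal_index(p2) == pytest.approx(f, rel=1e-12)

    def test_degenerate_area_rejected(self):
        patch_1m = label_patches(
            Grid(np.array([[1]]), resolution_m=1.0, nodata=-1), 1
        )[0]
        with pytest.raises(ValueError):
            fractal_index(patch_1m)


class TestDistanceToClass:
    def test_unit_step(self, grid_10m):
        g = grid_10m([[1, 0]])
        d = distance_to_class(g, 1)
        assert d.values[0, 0] == 0.0
        assert d.values[0, 1] == pytest.approx(10.0)

    def test_diagonal_step(self, grid_10m):
        g = grid_10m([[1, 0], [0, 0]])
        d = distance_to_class(g, 1)
        assert d.values[1, 1] == pytest.approx(10.0 * math.sqrt(2))

    def test_random_grid_matches_brute_force(self, rng, grid_10m):
        vals = (rng.random((16, 16)) < 0.1).astype(int)
        vals[3, 7] = 1  # ensure non-empty
        g = grid_10m(vals)
        d = distance_to_class(g, 1)
        expected = oracles.all_pairs_distance(vals == 1, 10.0)
        np.testing.assert_allclose(d.values, expected, atol=1e-9)

    def test_no_target_raises(self, grid_10m):
        with pytest.raises(ValueError, match="undefined"):
            distance_to_class(grid_10m([[0, 0]]), 1)


class TestResampleMajority:
    def test_uniform_block(self, grid_10m):
        g = grid_10m(np.full((6, 6), 4))
        out = resample_majority(g, 3)
        assert (out.values == 4).all()
        assert out.resolution_m == 30.0

    def test_strict_majority_5_4(self, grid_10m):
        block = np.array([[1, 1, 1], [1, 1, 0], [0, 0, 0]])
        out = resample_majority(grid_10m(block), 3)
        assert out.values[0, 0] == 1

    def test_three_class_mode(self, grid_10m):
        block = np.array([[2, 2, 2], [2, 5, 5], [5, 9, 9]])
        out = resample_majority(grid_10m(block), 3)
        assert out.values[0, 0] == 2  # 4/3/2 counts -> the 4-count class

    def test_padding_with_nodata(self, grid_10m):
        g = grid_10m(np.full((4, 4), 7))
        out = resample_majority(g, 3)
        assert out.shape == (2, 2)
        assert out.values[0, 0] == 7
        assert out.values[1, 1] == 7  # nodata never outvotes real cells

    def test_uniform_idempotence(self, rng, grid_10m):
        vals = np.repeat(np.repeat(rng.integers(1, 5, (4, 4)), 3, 0), 3, 1)
        out = resample_majority(grid_10m(vals), 3)
        np.testing.assert_array_equal(out.values, vals[::3, ::3])

    def test_factor_below_two_rejected(self, grid_10m):
        with pytest.raises(ValueError):
            resample_majority(grid_10m(np.zeros((4, 4))), 1)


class TestRemoveSinglePixels:
    def test_isolated_pixel_cleared(self, grid_10m):
        g = grid_10m([[0, 0, 0], [0, 1, 0], [0, 0, 0]], nodata=255)
        assert remove_single_pixels(g).values.sum() == 0

    def test_pair_untouched(self, grid_10m):
        g = grid_10m([[1, 1, 0], [0, 0, 0]], nodata=255)
        np.testing.assert_array_equal(remove_single_pixels(g).values, g.values)

    def test_mixed_mask_matches_oracle(self, rng, grid_10m):
        vals = (rng.random((20, 20)) < 0.2).astype(int)
        g = grid_10m(vals, nodata=255)
        for conn in (4, 8):
            got = remove_single_pixels(g, connectivity=conn)
            expected = np.zeros_like(vals)
            for comp in oracles.components(vals == 1, conn):
                if len(comp) > 1:
                    for r, c in comp:
                        expected[r, c] = 1
            np.testing.assert_array_equal(got.values, expected)


class TestHexAggregate:
    def test_all_zero(self, grid_10m):
        recs = hex_aggregate(grid_10m(np.zeros((10, 10)), nodata=255))
        assert all(r["damaged_ha"] == 0 for r in recs)

    def test_partition_conservation(self, rng):
        vals = (rng.random((40, 40)) < 0.3).astype(int)
        g = Grid(vals, resolution_m=30.0, nodata=255)
        recs = hex_aggregate(g, hex_area_km2=0.05)
        total = sum(r["damaged_ha"] for r in recs)
        assert total == pytest.approx(vals.sum() * g.pixel_area_ha)

    def test_single_pixel_in_one_hex(self):
        vals = np.zeros((20, 20), dtype=int)
        vals[7, 11] = 1
        g = Grid(vals, resolution_m=30.0, nodata=255)
        recs = hex_aggregate(g, hex_area_km2=0.03)
        nonzero = [r for r in recs if r["damaged_ha"] > 0]
        assert len(nonzero) == 1
        assert nonzero[0]["damaged_ha"] == pytest.approx(g.pixel_area_ha)

    def test_invalid_area(self, grid_10m):
        with pytest.raises(ValueError):
            hex_aggregate(grid_10m(np.zeros((4, 4))), hex_area_km2=0)


class TestIO:
    def test_ascii_roundtrip(self, tmp_path, rng):
        g = Grid(
            rng.integers(0, 9, (7, 5)).astype(float),
            resolution_m=30.0,
            origin=(1000.0, 2000.0),
            nodata=-1,
        )
        path = tmp_path / "g.asc"
        write_ascii_grid(g, path)
        back = read_ascii_grid(path)
        np.testing.assert_array_equal(back.values, g.values)
        assert back.resolution_m == g.resolution_m
        assert back.origin == g.origin

    def test_geotiff_roundtrip(self, tmp_path, rng):
        g = Grid(
            rng.normal(size=(6, 8)).astype(np.float32),
            resolution_m=10.0,
            origin=(5.0, 15.0),
            nodata=-9999,
        )
        path = tmp_path / "g.tif"
        write_geotiff(g, path)
        back = read_geotiff(path)
        np.testing.assert_array_equal(back.values, g.values)
        assert back.resolution_m == g.resolution_m


@settings(max_examples=25, deadline=None)
@given(
    arrays(np.int8, (8, 8), elements=st.integers(0, 1)),
    st.sampled_from([4, 8]),
)
def test_patch_labeling_matches_flood_fill(values, connectivity):
    g = Grid(values.astype(int), resolution_m=10.0, nodata=-1)
    patches = label_patches(g, 1, connectivity=connectivity)
    comps = oracles.components(values == 1, connectivity)
    assert {frozenset(p.pixels) for p in patches} == {frozenset(c) for c in comps}
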