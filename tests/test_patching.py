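"""Sliding-window grids, the overlap formula, extraction and stitching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cestmix.patching import (
    EmptyRegionError,
    GeometryError,
    aggregate_patches,
    build_grid,
    extract_patches,
    overlap_fraction,
)


class TestOverlapFraction:
    @pytest.mark.parametrize(
        "size,stride,expected",
        [(48, 12, 75.0), (48, 6, 87.5), (48, 24, 50.0), (48, 36, 25.0), (48, 48, 0.0)],
    )
    def test_printed_values(self, size, stride, expected):
        assert overlap_fraction(size, stride) == pytest.approx(expected)

    def test_two_decimal_rounding_case(self):
        assert round(overlap_fraction(48, 4), 2) == 91.67

    @pytest.mark.parametrize("s", [4, 16, 48, 64, 96, 128, 192, 240])
    def test_full_stride_zero_and_quarter_stride_75(self, s):
        assert overlap_fraction(s, s) == 0.0
        if s % 4 == 0:
            assert overlap_fraction(s, s // 4) == 75.0

    def test_strictly_decreasing_in_stride(self):
        vals = [overlap_fraction(48, s) for s in range(1, 49)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("size,stride", [(48, 49), (0, 1), (48, 0), (48, -3)])
    def test_invalid_arguments(self, size, stride):
        with pytest.raises(ValueError):
            overlap_fraction(size, stride)


class TestBuildGrid:
    def test_96_box_gives_25_origins(self):
        grid = build_grid((0, 0, 95, 95), (240, 240), 48, 12)
        assert len(grid) == 25  # floor((96-48)/12)+1 = 5 per axis
        rows = sorted({r for r, _ in grid.origins})
        assert rows == [0, 12, 24, 36, 48]

    def test_exact_box_single_origin(self):
        grid = build_grid((10, 20, 57, 67), (240, 240), 48, 12)
        assert grid.origins == ((10, 20),)

    def test_clamped_final_origin(self):
        # rows span 50 pixels: origins 0 then clamped to 2 so the far edge
        # is covered; columns span exactly 48: single origin
        grid = build_grid((0, 0, 49, 47), (240, 240), 48, 12)
        assert grid.origins == ((0, 0), (2, 0))

    def test_small_region_inflated_to_one_patch(self):
        mask = np.zeros((64, 64), bool)
        mask[30:34, 40:44] = True
        grid = build_grid(mask, (64, 64), 48, 12)
        assert len(grid) == 1
        (r, c) = grid.origins[0]
        assert 0 <= r <= 16 and 0 <= c <= 16  # fits inside the image
        assert r <= 30 and r + 48 >= 34 and c <= 40 and c + 48 >= 44

    def test_every_region_pixel_covered(self, rng):
        for _ in range(10):
            mask = np.zeros((100, 100), bool)
            r0, c0 = rng.integers(0, 40, 2)
            h, w = rng.integers(5, 60, 2)
            mask[r0 : r0 + h, c0 : c0 + w] = True
            grid = build_grid(mask, (100, 100), 48, 12)
            covered = np.zeros((100, 100), bool)
            for r, c in grid.origins:
                covered[r : r + 48, c : c + 48] = True
            assert covered[mask].all()

    def test_empty_region_rejected(self):
        with pytest.raises(EmptyRegionError):
            build_grid(np.zeros((64, 64), bool), (64, 64), 48, 12)

    def test_oversized_patch_rejected(self):
        with pytest.raises(GeometryError):
            build_grid((0, 0, 10, 10), (32, 32), 48, 12)


class TestExtractPatches:
    def test_count_and_shape(self, rng):
        vol = rng.random((240, 240, 41))
        grid = build_grid((0, 0, 95, 95), (240, 240), 48, 12)
        ps = extract_patches(vol, grid)
        assert ps.patches.shape == (25, 48, 48, 41)

    def test_constant_volume_constant_patches(self):
        vol = np.full((64, 64, 3), 0.7)
        grid = build_grid((0, 0, 55, 55), (64, 64), 48, 8)
        ps = extract_patches(vol, grid)
        assert np.all(ps.patches == 0.7)

    def test_pure_cropping_round_trip(self, rng):
        vol = rng.random((80, 80, 2))
        grid = build_grid((0, 0, 70, 70), (80, 80), 48, 12)
        ps = extract_patches(vol, grid)
        # a pixel appearing in several patches carries identical values in all
        r, c = 50, 50
        vals = [
            p[r - orow, c - ocol]
            for p, (orow, ocol) in zip(ps.patches, ps.origins)
            if orow <= r < orow + 48 and ocol <= c < ocol + 48
        ]
        assert len(vals) > 1
        for v in vals:
            np.testing.assert_array_equal(v, vol[r, c])

    def test_label_patches_cut_identically(self, rng):
        vol = rng.random((64, 64, 2))
        labels = (rng.random((64, 64)) > 0.5).astype(int)
        grid = build_grid((0, 0, 63, 63), (64, 64), 48, 12)
        ps = extract_patches(vol, grid, label_image=labels)
        for patch, (r, c) in zip(ps.labels, ps.origins):
            np.testing.assert_array_equal(patch, labels[r : r + 48, c : c + 48])

    def test_shape_mismatch_rejected(self, rng):
        vol = rng.random((64, 64, 2))
        grid = build_grid((0, 0, 63, 63), (64, 64), 48, 12)
        with pytest.raises(ValueError, match="label"):
            extract_patches(vol, grid, label_image=np.zeros((32, 32)))


def _brute_force_aggregate(predictions, grid, crop):
    """Dense sum/count oracle replicating the border-retention rule."""
    H, W = grid.image_shape
    rmin, cmin, rmax, cmax = grid.bbox
    s = grid.size
    acc = np.zeros((H, W) + predictions.shape[3:])
    cnt = np.zeros((H, W))
    for pred, (r, c) in zip(predictions, grid.origins):
        for i in range(s):
            for j in range(s):
                keep_r = (crop <= i < s - crop) or (i < crop and (r <= rmin or r == 0)) \
                    or (i >= s - crop and (r + s >= rmax + 1 or r + s == H))
                keep_c = (crop <= j < s - crop) or (j < crop and (c <= cmin or c == 0)) \
                    or (j >= s - crop and (c + s >= cmax + 1 or c + s == W))
                if keep_r and keep_c:
                    acc[r + i, c + j] += pred[i, j]
                    cnt[r + i, c + j] += 1
    out = np.zeros_like(acc)
    nz = cnt > 0
    out[nz] = acc[nz] / cnt[nz][(...,) + (None,) * (acc.ndim - 2)]
    return out, nz


class TestAggregatePatches:
    def test_constant_predictions_give_constant_map(self, rng):
        grid = build_grid((0, 0, 70, 70), (100, 100), 48, 12)
        preds = np.full((len(grid), 48, 48), 0.3)
        out, valid = aggregate_patches(preds, grid, crop=12)
        assert np.allclose(out[valid], 0.3)
        covered = np.zeros((100, 100), bool)
        for r, c in grid.origins:
            covered[r : r + 48, c : c + 48] = True
        assert valid[covered].all()  # border retention leaves no hole

    def test_single_patch_crop_zero_identity(self, rng):
        grid = build_grid((5, 5, 52, 52), (64, 64), 48, 12)
        pred = rng.random((1, 48, 48, 2))
        out, valid = aggregate_patches(pred, grid, crop=0)
        np.testing.assert_array_equal(out[5:53, 5:53], pred[0])
        assert valid.sum() == 48 * 48

    def test_two_overlapping_patches_average(self):
        grid = build_grid((0, 0, 59, 47), (64, 64), 48, 12)
        assert grid.origins == ((0, 0), (12, 0))
        preds = np.stack([np.full((48, 48), 0.2), np.full((48, 48), 0.8)])
        out, valid = aggregate_patches(preds, grid, crop=0)
        # overlap zone rows 12..47 gets (a+b)/2
        assert np.allclose(out[12:48, :48], 0.5)
        assert np.allclose(out[:12, :48], 0.2)
        assert np.allclose(out[48:60, :48], 0.8)

    def test_matches_dense_oracle(self, rng):
        grid = build_grid((3, 7, 64, 66), (80, 80), 32, 8)
        preds = rng.random((len(grid), 32, 32, 2))
        out, valid = aggregate_patches(preds, grid, crop=8)
        exp, exp_valid = _brute_force_aggregate(preds, grid, 8)
        np.testing.assert_array_equal(valid, exp_valid)
        np.testing.assert_allclose(out, exp, atol=1e-12)

    @pytest.mark.parametrize("crop", [0, 6, 12])
    def test_identity_predictor_reconstructs_input(self, rng, crop):
        # extract -> aggregate with the patches themselves must reproduce the
        # region pixel-for-pixel for any crop <= stride
        vol = rng.random((80, 80, 3))
        grid = build_grid((2, 2, 77, 77), (80, 80), 48, 12)
        ps = extract_patches(vol, grid)
        out, valid = aggregate_patches(ps.patches, grid, crop=crop)
        np.testing.assert_allclose(out[valid], vol[valid], atol=1e-12)

    def test_simplex_preserved(self, rng):
        grid = build_grid((0, 0, 59, 59), (64, 64), 48, 12)
        raw = rng.random((len(grid), 48, 48, 2))
        probs = raw / raw.sum(axis=-1, keepdims=True)
        out, valid = aggregate_patches(probs, grid, crop=12)
        sums = out[valid].sum(axis=-1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        assert out.min() >= 0 and out.max() <= 1

    def test_excessive_crop_rejected(self, rng):
        grid = build_grid((0, 0, 47, 47), (64, 64), 48, 12)
        with pytest.raises(ValueError, match="crop"):
            aggregate_patches(np.zeros((1, 48, 48)), grid, crop=24)


@settings(max_examples=25, deadline=None)
@given(
    size=st.integers(8, 48),
    stride_frac=st.integers(1, 4),
    h=st.integers(50, 90),
)
def test_grid_covers_bbox_property(size, stride_frac, h):
    stride = max(1, size // stride_frac)
    mask = np.zeros((96, 96), bool)
    mask[10 : 10 + h // 2, 12 : 12 + h // 2] = True
    grid = build_grid(mask, (96, 96), size, stride)
    covered = np.zeros((96, 96), bool)
    for r, c in grid.origins:
        covered[r : r + size, c : c + size] = True
    rmin, cmin, rmax, cmax = grid.bbox
    assert covered[rmin : rmax + 1, cmin : cmax + 1].all()
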