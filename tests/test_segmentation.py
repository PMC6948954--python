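"""Dual-marker segmentation: preprocessing, thresholds, overlay, plexus split."""

import numpy as np
import pytest
from skimage import filters

from renolymph.config import SegmentationParams
from renolymph.core import BinaryMask, VoxelGrid
from renolymph.segmentation import (
    auto_threshold,
    colocalize,
    extract_plexus,
    preprocess_channel,
    segment_lymphatics,
)

SP = (1.0, 1.0, 1.0)


def grid(data, spacing=SP, bits=8):
    return VoxelGrid(np.asarray(data), spacing, dtype_bits=bits)


class TestPreprocess:
    def test_constant_image_zero_after_subtraction(self):
        g = grid(np.full((8, 64, 64), 120, dtype=np.uint8))
        out = preprocess_channel(g, SegmentationParams())
        assert out.data.max() == pytest.approx(0.0, abs=1e-5)

    def test_hot_voxel_removed(self):
        data = np.zeros((4, 32, 32), dtype=np.uint8)
        data[2, 16, 16] = 255
        out = preprocess_channel(
            grid(data), SegmentationParams(rolling_ball_radius=0.0)
        )
        assert out.data[2, 16, 16] == 0

    def test_input_untouched(self):
        data = np.random.default_rng(0).integers(0, 255, (4, 32, 32), dtype=np.uint8)
        g = grid(data)
        before = g.data.copy()
        preprocess_channel(g, SegmentationParams())
        np.testing.assert_array_equal(g.data, before)

    def test_background_ramp_improves_separation(self):
        """A tube on a linear ramp separates better after preprocessing:
        Otsu's normalized separability (between-class over total
        variance) increases once the ramp is subtracted."""
        z, y, x = np.mgrid[0:16, 0:96, 0:96]
        ramp = (x * 1.2).astype(np.float32)
        tube = ((y - 48) ** 2 + (z - 8) ** 2 <= 16).astype(np.float32) * 90
        raw = np.clip(ramp + tube, 0, 255).astype(np.uint8)
        g = grid(raw)
        params = SegmentationParams(despeckle_radius=0, rolling_ball_radius=20.0)
        out = preprocess_channel(g, params)

        def separability(d):
            d = d.astype(np.float64)
            t = filters.threshold_otsu(d)
            fg, bg = d[d >= t], d[d < t]
            if fg.size == 0 or bg.size == 0:
                return 0.0
            w = fg.size / d.size
            between = w * (1 - w) * (fg.mean() - bg.mean()) ** 2
            return between / d.var()

        assert separability(out.data) > separability(raw)


class TestAutoThreshold:
    def test_li_between_modes(self):
        rng = np.random.default_rng(0)
        data = np.concatenate(
            [np.full(4000, 10.0), np.full(4000, 200.0)]
        ) + rng.normal(0, 1, 8000)
        g = grid(np.clip(data, 0, 255).reshape(20, 20, 20))
        mask = auto_threshold(g, "li")
        assert 10 < mask.threshold < 200

    def test_manual_is_definition(self, rng):
        data = rng.integers(0, 255, (8, 16, 16), dtype=np.uint8)
        g = grid(data)
        mask = auto_threshold(g, "manual", manual_threshold=77)
        np.testing.assert_array_equal(mask.data, data >= 77)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            auto_threshold(grid(np.full((4, 4, 4), 9, dtype=np.uint8)), "li")

    def test_unknown_method(self, rng):
        g = grid(rng.integers(0, 9, (4, 4, 4), dtype=np.uint8))
        with pytest.raises(ValueError):
            auto_threshold(g, "magic")


class TestColocalize:
    def _two_blob_setup(self):
        cellular = np.zeros((10, 20, 20), dtype=bool)
        cellular[2:5, 2:6, 2:6] = True  # blob A
        cellular[6:9, 12:16, 12:16] = True  # blob B
        nuclear = np.zeros_like(cellular)
        nuclear[3, 4, 4] = True  # inside blob A only
        return BinaryMask(nuclear, SP), BinaryMask(cellular, SP)

    def test_empty_nuclear_empty_output(self):
        nuc, cell = self._two_blob_setup()
        empty = BinaryMask(np.zeros_like(nuc.data), SP)
        out = colocalize(empty, cell)
        assert out.voxel_count == 0

    def test_keeps_exactly_nucleated_blob(self):
        nuc, cell = self._two_blob_setup()
        out = colocalize(nuc, cell)
        expected = np.zeros_like(cell.data)
        expected[2:5, 2:6, 2:6] = True
        np.testing.assert_array_equal(out.data, expected)

    def test_output_subset_of_cellular(self, small_phantom, analysis_config):
        stack, gt = small_phantom
        p = analysis_config.segmentation
        nuc = auto_threshold(preprocess_channel(stack["PROX1"], p), p.threshold_method)
        cell = auto_threshold(preprocess_channel(stack["LYVE1"], p), p.threshold_method)
        out = colocalize(nuc, cell, p.connectivity, p.min_component_voxels)
        assert not (out.data & ~cell.data).any()

    def test_confounders_removed(self, small_phantom, analysis_config):
        """LYVE-1-only macrophage blobs never survive the overlay."""
        stack, gt = small_phantom
        _, plexus, residual, _ = segment_lymphatics(
            stack["PROX1"], stack["LYVE1"], analysis_config.segmentation
        )
        kept = plexus.data | (residual.labels > 0)
        spacing = np.asarray(stack.spacing)
        for c in gt.confounders:
            if c.kind != "macrophage":
                continue
            idx = tuple(np.round(c.center / spacing).astype(int))
            assert not kept[idx]

    def test_shape_mismatch(self):
        a = BinaryMask(np.zeros((2, 2, 2), dtype=bool), SP)
        b = BinaryMask(np.zeros((2, 2, 3), dtype=bool), SP)
        with pytest.raises(ValueError):
            colocalize(a, b)


class TestExtractPlexus:
    def test_single_component_identity(self):
        data = np.zeros((6, 6, 6), dtype=bool)
        data[2:4, 2:4, 2:4] = True
        plexus, residual = extract_plexus(BinaryMask(data, SP))
        np.testing.assert_array_equal(plexus.data, data)
        assert residual.n_components == 0

    def test_largest_wins(self):
        data = np.zeros((10, 20, 20), dtype=bool)
        data[1:3, 1:6, 1:11] = True  # 100 voxels
        data[7:9, 15:20, 15:20] = False
        data[7, 15:20, 15:17] = True  # 10 voxels
        plexus, residual = extract_plexus(BinaryMask(data, SP))
        assert plexus.voxel_count == 100
        assert residual.n_components == 1
        assert residual.table["voxel_count"].iloc[0] == 10

    def test_partition_invariant(self, small_phantom, analysis_config):
        stack, _ = small_phantom
        coloc, plexus, residual, _ = segment_lymphatics(
            stack["PROX1"], stack["LYVE1"], analysis_config.segmentation
        )
        union = plexus.data | (residual.labels > 0)
        np.testing.assert_array_equal(union, coloc.data)
        assert not (plexus.data & (residual.labels > 0)).any()

    def test_tie_break_warns_and_picks_first(self, caplog):
        data = np.zeros((4, 4, 10), dtype=bool)
        data[1, 1, 0:2] = True
        data[2, 2, 6:8] = True
        import logging

        with caplog.at_level(logging.WARNING, logger="renolymph.segmentation"):
            plexus, _ = extract_plexus(BinaryMask(data, SP))
        assert "tie" in caplog.text
        assert plexus.data[1, 1, 0]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_plexus(BinaryMask(np.zeros((3, 3, 3), dtype=bool), SP))


class TestOracleEquivalence:
    def test_noiseless_segmentation_matches_membership(self, clean_phantom, analysis_config):
        """Zero-noise phantom: threshold + overlay + largest component
        reproduce the generator's own vessel membership exactly."""
        stack, gt = clean_phantom
        p = analysis_config.segmentation
        nuc = auto_threshold(stack["PROX1"], p.threshold_method)
        cell = auto_threshold(stack["LYVE1"], p.threshold_method)
        coloc = colocalize(nuc, cell, p.connectivity, p.min_component_voxels)
        plexus, residual = extract_plexus(coloc, p.connectivity)
        np.testing.assert_array_equal(plexus.data, gt.membership.labels > 0)

    def test_noisy_dice(self, small_phantom, analysis_config):
        """At 10%-of-foreground noise, Dice against ground truth ≥ 0.95."""
        stack, gt = small_phantom
        _, plexus, _, _ = segment_lymphatics(
            stack["PROX1"], stack["LYVE1"], analysis_config.segmentation
        )
        gt_mask = gt.membership.labels > 0
        inter = (plexus.data & gt_mask).sum()
        dice = 2 * inter / (plexus.data.sum() + gt_mask.sum())
        assert dice >= 0.95
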