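"""Puncta colocalization, coverage, ramification, 3D counts, uptake."""

import numpy as np
import pytest
from skimage import draw

from slicephys import synthgen as sg
from slicephys.core import ImageStack, ParameterError
from slicephys.imaging import (astro_uptake, count_cells_3d,
                               count_colocalized_synapses, coverage_intensity,
                               normalize_to_control, preprocess_channel,
                               ramification_index)


def _stack(arr, pixel=0.1):
    return ImageStack({"c": arr[None, :, :].repeat(3, axis=0)}, pixel_size_xy=pixel)


class TestPreprocessing:
    def test_constant_image_zeroed(self):
        out = preprocess_channel(_stack(np.full((64, 64), 37.0)), "c")
        assert np.allclose(out, 0.0, atol=1e-6)

    def test_speckle_removed_by_median(self):
        img = np.zeros((64, 64))
        img[30, 30] = 1000.0  # single-pixel speckle
        out = preprocess_channel(_stack(img), "c")
        assert out[30, 30] < 1.0

    def test_punctum_survives_gradient_subtraction(self):
        yy, xx = np.mgrid[0:96, 0:96]
        img = 50.0 * xx / 96.0  # smooth linear background
        rr, cc = draw.disk((48, 48), 4)
        img[rr, cc] += 500.0
        out = preprocess_channel(_stack(img), "c")
        assert out[48, 48] == pytest.approx(500.0, rel=0.10)

    def test_unknown_channel_rejected(self):
        with pytest.raises(KeyError):
            preprocess_channel(_stack(np.zeros((8, 8))), "nope")


class TestColocalization:
    def test_planted_pairs_recovered_exactly(self):
        stack, gt = sg.simulate_puncta_stack(
            sg.SimConfig(seed=50), sg.StackConfig(n_pairs=20, overlap_fraction=1.0))
        res = count_colocalized_synapses(preprocess_channel(stack, "pre"),
                                         preprocess_channel(stack, "post"),
                                         stack.pixel_size_xy)
        assert res.n_colocalized == gt.params["n_colocalized_in_range"] == 20

    def test_zero_overlap_zero_count(self):
        stack, _ = sg.simulate_puncta_stack(
            sg.SimConfig(seed=51), sg.StackConfig(n_pairs=12, overlap_fraction=0.0))
        res = count_colocalized_synapses(preprocess_channel(stack, "pre"),
                                         preprocess_channel(stack, "post"),
                                         stack.pixel_size_xy)
        assert res.n_colocalized == 0

    def test_oversize_objects_excluded(self):
        stack, gt = sg.simulate_puncta_stack(
            sg.SimConfig(seed=52), sg.StackConfig(n_pairs=10, overlap_fraction=1.0,
                                                  n_oversize=2))
        res = count_colocalized_synapses(preprocess_channel(stack, "pre"),
                                         preprocess_channel(stack, "post"),
                                         stack.pixel_size_xy)
        assert res.n_colocalized == 10
        for o in res.objects:
            assert 0.1 <= o["area_um2"] <= 1.2

    def test_self_pair_equals_size_filtered_count(self):
        stack, _ = sg.simulate_puncta_stack(
            sg.SimConfig(seed=53), sg.StackConfig(n_pairs=8, overlap_fraction=1.0))
        img = preprocess_channel(stack, "pre")
        res = count_colocalized_synapses(img, img, stack.pixel_size_xy)
        assert res.n_colocalized == 8  # AND idempotence

    def test_area_scales_with_pixel_size(self):
        img = np.zeros((64, 64))
        rr, cc = draw.disk((32, 32), 5)
        img[rr, cc] = 100.0
        r1 = count_colocalized_synapses(img, img, pixel_size=0.05,
                                        min_area_um2=0.0, max_area_um2=np.inf)
        r2 = count_colocalized_synapses(img, img, pixel_size=0.10,
                                        min_area_um2=0.0, max_area_um2=np.inf)
        assert r2.area_covered == pytest.approx(4 * r1.area_covered)

    def test_empty_mask_valid_zero(self):
        z = np.zeros((32, 32))
        res = count_colocalized_synapses(z, z, 0.1)
        assert res.n_colocalized == 0 and res.area_covered == 0.0


class TestCoverage:
    def test_half_bright_is_fifty_percent(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 100.0
        res = coverage_intensity(img, 0.1)
        assert res.percent_area == pytest.approx(50.0)
        assert res.mean_intensity_in_mask == pytest.approx(100.0)

    def test_planted_fraction_recovered(self):
        img = np.zeros((64, 64))
        img[:16, :32] = 200.0  # exactly 12.5 % of the field
        res = coverage_intensity(img, 0.1)
        assert res.percent_area == pytest.approx(12.5, abs=0.2)


class TestRamificationIndex:
    def test_disk_close_to_unity(self):
        mask = np.zeros((201, 201), bool)
        rr, cc = draw.disk((100, 100), 50.5)
        mask[rr, cc] = True
        assert ramification_index(mask) == pytest.approx(1.0, abs=0.03)

    def test_square_analytic_value(self):
        mask = np.zeros((201, 201), bool)
        mask[50:150, 50:150] = True
        assert ramification_index(mask) == pytest.approx(2 / np.sqrt(np.pi), abs=0.03)

    def test_star_more_ramified_than_hull(self):
        from skimage.morphology import convex_hull_image
        yy, xx = np.mgrid[0:201, 0:201]
        ang = np.arctan2(yy - 100, xx - 100)
        r = np.hypot(yy - 100, xx - 100)
        star = r < 40 + 25 * np.cos(6 * ang)
        hull = convex_hull_image(star)
        assert ramification_index(star) > ramification_index(hull)

    def test_empty_mask_rejected(self):
        with pytest.raises(ParameterError):
            ramification_index(np.zeros((10, 10), bool))


class TestCells3D:
    def test_planted_blobs_counted(self):
        stack, gt = sg.simulate_cell_stack(sg.SimConfig(seed=54))
        n, per_mm3 = count_cells_3d(stack, "cells")
        assert n == gt.params["n_blobs"]
        assert per_mm3 > 0

    def test_empty_stack_zero(self):
        stack = ImageStack({"cells": np.zeros((8, 32, 32))},
                           pixel_size_xy=0.5, z_step=1.0)
        n, _ = count_cells_3d(stack, "cells")
        assert n == 0

    def test_bridged_blobs_merge(self):
        vol = np.zeros((9, 64, 64))
        zz, yy, xx = np.mgrid[0:9, 0:64, 0:64]
        for cx in (20, 44):
            vol[((zz - 4) ** 2 / 4 + (yy - 32) ** 2 / 36 + (xx - cx) ** 2 / 36) <= 1] = 1000.0
        vol[4, 32, 20:45] = 1000.0  # 1-voxel bridge
        stack = ImageStack({"cells": vol}, pixel_size_xy=1.0, z_step=1.0)
        n, _ = count_cells_3d(stack, "cells", min_volume_um3=10.0)
        assert n == 1  # connectivity definition, no watershed


class TestAstroUptake:
    def test_planted_volume_fraction_recovered(self):
        stack, gt = sg.simulate_uptake_stack(sg.SimConfig(seed=55))
        vf = astro_uptake(stack, "glia", "puncta", glia_threshold=1000.0)
        assert vf == pytest.approx(gt.params["volume_fraction_pct"], rel=0.10)

    def test_all_puncta_outside_gives_zero(self):
        stack, _ = sg.simulate_uptake_stack(sg.SimConfig(seed=56), n_inside=0,
                                            n_outside=10)
        vf = astro_uptake(stack, "glia", "puncta", glia_threshold=1000.0)
        assert vf == pytest.approx(0.0, abs=0.01)

    def test_empty_glia_mask_rejected(self):
        stack, _ = sg.simulate_uptake_stack(sg.SimConfig(seed=57))
        with pytest.raises(ParameterError):
            astro_uptake(stack, "glia", "puncta", glia_threshold=1e9)

    def test_control_normalization(self):
        rel = normalize_to_control({"wt": 2.0, "ko": 3.0}, control="wt")
        assert rel == {"wt": 1.0, "ko": 1.5}
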