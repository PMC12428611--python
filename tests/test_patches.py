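"""Patch sampling, mask-derived labels, and the patch-restricted loss."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import capclean as cc
from capclean.patches import PROB_EPS


def bce_oracle(prob_patch, y):
    """Independent reference: elementwise binary cross-entropy with the
    label broadcast to every pixel, summed."""
    p = np.clip(np.asarray(prob_patch, float).ravel(), PROB_EPS, 1 - PROB_EPS)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).sum())


def single_batch(prob, x0, y0, h, w, y):
    lp = cc.LabeledPatch(cc.PatchRef("f", x0, y0, h, w), y)
    return [prob], cc.PatchBatch([(None, lp)])


class TestSamplePatches:
    def test_positions_respect_fit_constraint(self):
        refs = cc.sample_patches((256, 256), (64, 64), 10, seed=1)
        assert len(refs) == 10
        assert all(0 <= r.x0 <= 192 and 0 <= r.y0 <= 192 for r in refs)

    def test_unique_position_when_patch_fills_frame(self):
        refs = cc.sample_patches((64, 64), (64, 64), 3, seed=0)
        assert [(r.x0, r.y0) for r in refs] == [(0, 0)] * 3

    def test_uniformity_of_top_left_coordinates(self):
        refs = cc.sample_patches((256, 256), (64, 64), 5000, seed=2)
        assert abs(np.mean([r.x0 for r in refs]) - 96) <= 5
        assert abs(np.mean([r.y0 for r in refs]) - 96) <= 5

    def test_determinism_and_errors(self):
        a = cc.sample_patches((128, 128), (64, 64), 20, seed=9)
        b = cc.sample_patches((128, 128), (64, 64), 20, seed=9)
        assert a == b
        with pytest.raises(ValueError):
            cc.sample_patches((32, 32), (64, 64), 1)


class TestPatchLabelFromMask:
    def test_half_coverage_is_dirty_inclusive(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask.ravel()[:2048] = True  # exactly 50%
        ref = cc.PatchRef("f", 0, 0, 64, 64)
        assert cc.patch_label_from_mask(mask, ref) == 1

    def test_just_below_half_is_clean(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask.ravel()[:2047] = True
        assert cc.patch_label_from_mask(mask, cc.PatchRef("f", 0, 0, 64, 64)) == 0

    def test_empty_mask_is_clean(self):
        mask = np.zeros((128, 128), dtype=bool)
        assert cc.patch_label_from_mask(mask, cc.PatchRef("f", 10, 20, 64, 64)) == 0

    def test_patch_outside_mask_rejected(self):
        with pytest.raises(ValueError):
            cc.patch_label_from_mask(np.zeros((64, 64)), cc.PatchRef("f", 32, 0, 64, 64))


class TestPatchLoss:
    def test_uniform_half_probability_analytic_value(self):
        prob = np.full((128, 128), 0.5)
        for y in (0, 1):
            maps, batch = single_batch(prob, 0, 0, 64, 64, y)
            assert cc.patch_loss(maps, batch) == pytest.approx(4096 * np.log(2), rel=1e-12)

    def test_small_patch_hand_computed(self):
        prob = np.zeros((4, 4))
        prob[1:3, 1:3] = [[0.9, 0.8], [0.7, 0.6]]
        maps, batch = single_batch(prob, 1, 1, 2, 2, 1)
        expected = -(np.log(0.9) + np.log(0.8) + np.log(0.7) + np.log(0.6))
        assert cc.patch_loss(maps, batch) == pytest.approx(expected, rel=1e-12)
        assert cc.patch_loss(maps, batch) == pytest.approx(1.1960, abs=5e-5)

    def test_perfect_prediction_is_nearly_zero(self):
        prob = np.ones((64, 64))
        maps, batch = single_batch(prob, 0, 0, 64, 64, 1)
        loss = cc.patch_loss(maps, batch)
        assert 0 <= loss <= 4096 * -np.log1p(-PROB_EPS) + 1e-12

    def test_equivalence_with_broadcast_bce_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            H = int(rng.integers(16, 64))
            prob = rng.random((H, H))
            h = int(rng.integers(2, H + 1))
            x0 = int(rng.integers(0, H - h + 1))
            y0 = int(rng.integers(0, H - h + 1))
            y = int(rng.integers(2))
            maps, batch = single_batch(prob, x0, y0, h, h, y)
            expected = bce_oracle(prob[y0:y0 + h, x0:x0 + h], y)
            got = cc.patch_loss(maps, batch)
            assert got == pytest.approx(expected, rel=1e-9)

    def test_mean_reduction_divides_by_pixel_count(self):
        prob = np.full((64, 64), 0.3)
        maps, batch = single_batch(prob, 0, 0, 32, 32, 1)
        s = cc.patch_loss(maps, batch, reduce_pixels="sum")
        m = cc.patch_loss(maps, batch, reduce_pixels="mean")
        assert m == pytest.approx(s / (32 * 32), rel=1e-12)

    def test_batch_linearity(self):
        rng = np.random.default_rng(3)
        probs = [rng.random((32, 32)) for _ in range(4)]
        lps = [
            cc.LabeledPatch(cc.PatchRef("f", int(rng.integers(0, 17)),
                                        int(rng.integers(0, 17)), 16, 16),
                            int(rng.integers(2)))
            for _ in range(4)
        ]
        per_item = [
            cc.patch_loss([p], cc.PatchBatch([(None, lp)]))
            for p, lp in zip(probs, lps)
        ]
        combined = cc.patch_loss(probs, cc.PatchBatch([(None, lp) for lp in lps]))
        assert combined == pytest.approx(np.mean(per_item), rel=1e-12)

    def test_locality_pixels_outside_patches_do_not_matter(self):
        rng = np.random.default_rng(5)
        prob = rng.random((64, 64))
        maps, batch = single_batch(prob, 8, 8, 16, 16, 1)
        base = cc.patch_loss(maps, batch)
        prob2 = prob.copy()
        prob2[0, 0] = 0.999  # outside the patch
        prob2[40:, 40:] = 0.001
        assert cc.patch_loss([prob2], batch) == base

    def test_monotone_in_probability_for_dirty_patch(self):
        prob = np.full((32, 32), 0.4)
        maps, batch = single_batch(prob, 0, 0, 16, 16, 1)
        lo = cc.patch_loss(maps, batch)
        prob_hi = prob.copy()
        prob_hi[3, 3] = 0.6
        assert cc.patch_loss([prob_hi], batch) < lo

    def test_out_of_range_probability_rejected(self):
        prob = np.full((32, 32), 1.5)
        maps, batch = single_batch(prob, 0, 0, 16, 16, 1)
        with pytest.raises(ValueError):
            cc.patch_loss(maps, batch)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**32 - 1), st.integers(0, 1))
    def test_nonnegativity_property(self, seed, y):
        rng = np.random.default_rng(seed)
        prob = rng.random((16, 16))
        maps, batch = single_batch(prob, 0, 0, 8, 8, y)
        assert cc.patch_loss(maps, batch) >= 0


class TestPatchLossGrad:
    def test_zero_gradient_outside_patches(self):
        rng = np.random.default_rng(1)
        prob = rng.random((32, 32))
        maps, batch = single_batch(prob, 4, 4, 8, 8, 1)
        (g,) = cc.patch_loss_grad(maps, batch)
        inside = np.zeros((32, 32), dtype=bool)
        inside[4:12, 4:12] = True
        assert np.all(g[~inside] == 0)
        assert np.all(g[inside] != 0)

    def test_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        prob = np.clip(rng.random((16, 16)), 0.05, 0.95)
        maps, batch = single_batch(prob, 2, 2, 8, 8, 0)
        (g,) = cc.patch_loss_grad(maps, batch)
        eps = 1e-6
        for (i, j) in [(2, 2), (5, 7), (9, 9)]:
            up = prob.copy()
            up[i, j] += eps
            dn = prob.copy()
            dn[i, j] -= eps
            fd = (cc.patch_loss([up], batch) - cc.patch_loss([dn], batch)) / (2 * eps)
            assert g[i, j] == pytest.approx(fd, rel=1e-4)


def test_patch_label_csv_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    labeled = [
        (cc.PatchRef(f"frame{i}", int(rng.integers(0, 65)), int(rng.integers(0, 65)), 64, 64),
         int(rng.integers(2)))
        for i in range(10)
    ]
    path = str(tmp_path / "labels.csv")
    cc.write_patch_labels(path, labeled)
    back = cc.read_patch_labels(path)
    assert [(lp.patch, lp.y) for lp in back] == labeled
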