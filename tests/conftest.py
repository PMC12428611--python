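import numpy as np
import pytest

import capclean as cc
from capclean.synthetic import TRAIN_COVERAGE_RANGE


def make_labeled_frames(n, seed, size=128, patches_per_frame=8, patch=64):
    """Frames + sampled patch labels + truth masks, with content coverage
    spread uniformly from light to heavy occlusion (the distribution a
    patch-labeling campaign draws from)."""
    frames, groups, truths = [], [], []
    rng = np.random.default_rng(seed)
    targets = rng.uniform(*TRAIN_COVERAGE_RANGE, size=n)
    for i in range(n):
        f = cc.generate_frame(size, float(targets[i]), seed=int(rng.integers(2**31 - 1)))
        refs = cc.sample_patches(
            (size, size), (patch, patch), patches_per_frame,
            seed=int(rng.integers(2**31 - 1)), frame_id=f"f{i}",
        )
        lps = [cc.LabeledPatch(r, cc.patch_label_from_mask(f.truth_mask, r)) for r in refs]
        frames.append(f.image)
        groups.append(lps)
        truths.append(f.truth_mask)
    return frames, groups, truths


def make_eval_frames(n, seed, size=128, patches_per_frame=8, patch=64,
                     cov_range=(0.05, 0.75)):
    """Held-out frames for mask evaluation: every frame carries annotatable
    content, with coverage spread uniformly over ``cov_range``."""
    frames, groups, truths = [], [], []
    rng = np.random.default_rng(seed)
    targets = rng.uniform(*cov_range, size=n)
    for i in range(n):
        f = cc.generate_frame(size, float(targets[i]), seed=int(rng.integers(2**31 - 1)))
        refs = cc.sample_patches(
            (size, size), (patch, patch), patches_per_frame,
            seed=int(rng.integers(2**31 - 1)), frame_id=f"e{i}",
        )
        lps = [cc.LabeledPatch(r, cc.patch_label_from_mask(f.truth_mask, r)) for r in refs]
        frames.append(f.image)
        groups.append(lps)
        truths.append(f.truth_mask)
    return frames, groups, truths


@pytest.fixture(scope="session")
def tiny_trained_model():
    """A quickly trained segmenter on a small set, shared across tests that
    only need a plausibly trained model (not a high-quality one)."""
    frames, groups, _ = make_labeled_frames(10, seed=5, size=64, patches_per_frame=6, patch=32)
    cfg = cc.SegmenterConfig(input_size=(64, 64), epochs=5, seed=5)
    return cc.train_segmenter(frames, groups, cfg)
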