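"""Synthetic capsule-endoscopy phantoms with known ground truth.

Real colon-capsule footage cannot be redistributed, so every downstream
stage (patch supervision, segmentation, visibility, scoring) is exercised
on generated phantoms instead: frames with a bright circular field of view
(FOV) over near-black corners, a pink mucosa-like background, and irregular
yellow-brown "intraluminal content" blobs whose exact binary mask is known.
Clips are bounded random walks of per-frame visibility concentrated inside
one of the four CC-Clear bands, and raters are simulated by a row-stochastic
confusion kernel over the 0-3 score scale.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

# CC-Clear visibility bands: class c covers [BAND_EDGES[c], BAND_EDGES[c+1]),
# the last band closed at 1.0.
BAND_EDGES = (0.0, 0.50, 0.75, 0.90, 1.0)

# Mean-reverting walk parameters per class: (anchor, innovation sd).
# Anchors sit mid-band; innovations are small enough that the stationary
# spread stays well inside the band (AR(1) with phi = 0.9).
_WALK_PARAMS = {
    0: (0.30, 0.035),
    1: (0.625, 0.020),
    2: (0.825, 0.012),
    3: (0.955, 0.008),
}
_WALK_PHI = 0.9

# Appearance constants (RGB, 0-255): pink mucosa, yellow-brown content.
_MUCOSA_RGB = (190.0, 110.0, 110.0)
_CONTENT_RGB = (180.0, 140.0, 60.0)
_FOV_RADIUS_FRACTION = 0.48


@dataclass
class FramePhantom:
    """One synthetic frame with its ground-truth content and FOV masks."""

    image: np.ndarray  # H x W x 3 uint8
    truth_mask: np.ndarray  # H x W bool, True = intraluminal content
    fov_mask: np.ndarray  # H x W bool, True = inside field of view
    dirty_fraction: float  # content area / FOV area

    @property
    def visibility(self) -> float:
        return 1.0 - self.dirty_fraction


@dataclass
class ClipPhantom:
    """A simulated 10-minute clip: visibility trajectory plus optional frames."""

    clip_id: str
    truth_visibility: np.ndarray  # per-frame clean-mucosa fraction in [0, 1]
    true_class: int  # CC-Clear class 0-3
    frames: Optional[list[FramePhantom]] = None


@dataclass
class RaterModel:
    """Simulated panel of raters sharing one 4x4 confusion kernel.

    ``confusion_kernel[i, j]`` is the probability that a rater reports score
    ``j`` for a clip whose true class is ``i``.  The identity kernel
    reproduces the truth exactly.
    """

    n_raters: int = 3
    confusion_kernel: np.ndarray = field(default_factory=lambda: np.eye(4))
    seed: int = 0

    def __post_init__(self) -> None:
        self.confusion_kernel = np.asarray(self.confusion_kernel, dtype=float)
        if self.n_raters < 1:
            raise ValueError("n_raters must be >= 1")
        if self.confusion_kernel.shape != (4, 4):
            raise ValueError("confusion_kernel must be 4x4")
        if np.any(self.confusion_kernel < 0):
            raise ValueError("confusion_kernel entries must be nonnegative")
        rowsums = self.confusion_kernel.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-12):
            raise ValueError("confusion_kernel rows must each sum to 1")


def neighbor_kernel(diagonal: float = 0.7, spread: float = 0.15) -> np.ndarray:
    """Row-stochastic 4x4 kernel with ``spread`` mass on each existing
    neighbor score; at the scale ends the missing neighbor's mass stays on
    the diagonal."""
    k = np.zeros((4, 4))
    for i in range(4):
        k[i, i] = diagonal
        for j in (i - 1, i + 1):
            if 0 <= j <= 3:
                k[i, j] = spread
            else:
                k[i, i] += spread
    return k


def _fov_circle(size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    r = _FOV_RADIUS_FRACTION * size
    return (yy - c) ** 2 + (xx - c) ** 2 <= r * r


def generate_frame(
    size: int,
    target_dirty_fraction: float,
    blob_scale: float = 8.0,
    seed: int = 0,
) -> FramePhantom:
    """Render one phantom frame with ~``target_dirty_fraction`` of the FOV
    covered by content.

    The content region is built by thresholding Gaussian-smoothed white
    noise (correlation length ``blob_scale`` px) at the in-FOV quantile that
    achieves the requested coverage, which yields irregular blobs with the
    ill-defined borders typical of intraluminal debris.  Deterministic for a
    fixed seed.
    """
    if size < 32:
        raise ValueError("size must be >= 32")
    if not 0.0 <= target_dirty_fraction <= 0.95:
        raise ValueError("target_dirty_fraction must be in [0, 0.95]")

    rng = np.random.default_rng(seed)
    fov = _fov_circle(size)
    n_fov = int(fov.sum())

    if target_dirty_fraction > 0.0:
        # two spatial scales: fine structure gives irregular blob borders,
        # the coarse component pools content into localized regions (debris
        # collects in parts of the lumen; other areas stay clean)
        fine = ndimage.gaussian_filter(rng.standard_normal((size, size)), blob_scale)
        coarse = ndimage.gaussian_filter(rng.standard_normal((size, size)), 3.0 * blob_scale)
        blob_field = fine / max(fine.std(), 1e-12) + 1.5 * coarse / max(coarse.std(), 1e-12)
        thresh = np.quantile(blob_field[fov], 1.0 - target_dirty_fraction)
        truth = (blob_field > thresh) & fov
    else:
        truth = np.zeros((size, size), dtype=bool)

    img = np.empty((size, size, 3), dtype=float)
    texture = ndimage.gaussian_filter(rng.standard_normal((size, size)), 2.0)
    texture = 18.0 * texture / max(texture.std(), 1e-9)
    for c, base in enumerate(_MUCOSA_RGB):
        img[:, :, c] = base + texture + rng.normal(0.0, 4.0, (size, size))
    content_noise = rng.normal(0.0, 8.0, (size, size, 3))
    for c, base in enumerate(_CONTENT_RGB):
        img[:, :, c][truth] = base + content_noise[:, :, c][truth]
    # corners outside the FOV are near-black with tiny sensor noise
    dark = rng.uniform(0.0, 5.0, (size, size, 3))
    img[~fov] = dark[~fov]
    img = np.clip(img, 0, 255).astype(np.uint8)

    dirty = float(truth.sum()) / n_fov
    return FramePhantom(image=img, truth_mask=truth, fov_mask=fov, dirty_fraction=dirty)


def _visibility_walk(n_frames: int, true_class: int, rng: np.random.Generator) -> np.ndarray:
    anchor, sd = _WALK_PARAMS[true_class]
    v = np.empty(n_frames)
    # start at the stationary distribution of the AR(1) process
    stat_sd = sd / np.sqrt(1.0 - _WALK_PHI**2)
    v[0] = anchor + stat_sd * rng.standard_normal()
    for t in range(1, n_frames):
        v[t] = anchor + _WALK_PHI * (v[t - 1] - anchor) + sd * rng.standard_normal()
    # keep renderable: generate_frame caps dirty fraction at 0.95
    return np.clip(v, 0.06, 1.0)


# Content-coverage range for standalone segmenter-training frames: a patch
# labeling campaign draws frames spanning light to heavy occlusion.
TRAIN_COVERAGE_RANGE = (0.05, 0.75)


def generate_clip(
    n_frames: int,
    true_class: int,
    render: bool = False,
    seed: int = 0,
    frame_size: int = 128,
    clip_id: Optional[str] = None,
) -> ClipPhantom:
    """Simulate one clip of ``n_frames`` whose visibility stays (mostly)
    inside the CC-Clear band of ``true_class``; optionally render each frame
    with matching content coverage."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if true_class not in (0, 1, 2, 3):
        raise ValueError("true_class must be in {0, 1, 2, 3}")

    rng = np.random.default_rng(seed)
    vis = _visibility_walk(n_frames, true_class, rng)
    cid = clip_id if clip_id is not None else f"clip_c{true_class}_s{seed}"

    frames = None
    if render:
        frame_seeds = rng.integers(0, 2**31 - 1, size=n_frames)
        frames = [
            generate_frame(frame_size, 1.0 - vis[t], seed=int(frame_seeds[t]))
            for t in range(n_frames)
        ]
    return ClipPhantom(clip_id=cid, truth_visibility=vis, true_class=true_class, frames=frames)


def simulate_raters(
    true_classes: Sequence[int],
    model: RaterModel,
    clip_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Draw one score per (clip, rater) from the confusion kernel.

    Returns a long table with columns ``clip_id``, ``rater_id``, ``score``,
    deterministic for a fixed ``model.seed``.
    """
    true_classes = list(true_classes)
    if any(c not in (0, 1, 2, 3) for c in true_classes):
        raise ValueError("all true classes must be in {0, 1, 2, 3}")
    if clip_ids is None:
        clip_ids = [f"clip{i:03d}" for i in range(len(true_classes))]
    if len(clip_ids) != len(true_classes):
        raise ValueError("clip_ids and true_classes must have equal length")

    rng = np.random.default_rng(model.seed)
    rows = []
    for r in range(1, model.n_raters + 1):
        for cid, c in zip(clip_ids, true_classes):
            score = int(rng.choice(4, p=model.confusion_kernel[c]))
            rows.append((cid, r, score))
    return pd.DataFrame(rows, columns=["clip_id", "rater_id", "score"])


# ---------------------------------------------------------------------------
# Ready-made study designs shared by tests, scripts and examples.

def build_segmentation_study(
    n_train: int = 60,
    n_eval: int = 20,
    frame_size: int = 128,
    patches_per_frame: int = 8,
    patch_size: int = 64,
    seed: int = 0,
) -> dict:
    """A complete weak-supervision segmentation study: training frames with
    sampled patch labels, and held-out frames with truth masks for mask
    evaluation.  Content coverage is uniform over ``TRAIN_COVERAGE_RANGE``
    (light to heavy occlusion) in both splits."""
    from .patches import sample_patches, patch_label_from_mask

    rng = np.random.default_rng(seed)

    def draw(n, tag):
        frames, labels, truths = [], [], []
        targets = rng.uniform(*TRAIN_COVERAGE_RANGE, size=n)
        for i in range(n):
            fr = generate_frame(frame_size, float(targets[i]),
                                seed=int(rng.integers(2**31 - 1)))
            refs = sample_patches(
                (frame_size, frame_size), (patch_size, patch_size),
                patches_per_frame, seed=int(rng.integers(2**31 - 1)),
                frame_id=f"{tag}{i:03d}",
            )
            from .patches import LabeledPatch

            labels.append([LabeledPatch(r, patch_label_from_mask(fr.truth_mask, r))
                           for r in refs])
            frames.append(fr.image)
            truths.append(fr.truth_mask)
        return frames, labels, truths

    tr_frames, tr_labels, tr_truths = draw(n_train, "train")
    ev_frames, ev_labels, ev_truths = draw(n_eval, "eval")
    return {
        "train_frames": tr_frames,
        "train_labels": tr_labels,
        "train_truths": tr_truths,
        "eval_frames": ev_frames,
        "eval_labels": ev_labels,
        "eval_truths": ev_truths,
    }


def build_scoring_study(
    n_per_class: int = 13,
    n_frames: int = 60,
    frame_size: int = 64,
    render: bool = True,
    seed: int = 0,
) -> list[ClipPhantom]:
    """Balanced panel of clips (``n_per_class`` per CC-Clear class) for the
    segment-classification stage."""
    rng = np.random.default_rng(seed)
    clips = []
    i = 0
    for cls in range(4):
        for _ in range(n_per_class):
            clips.append(generate_clip(
                n_frames, cls, render=render, seed=int(rng.integers(2**31 - 1)),
                frame_size=frame_size, clip_id=f"clip{i:03d}",
            ))
            i += 1
    return clips


# ---------------------------------------------------------------------------
# On-disk dataset (PNG frames/masks + CSV tables), used by the CLI.

def write_frame_png(path: str, frame: FramePhantom) -> None:
    Image.fromarray(frame.image).save(path)


def write_mask_png(path: str, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(path)


def read_image_png(path: str) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def read_mask_png(path: str) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) >= 128


def write_dataset(
    out_dir: str,
    n_clips: int = 8,
    n_frames: int = 30,
    frame_size: int = 128,
    n_train_frames: int = 24,
    patches_per_frame: int = 8,
    patch_size: int = 64,
    rater_model: Optional[RaterModel] = None,
    render: bool = True,
    seed: int = 0,
) -> dict:
    """Generate a complete synthetic study on disk.

    Layout: ``frames/<clip>/fNNN.png`` + ``masks/...`` for rendered clips,
    standalone training frames under ``train_frames/`` with a patch-label
    CSV, a clip manifest, per-clip truth timelines and a rater-score table.
    Class labels cycle 0,1,2,3 across clips.
    """
    from .patches import sample_patches, patch_label_from_mask, write_patch_labels

    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)

    # training frames for the segmenter, at a spread of coverage levels
    train_dir = os.path.join(out_dir, "train_frames")
    mask_dir = os.path.join(out_dir, "train_masks")
    os.makedirs(train_dir, exist_ok=True)
    os.makedirs(mask_dir, exist_ok=True)
    labeled = []
    targets = rng.uniform(*TRAIN_COVERAGE_RANGE, size=n_train_frames)
    for i in range(n_train_frames):
        fr = generate_frame(frame_size, float(targets[i]), seed=int(rng.integers(2**31 - 1)))
        fid = f"train{i:03d}"
        write_frame_png(os.path.join(train_dir, fid + ".png"), fr)
        write_mask_png(os.path.join(mask_dir, fid + ".png"), fr.truth_mask)
        refs = sample_patches(
            (frame_size, frame_size), (patch_size, patch_size),
            patches_per_frame, seed=int(rng.integers(2**31 - 1)), frame_id=fid,
        )
        for ref in refs:
            labeled.append((ref, patch_label_from_mask(fr.truth_mask, ref)))
    write_patch_labels(os.path.join(out_dir, "patch_labels.csv"), labeled)

    # clips
    manifest = []
    timelines = []
    true_classes = []
    clip_ids = []
    for i in range(n_clips):
        cls = i % 4
        clip = generate_clip(
            n_frames, cls, render=render, seed=int(rng.integers(2**31 - 1)),
            frame_size=frame_size, clip_id=f"clip{i:03d}",
        )
        clip_ids.append(clip.clip_id)
        true_classes.append(cls)
        manifest.append((clip.clip_id, cls, n_frames))
        for t, v in enumerate(clip.truth_visibility):
            timelines.append((clip.clip_id, t, float(v)))
        if render:
            fdir = os.path.join(out_dir, "frames", clip.clip_id)
            mdir = os.path.join(out_dir, "masks", clip.clip_id)
            os.makedirs(fdir, exist_ok=True)
            os.makedirs(mdir, exist_ok=True)
            for t, fr in enumerate(clip.frames):
                write_frame_png(os.path.join(fdir, f"f{t:04d}.png"), fr)
                write_mask_png(os.path.join(mdir, f"f{t:04d}.png"), fr.truth_mask)

    pd.DataFrame(manifest, columns=["clip_id", "true_class", "n_frames"]).to_csv(
        os.path.join(out_dir, "clips.csv"), index=False
    )
    pd.DataFrame(timelines, columns=["clip_id", "frame_idx", "visibility"]).to_csv(
        os.path.join(out_dir, "truth_timelines.csv"), index=False
    )

    if rater_model is None:
        rater_model = RaterModel(
            n_raters=3, confusion_kernel=neighbor_kernel(), seed=int(rng.integers(2**31 - 1))
        )
    raters = simulate_raters(true_classes, rater_model, clip_ids=clip_ids)
    raters.to_csv(os.path.join(out_dir, "raters.csv"), index=False)

    return {"clip_ids": clip_ids, "true_classes": true_classes, "out_dir": out_dir}
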