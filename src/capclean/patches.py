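"""Patch sampling, patch labeling and the patch-restricted weak-supervision loss.

A segmentation ground truth is expensive to draw; a binary verdict on a
64x64 sub-window ("could the content here hide a pathology?") is cheap.
The loss below turns such patch verdicts into a dense training signal by
broadcasting each patch's binary label to every pixel of that patch and
applying cross-entropy there, leaving all unlabeled pixels out of the loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PROB_EPS = 1e-7  # probabilities are clamped to [PROB_EPS, 1 - PROB_EPS]


@dataclass(frozen=True)
class PatchRef:
    """A rectangular sub-window of a frame.

    Coordinates are 0-based with ``x0`` the left column and ``y0`` the top
    row; the window is half-open, covering ``[y0, y0+h) x [x0, x0+w)`` in
    array indexing.
    """

    frame_id: str
    x0: int
    y0: int
    h: int = 64
    w: int = 64

    def slice(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y0 + self.h), slice(self.x0, self.x0 + self.w)

    def validate_within(self, shape: tuple[int, int]) -> None:
        H, W = shape[:2]
        if self.x0 < 0 or self.y0 < 0 or self.x0 + self.w > W or self.y0 + self.h > H:
            raise ValueError(f"patch {self} does not fit inside frame of shape {(H, W)}")


@dataclass(frozen=True)
class LabeledPatch:
    patch: PatchRef
    y: int  # 1 = dirty (content could hide pathology), 0 = clean

    def __post_init__(self):
        if self.y not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class PatchBatch:
    """A batch of (image, labeled patch) pairs; images may repeat."""

    items: list  # list of (image_or_none, LabeledPatch)

    @property
    def B(self) -> int:
        return len(self.items)

    def __post_init__(self):
        if len(self.items) < 1:
            raise ValueError("batch must contain at least one item")


def sample_patches(
    frame_size: tuple[int, int],
    patch_size: tuple[int, int],
    n: int,
    seed: int = 0,
    frame_id: str = "",
) -> list[PatchRef]:
    """Sample ``n`` patch positions uniformly over all valid top-left
    coordinates (duplicates allowed); deterministic per seed."""
    H, W = frame_size
    h, w = patch_size
    if n < 1:
        raise ValueError("n must be >= 1")
    if h > H or w > W:
        raise ValueError(f"patch {h}x{w} does not fit in frame {H}x{W}")
    rng = np.random.default_rng(seed)
    xs = rng.integers(0, W - w + 1, size=n)
    ys = rng.integers(0, H - h + 1, size=n)
    return [PatchRef(frame_id, int(x), int(y), h, w) for x, y in zip(xs, ys)]


def patch_label_from_mask(
    mask: np.ndarray, patch: PatchRef, coverage_threshold: float = 0.5
) -> int:
    """1 iff content covers at least ``coverage_threshold`` of the patch
    (inclusive at the threshold)."""
    mask = np.asarray(mask)
    patch.validate_within(mask.shape)
    sub = mask[patch.slice()]
    frac = float(np.count_nonzero(sub)) / (patch.h * patch.w)
    return int(frac >= coverage_threshold)


def _clamped(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    return np.clip(p, PROB_EPS, 1.0 - PROB_EPS)


def patch_loss(
    prob_maps: Sequence[np.ndarray],
    batch: PatchBatch,
    reduce_pixels: str = "sum",
) -> float:
    """Cross-entropy between each patch's broadcast label and the per-pixel
    content probabilities, summed over patch pixels and averaged over the
    batch.

    ``prob_maps[k]`` is the probability map of the frame containing batch
    item ``k`` (maps may repeat when several patches come from one frame).
    With ``reduce_pixels="sum"`` each patch contributes the plain pixel sum;
    with ``"mean"`` each patch term is additionally divided by its pixel
    count, making the scale comparable across patch sizes.  Always >= 0.
    """
    if reduce_pixels not in ("sum", "mean"):
        raise ValueError("reduce_pixels must be 'sum' or 'mean'")
    if len(prob_maps) != batch.B:
        raise ValueError("prob_maps must align one-to-one with the batch")
    total = 0.0
    for pm, (_, lp) in zip(prob_maps, batch.items):
        ref = lp.patch
        ref.validate_within(np.asarray(pm).shape)
        p = _clamped(np.asarray(pm)[ref.slice()])
        ll = lp.y * np.log(p) + (1 - lp.y) * np.log1p(-p)
        lk = -float(ll.sum())
        if reduce_pixels == "mean":
            lk /= ref.h * ref.w
        total += lk
    return total / batch.B


def patch_loss_grad(
    prob_maps: Sequence[np.ndarray],
    batch: PatchBatch,
    reduce_pixels: str = "sum",
) -> list[np.ndarray]:
    """Gradient of :func:`patch_loss` with respect to each probability map.

    Exactly zero outside labeled patches; pixels covered by several patches
    accumulate.  Gradients are evaluated at the clamped probabilities.
    """
    if reduce_pixels not in ("sum", "mean"):
        raise ValueError("reduce_pixels must be 'sum' or 'mean'")
    grads = [np.zeros_like(np.asarray(pm, dtype=float)) for pm in prob_maps]
    for g, pm, (_, lp) in zip(grads, prob_maps, batch.items):
        ref = lp.patch
        p = _clamped(np.asarray(pm)[ref.slice()])
        dl = -(lp.y / p - (1 - lp.y) / (1.0 - p)) / batch.B
        if reduce_pixels == "mean":
            dl /= ref.h * ref.w
        g[ref.slice()] += dl
    return grads


# ---------------------------------------------------------------------------
# CSV interchange: frame_id,x0,y0,h,w,label

def write_patch_labels(path: str, labeled: Iterable[tuple[PatchRef, int]]) -> None:
    rows = [(r.frame_id, r.x0, r.y0, r.h, r.w, int(y)) for r, y in labeled]
    pd.DataFrame(rows, columns=["frame_id", "x0", "y0", "h", "w", "label"]).to_csv(
        path, index=False
    )


def read_patch_labels(path: str) -> list[LabeledPatch]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        ref = PatchRef(str(row.frame_id), int(row.x0), int(row.y0), int(row.h), int(row.w))
        out.append(LabeledPatch(ref, int(row.label)))
    return out
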