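"""Per-frame visibility, clip timelines, and the 4-bin CC-Clear features.

Visibility of a frame is the fraction of the field of view (FOV) left
unobscured by intraluminal content: ``1 - |mask & fov| / |fov|``.  Frame
counts over the four CC-Clear visibility regions — <50%, 50-75%, 75-90%,
>=90% — form the feature vector that the segment classifier consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

BIN_EDGES = (0.50, 0.75, 0.90)
BIN_NAMES = ("n_lt50", "n_50_75", "n_75_90", "n_ge90")
BAND_COLORS = ("red", "orange", "gold", "green")
DARKNESS_THRESHOLD = 10  # 0-255 scale; below this a pixel is "black corner"


@dataclass
class VisibilityTimeline:
    clip_id: str
    values: np.ndarray  # per-frame clean-mucosa fraction
    smoothed: Optional[np.ndarray] = None
    window: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("visibility values must lie in [0, 1]")
        if self.smoothed is not None:
            self.smoothed = np.asarray(self.smoothed, dtype=float)
            if len(self.smoothed) != len(self.values):
                raise ValueError("smoothed must match values in length")


@dataclass
class FeatureVector:
    clip_id: str
    counts: tuple[int, int, int, int]
    n_frames: int

    def __post_init__(self):
        if sum(self.counts) != self.n_frames or any(c < 0 for c in self.counts):
            raise ValueError("counts must be nonnegative and sum to n_frames")


def compute_fov_mask(image: np.ndarray, darkness_threshold: int = DARKNESS_THRESHOLD) -> np.ndarray:
    """Field-of-view mask: pixels whose 3x3-median-filtered max channel
    value exceeds the darkness threshold.

    If median denoising removes every bright pixel (possible for isolated
    speckles) the raw threshold mask is used instead, so the result is
    nonempty whenever the image has at least one bright pixel.  A fully
    dark image raises.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    bright = image.max(axis=2)
    mask = ndimage.median_filter(bright, size=3) > darkness_threshold
    if not mask.any():
        mask = bright > darkness_threshold
    if not mask.any():
        raise ValueError("empty field of view: image is fully dark")
    return mask


def circular_fov_mask(size: int) -> np.ndarray:
    """Fixed-geometry alternative matching the synthetic phantom optics."""
    from .synthetic import _fov_circle

    return _fov_circle(size)


def visibility_score(mask: np.ndarray, fov: np.ndarray) -> float:
    """Clean-mucosa fraction: 1 minus the occluded share of the FOV."""
    mask = np.asarray(mask, bool)
    fov = np.asarray(fov, bool)
    if mask.shape != fov.shape:
        raise ValueError("mask and fov shapes must match")
    n_fov = np.count_nonzero(fov)
    if n_fov == 0:
        raise ValueError("empty field of view")
    return 1.0 - np.count_nonzero(mask & fov) / n_fov


def smooth_timeline(values: Sequence[float], window: int) -> np.ndarray:
    """Centered moving average with the window truncated at the clip edges;
    window 1 is the identity.  The window must be odd."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def bin_counts(values: Sequence[float]) -> tuple[int, int, int, int]:
    """Frame counts over the four CC-Clear visibility regions.

    Bins partition [0, 1] as [0, .50), [.50, .75), [.75, .90), [.90, 1]:
    each boundary belongs to the upper bin.
    """
    v = np.asarray(values, dtype=float)
    if v.size and (v.min() < 0 or v.max() > 1):
        raise ValueError("visibility values must lie in [0, 1]")
    idx = np.digitize(v, BIN_EDGES)
    counts = np.bincount(idx, minlength=4)
    return tuple(int(c) for c in counts)


def features_from_timeline(
    timeline: VisibilityTimeline, use_smoothed: bool = False
) -> FeatureVector:
    vals = timeline.smoothed if (use_smoothed and timeline.smoothed is not None) else timeline.values
    counts = bin_counts(vals)
    return FeatureVector(timeline.clip_id, counts, len(vals))


def band_indices(values: Sequence[float]) -> np.ndarray:
    """CC-Clear band (0-3) of each value; 0 is the <50% (red) band."""
    return np.digitize(np.asarray(values, dtype=float), BIN_EDGES)


def timeline_report(
    timeline: VisibilityTimeline,
    path: Optional[str] = None,
    window: int = 25,
) -> np.ndarray:
    """Plot the per-frame visibility with its smoothed trace, dashed
    threshold lines at 0.50/0.75/0.90, and a top color bar banding each
    frame by its smoothed value's CC-Clear region.

    Returns the per-frame band indices (the color bar's content); writes
    the figure to ``path`` when given.
    """
    if len(timeline.values) == 0:
        raise ValueError("timeline is empty")
    if timeline.smoothed is not None and timeline.window == window:
        smoothed = timeline.smoothed
    else:
        w = min(window, len(timeline.values) // 2 * 2 + 1)
        smoothed = smooth_timeline(timeline.values, w)
    bands = band_indices(smoothed)

    if path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n = len(timeline.values)
        fig, ax = plt.subplots(figsize=(9, 3.2))
        ax.plot(timeline.values, lw=0.7, alpha=0.5, color="steelblue", label="per-frame")
        ax.plot(smoothed, lw=1.8, color="navy", label="moving average")
        for y in BIN_EDGES:
            ax.axhline(y, ls="--", lw=0.8, color="gray")
        for b in range(4):
            ax.fill_between(
                np.arange(n), 1.02, 1.08,
                where=bands == b, color=BAND_COLORS[b], step="mid",
            )
        ax.set_ylim(-0.02, 1.1)
        ax.set_xlabel("frame")
        ax.set_ylabel("visible mucosa fraction")
        ax.set_title(f"Clip {timeline.clip_id}")
        ax.legend(loc="lower left", fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return bands


# ---------------------------------------------------------------------------
# CSV interchange

def write_timelines(path: str, timelines: Sequence[VisibilityTimeline]) -> None:
    rows = []
    for tl in timelines:
        sm = tl.smoothed if tl.smoothed is not None else tl.values
        for i, (v, s) in enumerate(zip(tl.values, sm)):
            rows.append((tl.clip_id, i, float(v), float(s)))
    pd.DataFrame(rows, columns=["clip_id", "frame_idx", "visibility", "smoothed"]).to_csv(
        path, index=False
    )


def read_timelines(path: str) -> list[VisibilityTimeline]:
    df = pd.read_csv(path)
    out = []
    for cid, grp in df.groupby("clip_id", sort=False):
        grp = grp.sort_values("frame_idx")
        out.append(
            VisibilityTimeline(
                str(cid), grp["visibility"].to_numpy(), grp["smoothed"].to_numpy()
            )
        )
    return out


def write_features(path: str, feats: Sequence[FeatureVector]) -> None:
    rows = [(f.clip_id, *f.counts) for f in feats]
    pd.DataFrame(rows, columns=["clip_id", *BIN_NAMES]).to_csv(path, index=False)


def read_features(path: str) -> list[FeatureVector]:
    df = pd.read_csv(path)
    return [
        FeatureVector(
            str(r.clip_id),
            (int(r.n_lt50), int(r.n_50_75), int(r.n_75_90), int(r.n_ge90)),
            int(r.n_lt50 + r.n_50_75 + r.n_75_90 + r.n_ge90),
        )
        for r in df.itertuples(index=False)
    ]
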