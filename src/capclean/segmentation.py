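"""Image -> content-probability segmenter trained with the patch loss.

The backbone is a deliberately small fully-convolutional U-Net (one
down/up level, ~7k parameters) written directly on NumPy with explicit
backpropagation and Adam, so the whole method runs on a single CPU.
Intraluminal content in the phantoms (and largely in real footage) is
separable by color and local texture, which a shallow network captures;
the supervision scheme, not backbone capacity, is the point here.

Post-processing follows the method's two steps: a light Gaussian blur of
the probability map (default sigma 0.4 px, read as a standard deviation)
followed by a strict 0.5 threshold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .patches import LabeledPatch, PatchBatch, patch_label_from_mask, patch_loss


@dataclass
class SegmenterConfig:
    input_size: tuple[int, int] = (256, 256)
    backbone: str = "tiny_unet"
    epochs: int = 30
    batch_size: int = 8  # max labeled patches used per frame per step
    learning_rate: float = 1e-2
    seed: int = 0
    smoothing_sigma: float = 0.4  # px std-dev of the probability-map blur
    threshold: float = 0.5  # strict: pixel is content iff value > threshold

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if self.backbone == "transformer_hybrid":
            raise NotImplementedError(
                "the transformer-hybrid backbone is not provided; use 'tiny_unet'"
            )
        if self.backbone != "tiny_unet":
            raise ValueError(f"unknown backbone {self.backbone!r}")


# ---------------------------------------------------------------------------
# conv primitives (NHWC-less: single image, H x W x C float arrays)

def _im2col3(x: np.ndarray) -> np.ndarray:
    """3x3 same-padding patch matrix: (H*W, 9*C), column order (ky, kx, c)."""
    H, W, C = x.shape
    xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
    sw = sliding_window_view(xp, (3, 3), axis=(0, 1))  # (H, W, C, 3, 3)
    return np.ascontiguousarray(sw.transpose(0, 1, 3, 4, 2)).reshape(H * W, 9 * C)


def _conv3(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """3x3 convolution with same padding. W: (3, 3, Cin, Cout)."""
    H, Wd, Cin = x.shape
    cols = _im2col3(x)
    out = cols @ W.reshape(9 * Cin, -1) + b
    return out.reshape(H, Wd, -1), cols


def _conv3_input_grad(dout: np.ndarray, W: np.ndarray) -> np.ndarray:
    # gradient w.r.t. the input == convolution of dout with the rotated,
    # channel-transposed kernel
    W_rot = W[::-1, ::-1].transpose(0, 1, 3, 2)
    g, _ = _conv3(dout, np.ascontiguousarray(W_rot), np.zeros(W.shape[2]))
    return g


def _avgpool2(x: np.ndarray) -> np.ndarray:
    H, W, C = x.shape
    return x.reshape(H // 2, 2, W // 2, 2, C).mean(axis=(1, 3))


def _avgpool2_grad(d: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(d, 2, axis=0), 2, axis=1) / 4.0


def _upsample2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=0), 2, axis=1)


def _upsample2_grad(d: np.ndarray) -> np.ndarray:
    H, W, C = d.shape
    return d.reshape(H // 2, 2, W // 2, 2, C).sum(axis=(1, 3))


_LRELU_SLOPE = 0.1  # leaky slope; avoids dead units under large early steps


def _lrelu(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, z, _LRELU_SLOPE * z)


def _lrelu_grad(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, 1.0, _LRELU_SLOPE)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


_C1, _C2 = 8, 16  # encoder / bottleneck widths


class TinyUNet:
    """One-level U-Net: conv-pool-conv-upsample-concat-conv-1x1, sigmoid head."""

    PARAM_NAMES = ("W1", "b1", "W2", "b2", "W3", "b3", "W4", "b4")

    def __init__(self, config: SegmenterConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params = {
            "W1": he((3, 3, 3, _C1), 27),
            "b1": np.zeros(_C1),
            "W2": he((3, 3, _C1, _C2), 9 * _C1),
            "b2": np.zeros(_C2),
            "W3": he((3, 3, _C1 + _C2, _C1), 9 * (_C1 + _C2)),
            "b3": np.zeros(_C1),
            "W4": he((_C1, 1), _C1),
            "b4": np.zeros(1),
        }
        self.history: list[float] = []
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward -----------------------------------------------------------
    def _forward(self, x: np.ndarray, want_cache: bool = False):
        P = self.params
        a1, cols1 = _conv3(x, P["W1"], P["b1"])
        e1 = _lrelu(a1)
        p = _avgpool2(e1)
        a2, cols2 = _conv3(p, P["W2"], P["b2"])
        bneck = _lrelu(a2)
        u = _upsample2(bneck)
        c = np.concatenate([e1, u], axis=2)
        a3, cols3 = _conv3(c, P["W3"], P["b3"])
        d = _lrelu(a3)
        z = (d.reshape(-1, _C1) @ P["W4"] + P["b4"]).reshape(x.shape[0], x.shape[1])
        prob = _sigmoid(z)
        if not want_cache:
            return prob, None
        cache = dict(a1=a1, cols1=cols1, a2=a2, cols2=cols2, a3=a3, cols3=cols3, d=d)
        return prob, cache

    def predict_prob(self, image: np.ndarray) -> np.ndarray:
        """Probability map for one H x W x 3 image (any even H, W; odd sizes
        are reflect-padded to even and cropped back)."""
        image = np.asarray(image)
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError("expected an H x W x 3 RGB image")
        x = image.astype(float) / 255.0 - 0.5
        H, W = x.shape[:2]
        ph, pw = H % 2, W % 2
        if ph or pw:
            x = np.pad(x, ((0, ph), (0, pw), (0, 0)), mode="reflect")
        prob, _ = self._forward(x)
        return prob[:H, :W]

    # -- backward ----------------------------------------------------------
    def _backward(self, x: np.ndarray, cache: dict, dz: np.ndarray) -> dict:
        P = self.params
        H, W = dz.shape
        d = cache["d"]
        g = {}
        g["W4"] = d.reshape(-1, _C1).T @ dz.reshape(-1, 1)
        g["b4"] = np.array([dz.sum()])
        dd = dz[:, :, None] * P["W4"][:, 0][None, None, :]
        dd *= _lrelu_grad(cache["a3"])
        g["W3"] = (cache["cols3"].T @ dd.reshape(-1, _C1)).reshape(P["W3"].shape)
        g["b3"] = dd.sum(axis=(0, 1))
        dc = _conv3_input_grad(dd, P["W3"])
        de1 = dc[:, :, :_C1].copy()
        du = dc[:, :, _C1:]
        dbneck = _upsample2_grad(du)
        dbneck *= _lrelu_grad(cache["a2"])
        g["W2"] = (cache["cols2"].T @ dbneck.reshape(-1, _C2)).reshape(P["W2"].shape)
        g["b2"] = dbneck.sum(axis=(0, 1))
        dp = _conv3_input_grad(dbneck, P["W2"])
        de1 += _avgpool2_grad(dp)
        de1 *= _lrelu_grad(cache["a1"])
        g["W1"] = (cache["cols1"].T @ de1.reshape(-1, _C1)).reshape(P["W1"].shape)
        g["b1"] = de1.sum(axis=(0, 1))
        return g

    def _adam_step(self, grads: dict, lr_scale: float = 1.0) -> None:
        lr, b1, b2, eps = self.config.learning_rate * lr_scale, 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for k, gk in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * gk
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * gk * gk
            mhat = self._adam_m[k] / (1 - b1**t)
            vhat = self._adam_v[k] / (1 - b2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- persistence -------------------------------------------------------
    def save(self, path: str) -> None:
        """Write weights to ``<path>.npz`` and config+history to ``<path>.json``."""
        np.savez(path + ".npz", **self.params)
        meta = {"config": asdict(self.config), "history": self.history}
        with open(path + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "TinyUNet":
        with open(path + ".json") as fh:
            meta = json.load(fh)
        cfg = meta["config"]
        cfg["input_size"] = tuple(cfg["input_size"])
        model = cls(SegmenterConfig(**cfg))
        with np.load(path + ".npz") as npz:
            for k in cls.PARAM_NAMES:
                model.params[k] = npz[k]
        model.history = list(meta["history"])
        return model


def train_segmenter(
    frames: Sequence[np.ndarray],
    labels: Sequence[Sequence[LabeledPatch]],
    config: Optional[SegmenterConfig] = None,
) -> TinyUNet:
    """Fit the segmenter by minimizing the patch loss.

    ``labels[i]`` holds the labeled patches of ``frames[i]``.  One Adam step
    is taken per frame per epoch, with that frame's patches (at most
    ``config.batch_size`` of them, resampled each epoch) as the batch.  The
    recorded history is the mean per-frame patch loss (pixel-sum reduction)
    of each epoch.
    """
    config = config or SegmenterConfig()
    if len(frames) != len(labels):
        raise ValueError("frames and labels must align")
    all_y = [lp.y for lps in labels for lp in lps]
    if len(all_y) == 0:
        raise ValueError("no labeled patches provided")
    if len(set(all_y)) < 2:
        warnings.warn("patch labels are single-class; the model may collapse")

    model = TinyUNet(config)
    rng = np.random.default_rng(config.seed + 1)
    xs = [np.asarray(f).astype(float) / 255.0 - 0.5 for f in frames]
    for f, lps in zip(frames, labels):
        for lp in lps:
            lp.patch.validate_within(np.asarray(f).shape)

    total_steps = max(config.epochs * len(xs), 1)
    step = 0
    for _ in range(config.epochs):
        order = rng.permutation(len(xs))
        epoch_losses = []
        for i in order:
            lps = list(labels[i])
            if len(lps) == 0:
                continue
            if len(lps) > config.batch_size:
                idx = rng.choice(len(lps), size=config.batch_size, replace=False)
                lps = [lps[j] for j in idx]
            prob, cache = model._forward(xs[i], want_cache=True)
            batch = PatchBatch([(None, lp) for lp in lps])
            epoch_losses.append(patch_loss([prob] * len(lps), batch))
            # fused gradient of the patch loss through the sigmoid:
            # d(loss)/dz = (p - y)/B on each labeled patch's pixels
            dz = np.zeros_like(prob)
            for lp in lps:
                sl = lp.patch.slice()
                dz[sl] += (prob[sl] - lp.y) / len(lps)
            # cosine-decayed learning rate: full rate early, ~0 at the end
            lr_scale = 0.5 * (1.0 + np.cos(np.pi * step / total_steps))
            model._adam_step(model._backward(xs[i], cache, dz), lr_scale)
            step += 1
        if epoch_losses:
            model.history.append(float(np.mean(epoch_losses)))
    return model


def predict_mask(model: TinyUNet, image: np.ndarray) -> np.ndarray:
    """Per-pixel content probability map, same spatial size as the input."""
    return model.predict_prob(image)


def postprocess(prob: np.ndarray, sigma: float = 0.4, threshold: float = 0.5) -> np.ndarray:
    """Gaussian-smooth the probability map (sigma in px; 0 = identity) and
    binarize with a strict ``> threshold`` comparison."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    prob = np.asarray(prob, dtype=float)
    if sigma > 0:
        prob = ndimage.gaussian_filter(prob, sigma=sigma)
    return prob > threshold


def evaluate_miou(
    preds: Sequence[np.ndarray], truths: Sequence[np.ndarray]
) -> float:
    """Mean over images of content-class IoU; an image where both masks are
    empty scores 1 (a correct all-clean prediction)."""
    if len(preds) != len(truths):
        raise ValueError("preds and truths must have equal length")
    ious = []
    for p, t in zip(preds, truths):
        p = np.asarray(p, bool)
        t = np.asarray(t, bool)
        if p.shape != t.shape:
            raise ValueError("mask shape mismatch")
        union = np.count_nonzero(p | t)
        if union == 0:
            ious.append(1.0)
        else:
            ious.append(np.count_nonzero(p & t) / union)
    return float(np.mean(ious))


def evaluate_patch_classification(
    model: TinyUNet,
    frames: Sequence[np.ndarray],
    labeled_patches: Sequence[Sequence[LabeledPatch]],
    coverage_threshold: float = 0.5,
) -> dict:
    """Score patch-level dirty/clean classification derived from the
    segmentation output.

    Hard labels come from the post-processed binary mask via the coverage
    rule (content over >= 50% of the patch => dirty); the continuous score
    used for AUC is the mean probability inside the patch.  Dirty is the
    positive class.  AUC is ``None`` when the ground truth is single-class.
    """
    cfg = model.config
    y_true, y_pred, scores = [], [], []
    for frame, lps in zip(frames, labeled_patches):
        if not lps:
            continue
        prob = predict_mask(model, frame)
        binary = postprocess(prob, cfg.smoothing_sigma, cfg.threshold)
        for lp in lps:
            y_true.append(lp.y)
            y_pred.append(patch_label_from_mask(binary, lp.patch, coverage_threshold))
            scores.append(float(prob[lp.patch.slice()].mean()))
    y_true = np.array(y_true)
    y_pred = np.array(y_pred)
    auc = None
    if len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, scores))
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "auc": auc,
        "precision": float(precision_score(y_true, y_pred, zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
    }


# ---------------------------------------------------------------------------
# Baseline: classify whole patches and tile the verdicts into a mask.

class PatchTilingBaseline:
    """Patch classifier (logistic regression on per-channel mean/std) whose
    mask prediction paints each tile with its patch-level verdict — the
    approach the patch-loss segmenter is compared against."""

    def __init__(self, patch_size: int = 64, stride: Optional[int] = None, seed: int = 0):
        self.patch_size = patch_size
        self.stride = stride if stride is not None else patch_size // 2
        self.clf = LogisticRegression(max_iter=1000, random_state=seed)

    @staticmethod
    def _features(img: np.ndarray) -> np.ndarray:
        x = img.astype(float) / 255.0
        return np.concatenate([x.mean(axis=(0, 1)), x.std(axis=(0, 1))])

    def fit(self, frames, labeled_patches):
        X, y = [], []
        for frame, lps in zip(frames, labeled_patches):
            frame = np.asarray(frame)
            for lp in lps:
                X.append(self._features(frame[lp.patch.slice()]))
                y.append(lp.y)
        self.clf.fit(np.array(X), np.array(y))
        return self

    def predict_mask(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image)
        H, W = image.shape[:2]
        ps = self.patch_size
        votes = np.zeros((H, W))
        hits = np.zeros((H, W))
        ys = sorted(set(list(range(0, H - ps, self.stride)) + [H - ps]))
        xs = sorted(set(list(range(0, W - ps, self.stride)) + [W - ps]))
        for y0 in ys:
            for x0 in xs:
                lab = self.clf.predict(
                    self._features(image[y0:y0 + ps, x0:x0 + ps])[None, :]
                )[0]
                votes[y0:y0 + ps, x0:x0 + ps] += lab
                hits[y0:y0 + ps, x0:x0 + ps] += 1
        return votes / hits > 0.5
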