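"""Agreement statistics: Cohen's kappa, confusion matrices, score summaries.

Cohen's kappa corrects raw agreement for chance: kappa = (p_o - p_e) /
(1 - p_e), with p_o the observed fraction of identical ratings and p_e the
agreement expected from the two raters' marginal score distributions.
Unweighted kappa is the default; linear and quadratic weights are offered
for sensitivity analysis only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


def confusion_matrix(
    y_true: Sequence[int], y_pred: Sequence[int], n_classes: int = 4
) -> np.ndarray:
    """Count matrix with entry (i, j) = #(true i, predicted j)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr in (y_true, y_pred):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"labels must lie in [0, {n_classes})")
    m = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(m, (y_true, y_pred), 1)
    return m


def cohens_kappa(
    a: Sequence[int], b: Sequence[int], weights: Optional[str] = None
) -> float:
    """Chance-corrected agreement between two categorical ratings.

    ``weights`` may be ``None`` (default, unweighted), ``"linear"`` or
    ``"quadratic"``.  When both raters are constant and identical (expected
    agreement 1), kappa is defined as 1.
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("inputs must be equal-length nonempty 1-d sequences")
    cats = np.union1d(a, b)
    k = len(cats)
    remap = {c: i for i, c in enumerate(cats)}
    ai = np.array([remap[x] for x in a])
    bi = np.array([remap[x] for x in b])
    m = confusion_matrix(ai, bi, n_classes=k).astype(float)
    n = m.sum()
    pa = m.sum(axis=1) / n
    pb = m.sum(axis=0) / n

    if weights is None:
        w = 1.0 - np.eye(k)
    elif weights == "linear":
        idx = np.arange(k)
        w = np.abs(idx[:, None] - idx[None, :]) / max(k - 1, 1)
    elif weights == "quadratic":
        idx = np.arange(k)
        w = ((idx[:, None] - idx[None, :]) / max(k - 1, 1)) ** 2
    else:
        raise ValueError("weights must be None, 'linear' or 'quadratic'")

    # symmetrize before summing so kappa(a, b) == kappa(b, a) bit-exactly
    m_sym = (m + m.T) / 2.0
    e_sym = (np.outer(pa, pb) + np.outer(pb, pa)) / 2.0
    disagree_o = float((w * m_sym / n).sum())
    disagree_e = float((w * e_sym).sum())
    if disagree_e == 0.0:
        return 1.0 if disagree_o == 0.0 else float("-inf")
    return 1.0 - disagree_o / disagree_e


def mean_kappa(values: Sequence[float]) -> float:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("mean_kappa of an empty sequence")
    return float(values.mean())


@dataclass
class ScoreSummary:
    """Per-rater distribution over the 0-3 score scale."""

    counts: tuple[int, int, int, int]
    n: int
    mean: float
    sd: float  # population standard deviation
    sd_sample: float  # n-1 denominator, as commonly printed next to means

    @classmethod
    def from_counts(cls, counts: Sequence[int]) -> "ScoreSummary":
        counts = tuple(int(c) for c in counts)
        if len(counts) != 4 or any(c < 0 for c in counts):
            raise ValueError("counts must be four nonnegative integers")
        n = sum(counts)
        if n == 0:
            raise ValueError("empty score distribution")
        scores = np.arange(4)
        mean = float(np.dot(scores, counts)) / n
        var = float(np.dot(scores**2, counts)) / n - mean**2
        var = max(var, 0.0)
        sd_sample = float(np.sqrt(var * n / (n - 1))) if n > 1 else 0.0
        return cls(counts, n, mean, float(np.sqrt(var)), sd_sample)

    @classmethod
    def from_scores(cls, scores: Sequence[int]) -> "ScoreSummary":
        counts = np.bincount(np.asarray(scores, dtype=int), minlength=4)
        if len(counts) > 4:
            raise ValueError("scores must lie in {0, 1, 2, 3}")
        return cls.from_counts(counts)


def summarize_scores(rater_table: pd.DataFrame) -> dict[int, ScoreSummary]:
    """One :class:`ScoreSummary` per rater from a long (clip_id, rater_id,
    score) table."""
    out = {}
    for rid, grp in rater_table.groupby("rater_id"):
        out[rid] = ScoreSummary.from_scores(grp["score"].to_numpy())
    return out


@dataclass
class AgreementReport:
    """All agreement numbers of a study in one record: pairwise inter-rater
    kappas, per-rater model kappas, the consensus-model kappa, and their
    means."""

    pairwise_kappa: dict = field(default_factory=dict)  # (i, j) -> kappa
    model_kappas: dict = field(default_factory=dict)  # rater id -> kappa
    consensus_kappa: Optional[float] = None

    @property
    def mean_pairwise(self) -> float:
        return mean_kappa(list(self.pairwise_kappa.values()))

    @property
    def mean_model(self) -> float:
        return mean_kappa(list(self.model_kappas.values()))

    def to_dict(self) -> dict:
        return {
            "pairwise_kappa": {f"{i}-{j}": v for (i, j), v in self.pairwise_kappa.items()},
            "mean_pairwise": self.mean_pairwise,
            "model_kappas": {str(k): v for k, v in self.model_kappas.items()},
            "mean_model": self.mean_model,
            "consensus_kappa": self.consensus_kappa,
        }

    def to_markdown(self) -> str:
        lines = [
            "| quantity | value |",
            "|---|---|",
        ]
        for (i, j), v in sorted(self.pairwise_kappa.items()):
            lines.append(f"| kappa raters {i}-{j} | {v:.3f} |")
        lines.append(f"| mean inter-rater kappa | {self.mean_pairwise:.3f} |")
        for k, v in sorted(self.model_kappas.items()):
            lines.append(f"| kappa model vs rater {k} | {v:.3f} |")
        lines.append(f"| mean individual-model kappa | {self.mean_model:.3f} |")
        if self.consensus_kappa is not None:
            lines.append(f"| consensus-model kappa | {self.consensus_kappa:.3f} |")
        return "\n".join(lines)


def pairwise_rater_kappas(rater_table: pd.DataFrame) -> dict[tuple, float]:
    """Unweighted kappa for every pair of raters, aligned on clip id."""
    wide = rater_table.pivot(index="clip_id", columns="rater_id", values="score")
    if wide.isna().any().any():
        raise ValueError("every clip must be scored by every rater")
    raters = list(wide.columns)
    out = {}
    for i in range(len(raters)):
        for j in range(i + 1, len(raters)):
            out[(raters[i], raters[j])] = cohens_kappa(
                wide[raters[i]].to_numpy(dtype=int), wide[raters[j]].to_numpy(dtype=int)
            )
    return out
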