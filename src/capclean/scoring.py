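"""Segment-level CC-Clear classification with leave-one-out evaluation.

A depth-limited Random Forest maps each clip's four visibility-bin counts
to a CC-Clear score (0-3).  Because scored clips are scarce, evaluation is
leave-one-out: each clip is predicted by a forest trained on all the
others.  Two supervision modes mirror how rater panels are used in
practice: one model per individual rater, and one model trained on the
panel's consensus (the rounded mean score).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .agreement import cohens_kappa, confusion_matrix
from .visibility import FeatureVector


@dataclass
class ClassifierConfig:
    algorithm: str = "random_forest"
    n_estimators: int = 100
    max_depth: int = 2
    seed: int = 0
    normalize: bool = False  # divide counts by clip length (for mixed-length clips)
    # optional factory returning an unfitted sklearn-style classifier;
    # overrides `algorithm` (used for the alternative-classifier interface)
    estimator_factory: Optional[Callable[[], object]] = None

    def __post_init__(self):
        if self.n_estimators < 1 or self.max_depth < 1:
            raise ValueError("n_estimators and max_depth must be >= 1")

    def make_estimator(self):
        if self.estimator_factory is not None:
            return self.estimator_factory()
        if self.algorithm != "random_forest":
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; pass estimator_factory instead"
            )
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            random_state=self.seed,
        )


@dataclass
class LooResult:
    clip_ids: list
    y_true: np.ndarray
    y_pred: np.ndarray
    kappa: float
    accuracy: float
    confusion: np.ndarray  # 4x4

    def to_dict(self) -> dict:
        return {
            "clip_ids": list(self.clip_ids),
            "y_true": [int(v) for v in self.y_true],
            "y_pred": [int(v) for v in self.y_pred],
            "kappa": self.kappa,
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
        }


def consensus_score(scores: Sequence[int]) -> int:
    """Panel consensus: mean score rounded to the nearest integer, with
    exact halves rounded away from zero (halves cannot occur with three
    raters, whose mean is a multiple of 1/3)."""
    scores = list(scores)
    if len(scores) == 0:
        raise ValueError("consensus of an empty score list")
    if any(s not in (0, 1, 2, 3) for s in scores):
        raise ValueError("scores must lie in {0, 1, 2, 3}")
    m = float(np.mean(scores))
    return int(np.floor(m + 0.5))


def _feature_matrix(features: Sequence[FeatureVector], normalize: bool) -> np.ndarray:
    X = np.array([f.counts for f in features], dtype=float)
    if normalize:
        X /= np.array([[max(f.n_frames, 1)] for f in features], dtype=float)
    return X


def loo_evaluate(
    features: Sequence[FeatureVector],
    targets: Sequence[int],
    config: Optional[ClassifierConfig] = None,
) -> LooResult:
    """Leave-one-out evaluation: clip k is predicted by a classifier fit on
    every clip but k.  Deterministic for a fixed config seed."""
    config = config or ClassifierConfig()
    targets = np.asarray(targets, dtype=int)
    if len(features) != len(targets):
        raise ValueError("features and targets must align")
    n = len(features)
    if n < 2:
        raise ValueError("leave-one-out needs at least 2 clips")
    if len(np.unique(targets)) < 2:
        raise ValueError("targets must contain at least 2 distinct classes")

    X = _feature_matrix(features, config.normalize)
    y_pred = np.empty(n, dtype=int)
    train_mask = np.ones(n, dtype=bool)
    for k in range(n):
        train_mask[:] = True
        train_mask[k] = False
        y_tr = targets[train_mask]
        if len(np.unique(y_tr)) < 2:
            warnings.warn(f"fold {k}: single-class training set; predicting that class")
            y_pred[k] = y_tr[0]
            continue
        est = config.make_estimator()
        est.fit(X[train_mask], y_tr)
        y_pred[k] = int(est.predict(X[k:k + 1])[0])

    kappa = cohens_kappa(targets, y_pred)
    acc = float(np.mean(targets == y_pred))
    conf = confusion_matrix(targets, y_pred, n_classes=4)
    return LooResult(
        clip_ids=[f.clip_id for f in features],
        y_true=targets,
        y_pred=y_pred,
        kappa=kappa,
        accuracy=acc,
        confusion=conf,
    )


def permutation_null_kappas(
    y_pred: Sequence[int],
    targets: Sequence[int],
    n_permutations: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Chance floor for an observed prediction/target agreement: kappa
    between the fixed predictions and permuted target vectors.

    Permuting the targets destroys the pairing while preserving both
    marginals, giving an unbiased null for the agreement statistic.  (The
    alternative of retraining the leave-one-out pipeline on permuted
    targets is *not* centered on zero: excluding a clip tilts the training
    class balance against that clip's label, a well-known negative bias of
    leave-one-out under permutation.)
    """
    rng = rng or np.random.default_rng(0)
    y_pred = np.asarray(y_pred, dtype=int)
    targets = np.asarray(targets, dtype=int)
    return np.array([
        cohens_kappa(y_pred, rng.permutation(targets)) for _ in range(n_permutations)
    ])


@dataclass
class FitModesResult:
    individual: dict  # rater id -> LooResult
    consensus: LooResult
    consensus_targets: np.ndarray

    @property
    def mean_individual_kappa(self) -> float:
        return float(np.mean([r.kappa for r in self.individual.values()]))


def fit_modes(
    features: Sequence[FeatureVector],
    rater_table: pd.DataFrame,
    config: Optional[ClassifierConfig] = None,
) -> FitModesResult:
    """Run both supervision modes: one LOO evaluation per rater (that
    rater's scores as targets) and one with the consensus score.

    Requires a complete table: every clip scored by every rater.
    """
    config = config or ClassifierConfig()
    wide = rater_table.pivot(index="clip_id", columns="rater_id", values="score")
    clip_ids = [f.clip_id for f in features]
    missing = []
    for cid in clip_ids:
        if cid not in wide.index:
            missing.extend((cid, r) for r in wide.columns)
        else:
            missing.extend((cid, r) for r in wide.columns if pd.isna(wide.loc[cid, r]))
    if missing:
        raise ValueError(f"incomplete rater table; missing (clip, rater) pairs: {missing}")
    wide = wide.loc[clip_ids]

    individual = {}
    for rid in wide.columns:
        individual[rid] = loo_evaluate(features, wide[rid].to_numpy(dtype=int), config)
    cons = np.array([consensus_score(wide.loc[cid].to_numpy(dtype=int)) for cid in clip_ids])
    consensus = loo_evaluate(features, cons, config)
    return FitModesResult(individual=individual, consensus=consensus, consensus_targets=cons)
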