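"""Classifier-agnostic permutation feature importance and case signatures.

A feature's importance is the mean increase in prediction error when its
values are shuffled on held-out data: relevant features degrade the trained
model when destroyed, irrelevant ones do not. The default error metric is
the Brier score of the class-probability outputs (mean squared distance
between the score vector and the one-hot label). A rank-based alternative
(1 - AUC; for three-class cases, 1 - mean one-vs-rest AUC) is selectable,
but on strongly separated data it saturates — permuting one of several
redundant features often leaves the test-set ranking intact, so every
importance collapses to exactly zero — whereas the margin-sensitive Brier
score still registers the degradation of the probability outputs. Both
metrics work identically for both classifier adapters.

From the per-case top-10 rankings, case signatures separate the features
shared by all three classification cases from those unique to one case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import (
    ClassifierAdapter,
    EvaluationConfig,
    make_adapter,
    minmax_normalize,
    roc_and_auc,
    stratified_split,
)


@dataclass(frozen=True)
class ImportanceReport:
    """Importance scores and top-k ranking for one classification case."""

    case: str
    scores: dict[str, float]
    k: int = 10

    @property
    def ranking(self) -> list[str]:
        # descending score; lexicographic tie-break for determinism
        return sorted(self.scores, key=lambda c: (-self.scores[c], c))

    @property
    def top_k(self) -> list[str]:
        return self.ranking[: min(self.k, len(self.scores))]

    def to_frame(self) -> pd.DataFrame:
        ranking = self.ranking
        return pd.DataFrame(
            {
                "feature": ranking,
                "score": [self.scores[c] for c in ranking],
                "rank": np.arange(1, len(ranking) + 1),
            }
        )


def _case_auc(scores: np.ndarray, y: np.ndarray, classes: np.ndarray) -> float:
    """AUC of a score matrix: positive-column AUC for binary problems, mean
    one-vs-rest AUC otherwise."""
    if classes.size == 2:
        return roc_and_auc(scores[:, 1], y == classes[1]).auc
    aucs = [
        roc_and_auc(scores[:, i], y == cls).auc for i, cls in enumerate(classes)
    ]
    return float(np.mean(aucs))


def _brier(scores: np.ndarray, y: np.ndarray, classes: np.ndarray) -> float:
    """Multiclass Brier score: mean squared distance between the class-score
    vector and the one-hot true label."""
    onehot = (y[:, None] == classes[None, :]).astype(float)
    return float(np.mean(np.sum((scores - onehot) ** 2, axis=1)))


def _prediction_error(scores: np.ndarray, y: np.ndarray, classes: np.ndarray,
                      metric: str) -> float:
    if metric == "brier":
        return _brier(scores, y, classes)
    if metric == "one_minus_auc":
        return 1.0 - _case_auc(scores, y, classes)
    raise ValueError(f"unknown importance metric {metric!r}")


def permutation_importance(
    model: ClassifierAdapter,
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    n_shuffles: int = 5,
    seed: int = 0,
    metric: str = "brier",
) -> dict[str, float]:
    """Mean error increase per feature on held-out data.

    importance(f) = mean over shuffles of (error_after - error_before), with
    the prediction error given by ``metric`` (see module docstring). X is
    never modified in place.
    """
    if not getattr(model, "_fitted", False):
        raise RuntimeError("model must be fitted before importance estimation")
    y = np.asarray(y).astype(str)
    Xv = X.to_numpy(dtype=float)
    classes = model.classes_
    base_error = _prediction_error(model.predict_scores(Xv), y, classes, metric)
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for j, code in enumerate(X.columns):
        deltas = []
        for _ in range(n_shuffles):
            Xp = Xv.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            err = _prediction_error(model.predict_scores(Xp), y, classes, metric)
            deltas.append(err - base_error)
        out[str(code)] = float(np.mean(deltas))
    return out


def compute_importance(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    config: EvaluationConfig,
    n_shuffles: int = 5,
    k: int = 10,
    case: str = "",
    metric: str = "brier",
) -> ImportanceReport:
    """Importance averaged over the repeated stratified splits: per repeat,
    fit the adapter on the normalized training portion and measure
    permutation importance on the held-out third."""
    y = np.asarray(labels).astype(str)
    X = features.to_numpy(dtype=float)
    totals = {str(c): 0.0 for c in features.columns}
    for r in range(config.n_repeats):
        split_seed = (config.seed * 1000 + r) % 2**31
        tr, te = stratified_split(y, config.train_fraction, split_seed)
        Xtr, Xte = minmax_normalize(X[tr], X[te])
        adapter = make_adapter(config.classifier, split_seed)
        adapter.fit(Xtr, y[tr])
        imp = permutation_importance(
            adapter, pd.DataFrame(Xte, columns=features.columns), y[te],
            n_shuffles=n_shuffles, seed=split_seed, metric=metric,
        )
        for c, v in imp.items():
            totals[c] += v
    scores = {c: v / config.n_repeats for c, v in totals.items()}
    return ImportanceReport(case=case, scores=scores, k=k)


@dataclass(frozen=True)
class CaseSignature:
    """Unique vs shared top-k features for one case."""

    case: str
    top_k: tuple[str, ...]
    unique_features: tuple[str, ...]
    shared_features: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.unique_features) & set(self.shared_features):
            raise ValueError("unique and shared feature sets overlap")


def case_signatures(
    reports: dict[str, ImportanceReport], mode: str = "union"
) -> dict[str, CaseSignature]:
    """Partition each case's top-k list into unique and shared features.

    shared = features in every case's top-k. unique(case): with mode
    "union" (default), the case's top-k minus the union of the other cases'
    top-k lists; with mode "shared_only", the top-k minus only the shared
    set.
    """
    if mode not in ("union", "shared_only"):
        raise ValueError(f"unknown mode {mode!r}")
    feature_sets = {c: set(r.scores) for c, r in reports.items()}
    if len(set(map(frozenset, feature_sets.values()))) != 1:
        raise ValueError("importance reports computed on different feature sets")
    tops = {c: r.top_k for c, r in reports.items()}
    shared = set.intersection(*(set(t) for t in tops.values()))
    out: dict[str, CaseSignature] = {}
    for c, top in tops.items():
        if mode == "union":
            others = set().union(*(set(t) for cc, t in tops.items() if cc != c))
            unique = [f for f in top if f not in others]
        else:
            unique = [f for f in top if f not in shared]
        out[c] = CaseSignature(
            case=c,
            top_k=tuple(top),
            unique_features=tuple(unique),
            shared_features=tuple(f for f in top if f in shared),
        )
    return out


@dataclass(frozen=True)
class BoxWhiskerSummary:
    """Tukey box-and-whisker statistics for one group of values."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartiles out of order")


def box_whisker(values: np.ndarray | list[float]) -> BoxWhiskerSummary:
    """Tukey convention: box at the linear-interpolation quartiles, whiskers
    to the most extreme points within 1.5 IQR of the box, points beyond
    listed as outliers."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # type-7 linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return BoxWhiskerSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(np.sort(outliers).tolist()),
    )


def per_class_box_whisker(
    values: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray,
    normalize: bool = True,
) -> dict[str, BoxWhiskerSummary]:
    """Per-class box-whisker summaries of one feature. With normalize=True
    the values are min-max scaled to [0, 1] across all classes pooled first
    (the convention used for signature figures)."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(str)
    if normalize:
        lo, hi = v.min(), v.max()
        v = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    return {cls: box_whisker(v[y == cls]) for cls in np.unique(y)}
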