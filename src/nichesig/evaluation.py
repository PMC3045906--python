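"""Repeated stratified-split classifier evaluation with ROC/AUC and
permutation controls.

Protocol: the organisms are split into a training set (2/3, stratified by
class) and a test set (the remaining third); features are min-max normalized
with parameters fitted on the training portion only; a classifier adapter is
trained and the test set scored with class-probability outputs; the ROC curve
and its trapezoidal AUC are computed. This is repeated (default 10 times)
with different random splits and the per-repeat AUCs averaged.

Two adapters wrap the classifiers: a 1000-tree random-forest ensemble and an
RBF-kernel SVM with C/gamma grid search under internal cross-validation.
The adapters are thin contracts (fit / predict_scores); the learning
algorithms themselves come from scikit-learn.

Controls: independently permuting each feature column (destroying all
feature-label association while preserving marginals) or permuting the class
labels ("decoy classification") must drive the mean AUC to chance (~0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC


class StratificationError(ValueError):
    """A class is too small to stratify."""


class UndefinedAUCError(ValueError):
    """AUC is undefined with a single label class."""


DEFAULT_C_GRID = tuple(2.0 ** e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** e for e in range(-15, 4, 2))


@dataclass(frozen=True)
class ClassifierSpec:
    """Which adapter to use and its hyperparameters.

    kind "tree_ensemble": random forest, `n_trees` trees, other parameters at
    library defaults. kind "rbf_max_margin": RBF-kernel SVM with C/gamma grid
    search by internal cross-validation (up to `cv_folds`-fold, clamped to
    the smallest training-class size) on the training split only.
    """

    kind: str = "tree_ensemble"
    n_trees: int = 1000
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    cv_folds: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("tree_ensemble", "rbf_max_margin"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.n_trees < 1 or not self.c_grid or not self.gamma_grid:
            raise ValueError("n_trees >= 1 and non-empty grids required")


@dataclass(frozen=True)
class EvaluationConfig:
    train_fraction: float = 2.0 / 3.0
    n_repeats: int = 10
    seed: int = 0
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    normalization: str = "train_minmax"  # or "per_class_minmax"

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.normalization not in ("train_minmax", "per_class_minmax"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


class ClassifierAdapter:
    """fit(X, y) then predict_scores(X) -> (n, n_classes) scores in [0, 1];
    column order given by `classes_`."""

    classes_: np.ndarray

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ClassifierAdapter":
        raise NotImplementedError

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class TreeEnsembleAdapter(ClassifierAdapter):
    """Random forest; scores are the fraction of tree votes per class."""

    def __init__(self, spec: ClassifierSpec, seed: int):
        self.model = RandomForestClassifier(n_estimators=spec.n_trees, random_state=seed,
                                            n_jobs=1)
        self._fitted = False

    def fit(self, X, y):
        self.model.fit(X, y)
        self.classes_ = self.model.classes_
        self._fitted = True
        return self

    def predict_scores(self, X):
        if not self._fitted:
            raise RuntimeError("adapter not fitted")
        return self.model.predict_proba(X)


class RBFMaxMarginAdapter(ClassifierAdapter):
    """RBF-kernel SVM with internal-CV grid search.

    Class scores in [0, 1] come from Platt sigmoid calibration of the
    decision values, fitted by internal cross-validation on the training
    split (the construction behind LibSVM-style probability outputs)."""

    def __init__(self, spec: ClassifierSpec, seed: int):
        self.spec = spec
        self.seed = seed
        self._fitted = False

    def fit(self, X, y):
        _, counts = np.unique(y, return_counts=True)
        folds = max(int(min(self.spec.cv_folds, counts.min())), 2)
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=self.seed)
        grid = GridSearchCV(
            SVC(kernel="rbf"),
            {"C": list(self.spec.c_grid), "gamma": list(self.spec.gamma_grid)},
            cv=cv,
            n_jobs=1,
        )
        grid.fit(X, y)
        self.best_params_ = grid.best_params_
        self.model = CalibratedClassifierCV(
            SVC(kernel="rbf", **grid.best_params_), method="sigmoid",
            cv=cv, ensemble=False,
        )
        self.model.fit(X, y)
        self.classes_ = self.model.classes_
        self._fitted = True
        return self

    def predict_scores(self, X):
        if not self._fitted:
            raise RuntimeError("adapter not fitted")
        return self.model.predict_proba(X)


def make_adapter(spec: ClassifierSpec, seed: int) -> ClassifierAdapter:
    if spec.kind == "tree_ensemble":
        return TreeEnsembleAdapter(spec, seed)
    return RBFMaxMarginAdapter(spec, seed)


def stratified_split(
    labels: np.ndarray | pd.Series, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Random stratified split without replacement.

    Per class, round(train_fraction * n_class) organisms go to training
    (clamped so both portions keep >= 1 member), giving per-class train
    proportions within one organism of the target fraction.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        if members.size < 2:
            raise StratificationError(f"class {cls!r} has {members.size} member(s); need >= 2")
        perm = rng.permutation(members)
        n_train = int(round(train_fraction * members.size))
        n_train = min(max(n_train, 1), members.size - 1)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def minmax_normalize(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature affine map fitted on train (min -> 0, max -> 1), applied
    to test (test values may fall outside [0, 1]; no clipping). A constant
    training feature maps to all zeros."""
    lo = train.min(axis=0)
    span = train.max(axis=0) - lo
    safe = np.where(span == 0, 1.0, span)
    tr = (train - lo) / safe
    te = (test - lo) / safe
    const = span == 0
    if const.any():
        tr[:, const] = 0.0
        te[:, const] = 0.0
    return tr, te


def per_class_minmax_normalize(
    train: np.ndarray, y_train: np.ndarray, test: np.ndarray, y_test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Min-max normalization fitted within each class separately (train and
    test alike). This variant uses the labels of the instances being
    normalized — including the test labels — so it leaks label information
    at prediction time; it is provided only for comparison with the
    train-fitted default."""
    tr = train.copy().astype(float)
    te = test.copy().astype(float)
    for X, y in ((tr, y_train), (te, y_test)):
        for cls in np.unique(y):
            m = y == cls
            lo = X[m].min(axis=0)
            span = X[m].max(axis=0) - lo
            safe = np.where(span == 0, 1.0, span)
            X[m] = (X[m] - lo) / safe
            X[np.ix_(m, span == 0)] = 0.0
    return tr, te


@dataclass(frozen=True)
class ROCCurve:
    """Monotone staircase from (0,0) to (1,1) with trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fpr) < -1e-12) or np.any(np.diff(self.tpr) < -1e-12):
            raise ValueError("ROC points must be monotone non-decreasing")
        if not (self.fpr[0] == 0 and self.tpr[0] == 0 and self.fpr[-1] == 1 and self.tpr[-1] == 1):
            raise ValueError("ROC must run from (0,0) to (1,1)")
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC out of [0,1]")


def roc_and_auc(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC by sweeping a threshold over the distinct scores; AUC by the
    trapezoid rule, which equals the Mann-Whitney statistic
    (#{pos > neg} + 0.5 #ties) / (n_pos * n_neg)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("both classes must be present to compute an AUC")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    # keep only the last point of each tied-score run
    distinct = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, auc=auc)


def average_roc(curves: list[ROCCurve], n_grid: int = 101) -> ROCCurve:
    """Vertically averaged ROC over a common FPR grid (for plotting)."""
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = np.stack([np.interp(grid, c.fpr, c.tpr) for c in curves])
    mean_tpr = tprs.mean(axis=0)
    mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    return ROCCurve(fpr=grid, tpr=mean_tpr, auc=float(np.trapezoid(mean_tpr, grid)))


@dataclass
class EvaluationReport:
    """Per-case result: per-repeat AUCs, their mean, and ROC curves."""

    case: str
    per_repeat_aucs: list[float]
    roc_curves: list[ROCCurve]
    positive_class: str
    pairwise: dict[str, "EvaluationReport"] | None = None
    control_aucs: dict[str, float] = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_repeat_aucs))

    def to_dict(self) -> dict:
        d = {
            "case": self.case,
            "mean_auc": self.mean_auc,
            "per_repeat_aucs": [float(a) for a in self.per_repeat_aucs],
            "positive_class": self.positive_class,
            "control_aucs": dict(self.control_aucs),
        }
        if self.pairwise is not None:
            d["pairwise_mean_aucs"] = {k: v.mean_auc for k, v in self.pairwise.items()}
        return d


def _positive_class(labels: np.ndarray) -> str:
    """Default positive class: the minority label (ties break
    lexicographically)."""
    classes, counts = np.unique(labels, return_counts=True)
    return str(classes[np.lexsort((classes, counts))[0]])


def evaluate_case(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    config: EvaluationConfig,
    case: str = "",
    positive_class: str | None = None,
) -> EvaluationReport:
    """The repeated-split protocol on one binary (or binarized) case."""
    y = np.asarray(labels).astype(str)
    X = features.to_numpy(dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise UndefinedAUCError(f"case {case!r} has a single class")
    if classes.size > 2:
        raise ValueError("evaluate_case is binary; use one_against_one_multiclass")
    pos = positive_class if positive_class is not None else _positive_class(y)
    aucs: list[float] = []
    curves: list[ROCCurve] = []
    for r in range(config.n_repeats):
        split_seed = (config.seed * 1000 + r) % 2**31
        tr, te = stratified_split(y, config.train_fraction, split_seed)
        if config.normalization == "train_minmax":
            Xtr, Xte = minmax_normalize(X[tr], X[te])
        else:
            Xtr, Xte = per_class_minmax_normalize(X[tr], y[tr], X[te], y[te])
        adapter = make_adapter(config.classifier, split_seed)
        adapter.fit(Xtr, y[tr])
        scores = adapter.predict_scores(Xte)
        pos_col = int(np.flatnonzero(adapter.classes_ == pos)[0])
        curve = roc_and_auc(scores[:, pos_col], y[te] == pos)
        aucs.append(curve.auc)
        curves.append(curve)
    return EvaluationReport(case=case, per_repeat_aucs=aucs, roc_curves=curves,
                            positive_class=pos)


def one_against_one_multiclass(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    config: EvaluationConfig,
    case: str = "",
    include_one_vs_all: bool = True,
) -> EvaluationReport:
    """Multiclass reduction: one binary evaluation per unordered class pair,
    plus (optionally) each class vs. the rest. The report's per-repeat AUCs
    are the averages of the pairwise AUCs repeat by repeat, so mean_auc is
    the average of the pairwise mean AUCs."""
    y = pd.Series(np.asarray(labels).astype(str))
    classes = sorted(y.unique())
    if len(classes) < 3:
        raise ValueError("need >= 3 classes; use evaluate_case for binary problems")
    pairwise: dict[str, EvaluationReport] = {}
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            mask = y.isin([a, b]).to_numpy()
            if y[mask].nunique() < 2:
                continue
            sub = evaluate_case(features.iloc[mask], y[mask].to_numpy(), config,
                                case=f"{a}_vs_{b}")
            pairwise[f"{a}_vs_{b}"] = sub
    if include_one_vs_all:
        for a in classes:
            bin_labels = np.where(y.to_numpy() == a, a, "rest")
            pairwise[f"{a}_vs_rest"] = evaluate_case(
                features, bin_labels, config, case=f"{a}_vs_rest", positive_class=a
            )
    pair_keys = [k for k in pairwise if "_vs_rest" not in k]
    per_repeat = np.mean(
        [pairwise[k].per_repeat_aucs for k in pair_keys], axis=0
    ).tolist()
    curves = [average_roc(pairwise[k].roc_curves) for k in pair_keys]
    return EvaluationReport(case=case, per_repeat_aucs=per_repeat, roc_curves=curves,
                            positive_class="", pairwise=pairwise)


def permute_feature_values(features: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Independently shuffle each feature column across organisms (preserves
    marginals, destroys feature-label association)."""
    rng = np.random.default_rng(seed)
    out = features.copy()
    for col in out.columns:
        out[col] = rng.permutation(out[col].to_numpy())
    return out


def permute_labels(labels: pd.Series | np.ndarray, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.permutation(np.asarray(labels))


def _evaluate_any(features, labels, config, case):
    n_classes = np.unique(np.asarray(labels).astype(str)).size
    if n_classes > 2:
        return one_against_one_multiclass(features, labels, config, case=case)
    return evaluate_case(features, labels, config, case=case)


def permutation_control(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    config: EvaluationConfig,
    mode: str,
    permutation_seed: int | None = None,
    case: str = "",
    fresh_permutation_per_repeat: bool = True,
) -> EvaluationReport:
    """Run the unchanged evaluation after destroying the signal.

    mode "feature_values": independently permute each feature column;
    mode "class_labels": permute the label vector (decoy classification).

    By default a fresh permutation is drawn for each of the protocol's
    repeats, so the reported mean AUC estimates the mean of the chance-level
    null distribution. With ``fresh_permutation_per_repeat=False`` a single
    permuted dataset is evaluated across all repeats — that mean is itself
    one draw from the null and scatters more widely around 0.5, because the
    overlapping splits repeatedly relearn the same spurious associations.
    """
    if mode not in ("feature_values", "class_labels"):
        raise ValueError(f"unknown control mode {mode!r}")
    base = permutation_seed if permutation_seed is not None else config.seed + 104729

    def permuted(pseed: int):
        if mode == "feature_values":
            return permute_feature_values(features, pseed), np.asarray(labels)
        return features, permute_labels(labels, pseed)

    name = f"{case}:{mode}" if case else mode
    if not fresh_permutation_per_repeat:
        f, y = permuted(base % 2**31)
        return _evaluate_any(f, y, config, name)

    aucs: list[float] = []
    curves: list[ROCCurve] = []
    positive = ""
    for r in range(config.n_repeats):
        f, y = permuted((base * 1000 + r) % 2**31)
        sub = replace(config, n_repeats=1, seed=(config.seed * 977 + r) % 2**31)
        rep = _evaluate_any(f, y, sub, name)
        aucs.extend(rep.per_repeat_aucs)
        curves.extend(rep.roc_curves)
        positive = rep.positive_class
    return EvaluationReport(case=name, per_repeat_aucs=aucs, roc_curves=curves,
                            positive_class=positive)
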