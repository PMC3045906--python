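"""Split protocol, normalization, ROC/AUC vs pair-counting oracle, and the
evaluation loop on planted and null data."""

import numpy as np
import pandas as pd
import pytest

from nichesig.evaluation import (
    ClassifierSpec,
    EvaluationConfig,
    StratificationError,
    UndefinedAUCError,
    evaluate_case,
    make_adapter,
    minmax_normalize,
    one_against_one_multiclass,
    per_class_minmax_normalize,
    permutation_control,
    roc_and_auc,
    stratified_split,
)


def mann_whitney_auc(scores, labels):
    """Oracle: exhaustive positive/negative pair counting with half-credit
    ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestStratifiedSplit:
    def test_exact_thirds(self):
        labels = np.array(["A"] * 90 + ["B"] * 9)
        tr, te = stratified_split(labels, 2 / 3, seed=0)
        assert (labels[tr] == "A").sum() == 60
        assert (labels[tr] == "B").sum() == 6
        assert len(set(tr) & set(te)) == 0
        assert len(tr) + len(te) == 99

    def test_same_seed_reproducible_different_seed_varies(self):
        labels = np.array(["A"] * 30 + ["B"] * 30)
        tr0, _ = stratified_split(labels, 2 / 3, seed=4)
        tr0b, _ = stratified_split(labels, 2 / 3, seed=4)
        assert np.array_equal(tr0, tr0b)
        assert any(
            not np.array_equal(tr0, stratified_split(labels, 2 / 3, seed=s)[0])
            for s in range(5, 15)
        )

    def test_study_sized_split(self):
        labels = np.array(["non-halophile"] * 129 + ["halophile"] * 63)
        tr, te = stratified_split(labels, 2 / 3, seed=1)
        assert abs(len(tr) - 128) <= 1
        # per-class proportions within one organism of 2/3
        for cls, n in (("non-halophile", 129), ("halophile", 63)):
            got = (labels[tr] == cls).sum()
            assert abs(got - 2 / 3 * n) <= 1

    def test_tiny_class_raises(self):
        with pytest.raises(StratificationError):
            stratified_split(np.array(["A", "A", "B"]), 2 / 3, seed=0)


class TestMinMaxNormalize:
    def test_affine_map(self):
        tr = np.array([[2.0], [4.0], [6.0]])
        te = np.array([[8.0]])
        ntr, nte = minmax_normalize(tr, te)
        assert np.allclose(ntr[:, 0], [0, 0.5, 1])
        assert nte[0, 0] == pytest.approx(1.5)  # extrapolation, no clipping

    def test_constant_column_maps_to_zero(self):
        tr = np.full((3, 1), 5.0)
        te = np.array([[7.0]])
        ntr, nte = minmax_normalize(tr, te)
        assert np.all(ntr == 0) and np.all(nte == 0)

    def test_per_class_variant_normalizes_within_class(self):
        tr = np.array([[0.0], [10.0], [100.0], [110.0]])
        y = np.array(["a", "a", "b", "b"])
        ntr, _ = per_class_minmax_normalize(tr, y, tr, y)
        assert np.allclose(ntr[:, 0], [0, 1, 0, 1])


class TestROCAndAUC:
    def test_perfect_separation(self):
        curve = roc_and_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert curve.auc == pytest.approx(1.0)

    def test_all_ties_gives_half(self):
        curve = roc_and_auc([0.5] * 8, [True, False] * 4)
        assert curve.auc == pytest.approx(0.5)

    def test_interleaved_example_against_pair_counting(self):
        scores = [0.9, 0.4, 0.35, 0.8]
        labels = [True, False, True, False]
        assert mann_whitney_auc(scores, labels) == pytest.approx(0.5)
        assert roc_and_auc(scores, labels).auc == pytest.approx(0.5)

    def test_trapezoid_equals_mann_whitney_on_random_sets(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 40))
            scores = rng.choice(np.round(rng.uniform(size=8), 2), size=n)
            labels = rng.uniform(size=n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert roc_and_auc(scores, labels).auc == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12
            )

    def test_curve_is_monotone_staircase(self, rng):
        scores = rng.uniform(size=30)
        labels = rng.uniform(size=30) < 0.4
        c = roc_and_auc(scores, labels)
        assert c.fpr[0] == 0 and c.tpr[0] == 0
        assert c.fpr[-1] == 1 and c.tpr[-1] == 1
        assert np.all(np.diff(c.fpr) >= 0) and np.all(np.diff(c.tpr) >= 0)

    def test_single_class_raises(self):
        with pytest.raises(UndefinedAUCError):
            roc_and_auc([0.1, 0.2], [True, True])


def _gaussian_case(rng, n_per_class=24, n_features=8, shift=3.0):
    X = rng.normal(size=(2 * n_per_class, n_features))
    X[:n_per_class, :3] += shift
    y = np.array(["pos"] * n_per_class + ["neg"] * n_per_class)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)]), y


class TestEvaluateCase:
    def test_planted_signal_gives_high_auc_both_adapters(self, rng):
        X, y = _gaussian_case(rng)
        for kind in ("tree_ensemble", "rbf_max_margin"):
            cfg = EvaluationConfig(
                n_repeats=3, seed=2,
                classifier=ClassifierSpec(kind=kind, n_trees=200,
                                          c_grid=(1.0, 10.0), gamma_grid=(0.01, 0.1)),
            )
            rep = evaluate_case(X, y, cfg)
            assert rep.mean_auc > 0.95, kind

    def test_null_data_gives_chance_auc(self, rng):
        X = pd.DataFrame(rng.normal(size=(64, 8)))
        y = np.array(["a", "b"] * 32)
        cfg = EvaluationConfig(n_repeats=10, seed=3,
                               classifier=ClassifierSpec(n_trees=200))
        rep = evaluate_case(X, y, cfg)
        assert abs(rep.mean_auc - 0.5) < 0.12

    def test_repeat_count_and_report_shape(self, rng):
        X, y = _gaussian_case(rng, n_per_class=12)
        cfg = EvaluationConfig(n_repeats=10, seed=4, classifier=ClassifierSpec(n_trees=50))
        rep = evaluate_case(X, y, cfg)
        assert len(rep.per_repeat_aucs) == 10
        assert len(rep.roc_curves) == 10
        assert rep.mean_auc == pytest.approx(np.mean(rep.per_repeat_aucs))

    def test_deterministic_given_seed(self, rng):
        X, y = _gaussian_case(rng, n_per_class=12)
        cfg = EvaluationConfig(n_repeats=2, seed=5, classifier=ClassifierSpec(n_trees=50))
        assert evaluate_case(X, y, cfg).per_repeat_aucs == evaluate_case(X, y, cfg).per_repeat_aucs


class TestMulticlass:
    def test_three_pairwise_and_three_one_vs_all_curves(self, rng):
        n = 15
        X = rng.normal(size=(3 * n, 6))
        X[:n, 0] += 4
        X[n:2 * n, 1] += 4
        y = np.array(["meso"] * n + ["mesothermo"] * n + ["thermo"] * n)
        cfg = EvaluationConfig(n_repeats=2, seed=6, classifier=ClassifierSpec(n_trees=100))
        rep = one_against_one_multiclass(pd.DataFrame(X), y, cfg)
        pair_keys = [k for k in rep.pairwise if "_vs_rest" not in k]
        ova_keys = [k for k in rep.pairwise if "_vs_rest" in k]
        assert len(pair_keys) == 3 and len(ova_keys) == 3
        # headline AUC = arithmetic mean of the pairwise means
        assert rep.mean_auc == pytest.approx(
            np.mean([rep.pairwise[k].mean_auc for k in pair_keys])
        )

    def test_indistinguishable_pair_near_chance(self, rng):
        n = 16
        X = rng.normal(size=(3 * n, 6))
        X[2 * n:, 0] += 5  # only the third class separates
        y = np.array(["a"] * n + ["b"] * n + ["c"] * n)
        cfg = EvaluationConfig(n_repeats=4, seed=7, classifier=ClassifierSpec(n_trees=100))
        rep = one_against_one_multiclass(pd.DataFrame(X), y, cfg,
                                         include_one_vs_all=False)
        assert abs(rep.pairwise["a_vs_b"].mean_auc - 0.5) < 0.2
        assert rep.pairwise["a_vs_c"].mean_auc > 0.9


class TestPermutationControls:
    def test_controls_drive_planted_signal_to_chance(self, rng):
        X, y = _gaussian_case(rng, n_per_class=24)
        cfg = EvaluationConfig(n_repeats=5, seed=8, classifier=ClassifierSpec(n_trees=100))
        assert evaluate_case(X, y, cfg).mean_auc > 0.95
        for mode in ("feature_values", "class_labels"):
            ctrl = permutation_control(X, y, cfg, mode)
            assert abs(ctrl.mean_auc - 0.5) < 0.15, mode

    def test_label_permutation_distribution_centered_on_half(self, rng):
        X, y = _gaussian_case(rng, n_per_class=16, n_features=5)
        cfg = EvaluationConfig(n_repeats=1, seed=9, classifier=ClassifierSpec(n_trees=60))
        aucs = [
            permutation_control(X, y, cfg, "class_labels", permutation_seed=s).mean_auc
            for s in range(20)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.07

    def test_control_on_random_labels_stays_null(self, rng):
        X = pd.DataFrame(rng.normal(size=(48, 6)))
        y = np.array(["a", "b"] * 24)
        cfg = EvaluationConfig(n_repeats=3, seed=10, classifier=ClassifierSpec(n_trees=60))
        ctrl = permutation_control(X, y, cfg, "feature_values")
        assert abs(ctrl.mean_auc - 0.5) < 0.15

    def test_adapters_agree_on_planted_signal(self, rng):
        X, y = _gaussian_case(rng, n_per_class=20)
        means = {}
        for kind in ("tree_ensemble", "rbf_max_margin"):
            cfg = EvaluationConfig(
                n_repeats=3, seed=11,
                classifier=ClassifierSpec(kind=kind, n_trees=200,
                                          c_grid=(1.0, 10.0), gamma_grid=(0.01, 0.1)),
            )
            means[kind] = evaluate_case(X, y, cfg).mean_auc
        assert abs(means["tree_ensemble"] - means["rbf_max_margin"]) < 0.1


def test_adapter_requires_fit_before_scoring():
    adapter = make_adapter(ClassifierSpec(n_trees=5), seed=0)
    with pytest.raises(RuntimeError):
        adapter.predict_scores(np.zeros((2, 3)))
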