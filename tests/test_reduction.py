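"""Rank-correlation clustering: Spearman matrix, UPGMA cut vs a brute-force
agglomeration oracle, medoid selection, matrix reduction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nichesig.reduction import (
    CorrelationMatrix,
    InsufficientDataError,
    rank_correlation_matrix,
    reduce_features,
    reduce_matrix,
    select_representatives,
    upgma_cluster,
)


def brute_force_spearman(x, y):
    """Pearson correlation of average ranks, computed from first principles."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v)
        ranks = np.empty_like(v)
        i = 0
        sorted_v = v[order]
        pos = 1.0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i:j + 1]] = (pos + pos + (j - i)) / 2.0
            pos += j - i + 1
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def brute_force_upgma_cut(dist: np.ndarray, names: list[str], cut: float):
    """Oracle: agglomerate the pair of clusters with the smallest average
    pairwise distance while that distance stays <= cut."""
    clusters = [frozenset([n]) for n in names]
    idx = {n: i for i, n in enumerate(names)}
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([
                dist[idx[u], idx[v]] for u in clusters[a] for v in clusters[b]
            ])
            key = (d, tuple(sorted(clusters[a] | clusters[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _), a, b = best
        if d > cut + 1e-12:
            break
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return {frozenset(c) for c in clusters}


class TestRankCorrelation:
    def test_monotone_transform_gives_one(self):
        f = np.arange(10.0)
        df = pd.DataFrame({"f": f, "g": 2 * f + 1})
        corr = rank_correlation_matrix(df)
        assert corr.rho[0, 1] == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        f = np.arange(10.0)
        corr = rank_correlation_matrix(pd.DataFrame({"f": f, "g": -f}))
        assert corr.rho[0, 1] == pytest.approx(-1.0)

    def test_shifted_cycle_example_against_oracle(self):
        f = [1, 2, 3, 4, 5]
        g = [5, 1, 2, 3, 4]
        expected = brute_force_spearman(f, g)  # = 0.0 exactly
        assert expected == pytest.approx(0.0)
        corr = rank_correlation_matrix(pd.DataFrame({"f": f, "g": g}))
        assert corr.rho[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_matches_oracle_on_random_matrices_with_ties(self, rng):
        X = rng.integers(0, 5, size=(12, 6)).astype(float)  # many ties
        corr = rank_correlation_matrix(pd.DataFrame(X, columns=list("abcdef")))
        for i, j in itertools.combinations(range(6), 2):
            assert corr.rho[i, j] == pytest.approx(
                brute_force_spearman(X[:, i], X[:, j]), abs=1e-12
            )

    def test_constant_feature_flagged_with_zero_rho(self):
        df = pd.DataFrame({"f": [1.0, 2, 3, 4], "c": [7.0, 7, 7, 7]})
        corr = rank_correlation_matrix(df)
        assert corr.constant_features == ("c",)
        assert corr.rho[0, 1] == 0.0
        assert corr.rho[1, 1] == 1.0

    def test_too_few_organisms_raises(self):
        with pytest.raises(InsufficientDataError):
            rank_correlation_matrix(pd.DataFrame({"f": [1.0, 2.0], "g": [2.0, 1.0]}))


def _corr(names, rho):
    rho = np.asarray(rho, dtype=float)
    return CorrelationMatrix(feature_codes=tuple(names), rho=rho)


class TestUPGMACluster:
    def test_no_pair_above_threshold_gives_singletons(self):
        rho = np.eye(3)
        rho[0, 1] = rho[1, 0] = 0.5
        rho[0, 2] = rho[2, 0] = 0.3
        rho[1, 2] = rho[2, 1] = 0.2
        clus = upgma_cluster(_corr("abc", rho), threshold=0.9)
        assert clus.n_clusters == 3
        assert all(len(c) == 1 for c in clus.clusters)

    def test_perfect_correlation_gives_one_cluster(self):
        rho = np.full((4, 4), -1.0)  # |rho| = 1 everywhere
        np.fill_diagonal(rho, 1.0)
        clus = upgma_cluster(_corr("abcd", rho), threshold=0.9)
        assert clus.n_clusters == 1
        assert set(clus.clusters[0]) == set("abcd")

    def test_matches_brute_force_oracle_on_random_suite(self, rng):
        for trial in range(30):
            n = int(rng.integers(2, 7))
            names = [f"f{i}" for i in range(n)]
            a = rng.uniform(-1, 1, size=(n, n))
            rho = (a + a.T) / 2
            np.fill_diagonal(rho, 1.0)
            rho = np.clip(rho, -1, 1)
            threshold = float(rng.uniform(0.3, 0.95))
            clus = upgma_cluster(_corr(names, rho), threshold=threshold)
            got = {frozenset(c) for c in clus.clusters}
            expected = brute_force_upgma_cut(1 - np.abs(rho), names, 1 - threshold)
            assert got == expected, f"trial {trial}: {got} != {expected}"

    def test_raising_threshold_never_decreases_cluster_count(self, rng):
        n = 8
        a = rng.uniform(-1, 1, size=(n, n))
        rho = np.clip((a + a.T) / 2, -1, 1)
        np.fill_diagonal(rho, 1.0)
        corr = _corr([f"f{i}" for i in range(n)], rho)
        counts = [upgma_cluster(corr, t).n_clusters for t in (0.3, 0.5, 0.7, 0.9, 0.99)]
        assert counts == sorted(counts)


class TestRepresentatives:
    def test_singleton_represents_itself(self):
        rho = np.eye(2)
        clus = upgma_cluster(_corr("ab", rho), threshold=0.9)
        assert set(clus.representative_codes()) == {"a", "b"}

    def test_medoid_maximizes_mean_abs_rho(self):
        # |rho|(a,b)=0.95, |rho|(a,c)=0.95, |rho|(b,c)=0.91 -> a wins (0.95 > 0.93)
        rho = np.array([
            [1.0, 0.95, 0.95],
            [0.95, 1.0, 0.91],
            [0.95, 0.91, 1.0],
        ])
        corr = _corr("abc", rho)
        clus = upgma_cluster(corr, threshold=0.9)
        assert clus.n_clusters == 1
        assert clus.representatives[0] == "a"

    def test_tie_breaks_lexicographically(self):
        rho = np.array([
            [1.0, 0.95, 0.93],
            [0.95, 1.0, 0.93],
            [0.93, 0.93, 1.0],
        ])
        corr = _corr(["z_feat", "a_feat", "m_feat"], rho)
        clus = upgma_cluster(corr, threshold=0.9)
        # z and a have identical mean |rho|; 'a_feat' sorts first
        assert clus.representatives[0] == "a_feat"

    def test_representative_belongs_to_its_cluster(self, rng):
        n = 10
        a = rng.uniform(-1, 1, size=(n, n))
        rho = np.clip((a + a.T) / 2, -1, 1)
        np.fill_diagonal(rho, 1.0)
        corr = _corr([f"f{i}" for i in range(n)], rho)
        clus = select_representatives(upgma_cluster(corr, 0.6), corr)
        for k, members in enumerate(clus.clusters):
            assert clus.representatives[k] in members


class TestReduceMatrix:
    def test_all_singletons_is_identity(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        reduced, clus, _ = reduce_features(df, threshold=0.9999)
        if clus.n_clusters == 4:
            pd.testing.assert_frame_equal(reduced, df)

    def test_duplicated_feature_collapses(self, rng):
        base = rng.normal(size=30)
        df = pd.DataFrame({
            "orig": base,
            "copy": base + rng.normal(scale=1e-6, size=30),
            "other": rng.normal(size=30),
        })
        reduced, clus, _ = reduce_features(df, threshold=0.9)
        dup_cluster = next(c for c in clus.clusters if "orig" in c)
        assert "copy" in dup_cluster
        assert sum(c in reduced.columns for c in ("orig", "copy")) == 1
        assert "other" in reduced.columns

    def test_projection_property(self, small_halo_features):
        fm, _, _ = small_halo_features
        reduced, clus, _ = reduce_features(fm, threshold=0.9)
        assert set(reduced.columns) <= set(fm.columns)
        assert reduced.shape[1] == clus.n_clusters
        # column order preserved
        assert list(reduced.columns) == [c for c in fm.columns if c in set(reduced.columns)]

    def test_missing_representative_raises(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        _, clus, _ = reduce_features(df, 0.9)
        with pytest.raises(ValueError):
            reduce_matrix(df[["a"]], clus)
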