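"""Feature-redundancy reduction by rank-correlation clustering.

Spearman rank correlations are computed for all feature pairs across
organisms; features are clustered hierarchically on the distance
d = 1 - |rho| with unweighted pair-group average (UPGMA) agglomeration, the
tree is cut so that clusters group features whose average absolute rank
correlation is at least the threshold (default 0.9), and one representative
per cluster — the medoid, i.e. the member with the highest mean |rho| to the
other members — survives into the reduced feature matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats as scipy_stats
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Fewer than 3 organisms: rank correlations are meaningless."""


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Spearman correlation matrix over feature columns."""

    feature_codes: tuple[str, ...]
    rho: np.ndarray
    constant_features: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.feature_codes)
        if self.rho.shape != (n, n):
            raise ValueError("rho shape inconsistent with feature codes")
        if not np.allclose(self.rho, self.rho.T, atol=1e-12):
            raise ValueError("rho must be symmetric")
        if not np.allclose(np.diag(self.rho), 1.0):
            raise ValueError("rho diagonal must be 1")

    def abs_corr(self, a: str, b: str) -> float:
        i, j = self.feature_codes.index(a), self.feature_codes.index(b)
        return abs(float(self.rho[i, j]))


@dataclass(frozen=True)
class FeatureClustering:
    """Dendrogram cut: a partition of the features plus chosen medoids."""

    threshold: float
    linkage_matrix: np.ndarray  # scipy linkage format (merge steps + heights)
    clusters: tuple[tuple[str, ...], ...]
    representatives: dict[int, str]  # cluster position -> feature code

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def representative_codes(self) -> list[str]:
        return [self.representatives[i] for i in range(len(self.clusters))]


def rank_correlation_matrix(features: pd.DataFrame) -> CorrelationMatrix:
    """Spearman correlation (average ranks on ties) of all feature pairs.

    Constant features have undefined rank correlation; they get rho = 0 to
    every other feature and are flagged.
    """
    if features.shape[0] < 3:
        raise InsufficientDataError(
            f"need >= 3 organisms for rank correlations, got {features.shape[0]}"
        )
    if features.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    X = features.to_numpy(dtype=float)
    codes = tuple(features.columns)
    constant = [c for c, col in zip(codes, X.T) if np.all(col == col[0])]
    if constant:
        logger.warning("constant feature(s) get rho=0: %s", constant)
    if X.shape[1] == 1:
        rho = np.ones((1, 1))
    else:
        import warnings

        with warnings.catch_warnings():
            # constant columns are handled explicitly below (rho = 0)
            warnings.simplefilter("ignore", scipy_stats.ConstantInputWarning)
            stat = spearmanr(X, axis=0).statistic
        if np.ndim(stat) == 0:  # scipy collapses the 2-column case to a scalar
            r = float(stat)
            rho = np.array([[1.0, r], [r, 1.0]])
        else:
            rho = np.asarray(stat)
    rho = np.where(np.isnan(rho), 0.0, rho)
    np.fill_diagonal(rho, 1.0)
    rho = 0.5 * (rho + rho.T)  # enforce exact symmetry
    return CorrelationMatrix(feature_codes=codes, rho=rho, constant_features=tuple(constant))


def upgma_cluster(corr: CorrelationMatrix, threshold: float = 0.9) -> FeatureClustering:
    """UPGMA agglomeration on d = 1 - |rho|, cut at height 1 - threshold.

    Merges are allowed while the average pairwise distance is <= 1 -
    threshold, i.e. clusters group features with mean absolute rank
    correlation >= threshold.
    """
    n = len(corr.feature_codes)
    dist = 1.0 - np.abs(corr.rho)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    if n == 1:
        Z = np.empty((0, 4))
        labels = np.array([1])
    else:
        Z = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(Z, t=1.0 - threshold, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for code, lab in zip(corr.feature_codes, labels):
        clusters.setdefault(int(lab), []).append(code)
    # deterministic ordering: by first-appearing member in input column order
    ordered = sorted(clusters.values(), key=lambda members: corr.feature_codes.index(members[0]))
    clustering = FeatureClustering(
        threshold=threshold,
        linkage_matrix=Z,
        clusters=tuple(tuple(m) for m in ordered),
        representatives={},
    )
    return select_representatives(clustering, corr)


def select_representatives(
    clustering: FeatureClustering, corr: CorrelationMatrix
) -> FeatureClustering:
    """Choose the medoid of each cluster as its representative.

    For clusters of size >= 2 the representative maximizes the mean |rho| to
    the other members ("closest to the center"); singletons represent
    themselves. Ties break to the lexicographically smaller feature code.
    """
    idx = {c: i for i, c in enumerate(corr.feature_codes)}
    reps: dict[int, str] = {}
    for k, members in enumerate(clustering.clusters):
        if len(members) == 1:
            reps[k] = members[0]
            continue
        best_code, best_score = None, -np.inf
        for m in sorted(members):
            others = [idx[o] for o in members if o != m]
            score = float(np.mean(np.abs(corr.rho[idx[m], others])))
            if score > best_score + 1e-15:
                best_code, best_score = m, score
        reps[k] = best_code  # type: ignore[assignment]
    return FeatureClustering(
        threshold=clustering.threshold,
        linkage_matrix=clustering.linkage_matrix,
        clusters=clustering.clusters,
        representatives=reps,
    )


def reduce_matrix(features: pd.DataFrame, clustering: FeatureClustering) -> pd.DataFrame:
    """Restrict the feature matrix to the representative columns (input
    column order preserved)."""
    reps = set(clustering.representative_codes())
    missing = reps - set(features.columns)
    if missing:
        raise ValueError(f"representatives missing from matrix: {sorted(missing)}")
    keep = [c for c in features.columns if c in reps]
    return features[keep]


def reduce_features(
    features: pd.DataFrame, threshold: float = 0.9
) -> tuple[pd.DataFrame, FeatureClustering, CorrelationMatrix]:
    """Full reduction step: correlations -> UPGMA cut -> representative
    columns."""
    corr = rank_correlation_matrix(features)
    clustering = upgma_cluster(corr, threshold)
    return reduce_matrix(features, clustering), clustering, corr


def write_clustering_report(
    clustering: FeatureClustering, corr: CorrelationMatrix, path: str | Path
) -> None:
    """TSV report: cluster id, members, representative, mean within-cluster
    |rho|."""
    idx = {c: i for i, c in enumerate(corr.feature_codes)}
    rows = []
    for k, members in enumerate(clustering.clusters):
        if len(members) >= 2:
            ii = [idx[m] for m in members]
            sub = np.abs(corr.rho[np.ix_(ii, ii)])
            mean_rho = float((sub.sum() - len(ii)) / (len(ii) * (len(ii) - 1)))
        else:
            mean_rho = 1.0
        rows.append(
            {
                "cluster_id": k,
                "n_members": len(members),
                "members": ",".join(members),
                "representative": clustering.representatives[k],
                "mean_abs_rho": mean_rho,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def dendrogram_newick(clustering: FeatureClustering, corr: CorrelationMatrix) -> str:
    """Newick export of the UPGMA dendrogram (branch lengths in d = 1-|rho|)."""
    from scipy.cluster.hierarchy import to_tree

    if clustering.linkage_matrix.shape[0] == 0:
        return f"({corr.feature_codes[0]});"
    tree = to_tree(clustering.linkage_matrix)

    def rec(node) -> str:
        if node.is_leaf():
            return corr.feature_codes[node.id]
        left, right = rec(node.left), rec(node.right)
        bl_l = node.dist - node.left.dist
        bl_r = node.dist - node.right.dist
        return f"({left}:{bl_l:.6g},{right}:{bl_r:.6g})"

    return rec(tree) + ";"
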