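"""Cluster-number heuristics, four clustering methods, and validation.

The number of clusters is chosen by consensus of four heuristics computed
on centroid-based reference partitions (silhouette max, Calinski-Harabasz
max, inertia knee, Davies-Bouldin min): a value named by two or more
heuristics wins, otherwise the lower median.  Four clusterers are then run
with method-specific parameter rules and validated against reference
labelings (tissue state, embryonic day) with five agreement metrics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import DBSCAN, KMeans, SpectralClustering
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    calinski_harabasz_score,
    completeness_score,
    davies_bouldin_score,
    homogeneity_score,
    silhouette_score,
    v_measure_score,
)
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import normalize

from ._knee import find_knee

logger = logging.getLogger(__name__)

NOISE = -1

#: Fixed tie-break order for best-method selection.
METHOD_ORDER = ("agglomerative", "kmeans", "spectral", "dbscan")


@dataclass
class ClusterAssignment:
    """Labels produced by one clustering method, with its parameters.

    ``labels`` is indexed by sample id; -1 marks density-method noise.
    ``degenerate`` flags results with no non-noise cluster.
    """

    method: str
    parameters: dict
    labels: pd.Series
    linkage_tree: np.ndarray | None = None
    degenerate: bool = False

    def __post_init__(self):
        non_noise = set(self.labels) - {NOISE}
        if not non_noise:
            self.degenerate = True
            logger.warning("%s produced no non-noise cluster", self.method)
        if NOISE in set(self.labels) and self.method != "dbscan":
            raise ValueError("noise labels are only valid for dbscan")


@dataclass
class HeuristicReport:
    """Per-k heuristic curves, per-heuristic best k, and the consensus k."""

    k_range: tuple[int, ...]
    silhouette: dict[int, float]
    calinski_harabasz: dict[int, float]
    inertia: dict[int, float]
    davies_bouldin: dict[int, float]
    best_k: dict[str, int | None]
    consensus: int = field(init=False)

    def __post_init__(self):
        self.consensus = consensus_k(self.best_k)


def consensus_k(best_k: dict[str, int | None]) -> int:
    """Consensus cluster number from the per-heuristic best-k votes.

    A value named by >= 2 heuristics wins; if two values tie at
    multiplicity 2 the smaller wins (parsimony); with no agreement the
    lower median of the votes is used (guaranteeing an integer).
    Heuristics that failed (None) simply do not vote.
    """
    votes = sorted(v for v in best_k.values() if v is not None)
    if not votes:
        raise ValueError("no heuristic produced a best k")
    counts = pd.Series(votes).value_counts()
    top = counts.max()
    if top >= 2:
        modes = sorted(counts.index[counts == top])
        return int(modes[0])
    return int(votes[(len(votes) - 1) // 2])


def heuristic_scan(
    scores: pd.DataFrame | np.ndarray,
    k_range: range | None = None,
    seed: int = 0,
) -> HeuristicReport:
    """Evaluate the four cluster-number heuristics over a k range.

    All four are computed on centroid-based (k-means) reference partitions,
    the only partition family for which inertia is defined.  Best k per
    heuristic: silhouette max, Calinski-Harabasz max, inertia knee
    (maximum-curvature point of the decreasing convex curve), and
    Davies-Bouldin min.
    """
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("heuristic scan requires at least 3 samples")
    if k_range is None:
        k_range = range(2, min(10, n - 1) + 1)
    ks = [int(k) for k in k_range]
    if not ks or min(ks) < 2 or max(ks) > n - 1:
        raise ValueError(f"k_range {ks} outside [2, n-1] = [2, {n - 1}]")

    sil, ch, inertia, db = {}, {}, {}, {}
    # k = 1 anchors the inertia curve (total sum of squares) so the elbow is
    # visible even when the true cluster count is at the low end of k_range;
    # the other heuristics are undefined there.
    tss = float(((X - X.mean(axis=0)) ** 2).sum())
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        labels = km.labels_
        inertia[k] = float(km.inertia_)
        if len(set(labels)) > 1:
            sil[k] = float(silhouette_score(X, labels))
            ch[k] = float(calinski_harabasz_score(X, labels))
            db[k] = float(davies_bouldin_score(X, labels))
        else:  # pragma: no cover - k>=2 k-means rarely collapses
            sil[k], ch[k], db[k] = -1.0, 0.0, np.inf

    knee_ks = ks if 1 in ks else [1] + ks
    knee_ys = [tss if k == 1 else inertia[k] for k in knee_ks]
    knee = find_knee(
        np.array(knee_ks, dtype=float),
        np.array(knee_ys),
        curve="convex",
        direction="decreasing",
    )
    best = {
        "silhouette": max(sil, key=sil.get),
        "calinski_harabasz": max(ch, key=ch.get),
        "inertia_knee": int(knee) if knee is not None and int(knee) in ks else None,
        "davies_bouldin": min(db, key=db.get),
    }
    if len(ks) == 1:
        best = {name: ks[0] for name in best}
    return HeuristicReport(
        k_range=tuple(ks),
        silhouette=sil,
        calinski_harabasz=ch,
        inertia=inertia,
        davies_bouldin=db,
        best_k=best,
    )


def _index_of(scores) -> pd.Index:
    if isinstance(scores, pd.DataFrame):
        return scores.index
    return pd.RangeIndex(len(scores))


def kmeans_cluster(
    scores: pd.DataFrame | np.ndarray, k: int, seed: int = 0
) -> ClusterAssignment:
    """Two-stage k-means: subsampled center search, then full-data refinement.

    Stage 1 draws 30 % of the samples without replacement and runs five
    random initializations capped at three Lloyd iterations each, keeping
    the centers with the lowest subsample inertia.  Stage 2 refines those
    centers on all samples to convergence (tol 1e-6).
    """
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, n={n}]")
    rng = np.random.default_rng(seed)
    m = max(1, int(round(0.30 * n)))
    if m < k:
        logger.warning("30%% subsample (%d) < k=%d; using full data for stage 1", m, k)
        sub = X
    else:
        sub = X[rng.choice(n, size=m, replace=False)]

    best_centers, best_inertia = None, np.inf
    for attempt in range(5):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # max_iter=3 triggers ConvergenceWarning
            km = KMeans(
                n_clusters=k,
                init="random",
                n_init=1,
                max_iter=3,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(sub)
        if km.inertia_ < best_inertia:
            best_inertia, best_centers = km.inertia_, km.cluster_centers_

    final = KMeans(
        n_clusters=k, init=best_centers, n_init=1, max_iter=300, tol=1e-6
    ).fit(X)
    return ClusterAssignment(
        method="kmeans",
        parameters={"k": k, "seed": seed, "subsample": int(len(sub)),
                    "attempts": 5, "stage1_max_iter": 3},
        labels=pd.Series(final.labels_, index=_index_of(scores)),
    )


def spectral_cluster(
    scores: pd.DataFrame | np.ndarray, k: int, seed: int = 0
) -> ClusterAssignment:
    """Spectral clustering on row-normalized data, best of two affinities.

    Rows are L2-normalized first; the neighbor count is n/4 (floored, at
    least 1).  Both a Gaussian (rbf) kernel and a nearest-neighbors graph
    are fitted and the labeling with the higher silhouette is kept; a
    disconnected neighbor graph falls back to the Gaussian kernel.
    """
    X = normalize(np.asarray(scores, dtype=float))
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k={k} outside [2, n={n}]")
    n_neighbors = max(1, n // 4)

    candidates: dict[str, np.ndarray] = {}
    labels_rbf = SpectralClustering(
        n_clusters=k, affinity="rbf", random_state=seed
    ).fit_predict(X)
    candidates["rbf"] = labels_rbf
    try:
        with warnings.catch_warnings():
            warnings.filterwarnings("error", message=".*not fully connected.*")
            labels_nn = SpectralClustering(
                n_clusters=k,
                affinity="nearest_neighbors",
                n_neighbors=n_neighbors,
                random_state=seed,
            ).fit_predict(X)
        candidates["nearest_neighbors"] = labels_nn
    except Warning:
        logger.warning("neighbor graph disconnected; using Gaussian kernel only")
    except Exception as exc:  # pragma: no cover - rare numerical failures
        logger.warning("nearest-neighbors affinity failed (%s)", exc)

    def sil(labels):
        return (
            silhouette_score(X, labels) if len(set(labels)) > 1 else -np.inf
        )

    affinity = max(candidates, key=lambda a: sil(candidates[a]))
    return ClusterAssignment(
        method="spectral",
        parameters={"k": k, "seed": seed, "n_neighbors": n_neighbors,
                    "affinity": affinity},
        labels=pd.Series(candidates[affinity], index=_index_of(scores)),
    )


class EpsNotFoundError(ValueError):
    """No knee in the k-distance curve; pass an explicit eps."""


def dbscan_cluster(
    scores: pd.DataFrame | np.ndarray,
    dims: int,
    eps: float | None = None,
) -> ClusterAssignment:
    """Density clustering with min_samples = 2 x the PCA dimensionality.

    The neighborhood radius eps defaults to the knee of the sorted
    min_samples-th nearest-neighbor distance curve; if no knee exists an
    explicit eps is required.  Noise points keep the label -1.
    """
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    min_samples = 2 * int(dims)
    if n <= min_samples:
        raise ValueError(f"need n > min_samples = {min_samples}, got n={n}")
    if eps is None:
        nn = NearestNeighbors(n_neighbors=min_samples).fit(X)
        dist, _ = nn.kneighbors(X)
        kdist = np.sort(dist[:, -1])
        eps = find_knee(
            np.arange(1, n + 1, dtype=float),
            kdist,
            curve="convex",
            direction="increasing",
        )
        if eps is None or eps <= 0:
            raise EpsNotFoundError(
                "no knee found in the k-distance curve; supply eps explicitly"
            )
        eps = float(kdist[int(eps) - 1])
        if eps <= 0:
            raise EpsNotFoundError("k-distance knee is at distance 0; supply eps")
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(X)
    return ClusterAssignment(
        method="dbscan",
        parameters={"eps": float(eps), "min_samples": min_samples},
        labels=pd.Series(labels, index=_index_of(scores)),
    )


def agglomerative_cluster(
    scores: pd.DataFrame | np.ndarray, k: int
) -> ClusterAssignment:
    """Ward-linkage hierarchical clustering cut at k clusters.

    The full linkage tree is retained for dendrogram/newick export.
    """
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, n={n}]")
    tree = hierarchy.linkage(X, method="ward")
    labels = hierarchy.fcluster(tree, t=k, criterion="maxclust") - 1
    return ClusterAssignment(
        method="agglomerative",
        parameters={"k": k, "linkage": "ward"},
        labels=pd.Series(labels, index=_index_of(scores)),
        linkage_tree=tree,
    )


def linkage_to_newick(tree: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a linkage matrix as a Newick string (heights as branch lengths)."""
    n = len(leaf_names)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return leaf_names[i]
        a, b, h, _ = tree[i - n]
        a, b = int(a), int(b)
        heights[i] = h
        return (
            f"({node(a)}:{h - heights[a]:.6g},{node(b)}:{h - heights[b]:.6g})"
        )

    return node(2 * n - 2) + ";"


@dataclass(frozen=True)
class ClusterEvaluation:
    """Agreement between a clustering and a reference labeling."""

    method: str
    reference: str
    ari: float
    ami: float
    v_measure: float
    homogeneity: float
    completeness: float

    def as_dict(self) -> dict:
        return {
            "ari": self.ari,
            "ami": self.ami,
            "v_measure": self.v_measure,
            "homogeneity": self.homogeneity,
            "completeness": self.completeness,
        }

    @property
    def mean_score(self) -> float:
        return float(np.mean(list(self.as_dict().values())))


def evaluate_clustering(
    assignment: ClusterAssignment,
    reference: pd.Series,
    reference_name: str = "reference",
) -> ClusterEvaluation:
    """Five agreement metrics between an assignment and reference labels.

    Noise points (label -1) are kept as their own category — excluding them
    would inflate agreement.  The reference must cover the same samples.
    """
    ref = pd.Series(reference)
    if set(ref.index) != set(assignment.labels.index):
        raise ValueError("reference labels must cover exactly the clustered samples")
    ref = ref.loc[assignment.labels.index]
    y_pred = assignment.labels.to_numpy()
    y_true = ref.astype(str).to_numpy()
    return ClusterEvaluation(
        method=assignment.method,
        reference=reference_name,
        ari=float(adjusted_rand_score(y_true, y_pred)),
        ami=float(adjusted_mutual_info_score(y_true, y_pred)),
        v_measure=float(v_measure_score(y_true, y_pred)),
        homogeneity=float(homogeneity_score(y_true, y_pred)),
        completeness=float(completeness_score(y_true, y_pred)),
    )


def select_best_method(
    evaluations: dict[str, dict[str, ClusterEvaluation]],
    references: tuple[str, str] = ("tissue_state", "stage"),
) -> str:
    """Pick the method separating both references best.

    Score = mean of the five metrics averaged over the two references;
    ties break by ARI on the first reference, then by the fixed order
    agglomerative, kmeans, spectral, dbscan.
    """
    if not evaluations:
        raise ValueError("no evaluations provided")

    def key(method: str):
        evs = evaluations[method]
        score = float(np.mean([evs[r].mean_score for r in references]))
        ari_primary = evs[references[0]].ari
        order = METHOD_ORDER.index(method) if method in METHOD_ORDER else 99
        return (-score, -ari_primary, order)

    return min(evaluations, key=key)
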