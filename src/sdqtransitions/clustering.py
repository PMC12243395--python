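"""UMAP embedding and k-means profile clustering with a tri-criterion
validity rule.

Each wave's elevated, screened, z-scored subscale table is projected to
two dimensions with UMAP (many neighbours, small min_dist, correlation
metric — parameters chosen to suppress noise-driven microstructure and
produce dense, well-separated clusters) and partitioned with k-means.
A candidate k must satisfy three criteria to be accepted:

1. separation — mean silhouette > 0.5 with every per-cluster mean > 0;
2. a steep increase in the Calinski–Harabasz index at k;
3. stability — every cluster's mean bootstrap Jaccard overlap >= 0.85.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_samples

from sdqtransitions.scoring import SUBSCALES

__all__ = [
    "EmbeddingParams",
    "ClusterSolution",
    "embed",
    "cluster_k",
    "validity_metrics",
    "bootstrap_jaccard",
    "select_k",
]


@dataclass(frozen=True)
class EmbeddingParams:
    """UMAP parameters; the defaults (many neighbours, tiny min_dist,
    correlation metric) favour coarse, dense, shape-based clusters."""

    n_neighbors: int = 50
    min_dist: float = 0.01
    metric: str = "correlation"
    n_components: int = 2
    seed: int = 0


@dataclass
class ClusterSolution:
    """An accepted (or best-available) clustering of one wave."""

    wave: str
    coordinates: np.ndarray
    k: int
    labels: np.ndarray
    mean_silhouette: float
    per_cluster_silhouette: dict[int, float]
    calinski_harabasz: float
    per_cluster_jaccard: dict[int, float] = field(default_factory=dict)
    accepted: bool = False
    #: per-candidate-k metrics recorded during selection
    diagnostics: dict = field(default_factory=dict)

    def silhouette_scores(self) -> np.ndarray:
        """Per-child silhouette values in the embedding."""
        return silhouette_samples(self.coordinates, self.labels)

    def summary(self) -> dict:
        d = asdict(self)
        d.pop("coordinates")
        d["labels"] = None
        d["n"] = len(self.labels)
        return d


def embed(zscored: pd.DataFrame, params: EmbeddingParams | None = None) -> np.ndarray:
    """Project the five z-scored subscales to 2-D with UMAP.

    Deterministic given ``params.seed`` (single-threaded exact mode).
    """
    import umap

    if params is None:
        params = EmbeddingParams()
    if isinstance(zscored, pd.DataFrame) and set(SUBSCALES) <= set(zscored.columns):
        x = zscored[list(SUBSCALES)].to_numpy(dtype=float)
    else:
        x = np.asarray(zscored, dtype=float)
    if len(x) < params.n_neighbors + 1:
        raise ValueError(
            f"embedding needs at least n_neighbors + 1 = {params.n_neighbors + 1} rows, "
            f"got {len(x)}"
        )
    logging.getLogger(__name__).info("embedding %d rows with %s", len(x), params)
    reducer = umap.UMAP(
        n_neighbors=params.n_neighbors,
        min_dist=params.min_dist,
        metric=params.metric,
        n_components=params.n_components,
        random_state=params.seed,
        n_jobs=1,
    )
    return np.asarray(reducer.fit_transform(x), dtype=float)


def cluster_k(coordinates: np.ndarray, k: int, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """Standard k-means (k-means++ seeding, fixed restarts) on the embedding."""
    coordinates = np.asarray(coordinates, dtype=float)
    n = len(coordinates)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of points ({n})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(coordinates)


def validity_metrics(
    coordinates: np.ndarray, labels: np.ndarray
) -> tuple[float, dict[int, float], float]:
    """Mean silhouette, per-cluster mean silhouettes, and the
    Calinski–Harabasz index (Euclidean, in the embedding space)."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("validity metrics need at least 2 clusters")
    counts = np.array([(labels == u).sum() for u in uniq])
    if np.all(counts == 1):
        raise ValueError("silhouette undefined for singleton-only clusterings")
    sil = silhouette_samples(coordinates, labels)
    per_cluster = {int(u): float(sil[labels == u].mean()) for u in uniq}
    ch = float(calinski_harabasz_score(coordinates, labels))
    return float(sil.mean()), per_cluster, ch


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def bootstrap_jaccard(
    coordinates: np.ndarray,
    labels: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    n_init: int = 10,
) -> dict[int, float]:
    """Cluster-wise bootstrap stability on the fixed embedding.

    For each of ``B`` row resamples (with replacement) k-means is refit
    with the same k; each original cluster is matched to the bootstrap
    cluster maximising the Jaccard overlap over the children present in
    the resample (a child drawn multiple times counts once); returns the
    mean best overlap per original cluster.  Stability holds when every
    mean is >= 0.85.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    coordinates = np.asarray(coordinates, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    n = len(labels)
    uniq = np.unique(labels)
    k = len(uniq)
    orig_sets = {int(u): set(np.flatnonzero(labels == u)) for u in uniq}
    sums = {int(u): 0.0 for u in uniq}
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        present = np.unique(idx)
        km = KMeans(n_clusters=k, n_init=n_init, random_state=int(rng.integers(2**31)))
        boot_labels = km.fit_predict(coordinates[idx])
        boot_sets = []
        for u in np.unique(boot_labels):
            boot_sets.append(set(np.unique(idx[boot_labels == u])))
        present_set = set(present)
        for u in uniq:
            a = orig_sets[int(u)] & present_set
            best = max(_jaccard(a, b) for b in boot_sets)
            sums[int(u)] += best
    return {u: s / B for u, s in sums.items()}


def select_k(
    coordinates: np.ndarray,
    wave: str = "",
    k_range: range = range(2, 11),
    silhouette_threshold: float = 0.5,
    jaccard_threshold: float = 0.85,
    B: int = 1000,
    seed: int = 0,
    ch_rule: str = "steep_increase",
) -> ClusterSolution:
    """Choose k by separation, CH steep increase, and bootstrap stability.

    Candidates are the k whose mean silhouette exceeds the threshold with
    all per-cluster means positive.  Candidates are ranked by the relative
    forward jump in the Calinski–Harabasz index,
    ``(CH(k) - CH(k-1)) / CH(k-1)`` (``ch_rule='max_ch'`` ranks by raw CH
    instead); the highest-ranked candidate whose per-cluster bootstrap
    Jaccard means all reach the stability threshold is accepted.  If no
    candidate passes every criterion the best available solution is
    returned with ``accepted=False`` and per-k diagnostics.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    n = len(coordinates)
    ks = [k for k in k_range if 2 <= k < n]
    if not ks:
        raise ValueError("no valid k in range for this sample size")

    per_k: dict[int, dict] = {}
    for k in ks:
        labels = cluster_k(coordinates, k, seed=seed)
        mean_sil, per_cluster_sil, ch = validity_metrics(coordinates, labels)
        per_k[k] = {
            "labels": labels,
            "mean_silhouette": mean_sil,
            "per_cluster_silhouette": per_cluster_sil,
            "calinski_harabasz": ch,
        }

    def steep_score(k: int) -> float:
        if ch_rule == "max_ch":
            return per_k[k]["calinski_harabasz"]
        prev = k - 1
        if prev not in per_k:
            return float("-inf")
        ch_prev = per_k[prev]["calinski_harabasz"]
        return (per_k[k]["calinski_harabasz"] - ch_prev) / ch_prev if ch_prev > 0 else float("-inf")

    candidates = [
        k
        for k in ks
        if per_k[k]["mean_silhouette"] > silhouette_threshold
        and all(v > 0 for v in per_k[k]["per_cluster_silhouette"].values())
    ]
    diagnostics = {
        k: {
            "mean_silhouette": per_k[k]["mean_silhouette"],
            "calinski_harabasz": per_k[k]["calinski_harabasz"],
            "steep_score": steep_score(k),
            "candidate": k in candidates,
        }
        for k in ks
    }

    def build(k: int, jaccard: dict[int, float], accepted: bool) -> ClusterSolution:
        return ClusterSolution(
            wave=wave,
            coordinates=coordinates,
            k=k,
            labels=per_k[k]["labels"],
            mean_silhouette=per_k[k]["mean_silhouette"],
            per_cluster_silhouette=per_k[k]["per_cluster_silhouette"],
            calinski_harabasz=per_k[k]["calinski_harabasz"],
            per_cluster_jaccard=jaccard,
            accepted=accepted,
            diagnostics=diagnostics,
        )

    if not candidates:
        best = max(ks, key=lambda k: per_k[k]["mean_silhouette"])
        return build(best, {}, accepted=False)

    ranked = sorted(candidates, key=steep_score, reverse=True)
    if all(steep_score(k) == float("-inf") for k in ranked):
        ranked = sorted(candidates, key=lambda k: per_k[k]["calinski_harabasz"], reverse=True)
    last_jaccard: dict[int, float] = {}
    for k in ranked:
        jac = bootstrap_jaccard(coordinates, per_k[k]["labels"], B=B, seed=seed)
        diagnostics[k]["per_cluster_jaccard"] = jac
        last_jaccard = jac
        if min(jac.values()) >= jaccard_threshold:
            return build(k, jac, accepted=True)
    return build(ranked[0], diagnostics[ranked[0]].get("per_cluster_jaccard", last_jaccard), accepted=False)
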