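"""Uniform wrappers over standard clustering algorithms and quality metrics.

Deliberately thin: the estimators and metrics are scikit-learn's; the
contract here is a uniform call signature, seeding, and provenance
recording via :class:`ClusteringResult`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cnvdata import CNVMatrix


class ClusteringError(ValueError):
    pass


@dataclass(frozen=True)
class ClusteringResult:
    labels: np.ndarray  # -1 marks noise where the algorithm allows
    method: str
    params: dict
    seed: int | None


def _estimator(method: str, seed, params: dict):
    from sklearn import cluster as skc

    if method == "kmeans":
        return skc.KMeans(random_state=seed, n_init=10, **params)
    if method == "affinity_propagation":
        return skc.AffinityPropagation(random_state=seed, **params)
    if method == "birch":
        return skc.Birch(**params)
    if method == "dbscan":
        return skc.DBSCAN(**params)
    if method == "hdbscan":
        return skc.HDBSCAN(**params)
    if method == "agglomerative":
        return skc.AgglomerativeClustering(**params)
    if method == "optics":
        return skc.OPTICS(**params)
    if method == "spectral":
        return skc.SpectralClustering(random_state=seed, **params)
    raise ClusteringError(
        f"unknown clustering method {method!r}; choose from kmeans, "
        "affinity_propagation, birch, dbscan, hdbscan, agglomerative, "
        "optics, spectral")


def cluster(data, method: str, seed: int | None = None,
            **params) -> ClusteringResult:
    """Cluster cells (rows) of a matrix or embedding.

    Stochastic methods are deterministic given ``seed``; parameters are
    passed through to the underlying scikit-learn estimator.
    """
    X = data.X if isinstance(data, CNVMatrix) else np.asarray(data)
    X = X.astype(float)
    try:
        est = _estimator(method, seed, params)
        labels = est.fit_predict(X)
    except ClusteringError:
        raise
    except TypeError as exc:
        raise ClusteringError(f"invalid params for {method}: {exc}") from exc
    return ClusteringResult(labels=np.asarray(labels), method=method,
                            params=dict(params), seed=seed)


_EXTERNAL = ("adjusted_rand", "v_measure", "fowlkes_mallows", "mutual_info")
_INTERNAL = ("silhouette", "davies_bouldin", "calinski_harabasz")


def evaluate(labels, metric: str, truth=None, data=None) -> float:
    """Score a clustering with one of the standard quality metrics.

    External metrics (adjusted_rand, v_measure, fowlkes_mallows,
    mutual_info) compare ``labels`` to ``truth``; internal metrics
    (silhouette, davies_bouldin, calinski_harabasz) need the clustered
    ``data`` instead.
    """
    from sklearn import metrics as skm

    labels = np.asarray(labels if not isinstance(labels, ClusteringResult)
                        else labels.labels)
    if metric in _EXTERNAL:
        if truth is None:
            raise ClusteringError(f"{metric} requires ground-truth labels")
        truth = np.asarray(truth)
        fn = {"adjusted_rand": skm.adjusted_rand_score,
              "v_measure": skm.v_measure_score,
              "fowlkes_mallows": skm.fowlkes_mallows_score,
              "mutual_info": skm.mutual_info_score}[metric]
        return float(fn(truth, labels))
    if metric in _INTERNAL:
        if data is None:
            raise ClusteringError(f"{metric} requires the clustered data")
        X = data.X if isinstance(data, CNVMatrix) else np.asarray(data)
        if len(np.unique(labels)) < 2:
            raise ClusteringError(
                f"{metric} is undefined for a single cluster")
        fn = {"silhouette": skm.silhouette_score,
              "davies_bouldin": skm.davies_bouldin_score,
              "calinski_harabasz": skm.calinski_harabasz_score}[metric]
        return float(fn(X, labels))
    raise ClusteringError(
        f"unknown metric {metric!r}; choose from {_EXTERNAL + _INTERNAL}")
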