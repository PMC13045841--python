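"""Classification metrics and embedding-quality diagnostics.

The classification report covers AUC-ROC, accuracy, recall, precision, F1
and AUC-PR at a 0.5 threshold.  The embedding diagnostics quantify how much
cluster structure a set of learned embeddings carries:

Hopkins score (HS)
    Sample ``n_test`` real points; for each, take the nearest-neighbour
    distance to the rest of the data (``D_T``).  Sample ``n_test`` uniform
    reference points in the data's axis-aligned bounding box; take their
    nearest-data distances (``D_R``).  ``HS = D_R / (D_R + D_T)`` - about
    0.5 for uniformly spread data, approaching 1 for strongly clustered
    data.  Plain Euclidean distances are used here.

Cluster tendency score (CTS)
    The same machinery with *squared* Euclidean distances, then the
    normalisation ``CTS = 2 * max(ratio - 0.5, 0)``, mapping uniform data to
    about 0 and strong clustering toward 1.

Silhouette index (SI) and Calinski-Harabasz index (CHI)
    Internal cluster-validity measures over a labelling (here produced by
    seeded k-means with k=2, following how the diagnostics are applied to
    binding/non-binding embeddings).

HS and CTS are computed from the raw points; SI and CHI from the k-means
partition.  All four are bundled by :func:`embedding_diagnostics`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

__all__ = [
    "MetricReport",
    "EmbeddingDiagnostics",
    "classification_metrics",
    "hopkins_score",
    "cluster_tendency_score",
    "silhouette_index",
    "calinski_harabasz",
    "embedding_diagnostics",
]

CHI_SENTINEL = 1e12  # stands in for +inf when within-cluster scatter vanishes


@dataclass
class MetricReport:
    """Six classification metrics plus provenance."""

    auc_roc: float
    accuracy: float
    recall: float
    precision: float
    f1: float
    auc_pr: float
    n: int
    threshold: float = 0.5
    auc_defined: bool = True
    seed: int | None = None
    split_id: str | None = None

    def as_dict(self) -> dict:
        return {
            "auc_roc": self.auc_roc, "accuracy": self.accuracy, "recall": self.recall,
            "precision": self.precision, "f1": self.f1, "auc_pr": self.auc_pr,
            "n": self.n, "threshold": self.threshold, "auc_defined": self.auc_defined,
            "seed": self.seed, "split_id": self.split_id,
        }


@dataclass
class EmbeddingDiagnostics:
    """Clustering-tendency and cluster-validity scores for one embedding set."""

    hopkins: float
    cts: float
    silhouette: float
    chi: float
    n_points: int
    n_test_points: int
    seed: int | None = None

    def as_dict(self) -> dict:
        return {"hopkins": self.hopkins, "cts": self.cts, "silhouette": self.silhouette,
                "chi": self.chi, "n_points": self.n_points,
                "n_test_points": self.n_test_points, "seed": self.seed}


def classification_metrics(y_hat, y, threshold: float = 0.5,
                           seed: int | None = None, split_id: str | None = None) -> MetricReport:
    """Thresholded and rank-based classification metrics.

    AUC-ROC uses tie-averaged ranks; AUC-PR is the step-integrated
    precision-recall area (average precision).  With a single-class ``y``
    both AUCs are undefined: they are reported as NaN with
    ``auc_defined=False``.
    """
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    y = np.asarray(y, dtype=int).ravel()
    if y_hat.shape != y.shape or y_hat.size == 0:
        raise ValueError("y_hat and y must be equal-length, non-empty")
    pred = (y_hat >= threshold).astype(int)
    both_classes = len(np.unique(y)) == 2
    if both_classes:
        auc_roc = float(roc_auc_score(y, y_hat))
        auc_pr = float(average_precision_score(y, y_hat))
    else:
        auc_roc = auc_pr = float("nan")
    return MetricReport(
        auc_roc=auc_roc,
        accuracy=float(accuracy_score(y, pred)),
        recall=float(recall_score(y, pred, zero_division=0)),
        precision=float(precision_score(y, pred, zero_division=0)),
        f1=float(f1_score(y, pred, zero_division=0)),
        auc_pr=auc_pr,
        n=int(y.size),
        threshold=threshold,
        auc_defined=both_classes,
        seed=seed,
        split_id=split_id,
    )


def default_n_test(n: int) -> int:
    """Default number of test points: min(100, n // 10), floored at 10."""
    return max(10, min(100, n // 10))


def _hopkins_ratio(points: np.ndarray, n_test: int, rng: np.random.Generator,
                   squared: bool) -> float:
    n, d = points.shape
    if n_test < 1 or n_test > n - 1:
        raise ValueError("need 1 <= n_test <= n - 1")
    idx = rng.choice(n, size=n_test, replace=False)
    tree = cKDTree(points)
    # nearest neighbour of each sampled real point, excluding itself
    d_real, _ = tree.query(points[idx], k=2)
    d_t = d_real[:, 1]
    lo, hi = points.min(axis=0), points.max(axis=0)
    uniform = rng.uniform(lo, hi, size=(n_test, d))
    d_ref, _ = tree.query(uniform, k=1)
    if squared:
        d_t, d_ref = d_t**2, d_ref**2
    dt, dr = float(d_t.sum()), float(d_ref.sum())
    if dt + dr == 0.0:
        warnings.warn("degenerate data: all points coincide; returning 1.0")
        return 1.0
    return dr / (dr + dt)


def hopkins_score(points, n_test: int | None = None, seed: int | None = None) -> float:
    """Hopkins clustering-tendency statistic with plain Euclidean distances."""
    points = np.asarray(points, dtype=float)
    n_test = default_n_test(len(points)) if n_test is None else n_test
    rng = np.random.default_rng(seed)
    return _hopkins_ratio(points, n_test, rng, squared=False)


def cluster_tendency_score(points, n_test: int | None = None, seed: int | None = None) -> float:
    """CTS: squared-distance Hopkins ratio mapped through 2*max(r - 0.5, 0)."""
    points = np.asarray(points, dtype=float)
    n_test = default_n_test(len(points)) if n_test is None else n_test
    rng = np.random.default_rng(seed)
    ratio = _hopkins_ratio(points, n_test, rng, squared=True)
    return 2.0 * max(ratio - 0.5, 0.0)


def silhouette_index(points, labels) -> float:
    """Mean silhouette value, ``s(i) = (b(i) - a(i)) / max(a(i), b(i))``.

    ``a(i)`` is the mean intra-cluster distance excluding the point itself;
    ``b(i)`` the smallest mean distance to another cluster.  Points in
    singleton clusters score 0, as does the 0/0 case of coincident points.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    if len(labels) != len(points):
        raise ValueError("labels and points must align")
    diff = points[:, None, :] - points[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    s = np.zeros(len(points))
    masks = {c: labels == c for c in uniq}
    for i in range(len(points)):
        own = masks[labels[i]]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = dist[i, own].sum() / (n_own - 1)
        b = min(dist[i, masks[c]].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0.0 else (b - a) / denom
    return float(s.mean())


def calinski_harabasz(points, labels) -> float:
    """Variance-ratio criterion ``(B / (K-1)) / (W / (N-K))``.

    ``B`` is the centroid-weighted between-cluster scatter and ``W`` the
    within-cluster scatter.  When ``W`` vanishes (coincident points within
    every cluster) the ratio is unbounded; a large finite sentinel is
    returned with a warning.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n, k = len(points), len(uniq)
    if k < 2 or k >= n:
        raise ValueError("require 2 <= K < N clusters")
    c_all = points.mean(axis=0)
    b = w = 0.0
    for c in uniq:
        grp = points[labels == c]
        ck = grp.mean(axis=0)
        b += len(grp) * float(((ck - c_all) ** 2).sum())
        w += float(((grp - ck) ** 2).sum())
    if w <= 1e-300:
        warnings.warn("within-cluster scatter is zero; returning sentinel value")
        return CHI_SENTINEL
    return (b / (k - 1)) / (w / (n - k))


def embedding_diagnostics(points, labels=None, k: int = 2,
                          n_test: int | None = None, seed: int = 0) -> EmbeddingDiagnostics:
    """Bundle HS/CTS on the raw points with SI/CHI on a k-means partition.

    A seeded k-means (k=2 by default, multiple restarts) provides the
    partition for SI and CHI; pass ``labels`` explicitly (with ``k=None``)
    to score a given labelling instead.
    """
    points = np.asarray(points, dtype=float)
    if not np.isfinite(points).all():
        raise ValueError("points must be finite")
    n_test = default_n_test(len(points)) if n_test is None else n_test
    if k is not None:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(points)
    elif labels is None:
        raise ValueError("either k or labels must be given")
    return EmbeddingDiagnostics(
        hopkins=hopkins_score(points, n_test=n_test, seed=seed),
        cts=cluster_tendency_score(points, n_test=n_test, seed=seed),
        silhouette=silhouette_index(points, labels),
        chi=calinski_harabasz(points, labels),
        n_points=len(points),
        n_test_points=n_test,
        seed=seed,
    )
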