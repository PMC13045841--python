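"""Classification metrics and embedding diagnostics against brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from crossbind.metrics import (
    CHI_SENTINEL,
    calinski_harabasz,
    classification_metrics,
    cluster_tendency_score,
    embedding_diagnostics,
    hopkins_score,
    silhouette_index,
)
from crossbind.metrics import _hopkins_ratio


def auc_pair_count_oracle(scores, labels) -> float:
    """Mann-Whitney statistic: fraction of (pos, neg) pairs ranked correctly,
    ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_perfect_separation_gives_unit_auc():
    rep = classification_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert rep.auc_roc == 1.0 and rep.accuracy == 1.0 and rep.f1 == 1.0


def test_constant_scores_give_half_auc_with_tie_averaging():
    rep = classification_metrics([0.7] * 6, [1, 0, 1, 0, 1, 0])
    assert rep.auc_roc == pytest.approx(0.5)


def test_auc_matches_pair_count_oracle_hand_case():
    scores = [0.9, 0.6, 0.6, 0.4, 0.3, 0.1]
    labels = [1, 1, 0, 1, 0, 0]
    rep = classification_metrics(scores, labels)
    assert rep.auc_roc == pytest.approx(auc_pair_count_oracle(scores, labels), abs=1e-9)


def test_auc_matches_pair_count_oracle_random_fixtures():
    rng = np.random.default_rng(4)
    for _ in range(10):
        n = int(rng.integers(6, 30))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            continue
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        rep = classification_metrics(scores, labels)
        assert rep.auc_roc == pytest.approx(auc_pair_count_oracle(scores, labels), abs=1e-9)


def test_single_class_flags_undefined_aucs():
    rep = classification_metrics([0.2, 0.8], [1, 1])
    assert not rep.auc_defined
    assert np.isnan(rep.auc_roc) and np.isnan(rep.auc_pr)
    assert rep.accuracy == 0.5


def test_threshold_metrics_hand_case():
    rep = classification_metrics([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0])
    assert rep.accuracy == 0.5
    assert rep.recall == 0.5      # one of two positives recovered
    assert rep.precision == 0.5   # one true positive of two flagged


# -- Hopkins / CTS ------------------------------------------------------------

def test_hopkins_uniform_data_near_half():
    vals = []
    for seed in range(10):
        rng = np.random.default_rng([7, seed])
        pts = rng.uniform(size=(500, 6))
        vals.append(hopkins_score(pts, n_test=80, seed=seed))
    assert abs(np.mean(vals) - 0.5) < 0.05


def test_hopkins_two_tight_blobs_near_one():
    rng = np.random.default_rng(8)
    blob = lambda c: c + 0.001 * rng.normal(size=(200, 4))
    pts = np.vstack([blob(np.zeros(4)), blob(10.0 * np.ones(4))])
    assert hopkins_score(pts, n_test=50, seed=0) > 0.95


def test_hopkins_two_point_case_matches_hand_arithmetic():
    """Replicate the documented sampling protocol step by step."""
    pts = np.array([[0.0], [2.0]])
    seed = 123
    got = hopkins_score(pts, n_test=1, seed=seed)
    rng = np.random.default_rng(seed)
    idx = rng.choice(2, size=1, replace=False)
    d_t = 2.0  # nearest (only) neighbour of either point
    u = rng.uniform(0.0, 2.0, size=(1, 1))[0, 0]
    d_r = min(u, 2.0 - u)
    assert got == pytest.approx(d_r / (d_r + d_t), abs=1e-12)


def test_degenerate_coincident_points_return_one_with_warning():
    pts = np.zeros((20, 3))
    with pytest.warns(UserWarning, match="degenerate"):
        assert hopkins_score(pts, n_test=5, seed=0) == 1.0


def test_cts_normalisation_is_consistent_with_squared_ratio():
    rng = np.random.default_rng(9)
    pts = np.vstack([rng.normal(size=(100, 4)), 8 + rng.normal(size=(100, 4))])
    for seed in (0, 1, 2):
        ratio = _hopkins_ratio(pts, 40, np.random.default_rng(seed), squared=True)
        assert cluster_tendency_score(pts, n_test=40, seed=seed) == pytest.approx(
            2.0 * max(ratio - 0.5, 0.0), abs=1e-12)


def test_cts_uniform_data_approaches_zero():
    vals = [cluster_tendency_score(np.random.default_rng([11, s]).uniform(size=(400, 4)),
                                   n_test=50, seed=s)
            for s in range(20)]
    assert np.mean(vals) < 0.15
    assert all(0.0 <= v <= 1.0 for v in vals)


def test_cts_bounded_on_random_draws():
    rng = np.random.default_rng(13)
    for _ in range(30):
        pts = rng.normal(size=(60, 3)) * rng.uniform(0.5, 3)
        v = cluster_tendency_score(pts, n_test=10, seed=int(rng.integers(100)))
        assert 0.0 <= v <= 1.0


# -- silhouette ---------------------------------------------------------------

def silhouette_oracle(points, labels):
    n = len(points)
    dist = np.array([[np.linalg.norm(points[i] - points[j]) for j in range(n)]
                     for i in range(n)])
    vals = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            vals.append(0.0)
            continue
        a = np.mean([dist[i][j] for j in own])
        b = min(np.mean([dist[i][j] for j in range(n) if labels[j] == c])
                for c in set(labels) if c != labels[i])
        vals.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(vals))


def test_silhouette_far_separated_tight_clusters_approach_one():
    pts = np.vstack([np.zeros((5, 2)), 100 + np.zeros((5, 2))])
    labels = [0] * 5 + [1] * 5
    assert silhouette_index(pts, labels) == pytest.approx(1.0)


def test_silhouette_all_coincident_is_zero():
    assert silhouette_index(np.zeros((6, 2)), [0, 0, 0, 1, 1, 1]) == 0.0


def test_silhouette_five_point_hand_case_matches_loop_oracle():
    pts = np.array([[0.0, 0], [1, 0], [0, 1], [5, 5], [6, 5]])
    labels = [0, 0, 0, 1, 1]
    assert silhouette_index(pts, labels) == pytest.approx(
        silhouette_oracle(pts, labels), abs=1e-12)


def test_silhouette_matches_oracles_on_random_fixtures():
    rng = np.random.default_rng(15)
    for _ in range(8):
        n = int(rng.integers(6, 30))
        pts = rng.normal(size=(n, 3))
        labels = rng.integers(0, 3, size=n)
        if len(set(labels)) < 2:
            continue
        ours = silhouette_index(pts, labels)
        assert ours == pytest.approx(silhouette_oracle(pts, labels), abs=1e-9)
        if min(np.bincount(labels, minlength=3)[np.unique(labels)]) > 1:
            assert ours == pytest.approx(float(silhouette_score(pts, labels)), abs=1e-9)


def test_silhouette_one_cluster_rejected():
    with pytest.raises(ValueError, match="2 clusters"):
        silhouette_index(np.zeros((4, 2)), [0, 0, 0, 0])


# -- Calinski-Harabasz --------------------------------------------------------

def test_chi_two_symmetric_line_clusters_hand_case():
    pts = np.array([[-2.0], [-1.0], [1.0], [2.0]])
    labels = [0, 0, 1, 1]
    # centroids +-1.5, grand 0: B = 2*1.5^2 * 2 = 9 ; W = 4 * 0.5^2 = 1
    assert calinski_harabasz(pts, labels) == pytest.approx((9 / 1) / (1 / 2), abs=1e-12)


def test_chi_matches_sklearn_on_random_fixtures():
    rng = np.random.default_rng(16)
    for _ in range(8):
        n = int(rng.integers(6, 30))
        pts = rng.normal(size=(n, 4))
        labels = rng.integers(0, 2, size=n)
        if len(set(labels)) < 2:
            continue
        assert calinski_harabasz(pts, labels) == pytest.approx(
            float(calinski_harabasz_score(pts, labels)), rel=1e-9)


def test_chi_invariant_under_rotation_and_translation():
    rng = np.random.default_rng(17)
    pts = rng.normal(size=(20, 2))
    labels = rng.integers(0, 2, size=20)
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = pts @ rot.T + np.array([3.0, -5.0])
    assert calinski_harabasz(moved, labels) == pytest.approx(
        calinski_harabasz(pts, labels), rel=1e-9)


def test_chi_degenerate_within_scatter_returns_sentinel():
    pts = np.array([[0.0, 0], [0, 0], [1, 1], [1, 1]])
    with pytest.warns(UserWarning, match="sentinel"):
        assert calinski_harabasz(pts, [0, 0, 1, 1]) == CHI_SENTINEL


def test_chi_degenerate_cluster_counts_rejected():
    pts = np.zeros((4, 2))
    with pytest.raises(ValueError):
        calinski_harabasz(pts, [0, 0, 0, 0])
    with pytest.raises(ValueError):
        calinski_harabasz(pts, [0, 1, 2, 3])


# -- bundled diagnostics ------------------------------------------------------

def test_diagnostics_separated_blobs_score_high():
    rng = np.random.default_rng(18)
    pts = np.vstack([rng.normal(0, 0.3, size=(150, 5)),
                     rng.normal(6, 0.3, size=(150, 5))])
    diag = embedding_diagnostics(pts, k=2, n_test=50, seed=0)
    assert diag.hopkins > 0.7
    assert diag.cts > 0.4
    assert diag.silhouette > 0.5
    assert diag.chi > 100


def test_diagnostics_deterministic_under_seed():
    rng = np.random.default_rng(19)
    pts = rng.normal(size=(120, 4))
    a = embedding_diagnostics(pts, k=2, n_test=30, seed=5)
    b = embedding_diagnostics(pts, k=2, n_test=30, seed=5)
    assert a == b


def test_diagnostics_reject_non_finite_points():
    pts = np.zeros((10, 2))
    pts[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        embedding_diagnostics(pts, k=2, seed=0)


def test_nearest_neighbour_excludes_self():
    """The D_T summand for a sampled real point ignores the point itself."""
    pts = np.array([[0.0], [0.0], [10.0]])
    tree = cKDTree(pts)
    d, _ = tree.query(pts[[0]], k=2)
    assert d[0, 1] == 0.0  # duplicate point, not self
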