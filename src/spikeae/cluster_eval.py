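"""K-Means clustering and the six validation metrics, from their formulas.

External metrics (need ground truth): Rand index and its chance-adjusted
form (ARI), adjusted mutual information (AMI, exact permutation-model
expected MI), and V-Measure. Internal metrics (feature geometry + labels):
Davies-Bouldin, Calinski-Harabasz, Silhouette. On synthetic data the
internal metrics are evaluated with the ground-truth labels (they then
measure the feature extraction, not the clusterer); on unlabeled data they
use the K-Means labels.

All six are implemented directly from their defining formulas; scikit-learn's
versions are used only as independent cross-checks in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import rankdata, ttest_rel

from .models import FeatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringResult",
    "MetricReport",
    "kmeans_labels",
    "rand_index",
    "adjusted_rand_index",
    "adjusted_mutual_information",
    "v_measure",
    "davies_bouldin",
    "calinski_harabasz",
    "silhouette",
    "metric_report",
    "borda_aggregate",
    "paired_tests",
    "METRIC_DIRECTIONS",
]

#: higher-is-better flags; Davies-Bouldin is the one inverted metric
METRIC_DIRECTIONS = {
    "ari": "higher-better",
    "ami": "higher-better",
    "vm": "higher-better",
    "dbs": "lower-better",
    "chs": "higher-better",
    "ss": "higher-better",
}


@dataclass
class ClusteringResult:
    labels: np.ndarray
    k: int
    features: FeatureSet
    seed: int
    inertia: float


@dataclass
class MetricReport:
    ari: float
    ami: float
    vm: float
    dbs: float
    chs: float
    ss: float
    which_labels_internal: str = "predicted"

    def as_dict(self) -> dict:
        return {
            "ari": self.ari,
            "ami": self.ami,
            "vm": self.vm,
            "dbs": self.dbs,
            "chs": self.chs,
            "ss": self.ss,
        }


def kmeans_labels(features, k: int, seed: int = 0) -> ClusteringResult:
    """Euclidean K-Means with k-means++ seeding, deterministic per seed."""
    from sklearn.cluster import KMeans

    X = features.features if isinstance(features, FeatureSet) else np.asarray(features)
    if X.size == 0:
        raise ValueError("empty feature set")
    if k > X.shape[0]:
        raise ValueError("k cannot exceed the number of points")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    if isinstance(features, FeatureSet):
        fs = features
    else:
        fs = FeatureSet(X, method_tag="raw")
    return ClusteringResult(
        labels=labels, k=k, features=fs, seed=seed, inertia=float(km.inertia_)
    )


# ---------------------------------------------------------------------------
# External metrics
# ---------------------------------------------------------------------------

def _check_pair(true_labels, pred_labels):
    t = np.asarray(true_labels).ravel()
    p = np.asarray(pred_labels).ravel()
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    if t.size < 2:
        raise ValueError("need at least two points")
    return t, p


def _contingency(t: np.ndarray, p: np.ndarray) -> np.ndarray:
    _, ti = np.unique(t, return_inverse=True)
    _, pi = np.unique(p, return_inverse=True)
    C = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
    np.add.at(C, (ti, pi), 1)
    return C


def _comb2(x):
    x = np.asarray(x, dtype=float)
    return x * (x - 1) / 2.0


def rand_index(true_labels, pred_labels) -> float:
    """Fraction of point pairs on which the two labelings agree."""
    t, p = _check_pair(true_labels, pred_labels)
    C = _contingency(t, p)
    n = t.size
    total = _comb2(n)
    same_both = _comb2(C).sum()
    same_true = _comb2(C.sum(axis=1)).sum()
    same_pred = _comb2(C.sum(axis=0)).sum()
    agreements = same_both + (total - same_true - same_pred + same_both)
    return float(agreements / total)


def adjusted_rand_index(true_labels, pred_labels) -> float:
    """Chance-adjusted Rand index via the contingency-table formula.

    Degenerate case (both labelings trivially identical partitions, where the
    adjustment's denominator vanishes) is defined as 1.
    """
    t, p = _check_pair(true_labels, pred_labels)
    C = _contingency(t, p)
    n = t.size
    index = _comb2(C).sum()
    sum_a = _comb2(C.sum(axis=1)).sum()
    sum_b = _comb2(C.sum(axis=0)).sum()
    expected = sum_a * sum_b / _comb2(n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((index - expected) / (max_index - expected))


def _entropy(counts: np.ndarray) -> float:
    counts = counts[counts > 0].astype(float)
    n = counts.sum()
    p = counts / n
    return float(-(p * np.log(p)).sum())


def _mutual_information(C: np.ndarray) -> float:
    n = C.sum()
    a = C.sum(axis=1, keepdims=True)
    b = C.sum(axis=0, keepdims=True)
    nz = C > 0
    cij = C[nz].astype(float)
    outer = (a @ b)[nz].astype(float)
    return float((cij / n * (np.log(cij * n) - np.log(outer))).sum())


def _expected_mutual_information(a: np.ndarray, b: np.ndarray, n: int) -> float:
    """Exact E[MI] under the permutation model (hypergeometric sum)."""
    a = a.astype(np.int64)
    b = b.astype(np.int64)
    emi = 0.0
    log_n = np.log(n)
    gln_n = gammaln(n + 1)
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1)
            term_mi = nij / n * (np.log(nij) + log_n - np.log(ai) - np.log(bj))
            log_w = (
                gammaln(ai + 1)
                + gammaln(bj + 1)
                + gammaln(n - ai + 1)
                + gammaln(n - bj + 1)
                - gln_n
                - gammaln(nij + 1)
                - gammaln(ai - nij + 1)
                - gammaln(bj - nij + 1)
                - gammaln(n - ai - bj + nij + 1)
            )
            emi += float(np.sum(term_mi * np.exp(log_w)))
    return emi


def adjusted_mutual_information(true_labels, pred_labels) -> float:
    """AMI = (MI - E[MI]) / (mean(H(U), H(V)) - E[MI]).

    Both labelings constant (zero entropy on both sides) is defined as 1;
    a one-cluster prediction against a non-trivial truth gives 0.
    """
    t, p = _check_pair(true_labels, pred_labels)
    C = _contingency(t, p)
    a = C.sum(axis=1)
    b = C.sum(axis=0)
    h_u, h_v = _entropy(a), _entropy(b)
    if h_u == 0.0 and h_v == 0.0:
        return 1.0
    mi = _mutual_information(C)
    emi = _expected_mutual_information(a, b, t.size)
    denom = 0.5 * (h_u + h_v) - emi
    # keep the denominator away from zero with the sign preserved
    eps = np.finfo(float).eps
    denom = min(denom, -eps) if denom < 0 else max(denom, eps)
    return float((mi - emi) / denom)


def v_measure(true_labels, pred_labels, beta: float = 1.0):
    """(homogeneity, completeness, V) from conditional entropies."""
    t, p = _check_pair(true_labels, pred_labels)
    C = _contingency(t, p)
    n = t.size
    h_c = _entropy(C.sum(axis=1))
    h_k = _entropy(C.sum(axis=0))
    mi = _mutual_information(C)
    h_c_given_k = max(h_c - mi, 0.0)
    h_k_given_c = max(h_k - mi, 0.0)
    hom = 1.0 if h_c == 0 else 1.0 - h_c_given_k / h_c
    com = 1.0 if h_k == 0 else 1.0 - h_k_given_c / h_k
    if hom + com == 0:
        v = 0.0
    else:
        v = (1 + beta) * hom * com / (beta * hom + com)
    return float(hom), float(com), float(v)


# ---------------------------------------------------------------------------
# Internal metrics
# ---------------------------------------------------------------------------

def _features_labels(features, labels):
    X = features.features if isinstance(features, FeatureSet) else np.asarray(
        features, dtype=float
    )
    if X.ndim == 1:
        X = X[:, None]
    lab = np.asarray(labels).ravel()
    if X.shape[0] != lab.size:
        raise ValueError("features and labels must have equal length")
    return X, lab


def davies_bouldin(features, labels) -> float:
    """Mean over clusters of the worst (s_i + s_j) / d_ij similarity."""
    X, lab = _features_labels(features, labels)
    uniq = np.unique(lab)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    cents = np.array([X[lab == u].mean(axis=0) for u in uniq])
    s = np.array(
        [np.mean(np.linalg.norm(X[lab == u] - cents[i], axis=1)) for i, u in enumerate(uniq)]
    )
    k = len(uniq)
    worst = np.zeros(k)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            d = np.linalg.norm(cents[i] - cents[j])
            if d == 0:
                raise ZeroDivisionError("coincident centroids: DBS undefined")
            worst[i] = max(worst[i], (s[i] + s[j]) / d)
    return float(worst.mean())


def calinski_harabasz(features, labels) -> float:
    """tr(B_k)/tr(W_k) * (n-k)/(k-1)."""
    X, lab = _features_labels(features, labels)
    uniq = np.unique(lab)
    n, k = X.shape[0], len(uniq)
    if not 2 <= k < n:
        raise ValueError("need 2 <= k < n")
    mean = X.mean(axis=0)
    tr_b = tr_w = 0.0
    for u in uniq:
        Xu = X[lab == u]
        cu = Xu.mean(axis=0)
        tr_b += Xu.shape[0] * float(np.sum((cu - mean) ** 2))
        tr_w += float(np.sum((Xu - cu) ** 2))
    if tr_w == 0:
        raise ZeroDivisionError("zero within-cluster dispersion: CHS infinite")
    return float(tr_b / tr_w * (n - k) / (k - 1))


def silhouette(features, labels) -> float:
    """Mean over points of (b - a) / max(a, b).

    a: mean distance to the other points of the point's own cluster;
    b: mean distance to the points of the nearest other cluster. Points in
    singleton clusters score 0 (the intra-cluster mean is undefined there).
    """
    X, lab = _features_labels(features, labels)
    uniq = np.unique(lab)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    n = X.shape[0]
    from scipy.spatial.distance import cdist

    D = cdist(X, X)
    scores = np.zeros(n)
    masks = {u: lab == u for u in uniq}
    sizes = {u: int(masks[u].sum()) for u in uniq}
    for i in range(n):
        own = lab[i]
        if sizes[own] == 1:
            scores[i] = 0.0
            continue
        a = D[i, masks[own]].sum() / (sizes[own] - 1)
        b = min(D[i, masks[u]].mean() for u in uniq if u != own)
        scores[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(scores.mean())


def metric_report(
    features,
    pred_labels,
    true_labels=None,
    internal_labels: str | None = None,
) -> MetricReport:
    """All six metrics for one clustering.

    External metrics need ``true_labels`` (NaN otherwise). Internal metrics
    use the ground truth when it is available (``internal_labels='ground-truth'``,
    the synthetic-data protocol) and the predicted labels otherwise.
    """
    if internal_labels is None:
        internal_labels = "ground-truth" if true_labels is not None else "predicted"
    if internal_labels == "ground-truth":
        if true_labels is None:
            raise ValueError("ground-truth internal labels requested but none given")
        int_labels = true_labels
    else:
        int_labels = pred_labels

    if true_labels is not None:
        ari = adjusted_rand_index(true_labels, pred_labels)
        ami = adjusted_mutual_information(true_labels, pred_labels)
        vm = v_measure(true_labels, pred_labels)[2]
    else:
        ari = ami = vm = float("nan")
    try:
        dbs = davies_bouldin(features, int_labels)
        chs = calinski_harabasz(features, int_labels)
        ss = silhouette(features, int_labels)
    except (ValueError, ZeroDivisionError) as exc:
        logger.warning("internal metrics degenerate: %s", exc)
        dbs = chs = ss = float("nan")
    return MetricReport(
        ari=ari,
        ami=ami,
        vm=vm,
        dbs=dbs,
        chs=chs,
        ss=ss,
        which_labels_internal=internal_labels,
    )


# ---------------------------------------------------------------------------
# Rank aggregation and paired comparisons
# ---------------------------------------------------------------------------

def borda_aggregate(scores: pd.DataFrame, directions: dict | None = None) -> pd.DataFrame:
    """Borda rank aggregation of a methods x metrics score table.

    Per metric, methods are ranked (ties share averaged ranks) and converted
    to Borda points (m - rank); points are summed across metrics and the
    final ranking sorts by total points.
    """
    if scores.isna().any().any():
        raise ValueError("score table has missing cells")
    directions = directions or METRIC_DIRECTIONS
    m = len(scores.index)
    points = pd.DataFrame(index=scores.index, dtype=float)
    for col in scores.columns:
        direction = directions.get(col, "higher-better")
        vals = scores[col].to_numpy(dtype=float)
        ranks = rankdata(vals if direction == "lower-better" else -vals, method="average")
        points[col] = m - ranks
    out = pd.DataFrame(
        {"borda_points": points.sum(axis=1)}, index=scores.index
    )
    out["rank"] = rankdata(-out["borda_points"].to_numpy(), method="average")
    return out.sort_values("rank")


def paired_tests(scores_a, scores_b, n_comparisons: int = 1) -> dict:
    """Paired t-test with a Bonferroni correction (p multiplied, capped at 1)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length paired vectors of length >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        logger.warning("paired_tests: zero-variance difference vector")
        return {"t": float("nan"), "p_raw": float("nan"), "p_adjusted": float("nan"),
                "degenerate": True}
    t, p = ttest_rel(a, b)
    return {
        "t": float(t),
        "p_raw": float(p),
        "p_adjusted": float(min(1.0, p * n_comparisons)),
        "degenerate": False,
    }
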