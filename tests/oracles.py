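"""Direct-definition oracles for the internal cluster-validity metrics.

Deliberately written as plain per-point/per-cluster loops over Euclidean
norms, independent of the package implementation and of any library
shortcut, so they serve as precision references in tests.
"""

import numpy as np


def dbs_loop(X, lab):
    X = np.asarray(X, dtype=float)
    lab = np.asarray(lab)
    uniq = list(np.unique(lab))
    cents = [X[lab == u].mean(axis=0) for u in uniq]
    s = []
    for u, c in zip(uniq, cents):
        pts = X[lab == u]
        s.append(np.mean([np.linalg.norm(p - c) for p in pts]))
    total = 0.0
    for i in range(len(uniq)):
        worst = 0.0
        for j in range(len(uniq)):
            if i == j:
                continue
            d = np.linalg.norm(cents[i] - cents[j])
            worst = max(worst, (s[i] + s[j]) / d)
        total += worst
    return total / len(uniq)


def chs_loop(X, lab):
    X = np.asarray(X, dtype=float)
    lab = np.asarray(lab)
    uniq = list(np.unique(lab))
    n, k = len(X), len(uniq)
    g = X.mean(axis=0)
    tr_b = tr_w = 0.0
    for u in uniq:
        pts = X[lab == u]
        c = pts.mean(axis=0)
        tr_b += len(pts) * np.linalg.norm(c - g) ** 2
        for p in pts:
            tr_w += np.linalg.norm(p - c) ** 2
    return tr_b / tr_w * (n - k) / (k - 1)


def silhouette_loop(X, lab):
    X = np.asarray(X, dtype=float)
    lab = np.asarray(lab)
    uniq = list(np.unique(lab))
    scores = []
    for i in range(len(X)):
        own = lab[i]
        own_pts = [j for j in range(len(X)) if lab[j] == own and j != i]
        if not own_pts:
            scores.append(0.0)
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in own_pts])
        b = min(
            np.mean([np.linalg.norm(X[i] - X[j]) for j in range(len(X)) if lab[j] == u])
            for u in uniq
            if u != own
        )
        scores.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(scores))
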