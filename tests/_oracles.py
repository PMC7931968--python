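"""Independent reference implementations used only as test oracles.

These are deliberately written as plain loops, separate from the library's
vectorized code paths, so agreement is a meaningful check.
"""

from __future__ import annotations

import math

import numpy as np


def nsc_fields(X: np.ndarray, labels: list[str], delta: float, classes=("DDI", "NONDDI")):
    """Direct loop evaluation of every shrunken-centroid model field.

    X is genes x samples; labels one of ``classes`` per sample. Uses the
    m_k = sqrt(1/n_k + 1/n) normalizer and proportional priors.
    """
    J, n = X.shape
    idx = {k: [i for i, l in enumerate(labels) if l == k] for k in classes}
    n_k = {k: len(v) for k, v in idx.items()}
    class_cent = {k: [sum(X[j, i] for i in idx[k]) / n_k[k] for j in range(J)] for k in classes}
    overall = [sum(X[j, i] for i in range(n)) / n for j in range(J)]
    pooled = []
    for j in range(J):
        ss = 0.0
        for k in classes:
            for i in idx[k]:
                ss += (X[j, i] - class_cent[k][j]) ** 2
        pooled.append(math.sqrt(ss / (n - len(classes))))
    s0 = float(np.median(pooled))
    m_k = {k: math.sqrt(1.0 / n_k[k] + 1.0 / n) for k in classes}
    d = {k: [(class_cent[k][j] - overall[j]) / (m_k[k] * (pooled[j] + s0)) for j in range(J)]
         for k in classes}
    d_shrunk = {
        k: [math.copysign(max(abs(v) - delta, 0.0), v) for v in d[k]] for k in classes
    }
    priors = {k: n_k[k] / n for k in classes}
    return {
        "class_centroids": class_cent,
        "overall_centroid": overall,
        "pooled_sd": pooled,
        "s0": s0,
        "m_k": m_k,
        "d": d,
        "d_shrunk": d_shrunk,
        "priors": priors,
    }


def average_linkage_cophenetic(D: np.ndarray) -> np.ndarray:
    """Cophenetic distance matrix from a naive O(n^3) average-linkage loop.

    Merges the pair of clusters with the smallest unweighted average of
    original point-pair distances until one cluster remains.
    """
    n = D.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                tot = 0.0
                for i in clusters[a]:
                    for j in clusters[b]:
                        tot += D[i, j]
                avg = tot / (len(clusters[a]) * len(clusters[b]))
                if best is None or avg < best[0]:
                    best = (avg, a, b)
        h, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = h
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return coph


def pc1_projection(ref: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float]:
    """PC1 scores of reference rows and the projection of x, via an
    eigendecomposition of the sample covariance (independent of sklearn).

    ref is samples x genes; x a gene vector. Sign is arbitrary.
    """
    mu = ref.mean(axis=0)
    C = (ref - mu).T @ (ref - mu) / (ref.shape[0] - 1)
    w, V = np.linalg.eigh(C)
    v1 = V[:, np.argmax(w)]
    return (ref - mu) @ v1, float((x - mu) @ v1)


def hill_bmd(a: float, b: float, k: float, n: float, bmr: float) -> float:
    """Analytic inversion of |f(d) - a| = bmr * a for the Hill curve."""
    target = bmr * abs(a) / abs(b)
    if target >= 1:
        raise ValueError("benchmark response never reached")
    return k * (target / (1 - target)) ** (1.0 / n)


def overall_rule(pa: str, c2dc: str, pca: str) -> str:
    """The combination rule restated on text symbols."""
    calls = (pa, c2dc, pca)
    if "+" in calls:
        return "+"
    if all(c == "-" for c in calls):
        return "-"
    return "+/-"
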