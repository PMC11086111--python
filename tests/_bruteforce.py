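"""Naive reference implementations used as independent oracles.

Deliberately simple (explicit loops, textbook formulas) and independent of
the library code paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def naive_silhouette(points, labels) -> float:
    """Textbook silhouette: mean over points of (b - a)/max(a, b), with
    singleton clusters scoring 0."""
    points = np.asarray(points, dtype=float)
    labels = list(labels)
    n = len(labels)
    scores = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = np.mean([np.linalg.norm(points[i] - points[j]) for j in own])
        b = math.inf
        for other in set(labels) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == other]
            b = min(b, np.mean([np.linalg.norm(points[i] - points[j]) for j in members]))
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def naive_agglomerative(points, linkage: str, n_clusters: int):
    """Greedy agglomeration by exhaustive pair search.

    Returns (labels, merge_heights).  Linkage distances: complete = max
    pairwise, average = mean pairwise, ward = increase in total
    within-cluster sum of squares (scipy convention: sqrt of 2x increase).
    Ties broken by the lowest (i, j) pair index.
    """
    points = np.asarray(points, dtype=float)
    clusters = [[i] for i in range(len(points))]
    heights = []

    def dist(ca, cb):
        pair = [np.linalg.norm(points[i] - points[j]) for i in ca for j in cb]
        if linkage == "complete":
            return max(pair)
        if linkage == "average":
            return float(np.mean(pair))
        if linkage == "ward":
            merged = points[ca + cb]
            ess = lambda idx: np.sum((points[idx] - points[idx].mean(0)) ** 2)
            inc = ess(ca + cb) - ess(ca) - ess(cb)
            return math.sqrt(2.0 * inc)
        raise ValueError(linkage)

    while len(clusters) > n_clusters:
        best = None
        for (ia, ca), (ib, cb) in itertools.combinations(enumerate(clusters), 2):
            d = dist(ca, cb)
            key = (d, ia, ib)
            if best is None or key < best[0]:
                best = (key, ia, ib)
        (d, _, _), ia, ib = best
        heights.append(d)
        clusters[ia] = clusters[ia] + clusters[ib]
        del clusters[ib]
    labels = np.empty(len(points), dtype=int)
    for k, members in enumerate(clusters):
        labels[members] = k
    return labels, heights


def naive_icc_3k(matrix) -> float:
    """ICC(3,k) from the two-way ANOVA computed with explicit loops."""
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    grand = m.sum() / (n * k)
    ss_subj = 0.0
    for i in range(n):
        ss_subj += k * (m[i].mean() - grand) ** 2
    ms_subj = ss_subj / (n - 1)
    ss_err = 0.0
    for i in range(n):
        for j in range(k):
            resid = m[i, j] - m[i].mean() - m[:, j].mean() + grand
            ss_err += resid**2
    ms_err = ss_err / ((n - 1) * (k - 1))
    return (ms_subj - ms_err) / ms_subj


def partitions_equal(a, b) -> bool:
    """Same partition up to label permutation."""
    a, b = list(a), list(b)
    return {frozenset(i for i, x in enumerate(a) if x == v) for v in set(a)} == {
        frozenset(i for i, x in enumerate(b) if x == v) for v in set(b)
    }
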