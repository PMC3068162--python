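"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops over definitions, deliberately
sharing no code path with the package, so tests compare two independent
routes to the same quantity.
"""

from __future__ import annotations

import math

import numpy as np


def go_vector_bruteforce(query, homology, annotations, index) -> np.ndarray:
    """Tally (representative, term) pairs one by one; divide by set size."""
    reps = homology.representatives(query)
    values = np.zeros(len(index.ids))
    if not reps:
        return values
    for i, go_id in enumerate(index.ids):
        hits = 0
        for rep in reps:
            if go_id in annotations.terms(rep):
                hits += 1
        values[i] = hits / len(reps)
    return values


def product_matrix_bruteforce(m: np.ndarray, length_normalize: bool) -> np.ndarray:
    L, _ = m.shape
    out = np.zeros((20, 20))
    for r in range(20):
        for c in range(20):
            out[r, c] = sum(m[i, r] * m[i, c] for i in range(L))
    return out / L if length_normalize else out


def euclidean_bruteforce(u, v) -> float:
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(u, v)))


def knn_bruteforce(X, query, K, exclude_idx=None):
    """Full enumeration: sort (distance, index) pairs, stable on index."""
    pairs = [
        (euclidean_bruteforce(X[i], query), i)
        for i in range(len(X))
        if i != exclude_idx
    ]
    pairs.sort(key=lambda p: (p[0], p[1]))
    return pairs[:K]


def al_scores_bruteforce(labels, neighbor_indices, C) -> np.ndarray:
    """Layer-by-layer accumulation: layer k counts carriers among k nearest."""
    K = len(neighbor_indices)
    scores = np.zeros(C)
    for k in range(1, K + 1):
        for j in range(k):
            for site in labels[neighbor_indices[j]]:
                scores[site - 1] += 1
    return scores


def jackknife_bruteforce(dataset, K):
    """Naive leave-one-out re-loop: re-encode and re-rank from scratch.

    Returns (per-site correct/total dict, overall locative, absolute-true).
    """
    accs = dataset.accessions
    truths = {a: dataset.truths.labels(a) for a in accs}
    C = dataset.C

    def encode(acc, drop_self):
        reps = [r for r in dataset.homology.representatives(acc)
                if not (drop_self and r == acc)]
        vec = np.zeros(len(dataset.go_index.ids))
        if not reps:
            return vec
        for i, go_id in enumerate(dataset.go_index.ids):
            vec[i] = sum(
                1 for rep in reps if go_id in dataset.annotations.terms(rep)
            ) / len(reps)
        return vec

    train_vectors = {a: encode(a, drop_self=False) for a in accs}
    correct = {u: 0 for u in range(1, C + 1)}
    total = {u: 0 for u in range(1, C + 1)}
    exact = 0
    for acc in accs:
        q = encode(acc, drop_self=True)
        pool = [a for a in accs if a != acc]
        pairs = [(euclidean_bruteforce(train_vectors[a], q), i, a)
                 for i, a in enumerate(pool)]
        pairs.sort(key=lambda p: (p[0], p[1]))
        neighbors = pairs[:K]
        m = len(truths[neighbors[0][2]])
        scores = np.zeros(C)
        for rank, (_, _, a) in enumerate(neighbors):
            for site in truths[a]:
                scores[site - 1] += K - rank
        nearest_carrier = {u: math.inf for u in range(1, C + 1)}
        for d, _, a in neighbors:
            for site in truths[a]:
                nearest_carrier[site] = min(nearest_carrier[site], d)
        cands = [u for u in range(1, C + 1) if scores[u - 1] > 0]
        cands.sort(key=lambda u: (-scores[u - 1], nearest_carrier[u], u))
        predicted = frozenset(cands[:m])
        for u in truths[acc]:
            total[u] += 1
            if u in predicted:
                correct[u] += 1
        if predicted == truths[acc]:
            exact += 1
    overall = sum(correct.values()) / sum(total.values())
    return correct, total, overall, exact / len(accs)
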