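"""Multi-label accumulation-layer K-nearest-neighbor classification.

Prediction is a two-step scheme over a training set of multi-labelled
feature vectors:

1. the number of predicted sites m is inherited from the single nearest
   neighbor (a protein whose closest relative lives at two sites is itself
   predicted to live at two);
2. the concrete sites are the m highest accumulation-layer (AL) scores.
   Layer k counts, for each site, how many of the k nearest neighbors carry
   that site; summing the K nested layers gives neighbor at rank j a weight
   of K - j + 1 for each of its sites, so the scheme degrades gracefully to
   a majority vote while favouring nearer neighbors.

The query and the training set must live in the same feature space (GO or
SeqEvo): a naught GO vector triggers the SeqEvo fallback, and a query with
neither representation yields an abstention, never a mixed-space distance.

All ties (neighbor ranking, site selection) break deterministically:
neighbor ties by training order, site ties by nearest carrying neighbor then
by smaller site code.  A tie means bitwise-equal distance — no tolerance —
so repeated runs are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .sites import DEFAULT_C

__all__ = [
    "TrainingSet",
    "Neighbor",
    "Prediction",
    "euclidean_distance",
    "k_nearest",
    "al_scores",
    "neighbor_weights",
    "predict_label_count",
    "select_sites",
    "predict",
]

Space = Literal["GO", "SeqEvo"]


@dataclass(frozen=True)
class Neighbor:
    """One entry of a neighbor list: training index and distance to the query."""

    index: int
    distance: float


@dataclass
class TrainingSet:
    """Parallel accessions, feature matrix and label sets in one feature space."""

    space: Space
    accessions: list[str]
    X: np.ndarray
    labels: list[frozenset[int]]
    C: int = DEFAULT_C

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n = len(self.accessions)
        if n < 1:
            raise ValueError("training set must contain at least one protein")
        if self.X.ndim != 2 or self.X.shape[0] != n or len(self.labels) != n:
            raise ValueError("accessions, X and labels must have equal length")
        if len(set(self.accessions)) != n:
            raise ValueError("duplicate accessions in training set")
        for acc, lab in zip(self.accessions, self.labels):
            if not lab or not all(1 <= c <= self.C for c in lab):
                raise ValueError(f"invalid label set for {acc!r}")

    def __len__(self) -> int:
        return len(self.accessions)

    @property
    def dim(self) -> int:
        return self.X.shape[1]


def euclidean_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Euclidean norm of u - v; zero means 100% similarity."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    return float(np.linalg.norm(u - v))


def k_nearest(
    model: TrainingSet,
    query: np.ndarray,
    K: int,
    exclude: str | None = None,
) -> list[Neighbor]:
    """The K training items nearest to `query`, ascending by distance.

    Ties break by training order (stable).  `exclude` removes at most one
    item by accession — the jackknife hold-out.
    """
    query = np.asarray(query, dtype=float)
    if query.shape != (model.dim,):
        raise ValueError(f"query dimension {query.shape} != model dimension {model.dim}")
    if K < 1:
        raise ValueError("K must be positive")
    distances = np.linalg.norm(model.X - query, axis=1)
    eligible = np.arange(len(model))
    if exclude is not None:
        keep = [i for i in eligible if model.accessions[i] != exclude]
        eligible = np.asarray(keep, dtype=int)
    if K > len(eligible):
        raise ValueError(f"K={K} exceeds eligible pool of {len(eligible)}")
    d = distances[eligible]
    order = np.argsort(d, kind="stable")[:K]
    return [Neighbor(int(eligible[i]), float(d[i])) for i in order]


def neighbor_weights(K: int) -> np.ndarray:
    """AL weight of the neighbor at rank j = 1..K: it appears in layers j..K.

    Isolated so alternative layer-weighting rules can be swapped in one place.
    """
    return np.arange(K, 0, -1, dtype=float)


def al_scores(model: TrainingSet, neighbors: Sequence[Neighbor]) -> np.ndarray:
    """Accumulation-layer score per site from a ranked neighbor list.

    score_u = sum over layers k = 1..K of the number of site-u carriers among
    the k nearest neighbors; equivalently the rank-j neighbor contributes
    weight K - j + 1 to each of its sites.
    """
    if not neighbors:
        raise ValueError("neighbor list must be non-empty")
    weights = neighbor_weights(len(neighbors))
    scores = np.zeros(model.C, dtype=float)
    for w, nb in zip(weights, neighbors):
        for site in model.labels[nb.index]:
            scores[site - 1] += w
    return scores


def predict_label_count(model: TrainingSet, neighbors: Sequence[Neighbor]) -> int:
    """Predicted label cardinality m: that of the single nearest neighbor."""
    if not neighbors:
        raise ValueError("neighbor list must be non-empty")
    return len(model.labels[neighbors[0].index])


def select_sites(
    scores: np.ndarray,
    m: int,
    neighbors: Sequence[Neighbor],
    model: TrainingSet,
) -> frozenset[int]:
    """The m sites with highest AL scores.

    Ties break by (a) smallest distance of any neighbor carrying the site,
    then (b) smaller site code.  Only positive-score sites are eligible: if
    fewer than m exist the result is truncated (cannot happen when m comes
    from the nearest neighbor, whose own sites all score positively).
    """
    if m < 1 or m > model.C:
        raise ValueError(f"m={m} outside 1..{model.C}")
    nearest_carrier = np.full(model.C, np.inf)
    for nb in neighbors:
        for site in model.labels[nb.index]:
            if nb.distance < nearest_carrier[site - 1]:
                nearest_carrier[site - 1] = nb.distance
    candidates = [c for c in range(1, model.C + 1) if scores[c - 1] > 0]
    candidates.sort(key=lambda c: (-scores[c - 1], nearest_carrier[c - 1], c))
    return frozenset(candidates[:m])


@dataclass(frozen=True)
class Prediction:
    """Outcome of one query: predicted sites, inherited m, scores, space used."""

    accession: str
    labels: frozenset[int]
    m: int
    scores: np.ndarray
    space: Space | None
    status: Literal["ok", "abstained", "truncated"]


def _predict_in_space(
    model: TrainingSet,
    accession: str,
    query: np.ndarray,
    K: int,
    exclude: str | None,
) -> Prediction:
    neighbors = k_nearest(model, query, K, exclude=exclude)
    scores = al_scores(model, neighbors)
    m = predict_label_count(model, neighbors)
    labels = select_sites(scores, m, neighbors, model)
    status = "ok" if len(labels) == m else "truncated"
    # the nearest neighbor's own m sites always have positive score
    assert status == "ok", "nearest neighbor's sites must all score positively"
    return Prediction(accession, labels, m, scores, model.space, status)


def predict(
    go_model: TrainingSet,
    seqevo_model: TrainingSet | None,
    accession: str,
    q_go: np.ndarray | None,
    q_seqevo: np.ndarray | None,
    K: int,
    exclude: str | None = None,
) -> Prediction:
    """Predict a query's sites, preferring GO space, falling back to SeqEvo.

    A non-naught GO vector is classified against `go_model` regardless of
    SeqEvo availability; a naught (or missing) GO vector falls back to the
    SeqEvo space when a PSSM descriptor exists; otherwise the prediction
    abstains.  Spaces are never mixed within one distance computation.
    """
    C = go_model.C if go_model is not None else (seqevo_model.C if seqevo_model else DEFAULT_C)
    if go_model is not None and q_go is not None and np.any(q_go):
        return _predict_in_space(go_model, accession, q_go, K, exclude)
    if seqevo_model is not None and q_seqevo is not None:
        return _predict_in_space(seqevo_model, accession, q_seqevo, K, exclude)
    return Prediction(accession, frozenset(), 0, np.zeros(C), None, "abstained")
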