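"""GO hit-frequency encoding of proteins.

A fixed universe of GO terms is compressed onto consecutive integers 1..G
(ascending numeric GO id).  A protein is then represented by the fraction of
its homology-set members annotated with each compressed term: a real-valued
vector in [0, 1]^G rather than a 0/1 incidence vector, so that multiple
independent homologs hitting the same term strengthen its weight.

When a protein has no homologs, or none of its homologs carries an
annotation inside the term universe, the encoding degenerates to the all-zero
"naught" vector — the signal for the sequence-evolution fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io import AnnotationTable, HomologyTable, ValidationError, _validate_go_id

__all__ = ["GOIndex", "build_go_index", "encode_go", "is_naught"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GOIndex:
    """Bijection between a fixed GO term universe and compressed integers 1..G."""

    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValidationError("GO index must contain at least one term")
        object.__setattr__(
            self, "_to_int", {gid: i + 1 for i, gid in enumerate(self.ids)}
        )

    @property
    def G(self) -> int:
        return len(self.ids)

    def compress(self, go_id: str) -> int | None:
        """Compressed number in 1..G, or None for a term outside the universe."""
        return self._to_int.get(go_id)

    def decompress(self, number: int) -> str:
        return self.ids[number - 1]

    def __contains__(self, go_id: str) -> bool:
        return go_id in self._to_int

    def __len__(self) -> int:
        return len(self.ids)


def build_go_index(go_ids: Iterable[str]) -> GOIndex:
    """Compress a GO term universe onto 1..G.

    Duplicates are removed; the remaining identifiers are sorted ascending by
    numeric part and assigned consecutive compressed numbers starting at 1.
    """
    unique = {_validate_go_id(g, "GO index input") for g in go_ids}
    if not unique:
        raise ValidationError("cannot build a GO index from an empty term list")
    ordered = sorted(unique, key=lambda g: int(g.split(":")[1]))
    return GOIndex(tuple(ordered))


def encode_go(
    query: str,
    homology: HomologyTable,
    annotations: AnnotationTable,
    index: GOIndex,
) -> np.ndarray:
    """Encode `query` as its homology-set GO hit-frequency vector.

    For compressed term i the value is (number of representatives annotated
    with term i) / N, where N is the homology-set size; each representative
    counts at most once per term.  Degenerate inputs (no homologs, or no
    annotation mapping into the index) yield the naught vector, never an
    exception.
    """
    vec = np.zeros(index.G, dtype=float)
    reps = homology.representatives(query)
    if not reps:
        return vec
    for rep in reps:
        for term in annotations.terms(rep):
            k = index.compress(term)
            if k is None:
                logger.debug("term %s of representative %s outside index", term, rep)
                continue
            vec[k - 1] += 1.0
    vec /= len(reps)
    return vec


def is_naught(vector: np.ndarray) -> bool:
    """True iff the GO vector carries no information (all-zero support)."""
    return not np.any(vector)
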