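"""Sequence-evolution (SeqEvo) features from a position-specific scoring matrix.

The L x 20 PSSM is standardized column-wise (per amino-acid type, statistics
over the L positions, population standard deviation), then collapsed into the
20 x 20 transpose-product matrix, which compares the evolution-score profiles
of residue-type pairs on a common scale.  Being symmetric, the product matrix
is fully described by its 20 diagonal plus 190 lower-triangular entries,
serialized row-major into a fixed 210-dimensional descriptor that is
independent of sequence length and of the order of positions.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "N_FEATURES",
    "standardize_pssm",
    "product_matrix",
    "seqevo_features",
]

#: 20 diagonal + 190 strictly-lower-triangular entries of a 20 x 20 symmetric matrix
N_FEATURES = 210


def _check_pssm(pssm: np.ndarray) -> np.ndarray:
    pssm = np.asarray(pssm, dtype=float)
    if pssm.ndim != 2 or pssm.shape[1] != 20:
        raise ValueError(f"PSSM must be L x 20, got shape {pssm.shape}")
    if not np.all(np.isfinite(pssm)):
        raise ValueError("PSSM contains non-finite entries")
    return pssm


def standardize_pssm(pssm: np.ndarray) -> np.ndarray:
    """Column-standardize a PSSM: zero mean, unit population std per column.

    Columns with zero variance (constant score along the sequence) are mapped
    to all-zero columns rather than raising, so low-complexity profiles pass
    through the pipeline.  Requires L >= 2.
    """
    pssm = _check_pssm(pssm)
    if pssm.shape[0] < 2:
        raise ValueError("PSSM must have at least 2 positions to standardize")
    mean = pssm.mean(axis=0)
    std = pssm.std(axis=0)  # population (divisor L) by design
    centered = pssm - mean
    out = np.zeros_like(centered)
    nz = std > 0
    out[:, nz] = centered[:, nz] / std[nz]
    return out


def product_matrix(standardized: np.ndarray, length_normalize: bool = True) -> np.ndarray:
    """The 20 x 20 transpose-product of a standardized PSSM.

    Symmetric and positive semidefinite by construction.  With
    `length_normalize` (default) the product is divided by L so that proteins
    of different lengths are comparable under Euclidean distance; each entry
    is then the correlation-like inner product of two residue-type columns.
    """
    m = np.asarray(standardized, dtype=float)
    prod = m.T @ m
    if length_normalize:
        prod = prod / m.shape[0]
    return prod


def seqevo_features(pssm: np.ndarray, length_normalize: bool = True) -> np.ndarray:
    """The 210-dimensional SeqEvo descriptor of a PSSM.

    Standardizes, forms the transpose-product matrix, and serializes its
    diagonal and lower triangle row-major: (1,1), (2,1), (2,2), (3,1), ...,
    (20,20).  Invariant to any permutation of the sequence positions.
    """
    prod = product_matrix(standardize_pssm(pssm), length_normalize=length_normalize)
    rows, cols = np.tril_indices(20)
    features = prod[rows, cols]
    assert features.shape == (N_FEATURES,)
    return features
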