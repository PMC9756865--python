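"""Certainty-matrix postprocessing: symmetrization, pair calling, accuracy.

The network's output rows are softmax distributions, so the L x L
base-pairing certainty matrix M is row-stochastic but generally
asymmetric: M(i,j) is the probability that i picks j, not that j picks i.
Since the two events are dependent, the symmetric score takes the
elementwise minimum, S(i,j) = S(j,i) = min(M(i,j), M(j,i)), with no
rescaling.  Pair calling uses best bidirectional hits (BBH): (i, j) is
called iff j is the argmax of row i and i is the argmax of row j.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _check_square(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {M.shape}")
    return M


def symmetrize(M: np.ndarray) -> np.ndarray:
    """Elementwise minimum of M and its transpose (idempotent, no rescaling)."""
    M = _check_square(M)
    return np.minimum(M, M.T)


def _row_argmax(M: np.ndarray) -> np.ndarray:
    # np.argmax already breaks ties by lowest index.
    return np.argmax(M, axis=1)


def best_bidirectional_hits(
    M: np.ndarray, ignore_diagonal: bool = True, min_score: float = 0.0
) -> set[tuple[int, int]]:
    """Pairs (i, j), i < j, that are each other's highest-certainty partner.

    The diagonal is excluded by default (a base cannot pair with itself).
    Ties break toward the lowest index.  ``min_score`` additionally
    requires min(M(i,j), M(j,i)) to reach the given value — the magnitude
    of the symmetric score carries information on whether the positions
    are paired at all, so thresholding suppresses spurious mutual hits
    between unpaired positions.
    """
    M = _check_square(M)
    if ignore_diagonal:
        M = M.copy()
        np.fill_diagonal(M, -np.inf)
    best = _row_argmax(M)
    return {(i, int(best[i])) for i in range(len(best))
            if best[best[i]] == i and i < best[i]
            and min(M[i, best[i]], M[best[i], i]) >= min_score}


def top_k_accuracy(M: np.ndarray, true_pairs: set[tuple[int, int]], k: int = 1) -> float:
    """Fraction of queries whose true partner is among its row's top k.

    Every paired position is a query (each pair counted in both
    directions).  Ranking ties break toward the lowest index.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    M = _check_square(M)
    queries = [(i, j) for (i, j) in true_pairs] + [(j, i) for (i, j) in true_pairs]
    if not queries:
        raise ValueError("no paired positions to score")
    hits = 0
    order = np.argsort(-M, axis=1, kind="stable")
    for q, partner in queries:
        if partner in order[q, :k]:
            hits += 1
    return hits / len(queries)


def reciprocity_stats(
    M: np.ndarray, true_pairs: set[tuple[int, int]]
) -> tuple[float, float]:
    """Reciprocity of predictions, split by correctness.

    A prediction i -> j (j the argmax of row i) is *reciprocal* when the
    argmax of row j is i.  Returns the reciprocal fraction among correct
    predictions and among erroneous ones; an empty group yields NaN.
    """
    M = _check_square(M)
    if not true_pairs:
        raise ValueError("empty pair set")
    partner = {}
    for i, j in true_pairs:
        partner[i] = j
        partner[j] = i
    best = _row_argmax(M)
    correct_recip, correct_n, error_recip, error_n = 0, 0, 0, 0
    for q, true_j in partner.items():
        pred = int(best[q])
        reciprocal = int(best[pred]) == q
        if pred == true_j:
            correct_n += 1
            correct_recip += reciprocal
        else:
            error_n += 1
            error_recip += reciprocal
    return (
        correct_recip / correct_n if correct_n else float("nan"),
        error_recip / error_n if error_n else float("nan"),
    )


def save_matrix_tsv(M: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(M)).to_csv(path, sep="\t", header=False, index=False)


def load_matrix_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
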