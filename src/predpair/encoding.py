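"""Question/answer sample encoding.

A training sample is a one-hot encoded sequence of shape (L, 5): columns
0-3 carry the nucleotide identity (A, C, G, U), column 4 carries the query
mark — 2 at the marked position and 1 everywhere else.  The target is the
partner position, trained as a categorical distribution over the L
positions.  Every base pair (i, j) yields two samples: query i with target
j, and query j with target i.  Unpaired positions are never used as
training queries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structures import SecondaryStructure

NUCLEOTIDES = "ACGU"
_NUC_INDEX = {c: k for k, c in enumerate(NUCLEOTIDES)}


def encode_sequence(sequence: str) -> np.ndarray:
    """One-hot encode a sequence as (L, 4); non-ACGU letters become all-zero."""
    sequence = sequence.upper().replace("T", "U")
    out = np.zeros((len(sequence), 4), dtype=np.float32)
    for k, ch in enumerate(sequence):
        idx = _NUC_INDEX.get(ch)
        if idx is not None:
            out[k, idx] = 1.0
    return out


def decode_sequence(channels: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence`; all-zero rows decode to ``N``."""
    out = []
    for row in np.asarray(channels)[:, :4]:
        out.append(NUCLEOTIDES[int(np.argmax(row))] if row.any() else "N")
    return "".join(out)


def encode_question(structure: SecondaryStructure | str, query: int) -> np.ndarray:
    """Build the (L, 5) question sample for ``query``.

    Column 4 holds 2 at the query position and 1 elsewhere.
    """
    sequence = structure if isinstance(structure, str) else structure.sequence
    L = len(sequence)
    if not 0 <= query < L:
        raise IndexError(f"query {query} outside sequence of length {L}")
    sample = np.ones((L, 5), dtype=np.float32)
    sample[:, :4] = encode_sequence(sequence)
    sample[query, 4] = 2.0
    return sample


@dataclass
class SampleBatch:
    """All question/answer samples of one sequence.

    Attributes
    ----------
    sequence_id : str
    questions : (n, L, 5) float array
    targets : (n,) int array of partner positions
    queries : (n,) int array of query positions
    """

    sequence_id: str
    questions: np.ndarray
    targets: np.ndarray
    queries: np.ndarray

    def __len__(self) -> int:
        return len(self.targets)

    @property
    def length(self) -> int:
        return self.questions.shape[1]

    def one_hot_targets(self) -> np.ndarray:
        """Targets as (n, L) one-hot rows (each sums to 1)."""
        n, L = self.questions.shape[:2]
        out = np.zeros((n, L), dtype=np.float32)
        out[np.arange(n), self.targets] = 1.0
        return out


def make_samples(structure: SecondaryStructure) -> SampleBatch:
    """Emit the question batch of a structure: two samples per base pair.

    Only canonical/wobble pairs are used; a structure without usable pairs
    yields an empty batch with a warning.
    """
    pairs = sorted(structure.canonical_pairs())
    L = len(structure)
    if not pairs:
        warnings.warn(f"{structure.id}: no canonical pairs, empty sample batch")
        return SampleBatch(
            structure.id,
            np.zeros((0, L, 5), dtype=np.float32),
            np.zeros(0, dtype=np.int64),
            np.zeros(0, dtype=np.int64),
        )
    base = np.ones((L, 5), dtype=np.float32)
    base[:, :4] = encode_sequence(structure.sequence)
    queries: list[int] = []
    targets: list[int] = []
    for i, j in pairs:
        queries.extend((i, j))
        targets.extend((j, i))
    n = len(queries)
    questions = np.repeat(base[None, :, :], n, axis=0)
    questions[np.arange(n), np.asarray(queries), 4] = 2.0
    return SampleBatch(
        structure.id,
        questions,
        np.asarray(targets, dtype=np.int64),
        np.asarray(queries, dtype=np.int64),
    )


def save_batch(batch: SampleBatch, path) -> None:
    """Serialize one sample batch as a compressed array container."""
    np.savez_compressed(
        path,
        sequence_id=np.asarray(batch.sequence_id),
        questions=batch.questions,
        targets=batch.targets,
        queries=batch.queries,
    )


def load_batch(path) -> SampleBatch:
    with np.load(path) as data:
        return SampleBatch(
            str(data["sequence_id"]),
            data["questions"],
            data["targets"],
            data["queries"],
        )
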