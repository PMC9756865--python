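"""RNA secondary structures: types, WUSS/dot-bracket parsing, consensus projection.

Coordinates are 0-based half-open throughout the package; CT files (1-based)
are converted at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Canonical Watson-Crick plus GU wobble pairs (ordered 5'->3' tuples).
CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

GAP_CHARS = frozenset("-.~")
UNPAIRED_CHARS = frozenset(".,:_-~")

_OPEN_TO_CLOSE = {"(": ")", "<": ">", "[": "]", "{": "}"}
_CLOSE_TO_OPEN = {v: k for k, v in _OPEN_TO_CLOSE.items()}

#: Bracket layers used when writing dot-bracket strings with crossing pairs.
BRACKET_LAYERS = ["()", "<>", "[]", "{}"] + [
    chr(ord("A") + i) + chr(ord("a") + i) for i in range(26)
]


class WussParseError(ValueError):
    """Raised for unbalanced or unrecognised structure notation."""


def is_canonical(a: str, b: str) -> bool:
    """True if nucleotides ``a`` and ``b`` form a Watson-Crick or wobble pair."""
    return (a, b) in CANONICAL_PAIRS


@dataclass
class SecondaryStructure:
    """An RNA sequence together with its set of base pairs.

    Parameters
    ----------
    id : str
        Sequence identifier.
    sequence : str
        RNA string; ``T`` is normalised to ``U`` and case is upper-cased.
        Degenerate IUPAC letters are tolerated (they encode as all-zero
        nucleotide channels downstream).
    pairs : set of (int, int)
        0-based index pairs with ``i < j``.  Pseudoknots (crossing pairs)
        are allowed; base triples are not.
    """

    id: str
    sequence: str
    pairs: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("T", "U")
        self.pairs = {(min(i, j), max(i, j)) for (i, j) in self.pairs}
        L = len(self.sequence)
        seen: set[int] = set()
        for i, j in self.pairs:
            if i == j:
                raise ValueError(f"{self.id}: self-pair at position {i}")
            if not (0 <= i < L and 0 <= j < L):
                raise ValueError(f"{self.id}: pair ({i},{j}) outside [0,{L})")
            for k in (i, j):
                if k in seen:
                    raise ValueError(f"{self.id}: base triple at position {k}")
                seen.add(k)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def paired_positions(self) -> set[int]:
        return {k for ij in self.pairs for k in ij}

    def partner(self) -> dict[int, int]:
        """Map every paired position to its partner."""
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def canonical_pairs(self) -> set[tuple[int, int]]:
        """The subset of pairs that are canonical/wobble in this sequence."""
        s = self.sequence
        return {(i, j) for (i, j) in self.pairs if is_canonical(s[i], s[j])}

    def filter_canonical(self) -> "SecondaryStructure":
        """Return a copy keeping only canonical/wobble pairs."""
        return SecondaryStructure(self.id, self.sequence, self.canonical_pairs())


def parse_wuss(notation: str) -> set[tuple[int, int]]:
    """Parse a WUSS/dot-bracket string into a set of 0-based pairs.

    Each bracket type — ``()``, ``<>``, ``[]``, ``{}`` and the letter pairs
    ``Aa`` … ``Zz`` used for pseudoknots — is matched independently by stack
    discipline, so crossing (pseudoknotted) pairs are returned as-is.
    Unpaired annotation characters are ``. , : _ - ~``.

    Raises
    ------
    WussParseError
        On an unmatched symbol, naming its position and type.
    """
    stacks: dict[str, list[int]] = {}
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(notation):
        if ch in UNPAIRED_CHARS:
            continue
        if ch in _OPEN_TO_CLOSE:
            stacks.setdefault(ch, []).append(pos)
        elif ch in _CLOSE_TO_OPEN:
            opener = _CLOSE_TO_OPEN[ch]
            stack = stacks.get(opener, [])
            if not stack:
                raise WussParseError(
                    f"unmatched closing '{ch}' at position {pos}"
                )
            pairs.add((stack.pop(), pos))
        elif ch.isalpha():
            if ch.isupper():
                stacks.setdefault(ch, []).append(pos)
            else:
                opener = ch.upper()
                stack = stacks.get(opener, [])
                if not stack:
                    raise WussParseError(
                        f"unmatched pseudoknot closer '{ch}' at position {pos}"
                    )
                pairs.add((stack.pop(), pos))
        else:
            raise WussParseError(f"unrecognised symbol '{ch}' at position {pos}")
    for sym, stack in stacks.items():
        if stack:
            raise WussParseError(
                f"unmatched opening '{sym}' at position {stack[-1]}"
            )
    return pairs


def pairs_to_dotbracket(length: int, pairs: set[tuple[int, int]]) -> str:
    """Render pairs as dot-bracket, using extra bracket layers for crossings.

    Pairs are assigned greedily (sorted by opening position) to the first
    layer in which they do not cross any pair already placed there.
    """
    layers: list[list[tuple[int, int]]] = []
    assignment: dict[tuple[int, int], int] = {}
    for pair in sorted(pairs):
        placed = False
        for li, layer in enumerate(layers):
            if not any(_crosses(pair, other) for other in layer):
                layer.append(pair)
                assignment[pair] = li
                placed = True
                break
        if not placed:
            if len(layers) >= len(BRACKET_LAYERS):
                raise ValueError("too many crossing pair layers to render")
            layers.append([pair])
            assignment[pair] = len(layers) - 1
    out = ["."] * length
    for (i, j), li in assignment.items():
        open_ch, close_ch = BRACKET_LAYERS[li][0], BRACKET_LAYERS[li][1]
        out[i] = open_ch
        out[j] = close_ch
    return "".join(out)


def _crosses(a: tuple[int, int], b: tuple[int, int]) -> bool:
    (i, j), (k, l) = a, b
    return (i < k < j < l) or (k < i < l < j)


def project_consensus(
    seq_id: str, aligned_seq: str, consensus: str, canonical_only: bool = True
) -> SecondaryStructure:
    """Project an alignment consensus structure onto one aligned sequence.

    Pairs whose two columns both hold non-gap characters are remapped to
    ungapped coordinates; pairs touching a gap are dropped, as are (with
    ``canonical_only``) pairs that are not canonical/wobble in this
    particular sequence.
    """
    if len(aligned_seq) != len(consensus):
        raise ValueError(
            f"{seq_id}: aligned sequence length {len(aligned_seq)} != "
            f"consensus length {len(consensus)}"
        )
    aligned_seq = aligned_seq.upper().replace("T", "U")
    col_to_pos: dict[int, int] = {}
    ungapped: list[str] = []
    for col, ch in enumerate(aligned_seq):
        if ch not in GAP_CHARS:
            col_to_pos[col] = len(ungapped)
            ungapped.append(ch)
    seq = "".join(ungapped)
    pairs: set[tuple[int, int]] = set()
    for ci, cj in parse_wuss(consensus):
        if ci in col_to_pos and cj in col_to_pos:
            i, j = col_to_pos[ci], col_to_pos[cj]
            if not canonical_only or is_canonical(seq[i], seq[j]):
                pairs.add((i, j))
    return SecondaryStructure(seq_id, seq, pairs)


@dataclass
class FamilyRecord:
    """An RNA family: a set of member structures sharing one consensus.

    ``annotated_pair_count`` optionally records the pair count before
    canonical/wobble filtering; the family-level paired fraction is taken
    over the annotated structure when available, so the 20 % filter sees
    the structure as annotated, not as it survives canonical filtering.
    """

    family_id: str
    members: list[SecondaryStructure]
    annotated_pair_count: int | None = None

    @property
    def paired_fraction(self) -> float:
        """Fraction of nucleotides involved in annotated pairs, over all members."""
        total = sum(len(m) for m in self.members)
        if total == 0:
            return 0.0
        n_pairs = (
            self.annotated_pair_count
            if self.annotated_pair_count is not None
            else sum(len(m.pairs) for m in self.members)
        )
        return 2.0 * n_pairs / total


def filter_families(
    families: list[FamilyRecord], min_paired: float = 0.20
) -> list[FamilyRecord]:
    """Drop families in which fewer than ``min_paired`` of nucleotides pair.

    The comparison is strict less-than, so a family exactly at the threshold
    is retained.
    """
    if not 0.0 <= min_paired <= 1.0:
        raise ValueError("min_paired must lie in [0, 1]")
    return [f for f in families if not f.paired_fraction < min_paired]


@dataclass
class DatasetSplit:
    """Family-level train/validation/test partition."""

    train: set[str]
    validation: set[str]
    test: set[str]

    def __post_init__(self) -> None:
        sets = [self.train, self.validation, self.test]
        for a in range(3):
            for b in range(a + 1, 3):
                if sets[a] & sets[b]:
                    raise ValueError("split sets must be disjoint")

    @property
    def all_families(self) -> set[str]:
        return self.train | self.validation | self.test


def split_by_family(
    families: list[FamilyRecord] | list[str],
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> DatasetSplit:
    """Randomly partition whole families into train/validation/test.

    Every member of a family lands in the same set, which avoids homology
    leakage between splits.  Deterministic under ``seed``.
    """
    if not math.isclose(sum(ratios), 1.0, abs_tol=1e-9):
        raise ValueError("ratios must sum to 1")
    ids = [f if isinstance(f, str) else f.family_id for f in families]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate family ids")
    if len(ids) < 3:
        raise ValueError("need at least 3 families to split")
    rng = np.random.default_rng(seed)
    order = [ids[k] for k in rng.permutation(len(ids))]
    n = len(order)
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    n_train = min(n_train, n - 2)
    n_val = min(max(n_val, 1), n - n_train - 1)
    return DatasetSplit(
        train=set(order[:n_train]),
        validation=set(order[n_train : n_train + n_val]),
        test=set(order[n_train + n_val :]),
    )
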