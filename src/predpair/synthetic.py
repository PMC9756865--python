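"""Synthetic data: planted-stretch sequences, structure-constrained random
sequences, random structure templates and accessibility profiles.

These generators emulate the three input classes the analyses need —
training sequences with known pairings, sequences compatible with a fixed
secondary structure, and DMS-seq-like per-nucleotide accessibility tables
— so the whole pipeline runs without any download.  All generators are
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import CANONICAL_PAIRS, SecondaryStructure

NUCLEOTIDES = "ACGU"
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Ordered canonical/wobble pair types, 5' base first.
PAIR_TYPES = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]


# --------------------------------------------------------------- stretch data


def _complement_run_matrix(seq: str) -> np.ndarray:
    """R[a, b] = length of the reverse-complement run ending at (a, b).

    A run of length r means seq[a-r+1 .. a] is the reverse complement of
    seq[b .. b+r-1]; runs correspond to anti-diagonal stretches of the
    complementarity matrix.
    """
    L = len(seq)
    comp = np.zeros((L, L), dtype=np.int32)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    for a, b in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
        comp |= (arr[:, None] == ord(a)) & (arr[None, :] == ord(b))
    runs = np.zeros((L, L), dtype=np.int32)
    runs[0, :] = comp[0, :]
    for a in range(1, L):
        runs[a, : L - 1] = comp[a, : L - 1] * (runs[a - 1, 1:] + 1)
        runs[a, L - 1] = comp[a, L - 1]
    return runs


def gen_stretch_sequences(
    n: int,
    length: int = 50,
    stretch_len: int = 7,
    seed: int = 0,
    min_loop: int = 3,
    max_attempts: int = 200,
) -> list[SecondaryStructure]:
    """Random sequences each carrying one planted complementary stretch.

    A random Watson-Crick reverse-complementary stretch of ``stretch_len``
    nucleotides is planted at two non-overlapping locations; position
    ``i + k`` pairs with ``j + stretch_len - 1 - k``.  Sequences with an
    accidental complementary run longer than ``stretch_len - 2`` elsewhere
    (or extending the planted stem) are rejected and redrawn, so the
    planted answer stays unambiguous.
    """
    if 2 * stretch_len > length:
        raise ValueError(
            f"cannot plant two {stretch_len}-nt stretches in length {length}"
        )
    min_loop = min(min_loop, length - 2 * stretch_len)
    rng = np.random.default_rng(seed)
    out: list[SecondaryStructure] = []
    for idx in range(n):
        for attempt in range(max_attempts):
            i = int(rng.integers(0, length - 2 * stretch_len - min_loop + 1))
            j = int(rng.integers(i + stretch_len + min_loop, length - stretch_len + 1))
            seq = list(rng.choice(list(NUCLEOTIDES), size=length))
            stretch = [str(c) for c in rng.choice(list(NUCLEOTIDES), size=stretch_len)]
            seq[i : i + stretch_len] = stretch
            seq[j : j + stretch_len] = [
                _COMPLEMENT[c] for c in reversed(stretch)
            ]
            s = "".join(seq)
            if _stretch_is_unique(s, i, j, stretch_len):
                pairs = {
                    (i + k, j + stretch_len - 1 - k) for k in range(stretch_len)
                }
                out.append(SecondaryStructure(f"stretch_{idx}", s, pairs))
                break
        else:
            raise RuntimeError(
                f"could not plant an unambiguous stretch after {max_attempts} draws"
            )
    return out


def _stretch_is_unique(seq: str, i: int, j: int, sl: int) -> bool:
    runs = _complement_run_matrix(seq)
    # the planted stem occupies the anti-diagonal ending at (i+sl-1, j)
    planted = np.zeros_like(runs, dtype=bool)
    for k in range(sl):
        planted[i + k, j + sl - 1 - k] = True
        planted[j + sl - 1 - k, i + k] = True
    if runs[i + sl - 1, j] != sl:
        return False  # planted stem extends into its flanks
    allowed = sl - 2
    other = np.where(planted, 0, runs)
    # cells continuing the planted run inherit its length; mask them too
    for k in range(1, allowed + 1):
        if i + sl - 1 + k < len(seq) and j - k >= 0:
            other[i + sl - 1 + k, j - k] = 0
            other[j - k, i + sl - 1 + k] = 0
    return int(other.max()) <= allowed


# ------------------------------------------------------------ frequency tables


@dataclass
class FrequencyTables:
    """Empirical nucleotide, pair-type and stacked-doublet frequencies."""

    nucleotide: dict[str, float]
    pair: dict[tuple[str, str], float]
    doublet: dict[tuple[tuple[str, str], tuple[str, str]], float] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for name, table in (("nucleotide", self.nucleotide), ("pair", self.pair)):
            total = sum(table.values())
            if table and not np.isclose(total, 1.0):
                raise ValueError(f"{name} table sums to {total}, expected 1")


def estimate_frequency_tables(structures: list[SecondaryStructure]) -> FrequencyTables:
    """Empirical tables from sequences and their annotated pairs."""
    if not structures:
        raise ValueError("empty structure set")
    nuc_counts = {c: 0 for c in NUCLEOTIDES}
    pair_counts: dict[tuple[str, str], int] = {}
    doublet_counts: dict[tuple[tuple[str, str], tuple[str, str]], int] = {}
    n_pairs = 0
    for s in structures:
        for ch in s.sequence:
            if ch in nuc_counts:
                nuc_counts[ch] += 1
        pairs = s.pairs
        for i, j in pairs:
            t = (s.sequence[i], s.sequence[j])
            pair_counts[t] = pair_counts.get(t, 0) + 1
            n_pairs += 1
            if (i + 1, j - 1) in pairs:
                t2 = (s.sequence[i + 1], s.sequence[j - 1])
                doublet_counts[(t, t2)] = doublet_counts.get((t, t2), 0) + 1
    if n_pairs == 0:
        raise ValueError("no annotated pairs; pair tables undefined")
    n_nuc = sum(nuc_counts.values())
    n_dbl = sum(doublet_counts.values())
    return FrequencyTables(
        nucleotide={c: v / n_nuc for c, v in nuc_counts.items()},
        pair={t: v / n_pairs for t, v in pair_counts.items()},
        doublet={t: v / n_dbl for t, v in doublet_counts.items()} if n_dbl else {},
    )


def uniform_frequency_tables() -> FrequencyTables:
    """Uniform tables over nucleotides, canonical pair types and doublets."""
    doublets = [(a, b) for a in PAIR_TYPES for b in PAIR_TYPES]
    return FrequencyTables(
        nucleotide={c: 0.25 for c in NUCLEOTIDES},
        pair={t: 1.0 / len(PAIR_TYPES) for t in PAIR_TYPES},
        doublet={d: 1.0 / len(doublets) for d in doublets},
    )


# ------------------------------------------------- structure-constrained seqs


def gen_random_templates(
    n_templates: int = 12,
    length: int = 140,
    seed: int = 0,
    allow_pseudoknots: bool = False,
) -> list[SecondaryStructure]:
    """Random secondary-structure templates (helices over an N backbone).

    Helices of 3-8 pairs are planted greedily at nested positions until
    ~40-55 % of positions pair; with ``allow_pseudoknots`` an extra
    crossing helix may be added.  Templates stand in for structures a
    curated database would provide.
    """
    rng = np.random.default_rng(seed)
    out = []
    for t in range(n_templates):
        pairs: set[tuple[int, int]] = set()
        used = np.zeros(length, dtype=bool)
        target = rng.uniform(0.40, 0.55) * length
        for _ in range(200):
            if 2 * len(pairs) >= target:
                break
            stem = int(rng.integers(3, 9))
            i = int(rng.integers(0, length - 2 * stem - 3))
            j = int(rng.integers(i + 2 * stem + 3, length))
            cand = {(i + k, j - k) for k in range(stem)}
            flat = {p for ij in cand for p in ij}
            if any(used[list(flat)]):
                continue
            # keep nesting unless pseudoknots are allowed
            crossing = any(
                (a < c < b < d) or (c < a < d < b)
                for a, b in cand for c, d in pairs
            )
            if crossing and not allow_pseudoknots:
                continue
            pairs |= cand
            used[list(flat)] = True
        out.append(SecondaryStructure(f"template_{t}", "N" * length, pairs))
    return out


def _helix_runs(pairs: set[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group pairs into stacked helix runs, 5' to 3' on the opening strand."""
    pairs = set(pairs)
    runs = []
    starts = sorted(p for p in pairs if (p[0] - 1, p[1] + 1) not in pairs)
    for start in starts:
        run = [start]
        i, j = start
        while (i + 1, j - 1) in pairs:
            i, j = i + 1, j - 1
            run.append((i, j))
        runs.append(run)
    return runs


def gen_structured_sequences(
    template: SecondaryStructure,
    n: int,
    tables: FrequencyTables | None = None,
    seed: int = 0,
) -> list[SecondaryStructure]:
    """Random sequences that can fold into ``template``'s structure.

    Unpaired positions draw from the nucleotide table.  Paired positions
    are drawn helix by helix: the first pair of each stacked run from the
    pair-type table, each subsequent pair from the doublet table
    conditioned on the previous pair (falling back to the pair table when
    the conditional mass is empty).  Every emitted sequence is therefore
    canonical/wobble-compatible with the template by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    tables = tables or uniform_frequency_tables()
    if not tables.pair:
        raise ValueError("empty pair table")
    rng = np.random.default_rng(seed)
    L = len(template)
    runs = _helix_runs(template.pairs)
    paired = template.paired_positions
    unpaired = [k for k in range(L) if k not in paired]

    nucs = list(tables.nucleotide)
    nuc_p = np.array([tables.nucleotide[c] for c in nucs])
    nuc_p = nuc_p / nuc_p.sum()
    pair_types = list(tables.pair)
    pair_p = np.array([tables.pair[t] for t in pair_types])
    pair_p = pair_p / pair_p.sum()

    cond: dict[tuple[str, str], tuple[list, np.ndarray]] = {}
    for prev in pair_types:
        weights = np.array(
            [tables.doublet.get((prev, nxt), 0.0) for nxt in pair_types]
        )
        if weights.sum() > 0:
            cond[prev] = (pair_types, weights / weights.sum())

    out = []
    for m in range(n):
        seq = [""] * L
        draws = rng.choice(nucs, size=len(unpaired), p=nuc_p)
        for ui, ch in zip(unpaired, draws):
            seq[ui] = str(ch)
        for run in runs:
            prev = None
            for i, j in run:
                if prev is not None and prev in cond:
                    types, p = cond[prev]
                else:
                    types, p = pair_types, pair_p
                t = types[int(rng.choice(len(types), p=p))]
                seq[i], seq[j] = t
                prev = t
        out.append(
            SecondaryStructure(f"{template.id}_seq{m}", "".join(seq), set(template.pairs))
        )
    return out


# ------------------------------------------------------- accessibility tables


def gen_accessibility_profiles(
    structures: list[SecondaryStructure],
    paired_mean: float = 0.2,
    unpaired_mean: float = 1.0,
    noise_sd: float = 0.25,
    coverage_range: tuple[int, int] = (20, 120),
    seed: int = 0,
) -> pd.DataFrame:
    """DMS-seq-like per-nucleotide accessibility with pairedness signal.

    Paired positions draw accessibility around ``paired_mean`` and
    unpaired positions around ``unpaired_mean`` (Gaussian noise, clipped
    at 0); per-position read coverage is uniform over ``coverage_range``.
    Columns: sequence_id, position, base, accessibility, coverage.
    """
    if not unpaired_mean > paired_mean or paired_mean < 0:
        raise ValueError("need unpaired_mean > paired_mean >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for s in structures:
        paired = s.paired_positions
        for pos in range(len(s)):
            mean = paired_mean if pos in paired else unpaired_mean
            val = max(0.0, float(rng.normal(mean, noise_sd)))
            cov = int(rng.integers(coverage_range[0], coverage_range[1] + 1))
            rows.append(
                {
                    "sequence_id": s.id,
                    "position": pos,
                    "base": s.sequence[pos],
                    "accessibility": val,
                    "coverage": cov,
                }
            )
    return pd.DataFrame(rows)
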