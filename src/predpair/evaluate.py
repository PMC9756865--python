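"""Scoring against reference structures and accessibility data.

Structure scoring thresholds a symmetric score matrix: pairs at or above
the threshold are predicted, compared with the reference pair set as
unordered pairs, giving Tp/Fp/Fn, precision = Tp/(Tp+Fp), recall =
Tp/(Tp+Fn), a precision-recall curve over evenly spaced thresholds, and
per-sequence F1.  Accessibility scoring ranks positions per gene from
least to most accessible, cuts them into ten equal-count deciles, and
counts predicted-paired positions per decile; two decile histograms are
compared with a two-sided Mann-Whitney test on the underlying decile
indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")


def _upper_pairs(pairs) -> set[tuple[int, int]]:
    return {(min(i, j), max(i, j)) for i, j in pairs}


def predicted_pairs_at(S: np.ndarray, threshold: float) -> set[tuple[int, int]]:
    """Unordered off-diagonal pairs with score >= threshold."""
    S = np.asarray(S)
    ii, jj = np.where(np.triu(S, k=1) >= threshold)
    return set(zip(ii.tolist(), jj.tolist()))


def confusion_at_threshold(
    S: np.ndarray, reference_pairs, threshold: float
) -> ConfusionCounts:
    """Tp/Fp/Fn of the thresholded prediction; each unordered pair once."""
    ref = _upper_pairs(reference_pairs)
    pred = predicted_pairs_at(S, threshold)
    tp = len(pred & ref)
    return ConfusionCounts(tp=tp, fp=len(pred) - tp, fn=len(ref) - tp)


def pr_curve(
    S: np.ndarray, reference_pairs, n_thresholds: int = 200
) -> pd.DataFrame:
    """Precision-recall curve over evenly spaced thresholds on [0, max(S)].

    Points with undefined precision (no predictions) are dropped, so the
    curve has at most ``n_thresholds`` rows.
    """
    if n_thresholds < 2:
        raise ValueError("n_thresholds must be >= 2")
    ref = _upper_pairs(reference_pairs)
    if not ref:
        raise ValueError("empty reference pair set")
    S = np.asarray(S)
    rows = []
    for thr in np.linspace(0.0, float(S.max()), n_thresholds):
        c = confusion_at_threshold(S, ref, thr)
        if c.tp + c.fp == 0:
            continue
        rows.append({"threshold": thr, "precision": c.precision, "recall": c.recall})
    return pd.DataFrame(rows)


def f1_per_sequence(S: np.ndarray, reference_pairs, threshold: float) -> float:
    """F1 of one sequence's thresholded prediction; 0 when Tp is 0."""
    c = confusion_at_threshold(S, reference_pairs, threshold)
    if c.tp == 0:
        return 0.0
    p, r = c.precision, c.recall
    return 2 * p * r / (p + r)


# ----------------------------------------------------------------- CDS filter


def read_gff3_cds(path) -> pd.DataFrame:
    """Light GFF3/BED-lite reader: feature, strand and coordinates only."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["seqid", "source", "feature", "start", "end", "score",
               "strand", "frame", "attributes"],
    )
    df["length"] = df["end"] - df["start"] + 1
    return df


def filter_cds(records: pd.DataFrame, min_coverage: float = 15.0) -> pd.DataFrame:
    """Keep plus-strand CDS records of length divisible by three with
    mean read coverage strictly above ``min_coverage``.

    ``records`` needs columns feature, strand, length and coverage (the
    per-gene mean; a per-position table can be aggregated first).
    """
    required = {"feature", "strand", "length", "coverage"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing fields: {sorted(missing)}")
    keep = (
        (records["feature"] == "CDS")
        & (records["strand"] == "+")
        & (records["length"] % 3 == 0)
        & (records["coverage"] > min_coverage)
    )
    return records[keep].reset_index(drop=True)


# ---------------------------------------------------------------- decile map


def decile_map(
    accessibility: pd.DataFrame,
    predicted_positions: dict[str, set[int]],
    n_bins: int = 10,
    ac_only: bool = True,
) -> np.ndarray:
    """Histogram of predicted-paired positions over accessibility deciles.

    Per gene, scored positions are sorted from least to most accessible
    (stable sort, position as tie-break) and cut into ``n_bins``
    equal-count bins (sizes differing by at most one); predicted positions
    are counted per bin and summed over genes.  With ``ac_only`` (the DMS
    convention) only A and C positions enter the ranking when a ``base``
    column is present.  Genes with fewer than ``n_bins`` scored positions
    are skipped with a warning.
    """
    hist = np.zeros(n_bins, dtype=int)
    for gene, sub in accessibility.groupby("sequence_id"):
        if ac_only and "base" in sub.columns:
            sub = sub[sub["base"].isin(["A", "C"])]
        sub = sub.sort_values(["accessibility", "position"], kind="stable")
        if len(sub) < n_bins:
            warnings.warn(f"{gene}: fewer than {n_bins} scored positions, skipped")
            continue
        predicted = predicted_positions.get(gene, set())
        bins = np.array_split(sub["position"].to_numpy(), n_bins)
        for b, positions in enumerate(bins):
            hist[b] += sum(1 for p in positions if p in predicted)
    return hist


def decile_samples(hist: np.ndarray) -> np.ndarray:
    """Expand a decile histogram into the underlying decile-index sample."""
    return np.repeat(np.arange(1, len(hist) + 1), hist)


def compare_decile_distributions(
    hist_a: np.ndarray, hist_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test on two decile histograms.

    The histograms are expanded back into their decile-index samples;
    returns (U, p).
    """
    a, b = decile_samples(np.asarray(hist_a)), decile_samples(np.asarray(hist_b))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty decile histogram")
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(u), float(p)


def decile_trend(hist: np.ndarray) -> tuple[float, float]:
    """Spearman correlation of decile counts against decile index.

    A negative rho means predicted-paired positions concentrate in the
    least-accessible deciles.
    """
    hist = np.asarray(hist)
    rho, p = stats.spearmanr(np.arange(1, len(hist) + 1), hist)
    return float(rho), float(p)


# ------------------------------------------------------------ matrix adapters


def import_external_matrix(
    path, dialect: str = "sparse", length: int | None = None, one_based: bool = True
) -> np.ndarray:
    """Read an externally produced base-pair score matrix.

    ``dialect='sparse'``: whitespace-separated triples ``i j score`` (as
    exported from RNAplfold-style pair probability output), 1-based by
    default; both (i, j) and (j, i) are populated and missing entries are
    zero.  ``dialect='dense'``: a full TSV matrix.
    """
    if dialect == "dense":
        M = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
        if M.shape[0] != M.shape[1]:
            raise ValueError(f"dense matrix is not square: {M.shape}")
        return M
    if dialect != "sparse":
        raise ValueError(f"unknown dialect '{dialect}'")
    triples = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ValueError(f"line {ln}: expected 'i j score', got {line!r}")
            try:
                i, j, score = int(fields[0]), int(fields[1]), float(fields[2])
            except ValueError as exc:
                raise ValueError(f"line {ln}: {exc}") from exc
            if one_based:
                i, j = i - 1, j - 1
            if i < 0 or j < 0:
                raise ValueError(f"line {ln}: negative index after conversion")
            triples.append((i, j, score))
    if length is None:
        length = 1 + max((max(i, j) for i, j, _ in triples), default=-1)
    M = np.zeros((length, length))
    for i, j, score in triples:
        M[i, j] = score
        M[j, i] = score
    return M


def export_sparse_matrix(M: np.ndarray, path, one_based: bool = True,
                         threshold: float = 0.0) -> None:
    """Write the upper triangle of a symmetric matrix as sparse triples."""
    M = np.asarray(M)
    off = 1 if one_based else 0
    with open(path, "w") as fh:
        for i, j in zip(*np.where(np.triu(M, k=1) > threshold)):
            fh.write(f"{i + off} {j + off} {M[i, j]:.6g}\n")
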