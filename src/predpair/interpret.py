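"""Interpretation: saliency maps, learned-feature statistics, embeddings.

Saliency follows the vanilla-gradient recipe — the gradient of the
cross-entropy loss for the output class with respect to the (L, 5) input,
reduced over channels — and saliency matrices are min-symmetrized like
certainty matrices.  Learned-feature statistics compare the frequencies
of called base-pair types and stacked doublets with nearest-neighbor
stacking free energies.  Embeddings average the BiLSTM activations of a
sequence's question batch into a single vector of length 2 x units (32).
"""

from __future__ import annotations

import importlib.resources
import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import encode_question, make_samples
from .nn import PredPairNetwork
from .postprocess import symmetrize
from .structures import SecondaryStructure

_REDUCTIONS = {
    "max_abs": lambda g: np.abs(g).max(axis=-1),
    "sum": lambda g: g.sum(axis=-1),
    "l2": lambda g: np.sqrt((g * g).sum(axis=-1)),
}

_COMPLEMENTS = {"A": {"U"}, "C": {"G"}, "G": {"C", "U"}, "U": {"A", "G"}}


def _require_trained(network: PredPairNetwork) -> None:
    if not network.is_trained:
        raise ValueError("saliency requires a trained network")


def saliency(
    network: PredPairNetwork,
    question: np.ndarray,
    target: int | None = None,
    reduction: str = "max_abs",
) -> np.ndarray:
    """Per-position importance of one (L, 5) question sample.

    The loss class is the true partner when ``target`` is given, else the
    network's own argmax prediction.  ``reduction`` collapses the 5 input
    channels per position: ``max_abs`` (default), ``sum`` or ``l2``.
    """
    _require_trained(network)
    question = np.asarray(question)
    if target is None:
        target = int(network.forward(question)[0].argmax())
    grad = network.input_gradient(question[None], np.asarray([target]))[0]
    return _REDUCTIONS[reduction](grad)


def saliency_matrix(
    network: PredPairNetwork,
    sequence: str | SecondaryStructure,
    structure: SecondaryStructure | None = None,
    reduction: str = "max_abs",
    chunk: int = 64,
) -> np.ndarray:
    """Symmetrized L x L importance matrix over all query positions.

    Row q is the channel-reduced input gradient for query q; the target
    class is the annotated partner where ``structure`` provides one,
    otherwise the predicted partner.  The stacked rows are min-symmetrized.
    """
    _require_trained(network)
    if isinstance(sequence, SecondaryStructure) and structure is None:
        structure = sequence
    seq = sequence.sequence if isinstance(sequence, SecondaryStructure) else sequence
    L = len(seq)
    partner = structure.partner() if structure is not None else {}
    base = encode_question(seq, 0)
    base[0, 4] = 1.0
    rows = []
    for start in range(0, L, chunk):
        stop = min(start + chunk, L)
        nb = stop - start
        xs = np.repeat(base[None], nb, axis=0)
        xs[np.arange(nb), np.arange(start, stop), 4] = 2.0
        probs = network.forward(xs)
        targets = np.array(
            [partner.get(q, int(probs[k].argmax()))
             for k, q in enumerate(range(start, stop))]
        )
        grads = network.input_gradient(xs, targets)
        rows.append(_REDUCTIONS[reduction](grads))
    return symmetrize(np.concatenate(rows, axis=0))


# ------------------------------------------------------------ pair statistics


def _unordered_class(a: str, b: str) -> str:
    return "".join(sorted((a, b)))


def pair_type_frequencies(
    sequences: Iterable[str | SecondaryStructure],
    called_pairs: Iterable[set[tuple[int, int]]],
) -> dict[str, float]:
    """Relative frequency of each unordered pair class among called pairs.

    Classes are the 10 unordered nucleotide combinations (canonical GC,
    AU, GU plus the 7 mismatch classes); frequencies sum to 1.
    """
    counts: dict[str, int] = {}
    total = 0
    for seq, pairs in zip(sequences, called_pairs):
        s = seq.sequence if isinstance(seq, SecondaryStructure) else seq
        for i, j in pairs:
            if not (0 <= i < len(s) and 0 <= j < len(s)):
                raise IndexError(f"pair ({i},{j}) outside sequence of length {len(s)}")
            cls = _unordered_class(s[i], s[j])
            counts[cls] = counts.get(cls, 0) + 1
            total += 1
    if total == 0:
        raise ValueError("empty pair set")
    return {cls: c / total for cls, c in sorted(counts.items())}


def canonical_doublet(
    pair1: tuple[str, str], pair2: tuple[str, str]
) -> tuple[tuple[str, str], tuple[str, str]]:
    """Canonical representative of a stacked doublet under strand symmetry.

    The stack of (x1-y1) under (x2-y2), read from the other strand, is
    (y2-x2) under (y1-x1); the lexicographically smaller reading is the
    class representative.
    """
    fwd = (pair1, pair2)
    rev = ((pair2[1], pair2[0]), (pair1[1], pair1[0]))
    return min(fwd, rev)


def doublet_name(doublet: tuple[tuple[str, str], tuple[str, str]]) -> str:
    (x1, y1), (x2, y2) = doublet
    return f"{x1}{x2}/{y1}{y2}"


def stacked_pair_frequencies(
    sequences: Iterable[str | SecondaryStructure],
    called_pairs: Iterable[set[tuple[int, int]]],
) -> dict[tuple[tuple[str, str], tuple[str, str]], int]:
    """Counts of stacked doublets: pairs (i,j) and (i+1,j-1) both called."""
    counts: dict[tuple[tuple[str, str], tuple[str, str]], int] = {}
    for seq, pairs in zip(sequences, called_pairs):
        s = seq.sequence if isinstance(seq, SecondaryStructure) else seq
        pairs = {(min(i, j), max(i, j)) for i, j in pairs}
        for i, j in pairs:
            if (i + 1, j - 1) in pairs:
                cls = canonical_doublet((s[i], s[j]), (s[i + 1], s[j - 1]))
                counts[cls] = counts.get(cls, 0) + 1
    return counts


def load_stacking_energies() -> dict[tuple[tuple[str, str], tuple[str, str]], float]:
    """The packaged nearest-neighbor stacking dG37 table (kcal/mol)."""
    ref = importlib.resources.files("predpair.data") / "stacking_energies.tsv"
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    table = {}
    for _, row in df.iterrows():
        top, bottom = row["doublet"].split("/")
        pair1 = (top[0], bottom[0])
        pair2 = (top[1], bottom[1])
        table[canonical_doublet(pair1, pair2)] = float(row["dG37_kcal_mol"])
    return table


def stack_energy_correlation(
    counts: dict, table: dict | None = None
) -> tuple[float, float]:
    """Spearman correlation between doublet frequencies and stacking dG37.

    Returns (rho, p).  Needs at least 3 doublet classes present in both
    the counts and the energy table; constant frequencies make the rank
    correlation undefined and raise.
    """
    if table is None:
        table = load_stacking_energies()
    common = [cls for cls in counts if cls in table]
    if len(common) < 3:
        raise ValueError(
            f"need >= 3 doublet classes with known energies, got {len(common)}"
        )
    freqs = np.array([counts[cls] for cls in common], dtype=float)
    energies = np.array([table[cls] for cls in common])
    if np.allclose(freqs, freqs[0]):
        raise ValueError("identical frequencies: rank correlation undefined")
    rho, p = stats.spearmanr(freqs, energies)
    return float(rho), float(p)


# ------------------------------------------------------------------ embeddings


def embed(network: PredPairNetwork, structure: SecondaryStructure) -> np.ndarray:
    """Length-32 embedding of one sequence.

    BiLSTM activations of the structure's question batch (n, L, 32) are
    averaged along the sequence and then over the batch.
    """
    batch = make_samples(structure)
    if len(batch) == 0:
        raise ValueError(f"{structure.id}: empty question batch, cannot embed")
    acts = network.lstm_activations(batch.questions)
    return acts.mean(axis=1).mean(axis=0)


def cluster_embeddings(
    embeddings: np.ndarray,
    labels: Iterable | None = None,
    seed: int = 0,
    perplexity: float = 30.0,
    learning_rate: float = 200.0,
    n_iter: int = 1000,
    plot_path=None,
) -> np.ndarray:
    """2-D t-SNE of embeddings (perplexity 30, lr 200, 1000 iterations).

    Returns the (n, 2) coordinates; with ``plot_path`` a labeled scatter
    is written.  Too few points for the requested perplexity triggers a
    warning and a reduced perplexity.
    """
    from sklearn.manifold import TSNE

    embeddings = np.asarray(embeddings)
    if len(embeddings) < 2:
        raise ValueError("need at least 2 embeddings")
    max_perp = (len(embeddings) - 1) / 3.0
    if perplexity > max_perp:
        warnings.warn(
            f"perplexity {perplexity} too large for {len(embeddings)} points; "
            f"reduced to {max_perp:.1f}"
        )
        perplexity = max_perp
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        learning_rate=learning_rate,
        max_iter=n_iter,
        random_state=seed,
        init="pca",
    )
    coords = tsne.fit_transform(embeddings)
    if plot_path is not None:
        _scatter_labeled(coords, labels, plot_path)
    return coords


def _scatter_labeled(coords: np.ndarray, labels, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    if labels is None:
        ax.scatter(coords[:, 0], coords[:, 1], s=12)
    else:
        labels = np.asarray(list(labels))
        for lab in pd.unique(labels):
            m = labels == lab
            ax.scatter(coords[m, 0], coords[m, 1], s=12, label=str(lab))
        if len(pd.unique(labels)) <= 20:
            ax.legend(fontsize=7, markerscale=1.5)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ------------------------------------------------------- attention inspection


def attention_inspection(
    network: PredPairNetwork,
    structures: Iterable[SecondaryStructure],
    max_samples_per_structure: int = 8,
) -> pd.DataFrame:
    """Where each attention channel puts its mass, by attended nucleotide.

    For every question sample the query row of the per-channel attention
    weights (which sum to 1 over attended positions) is split by the
    nucleotide at the attended position; a ``complementary`` column gives
    the mass on positions able to pair (canonically or by wobble) with the
    query nucleotide.  Rows are the attention channels — with the standard
    5-channel layout, channels 0-3 ride on the A/C/G/U input channels and
    channel 4 on the query mark.
    """
    if network.config.attention_channels != 5:
        raise ValueError(
            "attention inspection expects the 5-channel attention layout, "
            f"got {network.config.attention_channels} channels"
        )
    C = network.config.attention_channels
    mass = np.zeros((C, 4))
    comp_mass = np.zeros(C)
    n_samples = 0
    for s in structures:
        batch = make_samples(s)
        if len(batch) == 0:
            continue
        take = min(len(batch), max_samples_per_structure)
        xs = batch.questions[:take]
        queries = batch.queries[:take]
        weights = network.attention_weights(xs)  # (B, Lq, Lk, C)
        seq = np.array(list(s.sequence))
        for b in range(take):
            w = weights[b, queries[b]]  # (Lk, C)
            qnuc = s.sequence[queries[b]]
            for ni, nuc in enumerate("ACGU"):
                sel = seq == nuc
                mass[:, ni] += w[sel].sum(axis=0)
            comp = np.isin(seq, sorted(_COMPLEMENTS.get(qnuc, set())))
            comp_mass += w[comp].sum(axis=0)
            n_samples += 1
    if n_samples == 0:
        raise ValueError("no question samples to inspect")
    df = pd.DataFrame(
        mass / n_samples,
        index=[f"channel_{c}" for c in range(C)],
        columns=list("ACGU"),
    )
    df["complementary"] = comp_mass / n_samples
    return df
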