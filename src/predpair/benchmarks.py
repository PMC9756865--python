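"""The planted-stretch study: data conditions, training recipe, analyses.

This module pins the synthetic study conditions — 2,000 training / 200
validation / 400 held-out sequences of length 50, one planted 7-nt
complementary stretch each — and bundles the analyses run on the trained
model (top-k accuracy, reciprocity, saliency shift, accessibility decile
trend), so tests, scripts and users exercise the same pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .encoding import make_samples
from .interpret import _REDUCTIONS
from .model import PredPair, PredPairResults
from .nn import ModelConfig
from .structures import SecondaryStructure
from .synthetic import gen_accessibility_profiles, gen_stretch_sequences

#: Planted-stretch study conditions.
N_TRAIN = 2000
N_VAL = 200
N_TEST = 400
LENGTH = 50
STRETCH_LEN = 7
MAX_EPOCHS = 50


@dataclass
class StretchStudy:
    """A trained planted-stretch model plus its held-out test set."""

    results: PredPairResults
    test: list[SecondaryStructure]
    seed: int


def stretch_datasets(seed: int):
    """Train/validation/test splits of the planted-stretch task."""
    train = gen_stretch_sequences(N_TRAIN, LENGTH, STRETCH_LEN, seed=3 * seed + 1)
    val = gen_stretch_sequences(N_VAL, LENGTH, STRETCH_LEN, seed=3 * seed + 2)
    test = gen_stretch_sequences(N_TEST, LENGTH, STRETCH_LEN, seed=3 * seed + 3)
    return train, val, test


def train_stretch_model(
    seed: int = 0,
    epochs: int = MAX_EPOCHS,
    target_accuracy: float | None = 0.93,
    verbose: bool = False,
) -> StretchStudy:
    """Train the full architecture on the planted-stretch conditions.

    Training stops early once validation top-1 reaches
    ``target_accuracy`` (or on validation-loss patience), within at most
    ``epochs`` epochs.
    """
    train, val, test = stretch_datasets(seed)
    model = PredPair(train, val, ModelConfig(learning_rate=3e-3, seed=seed))
    res = model.fit(
        epochs=epochs,
        seed=seed,
        batch_size=64,
        patience=8,
        target_accuracy=target_accuracy,
        verbose=verbose,
    )
    return StretchStudy(results=res, test=test, seed=seed)


def held_out_accuracy(study: StretchStudy, k: int = 1, symmetrized: bool = False,
                      n_sequences: int | None = None) -> float:
    """Top-k accuracy over the held-out planted-stretch sequences."""
    test = study.test if n_sequences is None else study.test[:n_sequences]
    return study.results.top_k_accuracy(test, k=k, symmetrized=symmetrized)


def reciprocity_rank_test(
    study: StretchStudy, n_sequences: int = 250
) -> tuple[float, float, float]:
    """Correct- vs error-prediction reciprocity on held-out sequences.

    Returns (mean correct reciprocity, mean error reciprocity, one-sided
    Mann-Whitney p for correct > error over per-sequence fractions).
    """
    df = study.results.reciprocity(study.test[:n_sequences])
    corr = df["correct_reciprocity"].dropna().to_numpy()
    err = df["error_reciprocity"].dropna().to_numpy()
    if len(err) == 0:
        # a perfect model has no erroneous predictions at all
        return float(np.mean(corr)), float("nan"), 0.0
    _, p = stats.mannwhitneyu(corr, err, alternative="greater")
    return float(np.mean(corr)), float(np.mean(err)), float(p)


def saliency_rank_test(
    study: StretchStudy, n_sequences: int = 200, rng_seed: int = 0
) -> tuple[float, float, float]:
    """Saliency at true-pair partners vs random unpaired positions.

    For each held-out sequence the question batch's input gradients are
    reduced to per-position importances; the mean importance at the true
    partner positions is compared with the mean at matched random
    unpaired positions.  Returns (mean paired saliency, mean random
    saliency, one-sided Wilcoxon p over per-sequence differences).
    """
    net = study.results.network
    rng = np.random.default_rng(rng_seed)
    paired_means, random_means = [], []
    for s in study.test[:n_sequences]:
        batch = make_samples(s)
        grads = net.input_gradient(batch.questions, batch.targets)
        importance = _REDUCTIONS["max_abs"](grads)  # (n_questions, L)
        rows = np.arange(len(batch))
        paired_means.append(importance[rows, batch.targets].mean())
        unpaired = np.array(
            [k for k in range(len(s)) if k not in s.paired_positions]
        )
        rand_pos = rng.choice(unpaired, size=len(batch))
        random_means.append(importance[rows, rand_pos].mean())
    diffs = np.asarray(paired_means) - np.asarray(random_means)
    _, p = stats.wilcoxon(diffs, alternative="greater")
    return float(np.mean(paired_means)), float(np.mean(random_means)), float(p)


def accessibility_decile_study(seed: int = 0, n_sequences: int = 100):
    """Decile histogram of truly-paired positions on synthetic accessibility.

    Paired positions are less accessible by construction, so the
    histogram should fall from decile 1 (least accessible) to decile 10.
    Returns (histogram, spearman rho, p).
    """
    from .evaluate import decile_map, decile_trend

    structures = gen_stretch_sequences(n_sequences, LENGTH, STRETCH_LEN,
                                       seed=7 * seed + 5)
    table = gen_accessibility_profiles(structures, seed=7 * seed + 6)
    predicted = {s.id: s.paired_positions for s in structures}
    hist = decile_map(table, predicted, ac_only=False)
    rho, p = decile_trend(hist)
    return hist, rho, p
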