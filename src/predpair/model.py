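"""Model / Results interface around the network.

:class:`PredPair` holds the training data and configuration; ``fit()``
returns a :class:`PredPairResults` carrying the trained network, the
training history and the analysis methods (certainty matrices, pair
calls, saliency, embeddings, accuracy diagnostics, ``summary()``).

Training: question/answer samples built from
annotated base pairs (two per pair), categorical cross-entropy under Adam,
and early stopping on validation loss.  Samples of one sequence always
share a batch; sequences of equal length may be pooled into one batch,
which changes nothing per-sample and keeps the numpy backend efficient.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import postprocess
from .encoding import SampleBatch, encode_question, make_samples
from .nn import Adam, ModelConfig, PredPairNetwork
from .structures import SecondaryStructure


def pool_batches(
    batches: Sequence[SampleBatch], max_batch: int = 128
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group per-sequence sample batches into training arrays.

    Samples from different sequences are pooled only when their lengths
    match; pooled batches are capped at ``max_batch`` samples.
    """
    by_length: dict[int, list[SampleBatch]] = {}
    for b in batches:
        if len(b):
            by_length.setdefault(b.length, []).append(b)
    out: list[tuple[np.ndarray, np.ndarray]] = []
    for L, group in sorted(by_length.items()):
        xs = np.concatenate([b.questions for b in group], axis=0)
        ts = np.concatenate([b.targets for b in group], axis=0)
        for k in range(0, len(ts), max_batch):
            out.append((xs[k : k + max_batch], ts[k : k + max_batch]))
    return out


def _evaluate(net: PredPairNetwork, batches) -> tuple[float, float]:
    """Mean loss and top-1 accuracy over pre-built (X, targets) batches."""
    losses, hits, n = [], 0, 0
    for x, t in batches:
        probs = net.forward(x)
        losses.append(net.loss(probs, t) * len(t))
        hits += int((probs.argmax(axis=1) == t).sum())
        n += len(t)
    if n == 0:
        return float("nan"), float("nan")
    return float(np.sum(losses) / n), hits / n


class PredPair:
    """The base-pair partner prediction model.

    Parameters
    ----------
    train : iterable of SecondaryStructure
        Structures whose annotated canonical pairs supply the training
        questions and answers.
    validation : iterable of SecondaryStructure, optional
        Held-out structures used for per-epoch monitoring and early
        stopping.
    config : ModelConfig, optional
        Architecture and optimizer hyperparameters.
    """

    def __init__(
        self,
        train: Iterable[SecondaryStructure],
        validation: Iterable[SecondaryStructure] | None = None,
        config: ModelConfig | None = None,
    ) -> None:
        self.train_structures = list(train)
        self.validation_structures = list(validation) if validation else []
        self.config = config or ModelConfig()
        if not self.train_structures:
            raise ValueError("empty training set")
        self.train_batches = [make_samples(s) for s in self.train_structures]
        if sum(len(b) for b in self.train_batches) == 0:
            raise ValueError("training structures contain no canonical pairs")
        self.validation_batches = [make_samples(s) for s in self.validation_structures]

    @classmethod
    def from_stockholm(
        cls,
        path,
        min_paired: float = 0.20,
        ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
        seed: int = 0,
        config: ModelConfig | None = None,
    ) -> "PredPair":
        """Build a model from a Stockholm file with a family-wise split.

        Families below ``min_paired`` paired nucleotides are dropped; the
        remaining families are partitioned whole into train/validation/test.
        The test structures are kept on the model as ``test_structures``.
        """
        from .io import read_stockholm
        from .structures import filter_families, split_by_family

        families = filter_families(read_stockholm(path), min_paired)
        split = split_by_family(families, ratios, seed)
        members = {f.family_id: f.members for f in families}
        train = [m for fid in split.train for m in members[fid]]
        val = [m for fid in split.validation for m in members[fid]]
        model = cls(train, val, config)
        model.test_structures = [m for fid in split.test for m in members[fid]]
        model.split = split
        return model

    def fit(
        self,
        epochs: int = 50,
        seed: int | None = None,
        batch_size: int = 128,
        patience: int = 5,
        target_accuracy: float | None = None,
        lr_patience: int = 3,
        lr_factor: float = 0.5,
        min_lr: float = 1e-4,
        lr_decay_start: int | None = None,
        lr_decay_every: int = 4,
        verbose: bool = False,
        log_file=None,
    ) -> "PredPairResults":
        """Train the network and return a results object.

        Early stopping restores the parameters of the best validation-loss
        epoch (patience in epochs); ``target_accuracy`` additionally stops
        as soon as validation top-1 accuracy reaches the given level.  The
        learning rate is multiplied by ``lr_factor`` whenever the monitored
        loss has not improved for ``lr_patience`` epochs (down to
        ``min_lr``); with ``lr_decay_start`` set, a deterministic staircase
        is used instead — the rate is multiplied by ``lr_factor`` every
        ``lr_decay_every`` epochs from that epoch on.  ``epochs=0`` returns
        the freshly initialized network unchanged.
        """
        cfg = self.config
        if seed is not None:
            cfg = ModelConfig(**{**cfg.__dict__, "seed": seed})
        net = PredPairNetwork(cfg)
        optimizer = Adam(cfg.learning_rate, cfg.adam_beta1, cfg.adam_beta2,
                         cfg.adam_epsilon)
        rng = np.random.default_rng(cfg.seed)
        train_arrays = pool_batches(self.train_batches, batch_size)
        val_arrays = pool_batches(self.validation_batches, batch_size)
        history: list[dict] = []
        best_loss, best_params, best_epoch, since_best = np.inf, None, 0, 0
        log = log_file or sys.stderr

        base_lr = optimizer.lr
        for epoch in range(epochs):
            t0 = time.time()
            if lr_decay_start is not None and epoch >= lr_decay_start:
                steps = 1 + (epoch - lr_decay_start) // lr_decay_every
                optimizer.lr = max(min_lr, base_lr * lr_factor**steps)
            order = rng.permutation(len(train_arrays))
            losses, hits, n = [], 0, 0
            for bi in order:
                x, t = train_arrays[bi]
                loss = net.train_step(x, t, optimizer)
                losses.append(loss * len(t))
                hits += int((net._probs.argmax(axis=1) == t).sum())
                n += len(t)
            train_loss = float(np.sum(losses) / n)
            val_loss, val_acc = _evaluate(net, val_arrays)
            row = {
                "epoch": epoch + 1,
                "loss": train_loss,
                "accuracy": hits / n,
                "val_loss": val_loss,
                "val_accuracy": val_acc,
                "learning_rate": optimizer.lr,
                "seconds": time.time() - t0,
            }
            history.append(row)
            if verbose:
                print(
                    f"epoch {row['epoch']:3d}  loss {train_loss:.4f}  "
                    f"acc {row['accuracy']:.4f}  val_loss {val_loss:.4f}  "
                    f"val_acc {val_acc:.4f}  lr {optimizer.lr:.2g}  "
                    f"({row['seconds']:.1f}s)",
                    file=log,
                )
            monitored = val_loss if val_arrays else train_loss
            if monitored < best_loss:
                best_loss = monitored
                best_params = net.copy_parameters()
                best_epoch = epoch + 1
                since_best = 0
            else:
                since_best += 1
                if (lr_decay_start is None and lr_patience
                        and since_best % lr_patience == 0):
                    optimizer.lr = max(min_lr, optimizer.lr * lr_factor)
            target_met = (
                target_accuracy is not None
                and val_arrays
                and val_acc >= target_accuracy
            )
            if target_met or (patience and since_best >= patience):
                break

        if best_params is not None:
            net.set_parameters(best_params)
        net.is_trained = bool(history)
        return PredPairResults(
            network=net,
            model=self,
            history=pd.DataFrame(history),
            best_epoch=best_epoch,
        )


@dataclass
class PredPairResults:
    """A trained model: estimates, diagnostics and analysis methods."""

    network: PredPairNetwork
    model: PredPair | None = None
    history: pd.DataFrame = field(default_factory=pd.DataFrame)
    best_epoch: int = 0

    @property
    def config(self) -> ModelConfig:
        return self.network.config

    # ----------------------------------------------------------- predictions

    def predict_certainty(self, sequence: str | SecondaryStructure, query: int) -> np.ndarray:
        """The certainty distribution over partner positions for one query."""
        self._warn_untrained()
        x = encode_question(sequence, query)
        return self.network.forward(x)[0]

    def certainty_matrix(self, sequence: str | SecondaryStructure,
                         chunk: int = 64) -> np.ndarray:
        """Stack the certainty rows of every query position (L x L)."""
        self._warn_untrained()
        seq = sequence.sequence if isinstance(sequence, SecondaryStructure) else sequence
        L = len(seq)
        base = encode_question(seq, 0)
        base[0, 4] = 1.0
        rows = []
        for start in range(0, L, chunk):
            stop = min(start + chunk, L)
            xs = np.repeat(base[None], stop - start, axis=0)
            xs[np.arange(stop - start), np.arange(start, stop), 4] = 2.0
            rows.append(self.network.forward(xs))
        return np.concatenate(rows, axis=0)

    def symmetrized_matrix(self, sequence) -> np.ndarray:
        return postprocess.symmetrize(self.certainty_matrix(sequence))

    def best_pairs(self, sequence, symmetrized: bool = False,
                   min_score: float = 0.0) -> set[tuple[int, int]]:
        """Best-bidirectional-hit pair calls for a sequence."""
        M = self.certainty_matrix(sequence)
        if symmetrized:
            M = postprocess.symmetrize(M)
        return postprocess.best_bidirectional_hits(M, min_score=min_score)

    # ----------------------------------------------------------- diagnostics

    def top_k_accuracy(self, structures: Iterable[SecondaryStructure], k: int = 1,
                       symmetrized: bool = False) -> float:
        """Pooled top-k accuracy over all paired queries of the structures."""
        hits, n = 0, 0
        for s in structures:
            pairs = s.canonical_pairs()
            if not pairs:
                continue
            M = self.certainty_matrix(s)
            if symmetrized:
                M = postprocess.symmetrize(M)
            acc = postprocess.top_k_accuracy(M, pairs, k)
            n_q = 2 * len(pairs)
            hits += acc * n_q
            n += n_q
        if n == 0:
            raise ValueError("no paired positions to score")
        return hits / n

    def reciprocity(self, structures: Iterable[SecondaryStructure]) -> pd.DataFrame:
        """Per-sequence reciprocity of correct and erroneous predictions."""
        rows = []
        for s in structures:
            pairs = s.canonical_pairs()
            if not pairs:
                continue
            M = self.certainty_matrix(s)
            corr, err = postprocess.reciprocity_stats(M, pairs)
            rows.append({"sequence_id": s.id, "correct_reciprocity": corr,
                         "error_reciprocity": err})
        return pd.DataFrame(rows)

    # ------------------------------------------------------- interpretation

    def saliency_matrix(self, sequence) -> np.ndarray:
        from .interpret import saliency_matrix

        return saliency_matrix(self.network, sequence)

    def embedding(self, structure: SecondaryStructure) -> np.ndarray:
        from .interpret import embed

        return embed(self.network, structure)

    def attention_summary(self, structures: Iterable[SecondaryStructure]) -> pd.DataFrame:
        from .interpret import attention_inspection

        return attention_inspection(self.network, structures)

    # ---------------------------------------------------------------- report

    def summary(self) -> str:
        """Plain-text summary of the fit, statsmodels-style."""
        cfg = self.config
        lines = [
            "PredPair Results",
            "=" * 58,
            f"{'conv filters / kernel':<32}{cfg.conv_filters} / {cfg.conv_kernel}",
            f"{'attention channels':<32}{cfg.attention_channels}",
            f"{'LSTM units per direction':<32}{cfg.recurrent_units_per_direction}",
            f"{'dense sizes':<32}{cfg.dense_sizes}",
            f"{'L2 coefficient (output neuron)':<32}{cfg.l2_coefficient}",
            f"{'optimizer':<32}Adam(lr={cfg.learning_rate})",
            f"{'seed':<32}{cfg.seed}",
        ]
        if self.model is not None:
            n_train = sum(len(b) for b in self.model.train_batches)
            n_val = sum(len(b) for b in self.model.validation_batches)
            lines += [
                f"{'training sequences':<32}{len(self.model.train_structures)}",
                f"{'training samples':<32}{n_train}",
                f"{'validation samples':<32}{n_val}",
            ]
        if len(self.history):
            last = self.history.iloc[-1]
            lines += [
                f"{'epochs run':<32}{int(last['epoch'])}",
                f"{'best epoch (val loss)':<32}{self.best_epoch}",
                f"{'final train loss / accuracy':<32}"
                f"{last['loss']:.4f} / {last['accuracy']:.4f}",
            ]
            if np.isfinite(last["val_loss"]):
                lines.append(
                    f"{'final val loss / accuracy':<32}"
                    f"{last['val_loss']:.4f} / {last['val_accuracy']:.4f}"
                )
        lines.append("=" * 58)
        return "\n".join(lines)

    def save(self, path) -> None:
        self.network.save(path)
        hist_path = Path(str(path)).with_suffix(".history.tsv")
        self.history.to_csv(hist_path, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "PredPairResults":
        net = PredPairNetwork.load(path)
        hist_path = Path(str(path)).with_suffix(".history.tsv")
        history = (
            pd.read_csv(hist_path, sep="\t") if hist_path.exists() else pd.DataFrame()
        )
        return cls(network=net, history=history)

    def _warn_untrained(self) -> None:
        if not self.network.is_trained:
            import warnings

            warnings.warn("predicting with an untrained network")
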