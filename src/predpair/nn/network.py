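"""The question->answer network.

Architecture, front to back:

1. two parallel Conv1D branches (64 filters, kernel 10, 'same' padding,
   ReLU) read the (L, 5) question sample;
2. a channel-wise attention layer scores every (query, key) position pair
   per input channel from the two branch outputs and applies the weights
   to the original input, producing a 5-channel context;
3. the context is concatenated with the input (depth 10) and fed to a
   bidirectional LSTM with 16 units per direction (depth 32);
4. time-distributed dense layers of 16 and 8 units (ReLU) and a final
   single dense output neuron per position (L2-penalised kernel and bias);
5. the per-position logits are softmax-normalised over the sequence, so
   the output is a categorical distribution over partner positions.

Trained with categorical cross-entropy under Adam.  The network is fully
length-agnostic: one set of weights serves sequences of any length.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .layers import BiLSTM, ChannelAttention, Conv1D, Dense, Layer


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    Defaults: 64 conv filters of width
    10 in two branches, a 5-channel attention layer, 16 LSTM units per
    direction, dense layers of 16 and 8, and an L2 coefficient of 0.1 on
    the final output neuron's kernel and bias.
    """

    conv_filters: int = 64
    conv_kernel: int = 10
    conv_branches: int = 2
    attention_channels: int = 5
    attention_score: str = "dot"
    attention_head_dim: int = 8
    conv_activation: str = "relu"
    recurrent_units_per_direction: int = 16
    dense_sizes: tuple[int, ...] = (16, 8)
    l2_coefficient: float = 0.1
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-7
    input_channels: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conv_filters", "conv_kernel", "attention_channels",
                     "recurrent_units_per_direction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field '{name}' must be positive")
        if self.conv_branches != 2:
            raise ValueError("config field 'conv_branches' must be 2 "
                             "(query and key branches)")
        if any(s <= 0 for s in self.dense_sizes):
            raise ValueError("config field 'dense_sizes' must be positive")
        if self.l2_coefficient < 0:
            raise ValueError("config field 'l2_coefficient' must be >= 0")
        self.dense_sizes = tuple(self.dense_sizes)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        data = json.loads(text)
        data["dense_sizes"] = tuple(data["dense_sizes"])
        return cls(**data)


class PredPairNetwork:
    """Weights plus forward/backward machinery; see module docstring."""

    def __init__(self, config: ModelConfig | None = None, dtype=np.float32) -> None:
        self.config = config or ModelConfig()
        self.dtype = np.dtype(dtype).type
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        if cfg.conv_activation not in ("relu", "linear"):
            raise ValueError("config field 'conv_activation' must be "
                             "'relu' or 'linear'")
        conv_relu = cfg.conv_activation == "relu"
        self.conv_q = Conv1D(rng, cfg.input_channels, cfg.conv_filters,
                             cfg.conv_kernel, relu=conv_relu, dtype=dtype)
        self.conv_k = Conv1D(rng, cfg.input_channels, cfg.conv_filters,
                             cfg.conv_kernel, relu=conv_relu, dtype=dtype)
        self.attention = ChannelAttention(rng, cfg.conv_filters,
                                          cfg.attention_channels,
                                          head_dim=cfg.attention_head_dim,
                                          score_mode=cfg.attention_score,
                                          dtype=dtype)
        lstm_in = cfg.input_channels + cfg.attention_channels
        self.bilstm = BiLSTM(rng, lstm_in, cfg.recurrent_units_per_direction,
                             dtype=dtype)
        dense_in = 2 * cfg.recurrent_units_per_direction
        self.denses: list[Dense] = []
        for size in cfg.dense_sizes:
            self.denses.append(Dense(rng, dense_in, size, relu=True, dtype=dtype))
            dense_in = size
        self.out_dense = Dense(rng, dense_in, 1, relu=False, dtype=dtype)
        self.is_trained = False

    # ------------------------------------------------------------------ params

    @property
    def _layers(self) -> dict[str, Layer]:
        layers = {"conv_q": self.conv_q, "conv_k": self.conv_k,
                  "attention": self.attention,
                  "lstm_fwd": self.bilstm.fwd, "lstm_bwd": self.bilstm.bwd}
        for k, d in enumerate(self.denses):
            layers[f"dense_{k}"] = d
        layers["out"] = self.out_dense
        return layers

    def parameters(self) -> dict[str, np.ndarray]:
        return {f"{ln}/{pn}": p
                for ln, layer in self._layers.items()
                for pn, p in layer.params.items()}

    def gradients(self) -> dict[str, np.ndarray]:
        return {f"{ln}/{pn}": g
                for ln, layer in self._layers.items()
                for pn, g in layer.grads.items()}

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        for ln, layer in self._layers.items():
            for pn in layer.params:
                layer.params[pn] = params[f"{ln}/{pn}"].astype(layer.params[pn].dtype)

    def copy_parameters(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def zero_grads(self) -> None:
        for layer in self._layers.values():
            layer.zero_grads()

    # ----------------------------------------------------------------- forward

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Probabilities (B, L) over partner positions for questions (B, L, 5)."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        qf = self.conv_q.forward(x)
        kf = self.conv_k.forward(x)
        ctx = self.attention.forward(x, qf, kf)
        h = np.concatenate([x, ctx], axis=-1)
        h = self.bilstm.forward(h)
        self._lstm_out = h
        for d in self.denses:
            h = d.forward(h)
        logits = self.out_dense.forward(h)[..., 0]  # (B, L)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        self._probs = probs
        self._input = x
        return probs

    predict = forward

    def loss(self, probs: np.ndarray, targets: np.ndarray) -> float:
        """Mean categorical cross-entropy plus the L2 penalty."""
        B = probs.shape[0]
        eps = np.finfo(probs.dtype).tiny
        nll = -np.log(probs[np.arange(B), targets] + eps).mean()
        l2 = self.config.l2_coefficient
        pen = l2 * (np.sum(self.out_dense.params["W"] ** 2)
                    + np.sum(self.out_dense.params["b"] ** 2))
        return float(nll + pen)

    def backward(self, targets: np.ndarray) -> np.ndarray:
        """Backprop the loss of the last forward; returns d(loss)/d(input).

        Parameter gradients accumulate into each layer's ``grads`` (call
        :meth:`zero_grads` first for a fresh batch).
        """
        probs = self._probs
        B, L = probs.shape
        dlogits = probs.copy()
        dlogits[np.arange(B), targets] -= 1.0
        dlogits /= B
        dh = self.out_dense.backward(dlogits[..., None])
        l2 = self.config.l2_coefficient
        self.out_dense.grads["W"] += 2.0 * l2 * self.out_dense.params["W"]
        self.out_dense.grads["b"] += 2.0 * l2 * self.out_dense.params["b"]
        for d in reversed(self.denses):
            dh = d.backward(dh)
        dh = self.bilstm.backward(dh)
        C = self.config.input_channels
        dx = dh[:, :, :C].copy()
        dctx = np.ascontiguousarray(dh[:, :, C:])
        dx_att, dqf, dkf = self.attention.backward(dctx)
        dx += dx_att
        dx += self.conv_q.backward(dqf)
        dx += self.conv_k.backward(dkf)
        return dx

    def train_step(self, x: np.ndarray, targets: np.ndarray, optimizer) -> float:
        self.zero_grads()
        probs = self.forward(x)
        loss = self.loss(probs, targets)
        self.backward(targets)
        optimizer.step(self.parameters(), self.gradients())
        return loss

    # ------------------------------------------------------------- inspection

    def input_gradient(self, x: np.ndarray, targets: np.ndarray) -> np.ndarray:
        """Gradient of the cross-entropy loss w.r.t. the (B, L, 5) input."""
        self.zero_grads()
        self.forward(x)
        targets = np.atleast_1d(np.asarray(targets))
        return self.backward(targets)

    def lstm_activations(self, x: np.ndarray) -> np.ndarray:
        """Recurrent-layer output (B, L, 2*units); basis for embeddings."""
        self.forward(x)
        return self._lstm_out

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        """Per-channel attention weights (B, L_query, L_key, channels)."""
        self.forward(x)
        return self.attention.last_weights

    # ---------------------------------------------------------------- storage

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {k.replace("/", "__"): v for k, v in self.parameters().items()}
        np.savez(path, __config__=np.asarray(self.config.to_json()),
                 __trained__=np.asarray(int(self.is_trained)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "PredPairNetwork":
        with np.load(path) as data:
            config = ModelConfig.from_json(str(data["__config__"]))
            net = cls(config)
            params = {k.replace("__", "/"): data[k] for k in data.files
                      if not k.startswith("__")}
            net.set_parameters(params)
            net.is_trained = bool(int(data["__trained__"]))
        return net
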