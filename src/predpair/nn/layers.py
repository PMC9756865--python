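"""Network layers with explicit forward/backward passes.

Every layer stores parameters in ``self.params`` and accumulates exact
gradients into ``self.grads`` during ``backward``.  Shapes use
(batch, length, channels) convention; all layers are length-agnostic so a
trained network runs on sequences of any length.
"""

from __future__ import annotations

import numpy as np

from . import _kernels


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def orthogonal(rng: np.random.Generator, rows: int, cols: int, dtype) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))  # deterministic sign convention
    if rows < cols:
        q = q.T
    return q[:rows, :cols].astype(dtype)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grads(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


class Conv1D(Layer):
    """1-D convolution over the length axis, 'same' padding, optional ReLU."""

    def __init__(self, rng, in_channels: int, filters: int, kernel: int,
                 relu: bool = True, dtype=np.float32) -> None:
        super().__init__()
        self.kernel = kernel
        self.relu = relu
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel - 1 - self.pad_left
        fan_in = kernel * in_channels
        self.params["W"] = glorot_uniform(rng, (fan_in, filters), fan_in, filters, dtype)
        self.params["b"] = np.zeros(filters, dtype=dtype)
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        padded = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        # (B, L, C, K) -> (B, L, K, C) -> (B, L, K*C)
        win = np.lib.stride_tricks.sliding_window_view(padded, self.kernel, axis=1)
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, L, -1)
        pre = cols @ self.params["W"] + self.params["b"]
        self._cache = (cols, pre if self.relu else None, (B, L, C))
        return np.maximum(pre, 0.0) if self.relu else pre

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, pre, (B, L, C) = self._cache
        if self.relu:
            dy = dy * (pre > 0)
        self.grads["W"] += cols.reshape(-1, cols.shape[-1]).T @ dy.reshape(-1, dy.shape[-1])
        self.grads["b"] += dy.sum(axis=(0, 1))
        dcols = (dy @ self.params["W"].T).reshape(B, L, self.kernel, C)
        dpadded = np.zeros((B, L + self.kernel - 1, C), dtype=dy.dtype)
        for k in range(self.kernel):
            dpadded[:, k : k + L] += dcols[:, :, k]
        return dpadded[:, self.pad_left : self.pad_left + L]


class ChannelAttention(Layer):
    """Attention with one score channel per input channel.

    The two convolution branches provide query and key features; each is
    projected, per channel, to a ``head_dim``-dimensional vector per
    position.  For channel c the alignment between query position t and
    key position s is the scaled dot product ``q[t,c]·k[s,c]/sqrt(d)``,
    softmax-normalised over s, and the resulting weights are applied to
    input channel c, yielding a context vector with the same depth as the
    input (5: four nucleotide channels plus the query mark).  The
    per-channel weights are what `attention_inspection` reads.  An
    additive (tanh) scalar scoring variant is kept for comparison; it
    ranks key positions identically for every query and learns the
    partner task far more slowly.
    """

    def __init__(self, rng, feat_dim: int, channels: int, head_dim: int = 8,
                 score_mode: str = "dot", dtype=np.float32) -> None:
        super().__init__()
        if score_mode not in ("dot", "additive"):
            raise ValueError(f"unknown attention score_mode '{score_mode}'")
        self.channels = channels
        self.score_mode = score_mode
        self.head_dim = 1 if score_mode == "additive" else head_dim
        d = self.head_dim
        self.params["Wq"] = glorot_uniform(rng, (feat_dim, channels * d),
                                           feat_dim, channels * d, dtype)
        self.params["bq"] = np.zeros(channels * d, dtype=dtype)
        self.params["Wk"] = glorot_uniform(rng, (feat_dim, channels * d),
                                           feat_dim, channels * d, dtype)
        self.params["bk"] = np.zeros(channels * d, dtype=dtype)
        if score_mode == "additive":
            self.params["v"] = np.ones(channels, dtype=dtype)
        self.zero_grads()

    def _project(self, feat: np.ndarray, which: str) -> np.ndarray:
        """(B, L, F) -> channel-major (B, C, L, d)."""
        B, L, _ = feat.shape
        out = feat @ self.params[f"W{which}"] + self.params[f"b{which}"]
        return out.reshape(B, L, self.channels, self.head_dim).transpose(0, 2, 1, 3)

    def forward(self, x: np.ndarray, qfeat: np.ndarray, kfeat: np.ndarray) -> np.ndarray:
        # channel-major (B, C, ...) layout keeps the softmax axis contiguous
        q = self._project(qfeat, "q")  # (B,C,T,d)
        k = self._project(kfeat, "k")  # (B,C,S,d)
        if self.score_mode == "additive":
            tanh_pre = np.tanh(q[:, :, :, 0, None] + k[:, :, None, :, 0])
            scores = self.params["v"][None, :, None, None] * tanh_pre
        else:
            tanh_pre = None
            scores = (q @ k.transpose(0, 1, 3, 2)) / np.sqrt(
                np.array(self.head_dim, dtype=q.dtype)
            )  # (B,C,T,S)
        if _kernels.HAVE_NUMBA and scores.dtype == np.float32:
            attn = _kernels.softmax_lastaxis_f32(np.ascontiguousarray(scores))
        else:
            scores -= scores.max(axis=-1, keepdims=True)
            attn = np.exp(scores)
            attn /= attn.sum(axis=-1, keepdims=True)  # softmax over key axis s
        xT = np.ascontiguousarray(x.transpose(0, 2, 1))  # (B,C,S)
        context = (attn @ xT[:, :, :, None])[..., 0]  # (B,C,T)
        self._cache = (xT, qfeat, kfeat, q, k, attn, tanh_pre)
        return np.ascontiguousarray(context.transpose(0, 2, 1))

    def backward(self, dctx: np.ndarray):
        xT, qfeat, kfeat, q, k, attn, tanh_pre = self._cache
        dctxT = np.ascontiguousarray(dctx.transpose(0, 2, 1))  # (B,C,T)
        dattn = dctxT[:, :, :, None] * xT[:, :, None, :]  # (B,C,T,S)
        attn_T = attn.transpose(0, 1, 3, 2)
        dxT = (attn_T @ dctxT[:, :, :, None])[..., 0]  # (B,C,S)
        if _kernels.HAVE_NUMBA and attn.dtype == np.float32:
            dscores = _kernels.attention_softmax_backward_f32(attn, dattn)
        else:
            dscores = attn * (dattn - (attn * dattn).sum(axis=-1, keepdims=True))
        if self.score_mode == "additive":
            self.grads["v"] += (dscores * tanh_pre).sum(axis=(0, 2, 3))
            dpre = dscores * self.params["v"][None, :, None, None]
            dpre *= 1.0 - tanh_pre * tanh_pre
            dq = dpre.sum(axis=3)[..., None]  # (B,C,T,1)
            dk = dpre.sum(axis=2)[..., None]
        else:
            scale = 1.0 / np.sqrt(np.array(self.head_dim, dtype=q.dtype))
            dq = (dscores @ k) * scale  # (B,C,T,d)
            dk = (dscores.transpose(0, 1, 3, 2) @ q) * scale  # (B,C,S,d)
        B, C, L, d = dq.shape
        # back to (B*L, C*d) for the projection gradients
        dq = np.ascontiguousarray(dq.transpose(0, 2, 1, 3)).reshape(B * L, C * d)
        dk = np.ascontiguousarray(dk.transpose(0, 2, 1, 3)).reshape(B * L, C * d)
        F = qfeat.shape[-1]
        self.grads["Wq"] += qfeat.reshape(-1, F).T @ dq
        self.grads["bq"] += dq.sum(axis=0)
        self.grads["Wk"] += kfeat.reshape(-1, F).T @ dk
        self.grads["bk"] += dk.sum(axis=0)
        dqfeat = (dq @ self.params["Wq"].T).reshape(B, L, F)
        dkfeat = (dk @ self.params["Wk"].T).reshape(B, L, F)
        return dxT.transpose(0, 2, 1), dqfeat, dkfeat

    @property
    def last_weights(self) -> np.ndarray:
        """Attention weights (B, L_query, L_key, channels) of the last forward."""
        return self._cache[5].transpose(0, 2, 3, 1)


class LSTMDirection(Layer):
    """Single-direction LSTM; gate order i, f, g, o; forget bias init 1."""

    def __init__(self, rng, in_dim: int, hidden: int, dtype=np.float32) -> None:
        super().__init__()
        self.hidden = hidden
        H = hidden
        self.params["Wx"] = glorot_uniform(rng, (in_dim, 4 * H), in_dim, 4 * H, dtype)
        self.params["Wh"] = np.concatenate(
            [orthogonal(rng, H, H, dtype) for _ in range(4)], axis=1
        )
        b = np.zeros(4 * H, dtype=dtype)
        b[H : 2 * H] = 1.0
        self.params["b"] = b
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, _ = x.shape
        H = self.hidden
        Wh = self.params["Wh"]
        xz = x @ self.params["Wx"] + self.params["b"]
        if _kernels.HAVE_NUMBA and xz.dtype == np.float32:
            hs, gates, cs, tanh_cs = _kernels.lstm_forward_f32(
                np.ascontiguousarray(xz), np.ascontiguousarray(Wh)
            )
            self._cache = (x, hs, gates, cs, tanh_cs)
            return hs
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        hs = np.empty((B, L, H), dtype=x.dtype)
        gates = np.empty((B, L, 4 * H), dtype=x.dtype)  # i, f, g, o post-activation
        cs = np.empty((B, L, H), dtype=x.dtype)
        tanh_cs = np.empty((B, L, H), dtype=x.dtype)
        for t in range(L):
            z = xz[:, t] + h @ Wh
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            gates[:, t, :H] = i
            gates[:, t, H : 2 * H] = f
            gates[:, t, 2 * H : 3 * H] = g
            gates[:, t, 3 * H :] = o
            cs[:, t] = c
            tanh_cs[:, t] = tc
            hs[:, t] = h
        self._cache = (x, hs, gates, cs, tanh_cs)
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        x, hs, gates, cs, tanh_cs, = self._cache
        B, L, H = hs.shape
        Wh = self.params["Wh"]
        WhT = Wh.T
        if _kernels.HAVE_NUMBA and gates.dtype == np.float32:
            dz_all = _kernels.lstm_backward_f32(
                np.ascontiguousarray(dhs, dtype=np.float32), gates, cs,
                tanh_cs, np.ascontiguousarray(WhT)
            )
            return self._finish_backward(x, hs, dz_all)
        dz_all = np.empty((B, L, 4 * H), dtype=dhs.dtype)
        dh_next = np.zeros((B, H), dtype=dhs.dtype)
        dc_next = np.zeros((B, H), dtype=dhs.dtype)
        for t in range(L - 1, -1, -1):
            i = gates[:, t, :H]
            f = gates[:, t, H : 2 * H]
            g = gates[:, t, 2 * H : 3 * H]
            o = gates[:, t, 3 * H :]
            c_prev = cs[:, t - 1] if t > 0 else np.zeros((B, H), dtype=dhs.dtype)
            tc = tanh_cs[:, t]
            dh = dhs[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = dz_all[:, t]
            dz[:, :H] = di * i * (1.0 - i)
            dz[:, H : 2 * H] = df * f * (1.0 - f)
            dz[:, 2 * H : 3 * H] = dg * (1.0 - g * g)
            dz[:, 3 * H :] = do * o * (1.0 - o)
            dh_next = dz @ WhT
        return self._finish_backward(x, hs, dz_all)

    def _finish_backward(self, x, hs, dz_all):
        B, L, H = hs.shape
        h_prev = np.concatenate(
            [np.zeros((B, 1, H), dtype=hs.dtype), hs[:, :-1]], axis=1
        )
        self.grads["Wx"] += x.reshape(-1, x.shape[-1]).T @ dz_all.reshape(-1, 4 * H)
        self.grads["Wh"] += h_prev.reshape(-1, H).T @ dz_all.reshape(-1, 4 * H)
        self.grads["b"] += dz_all.sum(axis=(0, 1))
        return dz_all @ self.params["Wx"].T


class BiLSTM:
    """Bidirectional LSTM; output is [forward ; backward] concatenation."""

    def __init__(self, rng, in_dim: int, hidden: int, dtype=np.float32) -> None:
        self.fwd = LSTMDirection(rng, in_dim, hidden, dtype)
        self.bwd = LSTMDirection(rng, in_dim, hidden, dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1])[:, ::-1]
        return np.concatenate([hf, hb], axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        H = self.fwd.hidden
        dxf = self.fwd.backward(np.ascontiguousarray(dy[:, :, :H]))
        dxb = self.bwd.backward(np.ascontiguousarray(dy[:, ::-1, H:]))[:, ::-1]
        return dxf + dxb

    @property
    def layers(self) -> list[Layer]:
        return [self.fwd, self.bwd]


class Dense(Layer):
    """Time-distributed dense layer (applied independently per position)."""

    def __init__(self, rng, in_dim: int, out_dim: int, relu: bool = True,
                 dtype=np.float32) -> None:
        super().__init__()
        self.relu = relu
        self.params["W"] = glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim, dtype)
        self.params["b"] = np.zeros(out_dim, dtype=dtype)
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        pre = x @ self.params["W"] + self.params["b"]
        self._cache = (x, pre if self.relu else None)
        return np.maximum(pre, 0.0) if self.relu else pre

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, pre = self._cache
        if self.relu:
            dy = dy * (pre > 0)
        d_in = x.shape[-1]
        d_out = dy.shape[-1]
        self.grads["W"] += x.reshape(-1, d_in).T @ dy.reshape(-1, d_out)
        self.grads["b"] += dy.reshape(-1, d_out).sum(axis=0)
        return dy @ self.params["W"].T
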