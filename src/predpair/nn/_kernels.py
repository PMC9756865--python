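"""Numba-compiled hot loops (float32 path); numpy fallbacks elsewhere.

The LSTM time loops and the attention softmax dominate CPU time; the
kernels here fuse their elementwise work.  They are exact (no
approximation beyond float32 arithmetic), and the float64 code path in
the layers bypasses them so gradient checks run against the plain
numpy implementation.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=True)
def lstm_forward_f32(xz, Wh):
    """Forward recurrence.  xz: (B, L, 4H) pre-activations with bias added.

    Returns hs, gates (post-activation i|f|g|o), cs, tanh_cs.
    """
    B, L, H4 = xz.shape
    H = H4 // 4
    hs = np.empty((B, L, H), dtype=np.float32)
    gates = np.empty((B, L, H4), dtype=np.float32)
    cs = np.empty((B, L, H), dtype=np.float32)
    tanh_cs = np.empty((B, L, H), dtype=np.float32)
    h = np.zeros((B, H), dtype=np.float32)
    c = np.zeros((B, H), dtype=np.float32)
    for t in range(L):
        z = np.dot(h, Wh)
        for b in range(B):
            for u in range(H):
                zi = xz[b, t, u] + z[b, u]
                zf = xz[b, t, H + u] + z[b, H + u]
                zg = xz[b, t, 2 * H + u] + z[b, 2 * H + u]
                zo = xz[b, t, 3 * H + u] + z[b, 3 * H + u]
                i = 1.0 / (1.0 + np.exp(-zi))
                f = 1.0 / (1.0 + np.exp(-zf))
                g = np.tanh(zg)
                o = 1.0 / (1.0 + np.exp(-zo))
                cc = f * c[b, u] + i * g
                tc = np.tanh(cc)
                hh = o * tc
                c[b, u] = cc
                h[b, u] = hh
                gates[b, t, u] = i
                gates[b, t, H + u] = f
                gates[b, t, 2 * H + u] = g
                gates[b, t, 3 * H + u] = o
                cs[b, t, u] = cc
                tanh_cs[b, t, u] = tc
                hs[b, t, u] = hh
    return hs, gates, cs, tanh_cs


@njit(cache=True, fastmath=True)
def lstm_backward_f32(dhs, gates, cs, tanh_cs, WhT):
    """Backward recurrence; returns dz over all timesteps (B, L, 4H)."""
    B, L, H = dhs.shape[0], dhs.shape[1], dhs.shape[2] // 1
    H = gates.shape[2] // 4
    dz_all = np.empty((B, L, 4 * H), dtype=np.float32)
    dh_next = np.zeros((B, H), dtype=np.float32)
    dc_next = np.zeros((B, H), dtype=np.float32)
    dz_t = np.empty((B, 4 * H), dtype=np.float32)
    for t in range(L - 1, -1, -1):
        for b in range(B):
            for u in range(H):
                i = gates[b, t, u]
                f = gates[b, t, H + u]
                g = gates[b, t, 2 * H + u]
                o = gates[b, t, 3 * H + u]
                c_prev = cs[b, t - 1, u] if t > 0 else np.float32(0.0)
                tc = tanh_cs[b, t, u]
                dh = dhs[b, t, u] + dh_next[b, u]
                do = dh * tc
                dc = dc_next[b, u] + dh * o * (1.0 - tc * tc)
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                dc_next[b, u] = dc * f
                dz_t[b, u] = di * i * (1.0 - i)
                dz_t[b, H + u] = df * f * (1.0 - f)
                dz_t[b, 2 * H + u] = dg * (1.0 - g * g)
                dz_t[b, 3 * H + u] = do * o * (1.0 - o)
        dh_next = np.dot(dz_t, WhT)
        dz_all[:, t, :] = dz_t
    return dz_all


@njit(cache=True, fastmath=True)
def softmax_lastaxis_f32(scores):
    """In-place softmax over the last axis of a 4-D array."""
    B, C, T, S = scores.shape
    for b in range(B):
        for c in range(C):
            for t in range(T):
                m = scores[b, c, t, 0]
                for s in range(1, S):
                    if scores[b, c, t, s] > m:
                        m = scores[b, c, t, s]
                tot = np.float32(0.0)
                for s in range(S):
                    e = np.exp(scores[b, c, t, s] - m)
                    scores[b, c, t, s] = e
                    tot += e
                for s in range(S):
                    scores[b, c, t, s] /= tot
    return scores


@njit(cache=True, fastmath=True)
def attention_softmax_backward_f32(attn, dattn):
    """dscores for a softmax applied over the last axis (in place on dattn)."""
    B, C, T, S = attn.shape
    for b in range(B):
        for c in range(C):
            for t in range(T):
                acc = np.float32(0.0)
                for s in range(S):
                    acc += attn[b, c, t, s] * dattn[b, c, t, s]
                for s in range(S):
                    dattn[b, c, t, s] = attn[b, c, t, s] * (
                        dattn[b, c, t, s] - acc
                    )
    return dattn
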