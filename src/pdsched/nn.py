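"""Minimal numpy neural-network core for the patient-response models.

Implements exactly the two architectures the scheduling framework needs —
a feed-forward "history" network and an LSTM-based "impulse" network — with
closed-loop whole-day rollout: each predicted TRS state is fed back as the
next step's previous-state input, and gradients are backpropagated through
the entire predicted day (including the feedback path).  Both backward
passes are verified against finite differences in the test suite.

Weight layout follows common deep-learning conventions: Glorot-uniform
dense kernels, orthogonal LSTM recurrent kernel, forget-gate bias of one,
gate order (input, forget, cell, output).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["Adam", "HistoryNet", "ImpulseNet", "OutputSpec"]


def glorot_uniform(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


def orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    return q[:rows, :cols] if q.shape == (max(rows, cols), min(rows, cols)) else q.T[:rows, :cols]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class Adam:
    """Adam optimizer over a dict of weight arrays, with global-norm clipping."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7, clipnorm: float | None = 5.0):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.clipnorm = clipnorm
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, weights: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             frozen: set[str] = frozenset()) -> None:
        norms = [np.sum(g * g) for k, g in grads.items() if k not in frozen]
        gnorm = float(np.sqrt(sum(norms))) if norms else 0.0
        if not np.isfinite(gnorm):
            return  # skip a diverged update; checkpointing keeps the best weights
        scale = 1.0
        if self.clipnorm is not None and gnorm > self.clipnorm:
            scale = self.clipnorm / (gnorm + 1e-12)
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            if k in frozen:
                continue
            g = g * scale
            m = self.m.setdefault(k, np.zeros_like(g))
            v = self.v.setdefault(k, np.zeros_like(g))
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            weights[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass(frozen=True)
class OutputSpec:
    """How the scalar network output maps to the next raw TRS state.

    ``difference`` — the output is the state increment; ``tanh`` — the raw
    output is ``3*tanh(z)`` (and the resulting state is clamped to the TRS
    scale); otherwise the output is the standardized next state, rescaled by
    (``y_mean``, ``y_std``).
    """

    difference: bool = False
    tanh: bool = False
    y_mean: float = 0.0
    y_std: float = 1.0


def _output_forward(z: np.ndarray, s_prev: np.ndarray, spec: OutputSpec):
    """z (B,) -> next raw state (B,); returns (state, cache)."""
    if spec.tanh:
        th = np.tanh(z)
        out = 3.0 * th
    else:
        th = None
        out = spec.y_mean + spec.y_std * z
    s = s_prev + out if spec.difference else out
    if spec.tanh:
        s_clip = np.clip(s, -3.0, 3.0)
        if spec.difference:
            mask = (s > -3.0) & (s < 3.0)
        else:
            mask = np.ones_like(s, dtype=bool)  # 3*tanh already inside the scale
        return s_clip, (th, mask)
    return s, (th, None)


def _output_backward(g_s: np.ndarray, z: np.ndarray, cache, spec: OutputSpec):
    """Returns (g_z, g_sprev_direct)."""
    th, mask = cache
    if spec.tanh and mask is not None:
        g_s = g_s * mask
    g_out = g_s
    if spec.tanh:
        g_z = g_out * 3.0 * (1.0 - th * th)
    else:
        g_z = g_out * spec.y_std
    g_prev = g_s if spec.difference else np.zeros_like(g_s)
    return g_z, g_prev


class _MLPHead:
    """Two ReLU hidden layers + linear scalar output, with explicit backward."""

    def __init__(self, d_in: int, h1: int, h2: int):
        self.d_in, self.h1, self.h2 = d_in, h1, h2

    def init(self, rng: np.random.Generator, prefix: str = "") -> dict[str, np.ndarray]:
        p = prefix
        return {
            p + "W1": glorot_uniform(rng, self.h1, self.d_in),
            p + "b1": np.zeros(self.h1),
            p + "W2": glorot_uniform(rng, self.h2, self.h1),
            p + "b2": np.zeros(self.h2),
            p + "W3": glorot_uniform(rng, 1, self.h2),
            p + "b3": np.zeros(1),
        }

    def forward(self, w: dict, x: np.ndarray, prefix: str = ""):
        p = prefix
        a1 = x @ w[p + "W1"].T + w[p + "b1"]
        h1 = np.maximum(a1, 0.0)
        a2 = h1 @ w[p + "W2"].T + w[p + "b2"]
        h2 = np.maximum(a2, 0.0)
        z = (h2 @ w[p + "W3"].T + w[p + "b3"])[:, 0]
        return z, (x, a1 > 0, h1, a2 > 0, h2)

    def backward(self, w: dict, g_z: np.ndarray, cache, grads: dict, prefix: str = ""):
        p = prefix
        x, m1, h1, m2, h2 = cache
        gz = g_z[:, None]
        grads[p + "W3"] += gz.T @ h2
        grads[p + "b3"] += gz.sum(0)
        gh2 = gz @ w[p + "W3"]
        ga2 = gh2 * m2
        grads[p + "W2"] += ga2.T @ h1
        grads[p + "b2"] += ga2.sum(0)
        gh1 = ga2 @ w[p + "W2"]
        ga1 = gh1 * m1
        grads[p + "W1"] += ga1.T @ x
        grads[p + "b1"] += ga1.sum(0)
        return ga1 @ w[p + "W1"]  # gradient w.r.t. the input row


class HistoryNet:
    """Feed-forward rollout network over [previous states | dose features].

    Input rows hold ``n_prev`` fed-back states followed by ``2*k`` dose
    features; the feature normalization (per-feature mean/sd) is baked into
    the forward pass so the feedback path is differentiated exactly.
    """

    def __init__(self, n_prev: int, n_dose_feats: int, hidden: tuple[int, int]):
        self.n_prev = n_prev
        self.n_dose_feats = n_dose_feats
        self.d_in = n_prev + n_dose_feats
        self.mlp = _MLPHead(self.d_in, hidden[0], hidden[1])

    def init_weights(self, seed) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(seed)
        return self.mlp.init(rng)

    def rollout(self, w: dict, s_init: np.ndarray, dose_feats: np.ndarray,
                x_mean: np.ndarray, x_std: np.ndarray, spec: OutputSpec,
                want_cache: bool = False):
        """s_init (B,), dose_feats (B,T,2k) raw -> predicted raw states (B,T)."""
        B, T, _ = dose_feats.shape
        n = self.n_prev
        states = np.empty((B, T))
        prev = np.tile(s_init[:, None], (1, n))  # most recent first
        caches = [] if want_cache else None
        for t in range(T):
            raw = np.concatenate([prev, dose_feats[:, t, :]], axis=1)
            x = (raw - x_mean) / x_std
            z, mlp_cache = self.mlp.forward(w, x)
            s, out_cache = _output_forward(z, prev[:, 0], spec)
            states[:, t] = s
            if want_cache:
                caches.append((mlp_cache, z, out_cache))
            prev = np.concatenate([s[:, None], prev[:, :-1]], axis=1)
        return (states, caches) if want_cache else states

    def backward(self, w: dict, states: np.ndarray, targets: np.ndarray,
                 caches, x_std: np.ndarray, spec: OutputSpec) -> dict[str, np.ndarray]:
        """Gradient of mean((states-targets)^2) over all (B,T) entries."""
        B, T = states.shape
        n = self.n_prev
        grads = {k: np.zeros_like(v) for k, v in w.items()}
        G = np.zeros((B, T))  # accumulated dL/ds_t from future steps
        coef = 2.0 / (B * T)
        for t in range(T - 1, -1, -1):
            mlp_cache, z, out_cache = caches[t]
            g_s = coef * (states[:, t] - targets[:, t]) + G[:, t]
            g_z, g_prev_direct = _output_backward(g_s, z, out_cache, spec)
            if spec.difference and t >= 1:
                G[:, t - 1] += g_prev_direct
            g_x = self.mlp.backward(w, g_z, mlp_cache, grads)
            for j in range(n):
                src = t - 1 - j
                if src >= 0:
                    G[:, src] += g_x[:, j] / x_std[j]
        return grads


class ImpulseNet:
    """LSTM + two ReLU dense layers, rolled out over the day.

    Per-step input: (previous TRS state, dose at the step), standardized.
    The LSTM hidden state feeds the dense head; the prediction is fed back
    into the next step's input.  The recurrent cell starts at zero.
    """

    LSTM_KEYS = ("Wx", "Wh", "bl")

    def __init__(self, units: int, hidden: tuple[int, int]):
        self.units = units
        self.mlp = _MLPHead(units, hidden[0], hidden[1])

    def init_weights(self, seed) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(seed)
        H = self.units
        w = {
            "Wx": glorot_uniform(rng, 4 * H, 2),
            "Wh": np.concatenate([orthogonal(rng, H, H) for _ in range(4)], axis=0),
            "bl": np.zeros(4 * H),
        }
        w["bl"][H:2 * H] = 1.0  # forget-gate bias
        w.update(self.mlp.init(rng))
        return w

    def _cell(self, w: dict, u: np.ndarray, h: np.ndarray, c: np.ndarray):
        H = self.units
        zg = u @ w["Wx"].T + h @ w["Wh"].T + w["bl"]
        i = _sigmoid(zg[:, :H])
        f = _sigmoid(zg[:, H:2 * H])
        g = np.tanh(zg[:, 2 * H:3 * H])
        o = _sigmoid(zg[:, 3 * H:])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        return h_new, c_new, (u, h, c, i, f, g, o, c_new, tc)

    def rollout(self, w: dict, s_init: np.ndarray, dose_feats: np.ndarray,
                x_mean: np.ndarray, x_std: np.ndarray, spec: OutputSpec,
                want_cache: bool = False, h0: np.ndarray | None = None,
                c0: np.ndarray | None = None, return_cells: bool = False):
        """s_init (B,), dose_feats (B,T,1) raw doses -> raw states (B,T)."""
        B, T, _ = dose_feats.shape
        H = self.units
        h = np.zeros((B, H)) if h0 is None else h0.copy()
        c = np.zeros((B, H)) if c0 is None else c0.copy()
        states = np.empty((B, T))
        caches = [] if want_cache else None
        s = s_init.astype(float).copy()
        for t in range(T):
            u = np.stack([(s - x_mean[0]) / x_std[0],
                          (dose_feats[:, t, 0] - x_mean[1]) / x_std[1]], axis=1)
            h, c, cell_cache = self._cell(w, u, h, c)
            z, mlp_cache = self.mlp.forward(w, h)
            s, out_cache = _output_forward(z, cell_cache[0][:, 0] * x_std[0] + x_mean[0], spec)
            states[:, t] = s
            if want_cache:
                caches.append((cell_cache, mlp_cache, z, out_cache))
        if return_cells:
            return (states, h, c, caches) if want_cache else (states, h, c)
        return (states, caches) if want_cache else states

    def backward(self, w: dict, states: np.ndarray, targets: np.ndarray,
                 caches, x_std: np.ndarray, spec: OutputSpec) -> dict[str, np.ndarray]:
        B, T = states.shape
        H = self.units
        grads = {k: np.zeros_like(v) for k, v in w.items()}
        gh_next = np.zeros((B, H))
        gc_next = np.zeros((B, H))
        gs_next = np.zeros(B)  # dL/ds_t carried from step t+1
        coef = 2.0 / (B * T)
        for t in range(T - 1, -1, -1):
            cell_cache, mlp_cache, z, out_cache = caches[t]
            u, h_prev, c_prev, i, f, g, o, c_new, tc = cell_cache
            g_s = coef * (states[:, t] - targets[:, t]) + gs_next
            g_z, g_prev_direct = _output_backward(g_s, z, out_cache, spec)
            gh = self.mlp.backward(w, g_z, mlp_cache, grads) + gh_next
            go = gh * tc
            gc = gh * o * (1.0 - tc * tc) + gc_next
            gi = gc * g
            gf = gc * c_prev
            gg = gc * i
            gc_next = gc * f
            gz_all = np.concatenate([
                gi * i * (1.0 - i),
                gf * f * (1.0 - f),
                gg * (1.0 - g * g),
                go * o * (1.0 - o),
            ], axis=1)
            grads["Wx"] += gz_all.T @ u
            grads["Wh"] += gz_all.T @ h_prev
            grads["bl"] += gz_all.sum(0)
            gh_next = gz_all @ w["Wh"]
            gu = gz_all @ w["Wx"]
            gs_next = gu[:, 0] / x_std[0] + g_prev_direct
        return grads
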