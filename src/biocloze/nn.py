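"""Numerical building blocks for the reader: gated recurrent units and Adam.

Everything is plain numpy in float64 with hand-written backpropagation; the
analytic gradients are validated against finite differences in the test
suite.  Sequences are processed batched with end-padding and a {0,1} mask:
a masked step carries the hidden state through unchanged, so the state
after the last step equals the state at each sequence's last real token.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["sigmoid", "GRUDirection", "Adam", "clip_global_norm"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # tanh form is overflow-safe for large |x|
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


class GRUDirection:
    """One direction of a gated recurrent layer over a padded batch.

    Gate layout is ``[update z | reset r | candidate n]``:

        z_t = sigmoid(x_t Wz + h_{t-1} Uz + bz)
        r_t = sigmoid(x_t Wr + h_{t-1} Ur + br)
        n_t = tanh(x_t Wn + r_t * (h_{t-1} Un) + bn)
        h_t = (1 - z_t) * n_t + z_t * h_{t-1}

    ``reverse=True`` walks the time axis backwards, which with end-padding
    yields the backward half of a bidirectional encoder.
    """

    def __init__(self, input_dim: int, hidden_size: int,
                 rng: np.random.Generator, name: str):
        self.input_dim = input_dim
        self.hidden_size = hidden_size
        self.name = name
        h = hidden_size
        lim_w = math.sqrt(6.0 / (input_dim + h))
        lim_u = math.sqrt(6.0 / (2 * h))
        self.params = {
            f"{name}.W": rng.uniform(-lim_w, lim_w, (input_dim, 3 * h)),
            f"{name}.Uzr": rng.uniform(-lim_u, lim_u, (h, 2 * h)),
            f"{name}.Un": rng.uniform(-lim_u, lim_u, (h, h)),
            f"{name}.b": np.zeros(3 * h),
        }

    def forward(self, X: np.ndarray, mask: np.ndarray, reverse: bool = False):
        """Run the recurrence over ``X`` (B, L, D) with ``mask`` (B, L).

        Returns the per-position states (B, L, H), the final state (B, H),
        and the cache needed for :meth:`backward`.
        """
        W = self.params[f"{self.name}.W"]
        Uzr = self.params[f"{self.name}.Uzr"]
        Un = self.params[f"{self.name}.Un"]
        b = self.params[f"{self.name}.b"]
        B, L, _ = X.shape
        h_size = self.hidden_size
        states = np.zeros((B, L, h_size))
        h = np.zeros((B, h_size))
        cache = []
        A = X.reshape(B * L, -1) @ W + b  # input projections, all steps at once
        A = A.reshape(B, L, 3 * h_size)
        order = range(L - 1, -1, -1) if reverse else range(L)
        for t in order:
            az, ar, an = (A[:, t, :h_size], A[:, t, h_size:2 * h_size],
                          A[:, t, 2 * h_size:])
            uzr = h @ Uzr
            z = sigmoid(az + uzr[:, :h_size])
            r = sigmoid(ar + uzr[:, h_size:])
            hUn = h @ Un
            n = np.tanh(an + r * hUn)
            h_new = (1.0 - z) * n + z * h
            m = mask[:, t:t + 1]
            h_next = m * h_new + (1.0 - m) * h
            states[:, t, :] = h_next
            cache.append((t, h, z, r, n, hUn, m))
            h = h_next
        return states, h, cache

    def backward(self, X: np.ndarray, dstates: np.ndarray,
                 dfinal: np.ndarray | None, cache):
        """Backpropagate through the recurrence.

        ``dstates`` is the gradient w.r.t. every per-position state (may be
        all-zero) and ``dfinal`` an extra gradient on the final state.
        Returns (dX, parameter-gradient dict).
        """
        W = self.params[f"{self.name}.W"]
        Uzr = self.params[f"{self.name}.Uzr"]
        Un = self.params[f"{self.name}.Un"]
        B, L, _ = X.shape
        h_size = self.hidden_size
        dW = np.zeros_like(W)
        dUzr = np.zeros_like(Uzr)
        dUn = np.zeros_like(Un)
        db = np.zeros(3 * h_size)
        dX = np.zeros_like(X)
        dh = np.zeros((B, h_size)) if dfinal is None else dfinal.copy()
        for t, h_prev, z, r, n, hUn, m in reversed(cache):
            dh = dh + dstates[:, t, :]
            dh_new = dh * m
            dh_prev = dh * (1.0 - m) + dh_new * z
            dz = dh_new * (h_prev - n)
            dn = dh_new * (1.0 - z)
            dan = dn * (1.0 - n * n)
            dr = dan * hUn
            dhUn = dan * r
            dUn += h_prev.T @ dhUn
            dh_prev += dhUn @ Un.T
            daz = dz * z * (1.0 - z)
            dar = dr * r * (1.0 - r)
            dzr = np.concatenate([daz, dar], axis=1)
            dUzr += h_prev.T @ dzr
            dh_prev += dzr @ Uzr.T
            da = np.concatenate([dzr, dan], axis=1)
            dW += X[:, t, :].T @ da
            db += da.sum(axis=0)
            dX[:, t, :] = da @ W.T
            dh = dh_prev
        grads = {f"{self.name}.W": dW, f"{self.name}.Uzr": dUzr,
                 f"{self.name}.Un": dUn, f"{self.name}.b": db}
        return dX, grads


def clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Scale all gradients in place so their global L2 norm is <= max_norm."""
    total = math.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
    return total


class Adam:
    """Adaptive-moment-estimation updates over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], learning_rate: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        correction = self.lr * math.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for key, grad in grads.items():
            m = self.m[key]
            v = self.v[key]
            m *= b1
            m += (1 - b1) * grad
            v *= b2
            v += (1 - b2) * grad * grad
            self.params[key] -= correction * m / (np.sqrt(v) + self.eps)
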