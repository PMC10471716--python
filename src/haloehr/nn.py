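"""Minimal NumPy neural-network primitives with explicit backward passes.

Each ``*_forward`` returns ``(output, cache)`` and the matching ``*_backward``
consumes the upstream gradient plus that cache.  Shapes follow the convention
(batch, sequence, features).  All passes are finite-difference-checked in the
test suite, which is the contract that matters here — there is no autodiff.
"""

from __future__ import annotations

import numpy as np

NEG_INF = -1e9  # additive attention mask value; avoids inf-inf NaNs


def linear_forward(x, W, b):
    return x @ W + b, (x, W)


def linear_backward(dy, cache):
    x, W = cache
    dx = dy @ W.T
    F_in, F_out = W.shape
    dW = x.reshape(-1, F_in).T @ dy.reshape(-1, F_out)
    db = dy.reshape(-1, F_out).sum(axis=0)
    return dx, dW, db


def relu_forward(x):
    y = np.maximum(x, 0.0)
    return y, (x > 0.0)


def relu_backward(dy, cache):
    return dy * cache


def sigmoid(x):
    # numerically stable two-sided form
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def log_sigmoid(x):
    """log(sigmoid(x)) computed stably."""
    return np.where(x >= 0, -np.log1p(np.exp(-np.abs(x))), x - np.log1p(np.exp(x)))


def layernorm_forward(x, g, b, eps: float = 1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv, g)


def layernorm_backward(dy, cache):
    xhat, inv, g = cache
    F = xhat.shape[-1]
    dg = (dy * xhat).reshape(-1, F).sum(axis=0)
    db = dy.reshape(-1, F).sum(axis=0)
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    return dx, dg, db


def softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def causal_attention_forward(x, Wqkv, bqkv, Wo, bo, n_heads: int):
    """Multi-head self-attention where position j attends to keys k <= j.

    Padding rows always sit at the end of a sequence, so the causal mask alone
    already keeps every scored position from seeing padding.
    """
    B, L, E = x.shape
    d = E // n_heads
    qkv, lin1_cache = linear_forward(x, Wqkv, bqkv)  # (B, L, 3E)
    qkv = qkv.reshape(B, L, 3, n_heads, d).transpose(2, 0, 3, 1, 4)
    q, k, v = qkv[0], qkv[1], qkv[2]  # each (B, h, L, d)
    scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(d)
    mask = np.triu(np.full((L, L), NEG_INF), k=1)
    att = softmax(scores + mask, axis=-1)  # (B, h, L, L)
    ctx = att @ v  # (B, h, L, d)
    merged = ctx.transpose(0, 2, 1, 3).reshape(B, L, E)
    y, lin2_cache = linear_forward(merged, Wo, bo)
    cache = (lin1_cache, lin2_cache, q, k, v, att, n_heads)
    return y, cache


def causal_attention_backward(dy, cache):
    lin1_cache, lin2_cache, q, k, v, att, n_heads = cache
    B, h, L, d = q.shape
    E = h * d
    dmerged, dWo, dbo = linear_backward(dy, lin2_cache)
    dctx = dmerged.reshape(B, L, h, d).transpose(0, 2, 1, 3)
    datt = dctx @ v.transpose(0, 1, 3, 2)
    dv = att.transpose(0, 1, 3, 2) @ dctx
    # softmax backward (rowwise over the last axis)
    dscores = att * (datt - (datt * att).sum(axis=-1, keepdims=True))
    dscores /= np.sqrt(d)
    dq = dscores @ k
    dk = dscores.transpose(0, 1, 3, 2) @ q
    dqkv = np.stack([dq, dk, dv])  # (3, B, h, L, d)
    dqkv = dqkv.transpose(1, 3, 0, 2, 4).reshape(B, L, 3 * E)
    dx, dWqkv, dbqkv = linear_backward(dqkv, lin1_cache)
    return dx, dWqkv, dbqkv, dWo, dbo


def masked_linear_forward(h, W, b, mask, final: bool):
    """One autoregressive masked dense layer: ``act(h (W o mask) + b)`` with
    ReLU on hidden layers and sigmoid applied downstream on the final layer
    (this function returns the final layer's pre-activation)."""
    Weff = W * mask
    z = h @ Weff + b
    if final:
        return z, (h, Weff, mask, None)
    y, rcache = relu_forward(z)
    return y, (h, Weff, mask, rcache)


def masked_linear_backward(dy, cache):
    h, Weff, mask, rcache = cache
    dz = dy if rcache is None else relu_backward(dy, rcache)
    dh = dz @ Weff.T
    F_in, F_out = Weff.shape
    dW = (h.reshape(-1, F_in).T @ dz.reshape(-1, F_out)) * mask
    db = dz.reshape(-1, F_out).sum(axis=0)
    return dh, dW, db


def global_norm(grads: dict) -> float:
    total = 0.0
    for g in grads.values():
        total += float(np.sum(g * g))
    return float(np.sqrt(total))


def clip_by_global_norm(grads: dict, max_norm: float) -> dict:
    norm = global_norm(grads)
    if max_norm and norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        return {k: g * scale for k, g in grads.items()}
    return grads


class Adam:
    """Plain Adam with bias correction; operates on dicts of ndarrays."""

    def __init__(self, params: dict, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for key, g in grads.items():
            m = self.m[key] = b1 * self.m[key] + (1 - b1) * g
            v = self.v[key] = b2 * self.v[key] + (1 - b2) * (g * g)
            params[key] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
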