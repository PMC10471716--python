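"""The hierarchical autoregressive model over binary visit sequences.

The model assigns an explicit likelihood to a record matrix
``R = [v_s, v_l, v_1..v_T, v_e]`` by factorizing it twice:

* a *visit-level* module — a stack of causal transformer decoder blocks —
  turns each row prefix into a history embedding, so row t's prediction
  conditions on all earlier rows;
* a *code-level* module — masked dense layers over the concatenation of the
  history embedding and the next row itself — factorizes each visit across its
  C binary codes in the fixed vocabulary order, so code i conditions on codes
  1..i-1 of the same visit.

A ``coarse_only`` mode drops the code-level conditioning and maps the history
embedding straight to per-code probabilities (codes conditionally independent
within a visit given the history); it is the ablation used to measure how much
the intra-visit factorization buys.

Everything is NumPy; gradients are written by hand (see ``nn.py``) and checked
against finite differences in the tests.  The masked-weight convention is
MADE-style: hidden masked layers use an upper-triangular mask *including* the
diagonal, the final masked layer uses a *strict* upper-triangular mask, which
gives maximal connectivity with provably zero self-leak (code i's probability
can never depend on code i itself).
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn

PROB_FLOOR = 1e-8  # probabilities clamped to [floor, 1-floor] before any log


@dataclass
class ModelConfig:
    C: int
    T_max: int
    n_emb: int = 128
    n_blocks: int = 2          # M: transformer decoder blocks
    n_heads: int = 4
    n_masked: int = 2          # N: masked dense layers in the code module
    coarse_only: bool = False
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.C <= 2:
            raise ValueError("vocabulary size must exceed the two special codes")
        if self.n_emb % self.n_heads:
            raise ValueError("n_emb must be divisible by n_heads")
        if self.n_blocks < 1 or self.n_masked < 1:
            raise ValueError("need at least one block and one masked layer")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def max_rows(self) -> int:
        """Matrix rows: T_max content visits plus start, label, and end."""
        return self.T_max + 3


def desk_config(C: int, T_max: int, **kw) -> ModelConfig:
    """Small single-CPU preset: 2 blocks, 128-wide, 4 heads, 2 masked layers."""
    return ModelConfig(C=C, T_max=T_max, n_emb=128, n_blocks=2, n_heads=4,
                       n_masked=2, **kw)


def scored_row_mask(lengths, n_pred_rows: int) -> np.ndarray:
    """Mask over prediction rows.  Prediction row k targets input row k+1;
    rows 1 (label) through T+2 (end) are scored, so k runs 0..length-2."""
    lengths = np.asarray(lengths, dtype=int)
    return (np.arange(n_pred_rows)[None, :] <= (lengths - 2)[:, None]).astype(float)


def offset_and_concat(H: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Pair history-through-row-k with row k+1: output row k is
    ``[H[k] || R[k+1]]`` for k = 0..L-2."""
    return np.concatenate([H[:, :-1, :], R[:, 1:, :]], axis=-1)


class HALOModel:
    """Model parameters plus forward/backward passes.

    ``params`` is a flat dict of float64 arrays; the two triangular masks are
    fixed buffers, never trained.
    """

    def __init__(self, config: ModelConfig, params: dict | None = None):
        self.config = config
        E, C = config.n_emb, config.C
        D = E + C
        # hidden masked layers: j <= k (diagonal kept); final layer: j < k (strict)
        self.mask_hidden = np.triu(np.ones((D, D)))
        self.mask_final = np.triu(np.ones((D, D)), k=1)
        self.params = params if params is not None else self._init_params()

    # -- initialization ----------------------------------------------------

    def _init_params(self) -> dict:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        E, C, D = cfg.n_emb, cfg.C, cfg.n_emb + cfg.C
        s = 0.02

        def normal(*shape, scale=s):
            return rng.normal(0.0, scale, size=shape)

        p = {
            "W_e": normal(C, E),
            "W_p": normal(cfg.max_rows, E, scale=0.01),
            "lnf.g": np.ones(E),
            "lnf.b": np.zeros(E),
        }
        for m in range(cfg.n_blocks):
            p[f"b{m}.ln1.g"] = np.ones(E)
            p[f"b{m}.ln1.b"] = np.zeros(E)
            p[f"b{m}.attn.Wqkv"] = normal(E, 3 * E)
            p[f"b{m}.attn.bqkv"] = np.zeros(3 * E)
            p[f"b{m}.attn.Wo"] = normal(E, E)
            p[f"b{m}.attn.bo"] = np.zeros(E)
            p[f"b{m}.ln2.g"] = np.ones(E)
            p[f"b{m}.ln2.b"] = np.zeros(E)
            p[f"b{m}.ff.W1"] = normal(E, 4 * E)
            p[f"b{m}.ff.b1"] = np.zeros(4 * E)
            p[f"b{m}.ff.W2"] = normal(4 * E, E)
            p[f"b{m}.ff.b2"] = np.zeros(E)
        if self.config.coarse_only:
            p["out.W"] = normal(E, C)
            p["out.b"] = np.zeros(C)
        else:
            for n in range(cfg.n_masked):
                p[f"ml{n}.W"] = normal(D, D)
                p[f"ml{n}.b"] = np.zeros(D)
        return p

    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    def copy_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    # -- forward -----------------------------------------------------------

    def _dropout_mask(self, shape, rng):
        rate = self.config.dropout
        if rng is None or rate == 0.0:
            return None
        return rng.binomial(1, 1.0 - rate, size=shape) / (1.0 - rate)

    def visit_level_forward(self, R: np.ndarray, train_rng=None):
        """Embed rows and run the causal decoder stack; returns the history
        matrix H (B, L, n_emb) and the caches needed for backward."""
        p = self.params
        B, L, C = R.shape
        if L > self.config.max_rows:
            raise ValueError(f"matrix has {L} rows > T_max+3 = {self.config.max_rows}")
        if C != self.config.C:
            raise ValueError(f"matrix has {C} codes, model expects {self.config.C}")
        H = R @ p["W_e"] + p["W_p"][:L]
        drop0 = self._dropout_mask(H.shape, train_rng)
        if drop0 is not None:
            H = H * drop0
        blocks = []
        for m in range(self.config.n_blocks):
            x = H
            h1, ln1c = nn.layernorm_forward(x, p[f"b{m}.ln1.g"], p[f"b{m}.ln1.b"])
            a, attnc = nn.causal_attention_forward(
                h1, p[f"b{m}.attn.Wqkv"], p[f"b{m}.attn.bqkv"],
                p[f"b{m}.attn.Wo"], p[f"b{m}.attn.bo"], self.config.n_heads)
            dropa = self._dropout_mask(a.shape, train_rng)
            if dropa is not None:
                a = a * dropa
            x = x + a
            h2, ln2c = nn.layernorm_forward(x, p[f"b{m}.ln2.g"], p[f"b{m}.ln2.b"])
            f1, ff1c = nn.linear_forward(h2, p[f"b{m}.ff.W1"], p[f"b{m}.ff.b1"])
            f2, reluc = nn.relu_forward(f1)
            f3, ff2c = nn.linear_forward(f2, p[f"b{m}.ff.W2"], p[f"b{m}.ff.b2"])
            dropf = self._dropout_mask(f3.shape, train_rng)
            if dropf is not None:
                f3 = f3 * dropf
            H = x + f3
            blocks.append((ln1c, attnc, dropa, ln2c, ff1c, reluc, ff2c, dropf))
        Hn, lnfc = nn.layernorm_forward(H, p["lnf.g"], p["lnf.b"])
        cache = (R, drop0, blocks, lnfc)
        return Hn, cache

    def _visit_level_backward(self, dH, cache, grads):
        p = self.params
        R, drop0, blocks, lnfc = cache
        dH, grads["lnf.g"], grads["lnf.b"] = nn.layernorm_backward(dH, lnfc)
        for m in reversed(range(self.config.n_blocks)):
            ln1c, attnc, dropa, ln2c, ff1c, reluc, ff2c, dropf = blocks[m]
            df3 = dH if dropf is None else dH * dropf
            df2, grads[f"b{m}.ff.W2"], grads[f"b{m}.ff.b2"] = nn.linear_backward(df3, ff2c)
            df1 = nn.relu_backward(df2, reluc)
            dh2, grads[f"b{m}.ff.W1"], grads[f"b{m}.ff.b1"] = nn.linear_backward(df1, ff1c)
            dx, grads[f"b{m}.ln2.g"], grads[f"b{m}.ln2.b"] = nn.layernorm_backward(dh2, ln2c)
            dx = dx + dH  # residual around the feed-forward
            da = dx if dropa is None else dx * dropa
            dh1, dWqkv, dbqkv, dWo, dbo = nn.causal_attention_backward(da, attnc)
            grads[f"b{m}.attn.Wqkv"], grads[f"b{m}.attn.bqkv"] = dWqkv, dbqkv
            grads[f"b{m}.attn.Wo"], grads[f"b{m}.attn.bo"] = dWo, dbo
            dH0, grads[f"b{m}.ln1.g"], grads[f"b{m}.ln1.b"] = nn.layernorm_backward(dh1, ln1c)
            dH = dH0 + dx  # residual around the attention
        if drop0 is not None:
            dH = dH * drop0
        B, L, C = R.shape
        grads["W_e"] = np.einsum("blc,ble->ce", R, dH)
        Wp_grad = np.zeros_like(p["W_p"])
        Wp_grad[:L] = dH.sum(axis=0)
        grads["W_p"] = Wp_grad

    def logits(self, R: np.ndarray, train_rng=None):
        """Pre-sigmoid code logits, shape (B, L-1, C); prediction row k targets
        input row k+1."""
        p = self.params
        H, vcache = self.visit_level_forward(R, train_rng)
        if self.config.coarse_only:
            z, outc = nn.linear_forward(H[:, :-1, :], p["out.W"], p["out.b"])
            return z, (vcache, [outc])
        Hp = offset_and_concat(H, R)
        mls = []
        h = Hp
        for n in range(self.config.n_masked):
            final = n == self.config.n_masked - 1
            mask = self.mask_final if final else self.mask_hidden
            h, c = nn.masked_linear_forward(h, p[f"ml{n}.W"], p[f"ml{n}.b"], mask, final)
            mls.append(c)
        return h[:, :, self.config.n_emb:], (vcache, mls)

    def code_probabilities(self, R: np.ndarray) -> np.ndarray:
        """O: probability of each code at each predicted row, clamped away from
        exact 0/1 so log-likelihoods stay finite."""
        z, _ = self.logits(R)
        return np.clip(nn.sigmoid(z), PROB_FLOOR, 1.0 - PROB_FLOOR)

    # -- likelihood & loss --------------------------------------------------

    def record_log_probability(self, R: np.ndarray, lengths) -> np.ndarray:
        """Per-record log P(R): Bernoulli log-mass summed over every scored
        prediction row (label through end) and all C codes."""
        R = np.atleast_3d(R)
        if R.ndim != 3:
            raise ValueError("R must be (B, L, C)")
        O = self.code_probabilities(R)
        target = R[:, 1:, :]
        mask = scored_row_mask(lengths, O.shape[1])
        cell = target * np.log(O) + (1.0 - target) * np.log1p(-O)
        return (cell * mask[:, :, None]).sum(axis=(1, 2))

    def loss_and_grads(self, R: np.ndarray, lengths, train_rng=None):
        """Masked mean BCE over scored cells plus gradients for every
        trainable parameter.  Masked-out weight entries receive exactly zero
        gradient because forward always uses ``W * mask``."""
        z, (vcache, mls) = self.logits(R, train_rng)
        target = R[:, 1:, :]
        mask = scored_row_mask(lengths, z.shape[1])
        n_cells = mask.sum() * self.config.C
        if n_cells == 0:
            raise ValueError("no scored cells; are all lengths < 2?")
        # stable BCE from logits: max(z,0) - z*t + log(1+exp(-|z|))
        cell = np.maximum(z, 0.0) - z * target + np.log1p(np.exp(-np.abs(z)))
        loss = float((cell * mask[:, :, None]).sum() / n_cells)
        dz = (nn.sigmoid(z) - target) * mask[:, :, None] / n_cells

        grads = {}
        p = self.params
        if self.config.coarse_only:
            dh, grads["out.W"], grads["out.b"] = nn.linear_backward(dz, mls[0])
            B, Lm1, E = dh.shape
            dH = np.zeros((B, Lm1 + 1, E))
            dH[:, :-1, :] = dh
        else:
            E = self.config.n_emb
            dhp = np.zeros(mls[-1][0].shape[:2] + (E + self.config.C,))
            dhp[:, :, E:] = dz
            for n in reversed(range(self.config.n_masked)):
                dhp, grads[f"ml{n}.W"], grads[f"ml{n}.b"] = nn.masked_linear_backward(
                    dhp, mls[n])
            B, Lm1, _ = dhp.shape
            dH = np.zeros((B, Lm1 + 1, E))
            dH[:, :-1, :] = dhp[:, :, :E]  # gradient w.r.t. R input branch unused
        self._visit_level_backward(dH, vcache, grads)
        return loss, grads


def masked_bce_loss(O: np.ndarray, R: np.ndarray, lengths) -> float:
    """Mean binary cross-entropy over scored (row, code) cells given
    probabilities ``O`` aligned with prediction rows of ``R``."""
    O = np.clip(O, PROB_FLOOR, 1.0 - PROB_FLOOR)
    target = R[:, 1:, :]
    mask = scored_row_mask(lengths, O.shape[1])
    n_cells = mask.sum() * R.shape[2]
    cell = -(target * np.log(O) + (1.0 - target) * np.log1p(-O))
    return float((cell * mask[:, :, None]).sum() / n_cells)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(path, model: HALOModel, vocab_hash: str = "") -> None:
    """Single-archive checkpoint: config, vocabulary hash, all tensors."""
    meta = json.dumps({"config": asdict(model.config), "vocab_hash": vocab_hash})
    arrays = {f"param::{k}": v for k, v in model.params.items()}
    buf = io.BytesIO()
    np.savez(buf, meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_checkpoint(path, expect_vocab_hash: str | None = None) -> HALOModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        params = {
            k[len("param::"):]: data[k] for k in data.files if k.startswith("param::")
        }
    if expect_vocab_hash is not None and meta["vocab_hash"] != expect_vocab_hash:
        raise ValueError(
            "checkpoint was trained with a different vocabulary "
            f"(hash {meta['vocab_hash'][:12]}... != {expect_vocab_hash[:12]}...)"
        )
    cfg = ModelConfig(**meta["config"])
    model = HALOModel(cfg, params=params)
    model.vocab_hash = meta["vocab_hash"]
    return model
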