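"""Autoregressive generation of synthetic patient records.

Rows are produced one at a time (start, label, content visits, end) and codes
within a row are sampled one at a time in the fixed vocabulary order, each as
a Bernoulli draw from the model's conditional probability given all previous
rows and the codes already sampled in the current row.

Structural constraints keep every emitted matrix a valid record matrix:

* the label row may only contain label codes (clamped exactly to the requested
  labels in conditional mode);
* content rows may not contain start or label codes;
* the end code may only fire in a row that is still empty, and it then closes
  the row — so the end row always carries exactly the end code, generation
  terminates, and decoding back to a patient record is lossless;
* gap-bucket codes are mutually exclusive within a row (a visit has one gap),
  and are suppressed in the first content visit (which has no preceding gap);
  lab buckets can optionally be made exclusive per variable too.

Constrained cells are *forced* rather than resampled: the sampler emits the
forced outcome and accrues its log-probability, so the accumulated log-prob of
a generated record equals ``record_log_probability`` of its re-encoded matrix
exactly.  A well-trained model puts negligible mass on the forbidden outcomes,
so forcing barely perturbs the learned distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import PROB_FLOOR, HALOModel
from .records import (
    GAP_VARIABLE,
    CodeVocabulary,
    PatientRecord,
    RecordMatrix,
    decode_record,
)
from . import nn


@dataclass
class GenerationRequest:
    n_records: int
    condition_labels: set | None = None
    seed: int = 0
    max_visits: int | None = None
    enforce_bucket_exclusivity: bool = False


FREE, FORCE_ZERO, FORCE_ONE = 0, 1, 2


class RecordSampler:
    """Binds a trained model to a vocabulary and draws records from it."""

    def __init__(self, model: HALOModel, vocab: CodeVocabulary, schemes=(),
                 use_incremental: bool = True):
        if model.config.C != vocab.size:
            raise ValueError("model and vocabulary disagree on C")
        self.model = model
        self.vocab = vocab
        self.schemes = tuple(schemes)
        self.use_incremental = use_incremental and not model.config.coarse_only \
            and model.config.n_masked == 2
        cfg = model.config
        self.kinds = np.array(vocab.kinds)
        self.label_ids = set(vocab.ids_of_kind("label").tolist())
        self.end_id = vocab.end_id
        self.start_id = vocab.start_id
        # per-variable bucket code groups (for exclusivity rules)
        self.var_groups = {}
        for sch in self.schemes:
            ids = [vocab.id_of(sch.bucket_code(k))
                   for k in range(1, sch.n_buckets + 1)]
            self.var_groups[sch.variable] = ids
        if not cfg.coarse_only:
            p = model.params
            self.W_effs = []
            for n in range(cfg.n_masked):
                final = n == cfg.n_masked - 1
                mask = model.mask_final if final else model.mask_hidden
                self.W_effs.append(p[f"ml{n}.W"] * mask)

    # -- probability machinery --------------------------------------------

    def _history_embedding(self, prefix: np.ndarray) -> np.ndarray:
        H, _ = self.model.visit_level_forward(prefix[None])
        return H[0, -1]

    def _row_prob_fn(self, prefix: np.ndarray):
        """Return p(i, row_so_far_hook) giving the conditional probability of
        code i for the next row; the hook is fed each sampled 1."""
        cfg = self.model.config
        E = cfg.n_emb
        h = self._history_embedding(prefix)
        if cfg.coarse_only:
            p_vec = nn.sigmoid(h @ self.model.params["out.W"]
                               + self.model.params["out.b"])
            p_vec = np.clip(p_vec, PROB_FLOOR, 1 - PROB_FLOOR)
            return (lambda i: float(p_vec[i])), (lambda i: None)
        if self.use_incremental:
            W1, W2 = self.W_effs
            b1 = self.model.params["ml0.b"]
            b2 = self.model.params["ml1.b"]
            z1 = h @ W1[:E] + b1
            r1 = np.maximum(z1, 0.0)

            def prob(i: int) -> float:
                col = E + i
                z2 = float(r1[:col] @ W2[:col, col] + b2[col])
                return float(np.clip(nn.sigmoid(np.array(z2)), PROB_FLOOR,
                                     1 - PROB_FLOOR))

            def set_one(i: int) -> None:
                col = E + i
                z1[col:] += W1[col, col:]
                r1[col:] = np.maximum(z1[col:], 0.0)

            return prob, set_one
        # generic fallback: full forward per code (any N, used to cross-check)
        row = np.zeros(cfg.C)

        def prob(i: int) -> float:
            R = np.vstack([prefix, row[None]])[None]
            O = self.model.code_probabilities(R)
            return float(O[0, -1, i])

        def set_one(i: int) -> None:
            row[i] = 1.0

        return prob, set_one

    # -- row sampling ------------------------------------------------------

    def sample_row(self, prefix: np.ndarray, rng: np.random.Generator,
                   policy: np.ndarray, end_requires_empty: bool = True,
                   exclusive_groups=()):
        """Sample the next row given ``prefix`` rows.  ``policy`` holds
        FREE/FORCE_ZERO/FORCE_ONE per code; returns (row, log_prob)."""
        C = self.model.config.C
        prob, set_one = self._row_prob_fn(prefix)
        policy = policy.copy()
        groups = [list(g) for g in exclusive_groups]
        row = np.zeros(C)
        logp = 0.0
        any_one = False
        ended = False
        for i in range(C):
            p = prob(i)
            act = policy[i]
            if ended:
                act = FORCE_ZERO  # the end code closes the row
            elif act == FREE and i == self.end_id and end_requires_empty and any_one:
                act = FORCE_ZERO
            if act == FORCE_ONE:
                outcome = 1
            elif act == FORCE_ZERO:
                outcome = 0
            else:
                outcome = int(rng.random() < p)
            logp += float(np.log(p)) if outcome else float(np.log1p(-p))
            if outcome:
                row[i] = 1.0
                any_one = True
                if i == self.end_id:
                    ended = True
                set_one(i)
                for g in groups:
                    if i in g:
                        for j in g:
                            if j != i:
                                policy[j] = FORCE_ZERO
        return row, logp

    def _label_policy(self, condition_labels):
        C = self.model.config.C
        policy = np.full(C, FORCE_ZERO, dtype=int)
        if condition_labels is None:
            for i in self.label_ids:
                policy[i] = FREE
        else:
            for name in condition_labels:
                i = self.vocab.id_of(name)
                if i not in self.label_ids:
                    raise ValueError(f"{name!r} is not a label code")
                policy[i] = FORCE_ONE
        return policy

    def _content_policy(self, first_visit: bool, exclusivity: bool):
        C = self.model.config.C
        policy = np.full(C, FREE, dtype=int)
        policy[self.start_id] = FORCE_ZERO
        for i in self.label_ids:
            policy[i] = FORCE_ZERO
        gap_ids = self.var_groups.get(GAP_VARIABLE, [])
        if first_visit:
            for i in gap_ids:
                policy[i] = FORCE_ZERO
        groups = [ids for var, ids in self.var_groups.items()
                  if var == GAP_VARIABLE or exclusivity]
        return policy, groups

    # -- record sampling ---------------------------------------------------

    def sample_record_matrix(self, rng: np.random.Generator,
                             condition_labels=None, max_visits=None,
                             enforce_bucket_exclusivity: bool = False):
        """Returns (RecordMatrix, log_prob, truncated)."""
        cfg = self.model.config
        max_visits = cfg.T_max if max_visits is None else min(max_visits, cfg.T_max)
        C = cfg.C
        start = np.zeros(C)
        start[self.start_id] = 1.0
        rows = [start]
        label_row, logp = self.sample_row(
            np.asarray(rows), rng, self._label_policy(condition_labels),
            end_requires_empty=False)
        rows.append(label_row)

        visits, truncated = 0, False
        ended = False
        while visits < max_visits:
            policy, groups = self._content_policy(
                first_visit=(visits == 0),
                exclusivity=enforce_bucket_exclusivity)
            row, lp = self.sample_row(np.asarray(rows), rng, policy,
                                      end_requires_empty=True,
                                      exclusive_groups=groups)
            logp += lp
            rows.append(row)
            if row[self.end_id]:
                ended = True
                break
            visits += 1
        if not ended:
            # record hit the visit cap: force the stop row, scoring it honestly
            policy = np.full(C, FORCE_ZERO, dtype=int)
            policy[self.end_id] = FORCE_ONE
            row, lp = self.sample_row(np.asarray(rows), rng, policy,
                                      end_requires_empty=False)
            logp += lp
            rows.append(row)
            truncated = True

        M = np.zeros((cfg.max_rows, C))
        M[:len(rows)] = np.asarray(rows)
        return RecordMatrix(M, visits), logp, truncated

    def sample_record(self, rng: np.random.Generator, patient_id: str = "synthetic",
                      condition_labels=None, max_visits=None,
                      enforce_bucket_exclusivity: bool = False):
        """Returns (PatientRecord, log_prob)."""
        rm, logp, truncated = self.sample_record_matrix(
            rng, condition_labels, max_visits, enforce_bucket_exclusivity)
        record = decode_record(rm, self.vocab, self.schemes, rng,
                               patient_id=patient_id)
        record.truncated = truncated
        return record, logp


def sample_visit(model: HALOModel, history: np.ndarray,
                 rng: np.random.Generator, vocab: CodeVocabulary | None = None):
    """Sample one unconstrained visit vector given ``history`` rows (the first
    of which must be a valid start row); returns (visit, log_prob)."""
    if vocab is None:
        # anonymous vocabulary: all codes free, no structural rules
        kinds = ["start", "end"] + ["medical"] * (model.config.C - 2)
        vocab = CodeVocabulary(
            ["<start>", "<end>"] + [f"c{i}" for i in range(model.config.C - 2)],
            kinds)
    sampler = RecordSampler(model, vocab)
    policy = np.full(model.config.C, FREE, dtype=int)
    policy[vocab.start_id] = FORCE_ZERO
    return sampler.sample_row(history, rng, policy, end_requires_empty=True)


def generate_dataset(model: HALOModel, vocab: CodeVocabulary,
                     request: GenerationRequest, schemes=(),
                     use_incremental: bool = True):
    """Draw ``n_records`` independent records; returns (records, log_probs).

    Each record gets its own child RNG stream spawned from the request seed,
    so output is reproducible and independent of batching.
    """
    sampler = RecordSampler(model, vocab, schemes, use_incremental)
    records, logps = [], []
    children = np.random.SeedSequence(request.seed).spawn(request.n_records)
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        rec, lp = sampler.sample_record(
            rng, patient_id=f"synthetic-{i}",
            condition_labels=request.condition_labels,
            max_visits=request.max_visits,
            enforce_bucket_exclusivity=request.enforce_bucket_exclusivity)
        records.append(rec)
        logps.append(lp)
    return records, np.asarray(logps)
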