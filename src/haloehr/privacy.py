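"""Membership-inference attacks against the generator and its synthetic data.

Both attacks receive a balanced set of training-member records (positives) and
held-out records (negatives) and must decide who was in the training set:

* the *dataset attack* scores each record by the minimum Hamming distance from
  its code-presence vector to any synthetic record's presence vector and
  predicts the closer half as members;
* the *model attack* scores each record by its log-probability under the
  trained model and predicts the higher-likelihood half as members.

Because exactly half the attack set is predicted positive by construction,
accuracy equals recall; a safe generator keeps both attacks near 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import HALOModel
from .records import CodeVocabulary
from .train import EncodedDataset


@dataclass
class AttackSet:
    """Equal-sized pools of member (training) and non-member records."""

    members: list
    non_members: list

    def __post_init__(self):
        if len(self.members) != len(self.non_members):
            raise ValueError("member and non-member pools must have equal size")

    @property
    def records(self):
        return list(self.members) + list(self.non_members)

    @property
    def labels(self) -> np.ndarray:
        return np.concatenate([
            np.ones(len(self.members), dtype=int),
            np.zeros(len(self.non_members), dtype=int),
        ])


def make_attack_set(train_records, holdout_records, n_per_side: int,
                    seed: int = 0) -> AttackSet:
    if n_per_side > min(len(train_records), len(holdout_records)):
        raise ValueError("not enough records to build the attack set")
    rng = np.random.default_rng(seed)
    m = rng.choice(len(train_records), size=n_per_side, replace=False)
    h = rng.choice(len(holdout_records), size=n_per_side, replace=False)
    return AttackSet([train_records[i] for i in m],
                     [holdout_records[i] for i in h])


def presence_vector(record, vocab: CodeVocabulary) -> np.ndarray:
    """Binary length-C summary: 1 iff the code appears in any content visit
    (invariant to visit order; special codes never fire)."""
    v = np.zeros(vocab.size, dtype=np.int8)
    for visit in record.visits:
        for c in visit.codes:
            v[vocab.id_of(c)] = 1
    return v


def hamming(u: np.ndarray, v: np.ndarray) -> int:
    """Count of differing coordinates (= Manhattan distance on binaries)."""
    u, v = np.asarray(u), np.asarray(v)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    return int(np.sum(u != v))


def _half_split_metrics(scores: np.ndarray, labels: np.ndarray,
                        low_is_positive: bool):
    """Predict exactly the lower (or upper) half as members, stable order for
    ties, and report (accuracy, precision, recall)."""
    n = len(scores)
    order = np.argsort(scores, kind="stable")
    if not low_is_positive:
        order = np.argsort(-scores, kind="stable")
    predicted = np.zeros(n, dtype=int)
    predicted[order[: n // 2]] = 1
    tp = int(np.sum((predicted == 1) & (labels == 1)))
    fp = int(np.sum((predicted == 1) & (labels == 0)))
    fn = int(np.sum((predicted == 0) & (labels == 1)))
    accuracy = float(np.mean(predicted == labels))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return {"accuracy": accuracy, "precision": float(precision),
            "recall": float(recall), "n": n}


def min_hamming_scores(records, synthetic_records,
                       vocab: CodeVocabulary) -> np.ndarray:
    """Distance from each record to its nearest synthetic neighbour.

    Uses |a| + |b| - 2 a.b to get all pairwise Hamming distances in one
    matrix product.
    """
    if not synthetic_records:
        raise ValueError("synthetic dataset is empty")
    A = np.stack([presence_vector(r, vocab) for r in records]).astype(np.float64)
    B = np.stack([presence_vector(r, vocab) for r in synthetic_records]).astype(np.float64)
    d = A.sum(1)[:, None] + B.sum(1)[None, :] - 2.0 * (A @ B.T)
    return d.min(axis=1)


def dataset_attack(attack_set: AttackSet, synthetic_records,
                   vocab: CodeVocabulary) -> dict:
    """Nearest-synthetic-record distance attack."""
    scores = min_hamming_scores(attack_set.records, synthetic_records, vocab)
    return _half_split_metrics(scores, attack_set.labels, low_is_positive=True)


def model_attack(attack_set: AttackSet, model: HALOModel,
                 vocab: CodeVocabulary, schemes=(),
                 normalize_per_code: bool = False) -> dict:
    """Model log-likelihood attack; raw log-probability by default, with an
    optional per-present-code normalization."""
    data = EncodedDataset.from_records(attack_set.records, vocab, schemes,
                                       t_max=model.config.T_max)
    scores = np.concatenate([
        model.record_log_probability(X, ln)
        for X, ln in data.batches(64)
    ])
    if normalize_per_code:
        ones = data.matrices[:, 1:, :].sum(axis=(1, 2))
        scores = scores / np.maximum(ones, 1.0)
    return _half_split_metrics(scores, attack_set.labels, low_is_positive=False)
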