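"""Downstream-utility experiments: phenotype classification from synthetic vs
real records, and rare-label augmentation with conditionally generated data.

The classifier is a bidirectional recurrent sequence encoder (tanh RNN cells,
one layer each direction) over per-visit multi-hot vectors, with a single
dense head on the concatenated final states.  Label codes are removed from the
input — they are the prediction target.  Identical hyperparameters are used
for every experiment arm so comparisons isolate the training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .records import CodeVocabulary


@dataclass
class TaskSpec:
    """One balanced phenotype-classification task."""

    label: str
    n_train: int = 2500
    n_valid: int = 250
    n_test: int = 500
    seed: int = 0

    def __post_init__(self):
        for n in (self.n_train, self.n_valid, self.n_test):
            if n < 2 or n % 2:
                raise ValueError("split sizes must be positive and even (50-50 balance)")


@dataclass
class ClassifierConfig:
    hidden: int = 128
    epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 32
    clip_norm: float = 1.0
    seed: int = 0


# ---------------------------------------------------------------------------
# Task construction
# ---------------------------------------------------------------------------


def _split_by_label(dataset, label):
    pos = [r for r in dataset if label in r.labels]
    neg = [r for r in dataset if label not in r.labels]
    return pos, neg


def _draw_balanced(pos, neg, n_pos, n_neg, rng):
    if len(pos) < n_pos:
        raise ValueError(f"need {n_pos} positive records, only {len(pos)} available")
    if len(neg) < n_neg:
        raise ValueError(f"need {n_neg} negative records, only {len(neg)} available")
    pi = rng.choice(len(pos), size=n_pos, replace=False)
    ni = rng.choice(len(neg), size=n_neg, replace=False)
    records = [pos[i] for i in pi] + [neg[i] for i in ni]
    labels = np.array([1] * n_pos + [0] * n_neg)
    return records, labels


def build_balanced_task(dataset, task: TaskSpec):
    """Draw exactly 50-50 balanced, disjoint (train, valid) splits without
    replacement; deterministic under the task seed."""
    rng = np.random.default_rng(task.seed)
    pos, neg = _split_by_label(dataset, task.label)
    need_pos = (task.n_train + task.n_valid) // 2
    need_neg = need_pos
    if len(pos) < need_pos:
        raise ValueError(
            f"task {task.label!r} needs {need_pos} positives, only {len(pos)} available")
    if len(neg) < need_neg:
        raise ValueError(
            f"task {task.label!r} needs {need_neg} negatives, only {len(neg)} available")
    pi = rng.permutation(len(pos))[:need_pos]
    ni = rng.permutation(len(neg))[:need_neg]
    htr = task.n_train // 2
    train = [pos[i] for i in pi[:htr]] + [neg[i] for i in ni[:htr]]
    y_train = np.array([1] * htr + [0] * htr)
    valid = [pos[i] for i in pi[htr:]] + [neg[i] for i in ni[htr:]]
    y_valid = np.array([1] * (need_pos - htr) + [0] * (need_neg - htr))
    return (train, y_train), (valid, y_valid)


def build_real_test(real_test_pool, task: TaskSpec):
    """Balanced test split drawn from held-out real records only."""
    rng = np.random.default_rng(task.seed + 1)
    pos, neg = _split_by_label(real_test_pool, task.label)
    return _draw_balanced(pos, neg, task.n_test // 2, task.n_test // 2, rng)


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------


def featurize(records, vocab: CodeVocabulary):
    """Per-record sequences of multi-hot visit vectors with label codes (the
    target) removed; zero-visit records become a single all-zero step."""
    label_ids = set(vocab.ids_of_kind("label").tolist())
    seqs = []
    for r in records:
        T = max(len(r.visits), 1)
        X = np.zeros((T, vocab.size))
        for t, v in enumerate(r.visits):
            for c in v.codes:
                i = vocab.id_of(c)
                if i not in label_ids:
                    X[t, i] = 1.0
        seqs.append(X)
    return seqs


def _pad(seqs):
    B = len(seqs)
    T = max(s.shape[0] for s in seqs)
    C = seqs[0].shape[1]
    X = np.zeros((B, T, C))
    lengths = np.zeros(B, dtype=int)
    for i, s in enumerate(seqs):
        X[i, : s.shape[0]] = s
        lengths[i] = s.shape[0]
    return X, lengths


# ---------------------------------------------------------------------------
# Bidirectional recurrent classifier
# ---------------------------------------------------------------------------


class BiRNNClassifier:
    """Bidirectional tanh-RNN encoder + single dense head, trained with Adam
    on BCE; hand-written BPTT (no autodiff in this stack)."""

    def __init__(self, n_inputs: int, config: ClassifierConfig = ClassifierConfig()):
        self.config = config
        rng = np.random.default_rng(config.seed)
        H = config.hidden
        s_in, s_h = 0.1, 1.0 / np.sqrt(H)
        self.params = {}
        for d in ("f", "b"):
            self.params[f"Wx{d}"] = rng.normal(0, s_in, (n_inputs, H))
            self.params[f"Wh{d}"] = rng.normal(0, s_h, (H, H))
            self.params[f"b{d}"] = np.zeros(H)
        self.params["w"] = rng.normal(0, 0.1, 2 * H)
        self.params["b_out"] = np.zeros(1)

    # one direction over a (B, T, C) batch with carry-through masking past
    # each sequence's end, so the final state is the state at its last visit
    def _run_direction(self, X, lengths, d):
        p = self.params
        B, T, C = X.shape
        H = self.config.hidden
        h = np.zeros((B, H))
        states, acts, masks = [], [], []
        for t in range(T):
            m = (lengths > t).astype(float)[:, None]
            z = X[:, t] @ p[f"Wx{d}"] + h @ p[f"Wh{d}"] + p[f"b{d}"]
            a = np.tanh(z)
            h_new = m * a + (1 - m) * h
            states.append(h)
            acts.append(a)
            masks.append(m)
            h = h_new
        return h, (X, states, acts, masks, d)

    def _direction_backward(self, dh, cache, grads):
        p = self.params
        X, states, acts, masks, d = cache
        dWx = np.zeros_like(p[f"Wx{d}"])
        dWh = np.zeros_like(p[f"Wh{d}"])
        db = np.zeros_like(p[f"b{d}"])
        for t in reversed(range(len(acts))):
            m, a, h_prev = masks[t], acts[t], states[t]
            da = dh * m
            dz = da * (1 - a * a)
            dWx += X[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh = dz @ p[f"Wh{d}"].T + dh * (1 - m)
        grads[f"Wx{d}"], grads[f"Wh{d}"], grads[f"b{d}"] = dWx, dWh, db

    def _reverse(self, X, lengths):
        Xr = np.zeros_like(X)
        for i, L in enumerate(lengths):
            Xr[i, :L] = X[i, :L][::-1]
        return Xr

    def scores(self, seqs) -> np.ndarray:
        """Sigmoid scores (probability of the positive label) per record."""
        X, lengths = _pad(seqs)
        hf, _ = self._run_direction(X, lengths, "f")
        hb, _ = self._run_direction(self._reverse(X, lengths), lengths, "b")
        rep = np.concatenate([hf, hb], axis=1)
        logit = rep @ self.params["w"] + self.params["b_out"]
        return nn.sigmoid(logit)

    def _loss_and_grads(self, X, lengths, y):
        p = self.params
        hf, cf = self._run_direction(X, lengths, "f")
        hb, cb = self._run_direction(self._reverse(X, lengths), lengths, "b")
        rep = np.concatenate([hf, hb], axis=1)
        logit = rep @ p["w"] + p["b_out"]
        loss = float(np.mean(
            np.maximum(logit, 0) - logit * y + np.log1p(np.exp(-np.abs(logit)))))
        dlogit = (nn.sigmoid(logit) - y) / len(y)
        grads = {
            "w": rep.T @ dlogit,
            "b_out": np.array([dlogit.sum()]),
        }
        drep = dlogit[:, None] * p["w"][None, :]
        H = self.config.hidden
        self._direction_backward(drep[:, :H], cf, grads)
        self._direction_backward(drep[:, H:], cb, grads)
        return loss, grads

    def fit(self, train_seqs, y_train, valid_seqs, y_valid):
        """Train with Adam; keep the epoch with best validation accuracy."""
        y_train = np.asarray(y_train, dtype=float)
        if len(np.unique(y_train)) < 2:
            raise ValueError("training set contains a single class")
        cfg = self.config
        opt = nn.Adam(self.params, lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 1)
        best_acc, best_params = -1.0, {k: v.copy() for k, v in self.params.items()}
        history = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(train_seqs))
            for start in range(0, len(order), cfg.batch_size):
                sel = order[start:start + cfg.batch_size]
                X, lengths = _pad([train_seqs[i] for i in sel])
                loss, grads = self._loss_and_grads(X, lengths, y_train[sel])
                if not np.isfinite(loss):
                    raise FloatingPointError(f"non-finite classifier loss at epoch {epoch}")
                grads = nn.clip_by_global_norm(grads, cfg.clip_norm)
                opt.step(self.params, grads)
            acc = accuracy(self.scores(valid_seqs), y_valid)
            history.append({"epoch": epoch, "valid_accuracy": acc})
            if acc > best_acc:
                best_acc = acc
                best_params = {k: v.copy() for k, v in self.params.items()}
        self.params = best_params
        return history


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def accuracy(scores, y, threshold: float = 0.5) -> float:
    return float(np.mean((np.asarray(scores) >= threshold) == (np.asarray(y) == 1)))


def f1_score(scores, y, threshold: float = 0.5) -> float:
    pred = np.asarray(scores) >= threshold
    truth = np.asarray(y) == 1
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0


def auroc(scores, y) -> float:
    """Rank-statistic AUROC (Mann-Whitney with midranks for ties)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y) == 1
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    order = np.argsort(scores)
    ranks = np.empty(len(scores), dtype=float)
    ranks[order] = np.arange(1, len(scores) + 1)
    # midranks for ties
    for s in np.unique(scores):
        tie = scores == s
        if tie.sum() > 1:
            ranks[tie] = ranks[tie].mean()
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def bce(scores, y) -> float:
    p = np.clip(np.asarray(scores, dtype=float), 1e-8, 1 - 1e-8)
    y = np.asarray(y, dtype=float)
    return float(np.mean(-(y * np.log(p) + (1 - y) * np.log1p(-p))))


def evaluate_classifier(clf: BiRNNClassifier, test_seqs, y_test) -> dict:
    scores = clf.scores(test_seqs)
    return {
        "bce": bce(scores, y_test),
        "accuracy": accuracy(scores, y_test),
        "f1": f1_score(scores, y_test),
        "auroc": auroc(scores, y_test),
    }


def train_phenotype_classifier(train, valid, vocab: CodeVocabulary,
                               config: ClassifierConfig = ClassifierConfig()):
    """Fit the recurrent classifier on ((records, y), (records, y)) splits."""
    (tr_recs, y_tr), (va_recs, y_va) = train, valid
    clf = BiRNNClassifier(vocab.size, config)
    clf.fit(featurize(tr_recs, vocab), y_tr, featurize(va_recs, vocab), y_va)
    return clf


# ---------------------------------------------------------------------------
# Rare-condition augmentation experiment
# ---------------------------------------------------------------------------


@dataclass
class RareDiseaseSpec:
    """Scaled rare-label augmentation design: an imbalanced pool of n_negative
    negatives and n_positive (rare) positives, balanced either with
    conditionally generated synthetic positives or with real positives."""

    label: str
    n_negative: int = 1000
    n_positive: int = 20
    n_valid: int = 100
    n_test: int = 400
    seed: int = 0


def rare_disease_experiment(real_train_pool, real_test_pool, spec: RareDiseaseSpec,
                            synthetic_positive_generator,
                            classifier_config: ClassifierConfig = ClassifierConfig(),
                            vocab: CodeVocabulary = None) -> dict:
    """Train identical classifiers on three arms — imbalanced, synthetically
    balanced, real-balanced — and evaluate all on one shared real test set.

    ``synthetic_positive_generator(n)`` must return n records carrying the
    rare label (conditional generation from the trained model).
    """
    rng = np.random.default_rng(spec.seed)
    pos, neg = _split_by_label(real_train_pool, spec.label)
    n_fill = spec.n_negative - spec.n_positive
    need_pos = spec.n_negative + spec.n_valid // 2  # real-balanced arm + valid
    if len(pos) < need_pos:
        raise ValueError(
            f"rare-label pool needs {need_pos} positives, only {len(pos)} available")
    if len(neg) < spec.n_negative + spec.n_valid // 2:
        raise ValueError("not enough negative records for the experiment")

    pi = rng.permutation(len(pos))
    ni = rng.permutation(len(neg))
    rare_pos = [pos[i] for i in pi[: spec.n_positive]]
    full_pos = [pos[i] for i in pi[: spec.n_negative]]
    negatives = [neg[i] for i in ni[: spec.n_negative]]
    va_pos = [pos[i] for i in pi[spec.n_negative: spec.n_negative + spec.n_valid // 2]]
    va_neg = [neg[i] for i in ni[spec.n_negative: spec.n_negative + spec.n_valid // 2]]
    valid = (va_pos + va_neg,
             np.array([1] * len(va_pos) + [0] * len(va_neg)))

    synth_pos = list(synthetic_positive_generator(n_fill))
    for r in synth_pos:
        if spec.label not in r.labels:
            raise ValueError("generator produced a record without the rare label")

    test_task = TaskSpec(spec.label, n_test=spec.n_test, seed=spec.seed)
    test_recs, y_test = build_real_test(real_test_pool, test_task)
    test_seqs = featurize(test_recs, vocab)

    arms = {
        "imbalanced": (negatives + rare_pos,
                       np.array([0] * len(negatives) + [1] * len(rare_pos))),
        "halo_balanced": (negatives + rare_pos + synth_pos,
                          np.array([0] * len(negatives)
                                   + [1] * (len(rare_pos) + len(synth_pos)))),
        "real_balanced": (negatives + full_pos,
                          np.array([0] * len(negatives) + [1] * len(full_pos))),
    }
    results = {}
    for arm, (recs, y) in arms.items():
        clf = train_phenotype_classifier((recs, y), valid, vocab,
                                         replace(classifier_config))
        results[arm] = evaluate_classifier(clf, test_seqs, y_test)
    return results
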