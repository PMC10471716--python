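"""Statistical evaluation: held-out modeling metrics, perplexity per present
code, unigram/bigram code-probability tables with R^2 agreement, aggregate
shape statistics, and continuous-variable summaries.

Probability conventions (visit-level normalization):

* ``unigram[c]``  = #content visits containing c / #content visits
* ``same_visit_bigram[(a,b)]`` = #visits containing both a and b / #visits
  (keys stored with a < b; symmetric by construction)
* ``sequential_bigram[(a,b)]`` = #consecutive visit pairs with a in visit t
  and b in visit t+1 / #consecutive pairs (ordered; need not be symmetric)

Start/end/label codes are never counted; bucket codes for gaps and labs are
counted as codes when schemes are supplied.  R^2 between two tables is the
squared Pearson correlation over the union of keys observed in either table
(absent keys count as probability zero) — restricting to observed keys avoids
the astronomically many structurally-zero pairs inflating the correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .model import HALOModel, masked_bce_loss, scored_row_mask
from .records import GAP_VARIABLE, discretize_value
from .train import EncodedDataset


@dataclass
class ProbabilityTable:
    unigram: dict = field(default_factory=dict)
    same_visit_bigram: dict = field(default_factory=dict)
    sequential_bigram: dict = field(default_factory=dict)
    n_visits: int = 0
    n_consecutive_pairs: int = 0


def _visit_code_sets(record, schemes):
    """Effective code set per visit: medical codes plus bucket codes derived
    from the visit's labs and gap."""
    by_var = {s.variable: s for s in schemes}
    out = []
    for t, v in enumerate(record.visits):
        codes = set(v.codes)
        for name, value in v.labs:
            sch = by_var.get(name)
            if sch is not None:
                codes.add(sch.bucket_code(discretize_value(value, sch)))
        if v.gap_days is not None and t > 0 and GAP_VARIABLE in by_var:
            sch = by_var[GAP_VARIABLE]
            codes.add(sch.bucket_code(discretize_value(v.gap_days, sch)))
        out.append(codes)
    return out


def probability_tables(dataset, vocab=None, schemes=()) -> ProbabilityTable:
    """Count visit-level code probabilities over a dataset (sparsely)."""
    uni, same, seq = {}, {}, {}
    n_visits = n_pairs = 0
    for record in dataset:
        sets = _visit_code_sets(record, schemes)
        for codes in sets:
            n_visits += 1
            for c in codes:
                uni[c] = uni.get(c, 0) + 1
            for a, b in combinations(sorted(codes), 2):
                same[(a, b)] = same.get((a, b), 0) + 1
        for cur, nxt in zip(sets, sets[1:]):
            n_pairs += 1
            for a in cur:
                for b in nxt:
                    seq[(a, b)] = seq.get((a, b), 0) + 1
    if n_visits == 0:
        raise ValueError("dataset contains no content visits")
    table = ProbabilityTable(
        unigram={c: k / n_visits for c, k in uni.items()},
        same_visit_bigram={k: v / n_visits for k, v in same.items()},
        sequential_bigram={} if n_pairs == 0
        else {k: v / n_pairs for k, v in seq.items()},
        n_visits=n_visits,
        n_consecutive_pairs=n_pairs,
    )
    return table


def r2_between(table_real: ProbabilityTable, table_synth: ProbabilityTable,
               which: str) -> float:
    """Squared Pearson correlation between two tables' probabilities over the
    union of their observed keys."""
    a = getattr(table_real, which)
    b = getattr(table_synth, which)
    keys = sorted(set(a) | set(b))
    if len(keys) < 2:
        raise ValueError(f"need at least 2 {which} keys, got {len(keys)}")
    x = np.array([a.get(k, 0.0) for k in keys])
    y = np.array([b.get(k, 0.0) for k in keys])
    if x.std() == 0 or y.std() == 0:
        raise ValueError(f"{which} probabilities are constant; R^2 undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def export_table_tsv(path, table_real: ProbabilityTable,
                     table_synth: ProbabilityTable, which: str) -> None:
    a, b = getattr(table_real, which), getattr(table_synth, which)
    keys = sorted(set(a) | set(b))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("codes\treal_p\tsynth_p\n")
        for k in keys:
            name = k if isinstance(k, str) else "|".join(k)
            fh.write(f"{name}\t{a.get(k, 0.0):.8g}\t{b.get(k, 0.0):.8g}\n")


# ---------------------------------------------------------------------------
# Model-based metrics
# ---------------------------------------------------------------------------


def count_present_codes(data: EncodedDataset) -> int:
    """Number of 1-entries over all scored rows (label through end)."""
    mask = scored_row_mask(data.lengths, data.matrices.shape[1] - 1)
    return int((data.matrices[:, 1:, :] * mask[:, :, None]).sum())


def perplexity_per_code(model: HALOModel, data: EncodedDataset,
                        batch_size: int = 64) -> float:
    """PP = exp(-(sum of record log-likelihoods) / N) with N the count of
    present codes; computed by summing log-probabilities, never products."""
    N = count_present_codes(data)
    if N == 0:
        raise ValueError("dataset has no present codes; perplexity undefined")
    total = 0.0
    for X, ln in data.batches(batch_size):
        total += float(model.record_log_probability(X, ln).sum())
    return float(np.exp(-total / N))


def test_modeling_metrics(model: HALOModel, data: EncodedDataset,
                          batch_size: int = 64, threshold: float = 0.5):
    """Teacher-forced (bce, f1): masked mean BCE over scored cells and
    micro-averaged F1 of thresholded probabilities against the true codes."""
    tp = fp = fn = 0
    bce_sum, cells = 0.0, 0
    for X, ln in data.batches(batch_size):
        O = model.code_probabilities(X)
        mask = scored_row_mask(ln, O.shape[1])[:, :, None]
        target = X[:, 1:, :]
        pred = (O >= threshold) & (mask > 0)
        truth = (target > 0) & (mask > 0)
        tp += int(np.sum(pred & truth))
        fp += int(np.sum(pred & ~truth))
        fn += int(np.sum(~pred & truth))
        n = float(mask.sum() * X.shape[2])
        bce_sum += masked_bce_loss(O, X, ln) * n
        cells += n
    bce = bce_sum / cells
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return float(bce), float(f1)


# ---------------------------------------------------------------------------
# Shape and continuous-variable statistics
# ---------------------------------------------------------------------------


def aggregate_stats(dataset, schemes=()) -> dict:
    """Record/visit-length means and population stds plus label prevalences.
    Visit length counts medical codes and (when schemes are given) bucket
    codes; special codes never appear inside visits."""
    rec_lens, visit_lens = [], []
    label_counts, n_records = {}, 0
    for record in dataset:
        n_records += 1
        rec_lens.append(len(record.visits))
        for codes in _visit_code_sets(record, schemes):
            visit_lens.append(len(codes))
        for lab in record.labels:
            label_counts[lab] = label_counts.get(lab, 0) + 1
    rec = np.asarray(rec_lens, dtype=float)
    vis = np.asarray(visit_lens, dtype=float)
    return {
        "n_records": n_records,
        "record_length_mean": float(rec.mean()) if rec.size else 0.0,
        "record_length_std": float(rec.std()) if rec.size else 0.0,
        "visit_length_mean": float(vis.mean()) if vis.size else 0.0,
        "visit_length_std": float(vis.std()) if vis.size else 0.0,
        "label_prevalence": {k: v / n_records for k, v in sorted(label_counts.items())},
    }


def continuous_stats(dataset, schemes) -> dict:
    """Gap density (per-bucket histogram, mean/std, by visit number) and per
    lab presence probability plus conditional mean of present values."""
    by_var = {s.variable: s for s in schemes}
    gaps, gaps_by_visit = [], {}
    lab_values = {s.variable: [] for s in schemes if s.variable != GAP_VARIABLE}
    lab_present = {name: 0 for name in lab_values}
    n_visits = 0
    for record in dataset:
        for t, v in enumerate(record.visits):
            n_visits += 1
            if v.gap_days is not None and t > 0:
                gaps.append(v.gap_days)
                gaps_by_visit.setdefault(t + 1, []).append(v.gap_days)
            seen = set()
            for name, value in v.labs:
                if name not in lab_values:
                    raise ValueError(f"lab {name!r} has no bucket scheme")
                lab_values[name].append(value)
                seen.add(name)
            for name in seen:
                lab_present[name] += 1
    out = {"n_visits": n_visits}
    if GAP_VARIABLE in by_var and gaps:
        sch = by_var[GAP_VARIABLE]
        g = np.asarray(gaps)
        hist = np.zeros(sch.n_buckets)
        for x in gaps:
            hist[discretize_value(x, sch) - 1] += 1
        out["gap"] = {
            "mean": float(g.mean()),
            "std": float(g.std()),
            "bucket_density": (hist / hist.sum()).tolist(),
            "mean_by_visit_number": {
                t: float(np.mean(vals)) for t, vals in sorted(gaps_by_visit.items())
            },
        }
    out["labs"] = {}
    for name, values in lab_values.items():
        entry = {"presence_prob": lab_present[name] / n_visits if n_visits else 0.0}
        entry["conditional_mean"] = float(np.mean(values)) if values else None
        out["labs"][name] = entry
    return out


def evaluation_report(model: HALOModel, test_data: EncodedDataset,
                      real_records, synth_records, schemes=()) -> dict:
    """Assemble the full fidelity report (held-out metrics + table R^2s +
    shape statistics) as a JSON-serializable dict."""
    bce, f1 = test_modeling_metrics(model, test_data)
    pp = perplexity_per_code(model, test_data)
    t_real = probability_tables(real_records, schemes=schemes)
    t_synth = probability_tables(synth_records, schemes=schemes)
    report = {
        "test_bce": bce,
        "test_f1": f1,
        "perplexity_per_code": pp,
        "r2_unigram": r2_between(t_real, t_synth, "unigram"),
        "r2_same_visit_bigram": r2_between(t_real, t_synth, "same_visit_bigram"),
        "r2_sequential_bigram": r2_between(t_real, t_synth, "sequential_bigram"),
        "real_stats": aggregate_stats(real_records, schemes),
        "synthetic_stats": aggregate_stats(synth_records, schemes),
    }
    if schemes:
        report["real_continuous"] = continuous_stats(real_records, schemes)
        report["synthetic_continuous"] = continuous_stats(synth_records, schemes)
    return report
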