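"""The desk-scale reference study: one simulated cohort, trained full and
coarse generators, and the complete fidelity/utility/privacy read-outs.

This is the single-CPU analogue of the full evaluation protocol: simulate the
ground-truth cohort, train the generator (and its visit-level-only ablation)
with validation-selected checkpoints, generate synthetic data, and measure
distribution recovery, the hierarchy advantage, downstream utility, and
membership-inference resistance.  All randomness derives from one study seed
through named substreams, so a study is exactly reproducible.

Problem sizes (2000-record cohort, C = 106, T_max = 10, 50 epochs) are chosen
so the full study runs in minutes on one CPU while leaving every phenomenon
measurable.  The desk learning rate is 1e-3: with ~1/400th of a realistic
cohort, the reference setup's 1e-4 undertrains badly in 50 epochs, and 1e-3
minimizes validation loss.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .fidelity import (
    perplexity_per_code,
    probability_tables,
    r2_between,
    test_modeling_metrics,
)
from .model import HALOModel, ModelConfig
from .privacy import dataset_attack, make_attack_set, model_attack
from .records import build_vocabulary, encode_record
from .sample import GenerationRequest, RecordSampler, generate_dataset
from .simulate import desk_config, ground_truth_tables, simulate_cohort
from .train import EncodedDataset, TrainConfig, make_splits, train_model

DESK_N_RECORDS = 2000
DESK_EPOCHS = 50
DESK_LR = 1e-3


def substream(seed: int, name: str) -> int:
    """Stable named child seed below 2**31."""
    ss = np.random.SeedSequence([seed, zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class DeskStudy:
    seed: int
    config: object
    records: list
    vocab: object
    train_records: list
    val_records: list
    test_records: list
    train_data: EncodedDataset
    test_data: EncodedDataset
    model_full: HALOModel
    model_coarse: HALOModel
    synthetic: list
    history_full: list = field(default_factory=list)
    history_coarse: list = field(default_factory=list)


def run_desk_study(seed: int = 0, n_records: int = DESK_N_RECORDS,
                   epochs: int = DESK_EPOCHS, verbose: bool = False) -> DeskStudy:
    """Simulate, train full + coarse generators, and generate a synthetic
    dataset the size of the training split."""
    config = desk_config()
    records = simulate_cohort(config, n_records, seed=substream(seed, "cohort"))
    vocab = build_vocabulary(records, config.schemes, seed=substream(seed, "vocab"))
    train_recs, val_recs, test_recs = make_splits(records,
                                                  seed=substream(seed, "split"))
    enc = lambda rs: EncodedDataset.from_records(rs, vocab, config.schemes,
                                                 t_max=config.max_visits)
    dtr, dva, dte = enc(train_recs), enc(val_recs), enc(test_recs)
    tcfg = TrainConfig(learning_rate=DESK_LR, epochs=epochs,
                       seed=substream(seed, "batches"))
    model_full, hist_full = train_model(
        dtr, dva,
        ModelConfig(C=vocab.size, T_max=config.max_visits,
                    seed=substream(seed, "init")),
        tcfg, verbose=verbose)
    model_coarse, hist_coarse = train_model(
        dtr, dva,
        ModelConfig(C=vocab.size, T_max=config.max_visits, coarse_only=True,
                    seed=substream(seed, "init-coarse")),
        tcfg, verbose=verbose)
    synthetic, _ = generate_dataset(
        model_full, vocab,
        GenerationRequest(n_records=len(train_recs),
                          seed=substream(seed, "generate")))
    return DeskStudy(seed, config, records, vocab, train_recs, val_recs,
                     test_recs, dtr, dte, model_full, model_coarse, synthetic,
                     hist_full, hist_coarse)


# ---------------------------------------------------------------------------
# Read-outs
# ---------------------------------------------------------------------------


def distribution_recovery(study: DeskStudy, n_truth_records: int = 10000) -> dict:
    """R^2 of the synthetic dataset's code-probability tables against the
    simulator's ground-truth tables."""
    truth = ground_truth_tables(study.config, n_records=n_truth_records)
    synth = probability_tables(study.synthetic, schemes=study.config.schemes)
    out = {}
    for which in ("unigram", "sequential_bigram", "same_visit_bigram"):
        out[which] = {
            "r2": r2_between(truth, synth, which),
            "n_keys": len(set(getattr(truth, which)) | set(getattr(synth, which))),
        }
    return out


def hierarchy_advantage(study: DeskStudy) -> dict:
    """Held-out perplexity per present code, full vs coarse-only, plus the
    teacher-forced modeling metrics."""
    pp_full = perplexity_per_code(study.model_full, study.test_data)
    pp_coarse = perplexity_per_code(study.model_coarse, study.test_data)
    bce, f1 = test_modeling_metrics(study.model_full, study.test_data)
    return {"perplexity_full": pp_full, "perplexity_coarse": pp_coarse,
            "test_bce": bce, "test_f1": f1,
            "n_test_records": len(study.test_records)}


def sampler_consistency(study: DeskStudy, n_records: int = 100) -> dict:
    """Max |accumulated sampling log-prob - re-encoded record log-prob| over
    freshly generated records, both model modes."""
    worst = 0.0
    for model in (study.model_full, study.model_coarse):
        sampler = RecordSampler(model, study.vocab, study.config.schemes)
        rng = np.random.default_rng(substream(study.seed, "consistency"))
        for _ in range(n_records // 2):
            rec, lp = sampler.sample_record(rng)
            rm = encode_record(rec, study.vocab, study.config.schemes,
                               t_max=study.config.max_visits)
            lp2 = model.record_log_probability(rm.matrix[None], [rm.n_rows])[0]
            worst = max(worst, abs(lp - lp2))
    return {"max_abs_diff": worst, "n": n_records}


def privacy_suite(study: DeskStudy, n_per_side: int = 250,
                  overfit_epochs: int = 400) -> dict:
    """Honest membership-inference attacks plus both positive controls."""
    seed = study.seed
    attack = make_attack_set(study.train_records, study.test_records,
                             n_per_side, seed=substream(seed, "attack"))
    out = {
        "dataset_attack": dataset_attack(attack, study.synthetic, study.vocab),
        "model_attack": model_attack(attack, study.model_full, study.vocab,
                                     study.config.schemes),
        "dataset_attack_copy_control": dataset_attack(attack, attack.members,
                                                      study.vocab),
    }
    # deliberately overfit control: memorize a handful of training records
    members = study.train_records[:32]
    data = EncodedDataset.from_records(members, study.vocab,
                                       study.config.schemes,
                                       t_max=study.config.max_visits)
    overfit, _ = train_model(
        data, data,
        ModelConfig(C=study.vocab.size, T_max=study.config.max_visits,
                    n_emb=64, n_blocks=1, n_heads=2,
                    seed=substream(seed, "overfit")),
        TrainConfig(learning_rate=DESK_LR, epochs=overfit_epochs,
                    seed=substream(seed, "overfit-batches")))
    oa = make_attack_set(members, study.test_records[:32], 32,
                         seed=substream(seed, "overfit-attack"))
    out["model_attack_overfit_control"] = model_attack(
        oa, overfit, study.vocab, study.config.schemes)
    return out


def utility_suite(study: DeskStudy, n_pool: int = 6000,
                  n_synthetic: int = 3000, label: str = "phenotype_A") -> dict:
    """Phenotype classification from synthetic vs real data (balanced task)
    and the rare-label augmentation arms, all evaluated on one real test set
    drawn from a population never shown to the generator."""
    from .utility import (
        ClassifierConfig,
        RareDiseaseSpec,
        TaskSpec,
        build_balanced_task,
        build_real_test,
        evaluate_classifier,
        featurize,
        rare_disease_experiment,
        train_phenotype_classifier,
    )

    seed = study.seed
    pool = simulate_cohort(study.config, n_pool, seed=substream(seed, "pool"))
    pool_train, pool_test = pool[:3 * n_pool // 4], pool[3 * n_pool // 4:]
    synth_pool, _ = generate_dataset(
        study.model_full, study.vocab,
        GenerationRequest(n_records=n_synthetic,
                          seed=substream(seed, "generate-utility")))
    ccfg = ClassifierConfig(seed=substream(seed, "classifier"))

    task = TaskSpec(label, n_train=800, n_valid=100, n_test=400,
                    seed=substream(seed, "task"))
    test_recs, y_test = build_real_test(pool_test, task)
    test_seqs = featurize(test_recs, study.vocab)
    balanced = {}
    for arm, data in (("real", pool_train), ("synthetic", synth_pool)):
        tr_s, va_s = build_balanced_task(data, task)
        clf = train_phenotype_classifier(tr_s, va_s, study.vocab, ccfg)
        balanced[arm] = evaluate_classifier(clf, test_seqs, y_test)

    def gen_pos(n):
        recs, _ = generate_dataset(
            study.model_full, study.vocab,
            GenerationRequest(n_records=n, condition_labels={label},
                              seed=substream(seed, "generate-rare")))
        return recs

    spec = RareDiseaseSpec(label, n_negative=1000, n_positive=20, n_valid=100,
                           n_test=400, seed=substream(seed, "rare"))
    rare = rare_disease_experiment(pool_train, pool_test, spec, gen_pos, ccfg,
                                   study.vocab)
    return {"balanced_task": balanced, "rare_disease": rare, "label": label,
            "n_test": task.n_test}
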