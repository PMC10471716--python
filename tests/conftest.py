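import numpy as np
import pytest

from haloehr.records import (
    BucketScheme,
    CodeVocabulary,
    PatientRecord,
    Visit,
    build_vocabulary,
)


@pytest.fixture
def tiny_vocab():
    """Fixed-order 5-code vocabulary: start, end, two medical codes, a label."""
    return CodeVocabulary(
        ["<start>", "<end>", "A", "B", "L1"],
        ["start", "end", "medical", "medical", "label"],
    )


@pytest.fixture
def toy_records():
    return [
        PatientRecord("p1", {"L1"}, [Visit({"A"}), Visit({"A", "B"})]),
        PatientRecord("p2", set(), [Visit({"B"})]),
        PatientRecord("p3", {"L1"}, [Visit({"A", "B"}), Visit({"A"}), Visit(set())]),
    ]


@pytest.fixture
def heart_scheme():
    from haloehr.records import heart_rate_scheme

    return heart_rate_scheme()


@pytest.fixture
def small_cohort():
    """A 120-record simulated cohort with continuous variables, for I/O and
    encoding tests."""
    from haloehr.simulate import desk_config, simulate_cohort

    cfg = desk_config(n_codes=20, n_labels=2, n_pairs=4, continuous=True,
                      max_visits=6)
    return cfg, simulate_cohort(cfg, 120, seed=11)


@pytest.fixture
def small_vocab(small_cohort):
    cfg, records = small_cohort
    return build_vocabulary(records, cfg.schemes, seed=3)
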