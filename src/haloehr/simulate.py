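"""Ground-truth cohort simulator.

Emulates the statistical structure that the fidelity metrics measure on real
claims/ICU data, without any real data: label-dependent code prevalences,
within-visit code co-occurrence, across-visit code persistence, truncated
geometric record lengths, bucketed inter-visit gaps, and lab values.

The generative process per patient:

1. labels are independent Bernoullis with configured prevalences;
2. the number of visits T is geometric (mean ``mean_visits``) truncated at
   ``max_visits``;
3. each visit samples codes from per-code Bernoullis whose rates are the base
   long-tailed prevalences multiplied by the active labels' risk multipliers
   (capped at 0.9), then co-occurrence pairs add partner codes with the
   configured boost probability, then codes present in the previous visit
   persist with probability rho;
4. gaps (from the second visit on) draw a bucket from a categorical
   distribution and a uniform value inside it; labs are present per visit with
   a fixed probability and draw a truncated normal value.

``ground_truth_tables`` measures the implied unigram/bigram probabilities by
large-sample Monte Carlo of this same process under a fixed internal seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import (
    GAP_VARIABLE,
    BucketScheme,
    PatientRecord,
    Visit,
    heart_rate_scheme,
)


@dataclass
class LabelSpec:
    name: str
    prevalence: float
    multipliers: dict = field(default_factory=dict)  # code index -> risk factor


@dataclass
class LabSpec:
    name: str
    scheme: BucketScheme
    presence_prob: float
    mean: float
    sd: float


@dataclass
class SimConfig:
    n_codes: int
    base_prevalence: np.ndarray
    labels: list = field(default_factory=list)
    cooccurrence: list = field(default_factory=list)  # (a, b, boost_prob)
    persistence: float = 0.3
    mean_visits: float = 4.0
    max_visits: int = 10
    gap_scheme: BucketScheme | None = None
    gap_bucket_probs: np.ndarray | None = None
    labs: list = field(default_factory=list)

    def __post_init__(self):
        self.base_prevalence = np.asarray(self.base_prevalence, dtype=float)
        if self.base_prevalence.shape != (self.n_codes,):
            raise ValueError("base_prevalence must have one entry per code")
        if np.any(self.base_prevalence < 0) or np.any(self.base_prevalence > 1):
            raise ValueError("base prevalences must lie in [0, 1]")
        if not 0 <= self.persistence <= 1:
            raise ValueError("persistence must lie in [0, 1]")
        if self.mean_visits < 1:
            raise ValueError("mean_visits must be >= 1")
        for lab in self.labels:
            if not 0 <= lab.prevalence <= 1:
                raise ValueError(f"label {lab.name} prevalence outside [0, 1]")
            for mult in lab.multipliers.values():
                if mult < 0:
                    raise ValueError("risk multipliers must be >= 0")
        for a, b, boost in self.cooccurrence:
            if not 0 <= boost <= 1:
                raise ValueError("co-occurrence boosts must lie in [0, 1]")
        if self.gap_scheme is not None:
            p = np.asarray(self.gap_bucket_probs, dtype=float)
            if p.shape != (self.gap_scheme.n_buckets,) or abs(p.sum() - 1) > 1e-9:
                raise ValueError("gap bucket probabilities must sum to 1")
            self.gap_bucket_probs = p

    def code_name(self, i: int) -> str:
        return f"code{i:03d}"

    @property
    def schemes(self) -> list:
        out = [] if self.gap_scheme is None else [self.gap_scheme]
        out += [lab.scheme for lab in self.labs]
        return out

    def expected_record_length(self) -> float:
        """Analytic mean of min(Geometric(1/mean_visits), max_visits)."""
        q = 1.0 - 1.0 / self.mean_visits
        return float((1.0 - q ** self.max_visits) / (1.0 - q))


def desk_config(n_codes: int = 100, n_labels: int = 4, n_pairs: int = 20,
                persistence: float = 0.3, mean_visits: float = 4.0,
                max_visits: int = 10, continuous: bool = False,
                seed: int = 7) -> SimConfig:
    """The default desk-scale study cohort: 100 long-tailed codes, 4 chronic
    labels each quadrupling the risk of its own block of 10 codes, 20 strong
    within-visit co-occurrence pairs, persistence 0.3, ~4 visits per record.

    ``continuous=True`` adds bucketed inter-visit gaps and a heart-rate lab.
    """
    rng = np.random.default_rng(seed)
    base = 0.25 * (np.arange(1, n_codes + 1)) ** -0.7
    base = np.clip(base, 0.005, None)
    labels = []
    block = max(1, n_codes // (2 * max(n_labels, 1)))
    for j in range(n_labels):
        codes = range(j * block, (j + 1) * block)
        labels.append(LabelSpec(
            name=f"phenotype_{chr(ord('A') + j)}",
            prevalence=[0.35, 0.25, 0.15, 0.08][j % 4],
            multipliers={int(c): 4.0 for c in codes},
        ))
    # strong same-visit lifts among moderately common codes
    candidates = rng.permutation(np.arange(n_codes // 2))
    pairs = []
    for k in range(min(n_pairs, len(candidates) // 2)):
        a, b = int(candidates[2 * k]), int(candidates[2 * k + 1])
        pairs.append((a, b, 0.5))
    cfg = dict(
        n_codes=n_codes, base_prevalence=base, labels=labels,
        cooccurrence=pairs, persistence=persistence,
        mean_visits=mean_visits, max_visits=max_visits,
    )
    if continuous:
        gap_scheme = BucketScheme(
            GAP_VARIABLE, np.array([0, 1, 3, 7, 14, 30, 60, 90, 180, 365.0]))
        gap_probs = np.array([0.02, 0.06, 0.17, 0.25, 0.25, 0.13, 0.06, 0.04, 0.02])
        cfg.update(
            gap_scheme=gap_scheme, gap_bucket_probs=gap_probs,
            labs=[LabSpec("heart_rate", heart_rate_scheme(),
                          presence_prob=0.5, mean=82.0, sd=18.0)],
        )
    return SimConfig(**cfg)


def _sample_patient(config: SimConfig, rng: np.random.Generator,
                    patient_id: str) -> PatientRecord:
    active = [lab for lab in config.labels if rng.random() < lab.prevalence]
    p = config.base_prevalence.copy()
    for lab in active:
        for c, mult in lab.multipliers.items():
            p[c] *= mult
    p = np.clip(p, 0.0, 0.9)

    T = int(min(rng.geometric(1.0 / config.mean_visits), config.max_visits))
    visits = []
    prev = np.zeros(config.n_codes, dtype=bool)
    for t in range(T):
        present = rng.random(config.n_codes) < p
        for a, b, boost in config.cooccurrence:
            if present[a] and not present[b] and rng.random() < boost:
                present[b] = True
        carried = prev & ~present
        if carried.any():
            present |= carried & (rng.random(config.n_codes) < config.persistence)
        codes = {config.code_name(int(i)) for i in np.flatnonzero(present)}
        gap = None
        if t > 0 and config.gap_scheme is not None:
            k = int(rng.choice(config.gap_scheme.n_buckets,
                               p=config.gap_bucket_probs)) + 1
            gap = float(rng.uniform(config.gap_scheme.edges[k - 1],
                                    config.gap_scheme.edges[k]))
        labs = []
        for lab in config.labs:
            if rng.random() < lab.presence_prob:
                lo, hi = lab.scheme.edges[0], lab.scheme.edges[-1]
                value = float(np.clip(rng.normal(lab.mean, lab.sd),
                                      lo, np.nextafter(hi, lo)))
                labs.append((lab.name, value))
        visits.append(Visit(codes=codes, labs=labs, gap_days=gap))
        prev = present
    labels = {lab.name for lab in active}
    return PatientRecord(patient_id, labels, visits)


def simulate_cohort(config: SimConfig, n: int, seed: int = 0) -> list:
    """Draw ``n`` independent patient records; deterministic under the seed."""
    rng = np.random.default_rng(seed)
    return [_sample_patient(config, rng, f"sim-{i}") for i in range(n)]


GROUND_TRUTH_SEED = 987654321  # fixed internal stream for the reference tables


def ground_truth_tables(config: SimConfig, n_records: int = 25000):
    """Reference unigram/bigram probability tables for a configuration,
    estimated by Monte Carlo on ``n_records`` freshly simulated records under
    a fixed internal seed (independent of any cohort drawn for training)."""
    from .fidelity import probability_tables

    cohort = simulate_cohort(config, n_records, seed=GROUND_TRUTH_SEED)
    return probability_tables(cohort, schemes=config.schemes)
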