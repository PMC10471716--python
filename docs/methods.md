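# Methods

## Model

The generator defines an explicit density over binary record matrices
`R = [v_s, v_l, v_1..v_T, v_e]` of shape (T+3) × C via a two-level
autoregressive factorization: across rows (visits) and, within each row,
across the C codes in a fixed vocabulary order.

**Visit-level module.** `H0 = R W_e + W_p`, followed by M pre-normalization
transformer decoder blocks (causal multi-head self-attention, residual
connections, a 2-layer feed-forward with 4×n_emb hidden width and ReLU), and
a final layer normalization. Causal attention means row t's history embedding
depends only on rows ≤ t. Padding rows always sit at the sequence tail, so
the causal mask alone keeps every scored position from attending to padding.

**Code-level module.** Row k's history embedding is concatenated with input
row k+1 and passed through N masked dense layers of width n_emb + C. The
triangular mask convention is MADE-style: hidden layers keep the diagonal
(unit j may read input j), the final layer is strictly upper-triangular
(output code i reads only embedding units and codes j < i). This gives
maximal connectivity with provably zero self-leak; the test suite checks it
by exhaustive input flips. The coarse-only ablation replaces the masked stack
with a single dense layer + sigmoid on the history embedding, removing all
intra-visit conditioning; it is exactly the full model minus the code-level
module.

**Loss and likelihood.** Masked mean binary cross-entropy over scored cells.
The label and end rows are scored (unconditional generation must learn the
label and stop distributions); only the start row and padding are excluded.
Probabilities are clamped to [1e−8, 1−1e−8] before any logarithm so
log-likelihoods stay finite. Record log-probability sums Bernoulli log-mass
over the same scored cells, making per-code perplexity
`exp(−Σ log P(R) / N)` with N the number of 1-entries in scored rows.

**Reference hyperparameters vs desk preset.** The reference configuration is
M = 12 decoder blocks, N = 2 masked layers, Adam at 1e−4, batch 48, 50
epochs, 0.8/0.2 train-test and 0.9/0.1 train-validation splits, lowest
validation loss selects the checkpoint. The desk preset used throughout the
tests and the acceptance study is M = 2, n_emb = 128, 4 heads, N = 2, same
batch/epochs/splits, but learning rate 1e−3: with a 1440-record training
split, 50 epochs are ~1.9k optimizer steps, and 1e−4 leaves the model
visibly undertrained (validation loss 0.123 vs 0.112, held-out perplexity 24
vs 18, and systematically under-calibrated free-running samples). The desk
rate was chosen by validation loss. Embedding width, head count, and
feed-forward width have no stated reference values; the desk values are this
package's choices. Gradient clipping at global norm 1.0 stabilizes
small-batch runs. Dropout is supported but 0 in the desk preset —
determinism matters more than regularization at this scale.

**Implementation.** Forward and backward passes are hand-written NumPy
(float64). There is no autodiff dependency; correctness rests on
finite-difference gradient checks over every parameter tensor, exact
normalization checks by enumeration, and exhaustive leakage sweeps, all in
the test suite.

## Vocabulary order

The intra-visit autoregressive order is a single seeded random permutation of
the non-special codes, fixed when the vocabulary is built and stored with it;
the reference finding is that code order does not matter measurably, and a
frozen permutation keeps every downstream computation reproducible. The start
and end codes lead the order. Placing the end code first makes its
conditional exactly the record's stop hazard given the visit history — the
stop-token analogue. (Placing it last was tried first and failed visibly: to
stop, the sampler had to thread "no code has fired yet" through ~100
autoregressive columns, the model under-learned that conjunction, and
generated records ran to the visit cap — mean 9.2 visits against 3.8 in
training. With the end code leading, generated record lengths match training
within ~6%.)

## Sampling

Rows are generated in order; codes within a row are Bernoulli draws from the
model's conditionals in vocabulary order, with structural constraints that
keep every emitted matrix a valid record matrix: the label row carries only
label codes (clamped exactly to the requested set in conditional mode);
content rows never carry start/label codes; the end code may fire only in a
still-empty row and then closes it, so the end row always carries exactly the
end code; gap buckets are mutually exclusive per row and suppressed in the
first visit; lab-bucket exclusivity is optional (`enforce_bucket_exclusivity`).
Records hitting the visit cap force-emit the stop row and are flagged
truncated.

Constrained cells are *forced, not resampled*: the sampler emits the forced
outcome and accrues its log-probability, so the accumulated log-probability
of any generated record equals `record_log_probability` of its re-encoded
matrix exactly (tested to 1e−9; the acceptance band is 1e−6). A trained model
puts negligible mass on the forbidden outcomes, so forcing barely perturbs
the learned distribution. One consequence of the end-closes-row rule is that
a visit can never contain the end code alongside content codes; the
alternative (keep such a visit, then stop) would break the end-row invariant
and exact likelihood consistency.

Sequential sampling uses an incremental update of the two-layer masked stack
(O(C·(n_emb+C)) per row); a full-matrix recomputation fallback produces
bit-identical samples under the same seed and is tested against it. All
generation draws flow through per-record child streams spawned from the
request seed, so datasets are reproducible and independent of batching.

## Continuous variables

Each continuous variable (lab value, inter-visit gap) has a bucket scheme:
strictly increasing edges defining left-closed/right-open intervals
[e_{k−1}, e_k) — a tiling convention is required and this is the standard
one. Values are discretized to bucket codes for modelling and reconstituted
by uniform sampling within the bucket. Out-of-range values raise; there is no
silent clamping. When no clinician edges are supplied,
`equal_frequency_edges` builds quantile buckets from data. The bundled
20-bucket heart-rate scheme spans 0–400 bpm with bucket 1 = [0, 40) and
bucket 7 = [90, 100), so a measurement of 93 bpm activates the 7th heart-rate
variable. If a decoded visit carries two gap buckets (possible only for
hand-built matrices, not sampled ones), the lowest bucket wins with a
warning. Multiple labs of the same variable in one visit each contribute a
bucket code; the multi-hot representation collapses duplicates within the
same bucket.

## Ground-truth cohort simulator

The simulator generates the study conditions every other module is tested
against, emulating the statistical structure the fidelity metrics measure on
real claims/ICU data. Per patient: independent Bernoulli phenotype labels;
visit count geometric (mean μ_T) truncated at T_max, exercising both the
stop-code and truncation paths; per visit, codes drawn from long-tailed base
prevalences multiplied by active labels' risk factors (capped at 0.9), then
co-occurrence pairs add partner codes with a boost probability, then codes
from the previous visit persist with probability ρ; gaps draw a bucket from a
categorical distribution and a uniform value inside it; labs are present per
visit with fixed probability and draw truncated-normal values.

Desk preset: 100 codes with base prevalence 0.25·i^(−0.7) (floor 0.005), 4
labels with prevalences 0.35/0.25/0.15/0.08 each quadrupling the risk of its
own 10-code block (chronic phenotypes strongly modulate a subset of codes),
20 co-occurrence pairs with boost 0.5 among the commoner codes (strong
within-visit structure the coarse-only model cannot represent), ρ = 0.3,
μ_T = 4, T_max = 10, n = 2000. Reference probability tables
(`ground_truth_tables`) are large-sample Monte Carlo estimates of the same
process under a fixed internal seed (default 25k records ≈ 95k visits) — the
persistence/co-occurrence interplay makes closed forms unrewarding, and the
Monte-Carlo error at that size is well below the tolerances used anywhere.

What the simulator does *not* emulate: real coding vocabularies (ICD
hierarchies), visit-count overdispersion beyond geometric, code burstiness,
label correlations, or informative gap–code dependence. Passing tests
demonstrate the machinery recovers the structure this process has — not that
the model is sufficient for any particular real dataset.

## Evaluation

Probability tables use visit-level normalization: unigram = fraction of
content visits containing the code; same-visit bigram = fraction of visits
containing both codes of a pair (stored with a < b); sequential bigram =
fraction of consecutive visit pairs with code a in visit t and b in visit
t+1. Start/end/label codes are never counted; bucket codes are counted when
schemes are supplied. R² between two tables is the squared Pearson
correlation over the union of keys observed in either table (absent keys are
zero). Restricting to observed keys is deliberate: including the
astronomically many structurally-zero pairs would inflate R² toward 1.
Teacher-forced metrics are masked mean BCE and micro-averaged F1 at threshold
0.5 over scored cells. Perplexity normalizes by present codes in scored rows
only, mirroring the loss mask.

The phenotype classifier is a bidirectional recurrent encoder (tanh RNN
cells, hidden 128 per direction, hand-written BPTT) over per-visit multi-hot
vectors with label codes removed, a single dense head, Adam at 1e−3, 20
epochs, validation-accuracy checkpoint selection. The cell type is a design
choice: at desk scale (≤ 10 visits) gated cells add parameters without
changing the experiment's logic; the experiments compare *training data*, so
the identical classifier is used in every arm. Raw multi-hot featurization
(no embedding layer) is likewise a documented choice. AUROC is computed by
rank statistics with midranks for ties.

The rare-condition experiment scales the reference design (50k negatives /
1k positives, 49k synthetic positives) to 1000 negatives / 20 positives,
filling with 980 conditionally generated positives, against a real-balanced
upper bound of 1000 real positives, all evaluated on one shared balanced
real test set of 400 drawn from a held-out population. The balanced-task
comparison trains on 800 balanced records (desk analogue of the reference
2500) from real vs synthetic pools; the synthetic pool is 3000 generated
records so that it contains enough label-positives to fill balanced splits.

Membership inference follows the two standard attacks: the dataset attack
scores each probe record by minimum Hamming distance between code-presence
vectors (length-invariant summaries; Hamming = Manhattan on binaries) and
the synthetic dataset; the model attack scores by raw record log-probability
(a per-present-code normalization is available but off by default). Each
attack predicts exactly the lower/upper half as members, so accuracy equals
recall by construction. Positive controls: synthetic = verbatim copies of
the member pool (dataset attack should approach 1), and a model trained to
memorize 32 records (model attack should approach 1). Desk-scale honest
attacks are allowed a ±0.12 band around chance: with 500 probes the binomial
null alone spans ~±0.07 at 3σ, and a 1440-record training set incurs mild
benign memorization that the reference-scale numbers (~0.50 at 100k records)
do not show.

## Numerical and degenerate-input conventions

* Probabilities clamped to [1e−8, 1−1e−8] before logs; BCE computed from
  logits via the softplus form.
* Splits: train = ⌊0.9·⌊0.8·n⌋⌋, validation the remainder of the training
  pool, test the rest (100 → 72/8/20); seed-deterministic permutation.
* Batches pad to the batch max row count; masking makes this loss-neutral
  (tested).
* Zero-visit records encode as [start, label, end] and featurize as a single
  all-zero step for the classifier.
* Encoding truncates over-long records to the earliest T_max visits and
  always appends the end row, preserving the generative stop signal.
* Checkpoints embed the vocabulary hash; loading against a different
  vocabulary is a hard error.
* Attention uses −1e9 additive masking (not −inf) to avoid NaNs in fully
  masked rows.

## Known limitations

* Desk-scale model (M = 2) and cohort; nothing here validates behaviour at
  the reference scale (M = 12, ~10⁴ codes, ~10⁶ records), where attention
  cost and rare-code estimation dominate.
* The simulator's independence assumptions (labels independent, gaps/labs
  independent of codes) mean cross-structure fidelity is untested.
* No clinical-validity postprocessing: generated records are statistically,
  not clinically, constrained.
* Attribute-inference and nearest-neighbour adversarial-accuracy privacy
  evaluations are not implemented; the attack-set interface accepts custom
  scores, which is the intended extension hook.
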