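# Methods

## Problem setting

Binary classification of peptides as linear B-cell epitopes (label 1) or
non-epitopes (label 0). Peptides are strings over the 20 canonical amino
acids; lengths may vary within a dataset. The pipeline covers feature
encoding, training, cross-validation, evaluation, and a positional
enrichment analysis, plus a synthetic generator for self-contained
validation.

## Feature encoding

Every peptide maps to a fixed-dimension vector regardless of length, in the
block order **AAC | AAP | AAT | embedding**.

**AAC** (20 dims). Residue frequencies `f_i = R_i / N` with `R_i` the count
of residue *i* and *N* the peptide length.

**AAP / AAT antigenicity scales.** For each k-mer *m* (k = 2 dipeptides, k =
3 tripeptides) observed anywhere in the training data, the raw score is the
smoothed log odds of its occurrence in the positive vs negative class:

```
f±(m) = (count±(m) + α) / (total± + α·20^k)
raw(m) = ln( f⁺(m) / f⁻(m) )
```

- Counts are over **overlapping windows** (a length-N peptide contributes
  N−k+1 windows).
- Pseudocount **α = 1.0** (Laplace smoothing) so every observed k-mer has a
  finite score even with zero counts in one class; raw scores are exactly
  antisymmetric under class swap.
- **Natural log**; the base is a constant factor absorbed by the subsequent
  min–max normalisation onto **[−1, 1]** (all-equal raw scores map to 0).
- k-mers never observed in training get **default value 0** (the neutral
  midpoint) at application time.
- `apply_scale` mode `mean` (the default feature) averages the normalised
  score over a peptide's windows; peptides shorter than k contribute 0 and
  a warning. Mode `profile` instead emits the full 20^k frequency-weighted
  vector.

Because the scales are built from **labels**, they leak information if built
on data later used for testing. `cross_validate` therefore rebuilds AAP and
AAT from the k−1 training folds inside every fold; `train` builds them from
its full training set and persists them in the model bundle so prediction
never needs labels.

**Embeddings.** An `EmbeddingProvider` maps a peptide to a `dim`-vector with
a declared pooling (`cls` = single sequence-level vector; `avg` = mean over
per-residue vectors). Implementations: a deterministic hash-seeded mock
(uniform [−1,1], seeded by blake2b of the sequence, so identical sequences
embed identically across processes); an "informative" mock that blends the
base mock with a class-direction vector (for controlled experiments); a
precomputed TSV lookup keyed by peptide id; and an adapter for a locally
installed pretrained transformer, which raises an actionable error when the
optional dependencies are absent. Default `embedding_dim` is 768 (the
hidden size typical of base transformer encoders); any positive dimension
works. Re-implementing or shipping a language model is out of scope — the
provider interface is the extension point.

## Classifier

XGBoost gradient-boosted trees, binary logistic objective. Defaults
(`ModelConfig`): 200 trees, max depth 6, learning rate 0.1, subsample 0.8,
colsample_bytree 0.8, `tree_method="hist"`, single thread and fixed
`random_state` for bit-reproducible training. `default_grid()` spans depth
{3, 6} × learning rate {0.05, 0.1} × trees {100, 300}; `grid_search`
selects by mean CV AUROC with mean ACC as tiebreak (first configuration
wins exact ties). Scores ≥ **0.5** are called positive; the threshold is a
parameter everywhere it matters.

Stratified k-fold assignment shuffles each class independently with the run
seed and deals indices round-robin from fold 0, so per-fold class counts
differ by at most one. Model bundles persist the booster (JSON), both
scales (TSV), the encoder and model configurations, and a SHA-256
fingerprint of the feature-name list; loading verifies integrity and
refuses mismatched bundles.

## Evaluation

With TP/TN/FP/FN from the thresholded scores:

```
Sn  = TP/(TP+FN)            Pre = TP/(TP+FP)
ACC = (TP+TN)/(TP+TN+FP+FN) F1  = 2·Pre·Sn/(Pre+Sn)
MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
```

Zero denominators yield 0 with a flag recorded on the report rather than an
exception. AUROC is the midrank Mann–Whitney U statistic (exactly the
probability a random positive outscores a random negative, ties counting
half), which handles heavily tied scores correctly; ROC curves come from
scikit-learn with no intermediate-point dropping.

## Two-sample logo (positional enrichment)

For each position p and residue r in two equal-length peptide samples, the
two proportions are compared with a pooled two-proportion z-test; when any
expected count under the pooled rate is < 5 the p-value comes from an exact
binomial test instead (sample 1's count against the pooled rate). Cells
with p < α (default 0.05; optional Bonferroni over all L×20 cells) are
flagged "enriched" or "depleted" by the sign of the frequency difference.
The summary `overall_rate` is defined here as 100 × the mean over positions
of the summed |frequency difference| of that position's flagged cells — a
percentage measure of how much class-discriminating composition the flagged
cells carry. Variable-length inputs are analysed per length stratum.

## Synthetic data generator

Sequences are drawn i.i.d. uniform over the 20 residues, then modified:

- **Positional biases**: at position p, write residue r with probability
  `prob_pos` (positives) or `prob_neg` (negatives), else keep the
  background draw. Realised frequency is `q + (1−q)/20`.
- **k-mer biases**: multiplicative tilts on positives only, applied by
  rejection resampling with an indicator weight — a candidate positive is
  accepted with probability `Π_m m_mult^[contains m] / Π_{mult>1} mult`
  (capped at 1000 attempts). The indicator ("contains at least once") form
  keeps acceptance rates practical while guaranteeing the sign of each
  planted k-mer's log-odds; `planted_scale_oracle` returns those signs.
- Optional `embedding_signal` s ∈ [0,1] makes `provider_for_spec` return an
  informative mock whose embeddings blend toward a class direction.

Two presets mimic the *shape* of common benchmark conditions, as this
package's own design choices: `bcpreds_like` — balanced, fixed length 20,
701/701 at scale 1 — plants strong effects (P at five positions 0.50 vs
0.02; T, G, D at one position each 0.45 vs 0.03; L, I, F depleted at four
positions; dipeptide tilts PG 4.0, TG 4.0, LL 0.15; tripeptide PGT 10.0) so
the classes are separable by construction and recovery is a meaningful
check. `ibce_like` — imbalanced 4440:5485 at scale 1, lengths uniform 5–25
— plants mild effects and exercises variable-length handling. These presets
emulate dataset geometry (size, balance, length distribution) and
recoverable composition signal; they do **not** emulate real epitope
physico-chemistry, homology structure, or experimental label noise.

Problem sizes used in the tests and in `scripts/acceptance.py` (e.g.
500/500 for planted-signal CV, 200/200 for null calibration, 5-fold CV,
60-tree models in unit tests) are this package's own choices balancing
statistical resolution against runtime.

## Numerical and implementation choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; fixed seeds give byte-identical CV reports and predictions.
- Scale TSVs store values at full double precision (`%.17g`) so save/load
  round trips are exact to < 1e-12.
- A greedy equal-length identity filter is provided for redundancy
  reduction; it is deliberately simpler than clustering tools like CD-HIT
  and only removes exact-length duplicates/near-duplicates by fractional
  identity, first-seen wins.

## Limitations

Reported performance numbers are on synthetic data with planted signal and
validate the machinery, not biological accuracy. Real-data performance
depends on the embedding provider supplied and on redundancy control
between training and evaluation sets, which the identity filter only
coarsely addresses. The exact binomial fallback tests sample 1 against the
pooled rate (a one-sample approximation of the two-sample comparison), and
the logo analysis assumes positions are comparable across peptides, i.e.
inputs aligned or fixed-length per stratum.
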