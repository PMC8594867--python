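# Methods

This note records the models, conventions and numerical choices behind
`pcmbench`, and what its synthetic benchmarks do and do not demonstrate.

## Data model and encodings

A bioactivity record is one compound–protein pair with a log-scale binding
value (log10 of IC50/Ki/Kd). Labels are binary: **active ⇔ log value ≥ 6**.
The threshold comparison is inclusive at the boundary — the pActivity
convention where a higher value means stronger binding; both the threshold
and its direction are configurable in `binarize_activity`.

Compounds are 881-bit substructure fingerprints (stored as 0/1 vectors,
serialized as 881-character bit strings). Proteins are one-hot encoded over
a fixed 26-letter alphabet — the 25 IUPAC extended amino-acid letters in
the order `ACDEFGHIKLMNPQRSTVWYBJOUZ` plus a final catch-all channel `X`
for unrecognized symbols — into a 1499 × 26 matrix with *prepadding*: all
zero rows precede the residue rows, so a sequence of length L occupies the
last L rows. Sequences longer than 1499 are truncated from the front,
keeping the C-terminus inside the non-padded region adjacent to where
prepadding places the signal; both truncation and unknown symbols are
logged. Tables are comma- or tab-delimited (auto-detected from the header);
rows with unparsable activities or malformed fingerprints are rejected and
counted, a missing schema column is a hard error.

## Splitting

K-means (Euclidean on the raw 0/1 fingerprint vectors, k = 100 by default,
lowered with a warning when fewer distinct fingerprints exist) is fitted on
the distinct vectors so identical fingerprints can never split across
clusters. Clustering is computed **once per dataset**; the 10 folds redraw
only the cluster→set assignment. Whole clusters are assigned to
train/val/test with record-count targets 80/10/10: clusters are visited in
a seeded random order and each is placed into the set with the largest
remaining deficit. This keeps realized fractions close to target for many
small clusters, is deterministic per (seed, fold), and — unlike
deterministic largest-first packing — yields genuinely different
assignments across folds. Deviations beyond 5 percentage points (forced,
e.g., by one giant cluster) are logged. Set membership is defined at the
record level through the compound's cluster, so one protein typically
appears in all three sets — which is precisely what the per-protein
train-vs-test ratio analysis requires.

## Per-protein SMOTE

Each protein is balanced separately to an exact 50% active ratio by
interpolating synthetic minority fingerprints: s = vᵢ + u·(vⱼ − vᵢ),
u ~ U[0,1], with vⱼ one of the k = 5 nearest minority neighbours of a
uniformly chosen minority point vᵢ (Euclidean distance; candidate order
ties break by compound id; the point itself is excluded). Eligibility
requires **minority count ≥ k + 1**, so each minority point has k distinct
minority neighbours besides itself; single-class proteins and
minority-too-small proteins are discarded *from the set being resampled
only* and recorded in an audit table with their reason. Synthetic records
carry the minority label, a fresh compound id, no log-activity, and a
`synthetic` flag; original records are never modified or removed by
oversampling.

Synthetic fingerprints are binarized at 0.5 by default so every stored
compound vector remains a valid bit vector; the continuous variant is kept
behind `SmoteConfig.binarize_synthetic=False` (and is what the geometric
collinearity tests exercise). Whether the original bit vectors should be
binarized after interpolation is genuinely open; binarization was chosen to
keep one invariant for all fingerprints. In `resampling_after_clustering`
synthetic compounds inherit the cluster of their parent vᵢ (which lies in
the same split set, preserving cluster atomicity); the strategies that
cluster *after* resampling instead re-cluster the augmented compound set
from scratch.

## Strategies and round accounting

One *round* = one pass oversampling every eligible protein of one record
set. Over n folds: `no_resampling` 0; `resampling_after_clustering` 3n
(train, then val, then test, each with a set-specific derived seed);
`resampling_before_clustering` 1 (the single pre-split round is attached to
fold 0's ledger and shared by all folds); `semi_resampling` n (one pooled
train+val round per fold). The semi re-split ratio is 8:1 train:val,
restoring the original 80/10 proportions; its re-clustering uses the same k
(auto-lowered) with a fold-derived seed, and its cluster labels are
namespaced above the base labels so the untouched test set keeps its
original clustering. Base clustering and fold assignment depend only on
(dataset, master seed) — never on the strategy — which is what makes
`semi_resampling` test sets record-identical to `no_resampling`'s.

## Classifier and baseline

The PCM classifier has two branches: a 1-D convolution (32 filters, kernel
8, ReLU, global max pooling) over the 1499 × 26 protein matrix, and a dense
ReLU layer (64 units) over the 881-bit fingerprint; inverted dropout (0.25)
in both branches; a sigmoid unit on the concatenated representation.
Forward and backward passes are written directly on numpy arrays (the
backward pass is verified against finite differences in the test suite)
and optimized with Adam at learning rate 5 × 10⁻⁴ for 100 epochs, batch
128, with inverse-time step-size decay whose rate defaults to
learning rate / epochs. Selected weights are those of the epoch with maximum plain validation
accuracy, earliest epoch on ties. Adam defaults are the conventional
β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸; the nonstandard printed values sometimes
quoted for this architecture family (β₁ = 0.1, β₂ = 0.001) look like
transcribed 1−β values and are reachable through `ModelConfig` for anyone
who wants them. Class imbalance is deliberately **not** corrected in the
loss: the framework studies data-level balancing only. Architecture sizes
are configuration-driven with small defaults adequate for desk-scale data.

For benchmark loops where model capacity is irrelevant to the
balance-accounting questions, a logistic-regression surrogate over the
fingerprint bits plus cheap protein features (normalized length,
amino-acid composition) is provided and is the default runner model.

The random baseline draws, per protein, exactly ⌊fn + 0.5⌋ scores from
U[0.5, 1] and n − ⌊fn + 0.5⌋ from U[0, 0.5), shuffled; the active interval
is closed at 0.5 on the side that binarization counts as active, so the
per-draw active count is exact, never merely expected. Proteins absent
from a fold's training records fall back to the global training active
fraction (logged).

## Metrics and undefined-value conventions

Balanced accuracy, macro-F1, MCC and AUROC are the headline metrics; plain
accuracy is computed alongside (it drives epoch selection and is one of the
imbalance-sensitive metrics). AUROC is computed from raw scores via
midranks (ties count half); the others binarize at 0.5, the boundary
scoring active, consistent with the baseline's construction. Undefined
values are NaN and excluded downstream with per-metric exclusion counts:
balanced accuracy and AUROC when test labels are single-class, MCC when
any contingency marginal is zero. A per-class F1 with a zero denominator
scores 0 — a common convention, documented because it shifts macro-F1 on
degenerate proteins. All metric implementations are checked against
brute-force contingency/rank oracles on exhaustive small inputs and
against scikit-learn on random data. Strategy differences can also be
tested nonparametrically with a two-sided paired Wilcoxon signed-rank test
(zero differences split, incomplete pairs dropped; identical samples give
p = 1 by convention).

## Explanatory models

Observations are one row per protein × fold × strategy with r_training,
r_test, r_pred ∈ [0,1], n_int (the protein's interaction count in its test
set and fold), n_seq (sequence length) and all metric values.

**Predicted ratio.** logit E[r_pred] = β₀ + β₁ r_training + β₂ r_test +
β₃ n_int + β₄ n_seq + γ_fold, fitted per strategy (never for
`resampling_after_clustering`, where balance is enforced) as a binomial
GLM with variance weights equal to the per-protein test count — the
ratio's denominator, the natural quasibinomial weighting — and dispersion
estimated by Pearson X²; point estimates therefore equal the plain
binomial fit, dispersion rescales the standard errors only (asserted in
tests). When the Pearson residual variance is exactly zero (constant
response) the dispersion is not estimable and the fit falls back to unit
scale. Confidence intervals are normal-based (the statsmodels convention;
R's quasibinomial uses t quantiles — at the n ≥ hundreds where this model
is used the difference is negligible, and empirical coverage is nominal in
the recovery tests). Coefficients with |β| > 15 trigger a separation flag.
n_int and n_seq enter untransformed; main effects only, since any
interaction structure is unknown.

**Metrics.** metric ~ strategy + n_int + n_seq + k_fold by OLS, with
treatment coding against reference categories `no_resampling` and fold 0.
The strategy term is tested with a type-3 (marginal) ANOVA, implemented as
the joint Wald F-test of the strategy coefficients given all other terms —
with main effects only this equals the classical type-3 test under any
contrast coding. A metric is *imbalance-sensitive* iff this test is
significant (α = 0.05, two-sided, no cross-metric multiplicity correction)
in the **baseline's** model; sensitive metrics are then modeled on the
baseline-adjusted scale (model − paired baseline). Pairwise strategy
contrasts are differences of strategy coefficients with familywise
adjustment by the studentized-range distribution
(p = SF(|t|·√2; k levels, residual df), the standard generalized-Tukey
rule). Pearson correlations report Fisher-z 95% intervals. Rankings (1 =
best) order strategies by model-expected response at covariate means
averaged over folds; in an additive model this equals ranking by strategy
coefficient, exact ties break by strategy enumeration order and are
flagged.

A theoretical note on the sensitivity split: for a label-independent
baseline, expected MCC is 0 and expected AUROC 0.5 for *any* training
fraction f, so their strategy terms are null-distributed; expected
accuracy and macro-F1 move with f, giving the ANOVA power that grows with
imbalance heterogeneity. Expected *balanced* accuracy is also exactly 0.5
for any f whenever it is defined, so at desk scale it classifies as
insensitive; empirical classifications of it on large real data may differ
through exclusion effects and very high power.

## Synthetic data

The generator plants only the structure the analysis relies on, with
defaults chosen to echo kinase-scale bioactivity data: per-protein
interaction counts log-normal(μ = 3, σ = 1) rounded up (most proteins have
few interactions); per-protein active ratios Beta(2, 0.8) with point
masses 5% at 1 and 2% at 0 (skew toward actives, all-active/all-inactive
targets exist); compounds drawn from a shared pool, each belonging to one
of 20 "chemical series" whose sparse Bernoulli(0.1) prototype fingerprint
it perturbs with a 5% bit-flip rate; labels assigned so the protein-level
ratio matches its draw in expectation while compounds of one series share
a label with probability 0.8 (one shared label draw per protein × series);
sequence lengths uniform on [200, 1200] over the 20 standard amino acids;
log-activities drawn consistently with the label so binarization
round-trips. Everything is deterministic given the seed through an
integer-state generator; a ground-truth sidecar (per-protein planted
ratio, per-compound series id) supports assertions.

The generator does **not** simulate chemistry or binding physics, realistic
fingerprint bit correlations, protein families, or empirical family-wise
ratio distributions. Passing tests therefore demonstrate that the
*bookkeeping and statistical machinery* behave as specified under the
assumed imbalance/series structure — not that any particular model
performs well on real bioactivity data.

The parameter-recovery harness simulates predicted ratios from planted
coefficients with beta-binomial noise matched to quasibinomial variance
φ·n·μ(1−μ); recovery tests use a constant denominator (n = 40) so the
constant-dispersion assumption of the quasibinomial fit holds exactly, and
verify ≥ 90% empirical coverage of nominal 95% intervals over 200
replicates at n = 2000 observations.

## Seeding

Every random stream derives from one master seed:
seed = SHA-256(master, stage tags) mod 2³¹, with tags naming the stage,
strategy, fold, set and protein as applicable. Streams in different stages
are therefore decorrelated, results are platform-stable for all discrete
draws, and the run manifest (master seed + tag scheme) suffices to
re-derive every seed used anywhere.

## Problem sizes

Shipped tests and the reproduction script run on desk-scale synthetic data
(tens of proteins, tens of interactions each, 2–10 folds, the logistic
surrogate or a small CNN); these sizes are the package's chosen test
conditions, large enough for every structural assertion to be exact and
for the statistical assertions to have high power. The full-scale setting
(hundreds of targets, ~10⁵ pairs, 100-epoch CNN training) is reachable
through the same configuration objects.

## Known limitations

- The CNN is a faithful but compact implementation; no GPU path, no
  recurrent alternatives, no hyperparameter search.
- Only SMOTE oversampling is implemented — no undersampling,
  borderline-SMOTE/ADASYN, or cost-sensitive losses.
- Explanatory models are fixed-effects only; no mixed-effects or Bayesian
  variants, no cross-family meta-analysis.
- Wilcoxon and Tukey procedures assume exchangeable protein × fold pairs;
  correlation induced by shared folds is not modeled.
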