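# Methods

## The decision problem

Regulatory genotoxicity assessment asks whether *any* arm of a standard
assay battery flags a compound. The batteries share a fixed first slot (the
bacterial reverse-mutation / Ames test), a second slot of in vivo mammalian
cytogenetics (erythrocyte micronucleus or bone-marrow chromosome
aberration, mutually substitutable), and a third slot that differs between
the in vitro-weighted and germ-cell-weighted batteries and admits accepted
supplements (HGPRT, unscheduled DNA synthesis, Drosophila sex-linked
recessive lethal). `woeqsar` models each slot as one binary endpoint — Y1,
Y2, Y3 — and reproduces the weight-of-evidence verdict at the model level:
three per-endpoint classifiers whose calls are OR-ed.

## Assay integration

Outcomes are dichotomous (positive / negative) with an explicit
inconclusive state. Integration of a compound's records proceeds:

1. drop inconclusive records;
2. group the rest by the assay taxonomy (a closed enumeration with a
   config hook for additional codes);
3. within each group, majority vote; an exact tie is judged **positive**,
   the sensitivity-preserving convention for a screening model;
4. keep the compound only if all three groups retain at least one usable
   record. Exclusions are tagged by cause: a group that never had a record
   (`missing_group`) versus one emptied by inconclusive calls
   (`all_inconclusive`).

Voting applies uniformly to all three groups, including multiple Ames
records in Y1 — the natural extension when the reconciliation rule for the
first slot is otherwise unspecified. The voted label is monotone: flipping
any negative record to positive can never turn a group verdict from
positive to negative (property-tested, along with exhaustive agreement with
a brute-force majority-tie-positive oracle on all outcome vectors up to
length six).

## Dataset and split

Features are the 881 binary PubChem substructure keys per compound, read
and written in the PaDEL-Descriptor CSV dialect (a name column followed by
`PubchemFP0..PubchemFP880`); computing fingerprints from structures is out
of scope. Features and labels are inner-joined on compound id and sorted,
which makes every downstream stage invariant to input row order.

The train/test split is a uniform random partition at a configurable
ratio, default 0.8 (a 4:1 split; 665 compounds give exactly 532/133).
Train size is `floor(n·ratio + 0.5)` — decimal half-up, so the size is
platform-stable. An optional stratified mode keyed on the (Y1,Y2,Y3)
triple exists but is off by default, matching plain random selection.
Zero-variance feature columns are *not* pruned before ranking: a constant
column receives exactly zero attribution and is eliminated naturally.

## Fingerprint selection

For each endpoint a backing classifier is fitted on the training split
only and each fingerprint bit is scored by the mean absolute SHAP value
over training compounds (signed means are retained for inspection). The
backing model is a random forest — 200 trees, depth capped at 8 — because
tree-path Shapley attributions are exact and cheap for tree ensembles and
the depth cap both regularizes the fit on binary features and bounds the
attribution cost. Both the backing model and the aggregation are
configurable.

Attributions come from the package's own implementation of the
path-dependent polynomial-time tree-Shapley algorithm (`woeqsar.treeshap`),
a numba kernel using an explicit-stack depth-first traversal over a shared
triangular path buffer addressed by integer offsets. It is verified in the
test suite against a brute-force subset-enumeration Shapley oracle on small
trees and by the additivity identity (base + Σφ = predicted probability,
to machine precision) on unbounded-depth forests. One 200-tree run over
1600 compounds × 881 bits takes about five seconds on one CPU.

Bits are ranked per endpoint by descending importance (ties broken by
ascending bit index, so rankings are deterministic), the top
`floor(881 × fraction)` bits are taken per endpoint (fraction 0.2 — the
first quintile, 176 bits), and the selected descriptor set is the
intersection of the three top sets, ordered by descending mean importance.
The floor convention for the quintile (176 rather than 177) is a package
choice; the fraction is a parameter. Selection never sees the test split.

On the generator's default conditions (below), the intersection recovers
≥ 80% of the planted shared core per seed while admitting ≈ 1% of
never-informative bits — the cross-endpoint intersection is exactly the
filter that separates "informative everywhere" from "informative
somewhere".

## Sub-models

Three algorithm families per endpoint, all scikit-learn estimators behind
one interface:

| family | estimator | default grid |
|---|---|---|
| RF | `RandomForestClassifier` | trees {100, 300, 500} × depth {∞, 10, 20} |
| SVM | `SVC`, RBF kernel, Platt-calibrated scores | C {0.1, 1, 10, 100} × γ {scale, 0.01, 0.1} |
| BP | `MLPClassifier`, one sigmoid hidden layer, early stopping | width {32, 64, 128} × L2 {1e-4, 1e-3} |

Grids are configuration, not contract. Grid search is exhaustive, scored by
stratified five-fold cross-validated accuracy (the robustness criterion Q),
and the best configuration is refit on the whole training split. Scores are
positive-class probabilities in [0,1] (vote fraction / Platt probability /
output activation); decisions are scores thresholded at 0.5. The BP
optimizer uses a raised initial learning rate (0.01) and patience (25
epochs), without which adam tends to stall at the majority class on small
binary panels. No class reweighting is applied. Everything is seeded; the
determinism contract (same data, grid, seed ⇒ same hyperparameters and
decisions) is tested. Because resubstitution and cross-validated accuracy
answer different questions, both are stored, labelled `train_accuracy` and
`cv_accuracy`.

`cross_validate` reports pooled out-of-fold accuracy; if a fold's training
part is single-class the partition is re-drawn once with a shifted seed
before erroring.

## Fusion

The fused verdict is deterministic: negative iff all three sub-decisions
are negative (logical OR otherwise). For threshold-free evaluation the
sub-model scores combine by the noisy-OR `1 − (1−s1)(1−s2)(1−s3)` — the
probability of at least one positive under independence. The fused score
dominates each component, and clearing the fused threshold `1−(1−t)³`
implies at least one sub-score clears `t`; the two rules coincide exactly
when sub-scores are binary (for general unequal scores only that one-sided
implication holds). The reference label for fusion evaluation is the OR of
the observed endpoint labels — overall mutagenicity under the same
evidence reading. Consequences that follow from the OR structure and are
asserted on arbitrary panels: fused sensitivity ≥ every sub-model's,
fused specificity ≤ every sub-model's, and with independent per-compound
errors the fused sensitivity is 1 − ∏(1 − rᵢ) (Monte-Carlo checked at
n = 10⁵ within 0.01). A trained logistic meta-classifier over the three
scores is available as an explicit alternative but is not the default.

## Metrics

Accuracy Q = (TP+TN)/n, precision TP/(TP+FP), recall TP/(TP+FN),
F1 = 2pr/(p+r), each also computed for the negative class by treating 0 as
the class of interest; AUC is the rank statistic with midrank ties
(verified against brute-force concordant-pair counting). A metric whose
denominator is zero is reported as an undefined marker (NaN / null), never
as 0 or 1. Printed tables round half-up to three decimals, and every
report row's F1 is recomputed from that row's own precision and recall in
the tests — reports are self-consistent by construction.

## Synthetic panels

The generator draws, per compound, 881 independent Bernoulli bits with
per-bit prevalence uniform on [0.05, 0.5]; endpoint k's label comes from a
logistic model `logit = aₖ + β·Σ_{j∈Sₖ} xⱼ` where Sₖ is a shared core C
(default 20 bits, informative for all three endpoints) plus a private set
(default 15 bits each, disjoint). The intercept aₖ is calibrated by root
finding on the realized bit matrix so the expected positive rate hits its
target — defaults 43.23 / 55.64 / 53.01%, echoing a real mutagenicity
panel's distribution. Labels are flipped with ε = 0.05; each endpoint then
emits 1–3 assay records (exercising singleton, majority and tie voting
paths) with 10% per-record flip noise and a 2% inconclusive rate, and 10%
of compounds lose one whole group. Everything is reproducible from
config + seed, and the ground truth (informative sets, pre-noise labels,
intercepts, dropped groups) is emitted alongside.

What the generator does *not* emulate: substructure co-occurrence (real
fingerprint bits are strongly correlated through shared fragments),
non-additive structure–activity relationships, and curation artifacts of
real databases. Passing recovery and fusion tests on these panels
demonstrates the pipeline's statistical machinery, not real-data headline
performance — real-data accuracies depend on the deposited dataset and are
out of the package's test surface.

## Problem sizes and numerical choices

The acceptance script runs feature recovery on five 2000-compound panels
(the generator's default size) and a full three-family pipeline on an
800-compound panel — sizes chosen so the whole script is a few minutes on
one CPU while keeping the selection problem at its default scale.
Degenerate inputs fail loudly: single-class labels, empty grids, empty
outcome lists, unknown assay codes, non-binary fingerprint cells and
misaligned compound sets all raise with the offending item named. An empty
cross-endpoint intersection warns and returns an empty selection rather
than raising, leaving the fallback to the caller.

## Known limitations

- Independent-bit panels overstate how cleanly SHAP rankings separate
  informative from null features relative to correlated real fingerprints.
- The noisy-OR fused score is one defensible score-level analogue of the
  OR rule; it assumes independent sub-model errors, which co-trained
  sub-models violate to some degree.
- SVM probability calibration (Platt) is itself cross-validated inside the
  fit, so SVM sub-model scores are smooth but can disagree near 0.5 with
  the uncalibrated decision function.
- The assay taxonomy is a closed list reflecting the standard batteries;
  genuinely new assay types must be mapped explicitly via the extension
  hook.
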