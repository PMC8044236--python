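# woeqsar — weight-of-evidence QSAR for mutagenicity

No single genotoxicity assay detects every mutagenic mechanism: Ames-negative
clastogens are real, and regulatory practice (the ICH S2(R1) batteries)
therefore judges a compound by a *combination* of assays — a bacterial
reverse-mutation slot, an in vivo mammalian cytogenetics slot, and a third
substitutable slot of in vitro and germ-cell assays. `woeqsar` implements a
QSAR pipeline built around that decision rule, for toxicologists and
cheminformaticians who want an early-warning classifier over compound panels
with heterogeneous assay evidence:

1. **Assay integration.** Raw compound × assay × outcome records are mapped
   to the three evidence groups Y1 (Ames), Y2 (erythrocyte micronucleus /
   bone-marrow chromosome aberration) and Y3 (in vitro chromosome
   aberration, TK, germ-cell assays, plus HGPRT/UDS/SLRL supplements).
   Redundant outcomes within a group are reconciled by majority vote with
   ties resolved **positive**; only complete cases (all three groups
   observed) are modelled.
2. **Features.** Each compound carries the 881 binary PubChem substructure
   keys, read in the PaDEL-Descriptor CSV dialect.
3. **Selection.** For each endpoint a random forest is fitted on the
   training split and every bit is scored by its mean absolute SHAP value
   (exact tree-path Shapley attributions, implemented in
   `woeqsar.treeshap`). The top quintile (⌊881/5⌋ = 176 bits) is taken per
   endpoint, and the modelling descriptors are the **intersection** of the
   three quintiles — bits that matter for all three kinds of evidence.
4. **Sub-models.** Per endpoint and algorithm family (random forest,
   RBF support-vector classifier, one-hidden-layer backpropagation
   network), hyperparameters are chosen by exhaustive grid search scored
   with stratified five-fold cross-validated accuracy Q.
5. **Fusion.** The three sub-model verdicts under one algorithm are fused
   by the evidence rule itself: *all-negative → negative, otherwise
   positive* (logical OR). For ROC analysis the sub-model scores combine by
   the noisy-OR, 1 − ∏(1 − sᵢ). The reference label is the OR of the
   observed endpoint labels.
6. **Evaluation.** Accuracy Q = (TP+TN)/n, per-class precision, recall and
   F1 = 2pr/(p+r), and rank-based ROC/AUC, reported for both the positive
   and negative class; undefined ratios (zero denominators) stay undefined
   rather than being coerced to 0.

A seeded synthetic-panel generator (`woeqsar.simulate`) emulates the whole
input side — fingerprint bits of varying prevalence, three correlated
endpoint labels driven by a planted shared core of informative bits,
redundant noisy assay records, inconclusive calls and missing groups — so
every stage is testable without any external download.

## Worked example

`examples/03_train_and_fuse.py` generates a 600-compound synthetic panel,
integrates its assay records, selects fingerprints, grid-searches
random-forest sub-models and fuses them:

```
Compounds after integration and joining: 521
Selected fingerprint bits: 14

model      split     acc  recall+  recall-    auc
Y1         test    0.587    0.568    0.600  0.605
Y2         test    0.558    0.660    0.463  0.592
Y3         test    0.587    0.769    0.404  0.597
fusion     test    0.654    0.818    0.185  0.599
```

The fused row shows the rule's designed trade: its sensitivity (recall⁺
0.818) dominates every sub-model's, while specificity (recall⁻) drops —
a compound flagged by any evidence group is flagged overall. The other
examples demonstrate assay integration and voting
(`examples/01_integrate_assays.py`) and recovery of the planted shared
core by the quintile intersection (`examples/02_select_fingerprints.py`).

There is also a thin CLI:

```bash
woeqsar simulate --seed 1 --out panel/          # synthetic panel -> CSVs
woeqsar run --assays panel/assays.csv --fingerprints panel/fingerprints.csv \
            --seed 1 --out results/             # full pipeline -> reports
```

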