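# isosig — transcript-isoform signatures of tumor stage and survival

Most transcriptome analyses of tumor progression work at the gene level.
This package implements the complementary view: for each gene, the
*relative* abundances of its transcript isoforms — PSI values, a
transcript's TPM divided by its gene's total TPM — are screened for
association with clinical stage (TNM/S annotation), reduced to compact
per-tumor-type signatures, and validated through survival analysis,
including a blind test that predicts the stage of unannotated patients
and asks whether the predicted groups differ in outcome.

It is written for computational biologists who have a transcript-level
quantification (e.g. from Salmon/Sailfish/kallisto), a transcript
annotation (GTF), and a clinical table, and who want a reproducible,
seeded implementation of the whole procedure — plus a synthetic-cohort
generator with planted ground truth so every stage can be tested without
any external data.

## The method

1. **Quantification** (`isosig.quantify`). Genes are defined
   structurally: transcripts that overlap on the same locus and strand
   and share at least one splice-site coordinate are merged (transitive
   closure). Gene TPM is the sum of member TPMs; PSI(t, s) =
   TPM(t, s) / geneTPM(g(t), s), defined only where the gene reaches
   0.1 TPM.

2. **Discriminant isoforms** (`isosig.select`). Features must first move:
   |ΔPSI| ≥ 0.1 between the compared groups (gene features: log₂ fold
   change ≥ 2). Candidates are then scored over 100 balanced subsample
   iterations. Per iteration the same number of samples is drawn from
   each group (per tumor type for pooled designs), values are discretized
   (supervised MDLP), and three entropy measures are computed against the
   labels, in bits:

   - information gain IG(S, A) = H(S) − H(S|A),
   - gain ratio GR(S, A) = IG(S, A)/H(A),
   - symmetrical uncertainty SU(S, A) = 2·IG(S, A)/(H(S) + H(A)).

   The labels of the drawn subset are permuted and the measures
   recomputed, giving a matched null. A feature is *discriminant* when
   its mean observed value exceeds its mean permuted value for all three
   measures.

3. **Signatures** (`isosig.select.cfs_select`, `isosig.classify`).
   Correlation feature selection reduces the discriminant set: best-first
   search maximizing merit(F) = k·r̄꜀f / √(k + k(k−1)·r̄ff), with
   feature–label relevance and feature–feature redundancy measured as SU.
   A logistic model tree (information-gain splits, LogitBoost
   simple-logistic leaves, CV-chosen boosting iterations, CV-error
   pruning) is fitted on the selected features and evaluated by
   stratified ten-fold cross-validation (repeated; AUC and
   precision–recall area per held-out fold).

4. **Validation** (`isosig.downstream`). Hallmark-style Fisher-exact
   enrichment on the expressed multi-transcript background with BH
   correction; Wilcoxon differential expression (|log₂FC| > 0.5,
   adjusted p < 0.05) to check that isoform signals are not expression in
   disguise; Kaplan–Meier curves with a binary-covariate Cox model
   (Efron ties); and the blind test — for tumor types whose labeled
   early/late groups already separate in survival, unlabeled samples are
   predicted with that type's signature, pooled across types by predicted
   class, and compared by Cox regression.

5. **Synthetic cohorts** (`isosig.simulate`). Dirichlet isoform
   proportions around per-gene baselines, planted logit-scale PSI shifts,
   lognormal gene expression with planted fold changes, exponential
   survival with a group hazard ratio, independent censoring, and a
   fraction of blanked stage labels — with the ground truth returned
   alongside.

## Worked example

The `analysis/` scripts run the whole study on a simulated two-type
cohort (240 samples, 500 three-isoform genes, 10 planted isoform
switches of ΔPSI = 0.3, survival hazard ratio 2 for late-stage, 25 % of
stage labels blanked):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_quantify_psi.py
python analysis/03_select_discriminant_isoforms.py
python analysis/04_train_signatures.py
python analysis/05_blind_test.py
python analysis/06_downstream_characterization.py
```

Output of the selection, training and blind-test steps:

```
TT1: 47+43 labeled samples; 30 gated, 30 discriminant (10/10 planted switches found)
TT2: 47+43 labeled samples; 30 gated, 30 discriminant (10/10 planted switches found)

TT1: signature of 10 isoforms (G0005.t1, G0007.t1, G0008.t1, G0001.t1...); AUC mean 1.000 [1.000, 1.000], PRC mean 1.000
TT2: signature of 9 isoforms (G0002.t1, G0005.t1, G0010.t1, G0009.t1...); AUC mean 1.000 [1.000, 1.000], PRC mean 1.000

types with significant labeled-survival difference: ['TT2']
predicted 30 unlabeled samples (30 match the hidden truth)
predicted-late vs predicted-early survival: HR = 2.34, Cox p = 6.33e-02 (13+17 samples, 25 events)
```

Reading this: every planted isoform switch passes the effect gate and the
permutation test in both tumor types (each planted gene contributes its
shifted transcript and partially shifted siblings, hence 30 discriminant
transcripts from 10 genes); CFS compresses them to about ten transcripts
per type, and cross-validated accuracy is essentially perfect at this
planted effect size. Only TT2 passes the survival-eligibility gate for
the blind test in this draw (with ~90 labeled samples per type and a
true hazard ratio of 2, the labeled-survival Cox test itself has limited
power). Its signature labels all 30 held-out unannotated samples
correctly; the predicted groups show the expected hazard ratio (2.34 vs
a planted 2) but with only 30 samples in the pool the contrast stops
just short of significance (p = 0.063) — a useful reminder that the
blind test's power comes from aggregating predictions across tumor
types, which the validation suite exercises at larger scale. The
downstream step finds the planted gene set enriched (FDR < 0.05), no
overlap between signature genes and differentially expressed genes, and
no correlation of signature PSIs with a cohort gene-set score
(max |R| ≈ 0.14).

The same stages are available as a CLI for file-based pipelines:
`isosig simulate | quantify | select | train | blindtest | enrich |
survival | subgroup` (see `isosig --help`). Per-tumor-type early/late
stage groupings ship as an editable YAML configuration
(`src/isosig/resources/stage_groups.yaml`).

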