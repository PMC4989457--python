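# Methods

This note records the model assumptions, the defaults and why they were
chosen, the numerical conventions, and what the synthetic cohorts do and
do not establish about real data.

## Quantification model

A gene is defined structurally, not by an external gene annotation: the
transitive closure of "same chromosome and strand, overlapping spans,
and at least one shared splice-site coordinate". Because a shared splice
site lies strictly inside both transcripts' spans, sharing a site
already implies span overlap, so the implementation unions transcripts
per shared site coordinate and the closure follows from union-find.
Mono-exonic transcripts have no splice sites and always form singleton
genes. Gene ids are deterministic (`gene-` + lexicographically smallest
member transcript id) so runs are comparable.

PSI is transcript TPM over gene TPM, reported only where the gene
reaches the expression floor (default 0.1 TPM) in that sample; below the
floor all of the gene's PSIs are missing rather than zero, because a
ratio of two near-zero abundances is noise, not biology. Where present,
a gene's PSIs sum to 1 within 1e-9 by construction. PSI is invariant to
rescaling a sample's library (TPM normalization cancels).

Effect sizes use per-group means over present values only; a feature
must be observed in at least 80 % of each group's samples to enter
selection, and nothing is imputed at this stage — imputing PSI would
manufacture the very signal being tested. Gene-level effects are log₂
fold changes of group means with a pseudo-count of 0.01 TPM.

## Feature selection

The selection is deliberately two-gated. The effect gate (|ΔPSI| ≥ 0.1
for isoform features, ≥ 2 log₂ units for gene features, both measured on
the full comparison cohort) removes features whose difference is too
small to matter clinically regardless of significance. The permutation
gate then asks whether the association survives label exchange: over 100
iterations, a balanced subsample (the per-group minimum, drawn per tumor
type for pooled designs, so the larger group is subsampled and the
smaller exhausted) is discretized and scored with IG, GR and SU; the
same subsample with permuted labels is scored identically, including
re-discretization, so the null undergoes exactly the procedure the
observed data does. A feature is discriminant when the observed mean
exceeds the permuted mean for all three measures. The three measures
weight the same mutual information differently (GR penalizes
many-valued discretizations, SU symmetrizes), so requiring agreement of
all three guards against artifacts of any single normalization.

Discretization is Fayyad–Irani MDLP: recursive entropy-minimizing cuts
at boundaries between distinct adjacent values, accepted while the
information gain exceeds the minimum-description-length coding cost.
When no cut is accepted the feature falls back to a single median cut —
a feature should fail by scoring low, not by disappearing; a constant
feature gets one bin and scores exactly zero. An unsupervised
equal-frequency tertile strategy is available as a config switch
(`equal_frequency_k3`) so the sensitivity of results to the
discretization choice can be audited. Entropies are base 2 throughout.

CFS correlations are computed once on the full comparison cohort rather
than per subsample, for selection stability. Missing values are placed
in a dedicated extra bin so every vector stays total. The best-first
search expands subsets by single additions and stops after 15
expansions without improvement; on instances of up to 10 candidates this
matches exhaustive subset enumeration exactly (verified per run in the
acceptance checks), while remaining a genuine heuristic search at
realistic candidate counts.

## Classifier

The logistic model tree is re-implemented in simplified but faithful
form; bit-compatibility with any particular toolkit is not promised.
Leaves are "simple logistic" committees: LogitBoost where each round
fits a one-attribute weighted least-squares line to the working
response (working responses clipped at ±4, weights floored at 1e-6,
step damping 0.5). Since every base learner is linear, a leaf collapses
to an intercept plus one weight per feature, which keeps models small
and serializable as plain JSON. The boosting iteration count (max 200)
is chosen by internal stratified 5-fold cross-validated log-loss once at
the root and reused in subtrees. The tree grows by information-gain
splits (min 15 samples to split, min 5 per child, max depth 4) and each
node is pruned to a leaf whenever the leaf model's CV error is no worse
than its subtree's.

Accuracy is estimated by stratified k-fold cross-validation: AUC in the
Mann–Whitney formulation (ties count half) and precision–recall area
with step-wise interpolation, which avoids the optimistic trapezoid
bias. Fold counts drop to the minority-class size when necessary. The
mean reported is over all fold-level values. Missing feature values are
median-imputed from training folds only. The default is 10 repeats of
10 folds — 100 fits — which bounds the Monte-Carlo error of the mean AUC
well below the effects of interest; the repeat count is config-exposed
for heavier production runs (the classical choice is 100 repeats).
Sample order does not affect results for a fixed seed: folds are built
on a canonical ordering (label, then feature values).

## Survival and the blind test

Survival is days from collection to death (deceased) or last contact
(censored); a direct `survival_days` column takes precedence over dates.
Group contrasts use Kaplan–Meier curves plus a single binary-covariate
Cox proportional-hazards fit with Efron tie handling (via lifelines);
the reported p is the Wald test of the group coefficient and the hazard
ratio its exponential. Cox-Wald, not the log-rank test, is the primary
comparison throughout.

The blind test predicts only samples whose stage label is missing, with
the signature of their own tumor type, at probability threshold 0.5, and
only for tumor types whose labeled early/late groups already differ in
survival (Cox p < 0.05) — predicting survival-relevant stage only makes
sense where stage is survival-relevant. Predicted-early and
predicted-late pools are aggregated across types and compared with one
pooled Cox fit. Labeled samples are never predicted; the tests assert
this leak-freedom by construction.

## Downstream screens

Enrichment is a two-sided Fisher exact test per gene set, on the
background of expressed (mean gene TPM ≥ 0.1) multi-transcript genes —
single-isoform genes cannot produce isoform switches, so including them
would inflate significance — with Benjamini–Hochberg control at
FDR < 0.05. Differential expression is a Wilcoxon rank-sum test per gene
with BH adjustment, flagged at |log₂FC| > 0.5 and adjusted p < 0.05; a
non-parametric test was chosen because TPM distributions are heavy-
tailed, and the test is config-exposed.

The gene-set sample score used for the stromal/immune screen is a
rank-z mean: each set gene's expression is ranked across the cohort,
rank-standardized, and averaged per sample. This is deliberately simple
and is *not* a GSVA implementation (output headers name it
`geneset_score`); its downstream use is only a Pearson correlation
screen against signature PSIs, which is robust to the scoring flavor.
The |R| reporting threshold (0.4 by convention) is a parameter, not a
constant. Robust z-scores for applying external gene signatures are
(x − median)/(1.4826·MAD) per gene, zero where the MAD vanishes.

## Synthetic cohorts

The generator emulates the data model the pipeline assumes. Per gene, a
baseline isoform-proportion vector is drawn (Dirichlet, α = 2); per
sample, proportions are drawn around it with a single concentration
parameter (default 30, giving a within-group PSI standard deviation of
roughly 0.09 for a mid-range isoform — the scale seen for moderately
expressed genes). A planted switch moves the designated transcript's
baseline by ΔPSI on the logit scale in the late group, renormalizing the
siblings proportionally, so the realized mean ΔPSI equals the nominal
value (the generator refuses baselines with no room for the shift).
Gene expression is lognormal (per-gene location N(2, 1) in ln-TPM,
within-gene sd 0.4); planted expression changes multiply the late group
by 2^log2fc. Transcript TPM is gene TPM times proportion, so member
sums reproduce gene expression exactly and the intended gene partition
is recovered exactly by splice-site grouping (isoforms share their first
exon's donor; no sites cross genes). Survival is exponential (default
median ≈ 2.8 years for early samples) with a group hazard ratio and
independent exponential censoring; a configurable fraction of samples
has all stage labels blanked, with the truth retained separately.
Planted effects are placed one per gene.

What passing tests on these cohorts does **not** show about real data:
there are no batch effects, no tumor-purity confounding, no correlated
gene modules, no length or GC biases, no mapping uncertainty in the
TPMs, and isoform counts per gene are uniform. The cohorts establish
that the *procedure* is correct and calibrated — that it recovers known
signals, stays silent under the null, and is seed-reproducible — not
that real tumors contain such signals.

One subtlety the generator makes explicit: a planted isoform switch
necessarily moves the sibling isoforms of the same gene (proportions sum
to one; with two isoforms the sibling shifts by exactly −ΔPSI).
Recovery is therefore scored at the planted-gene level — detecting a
planted gene through any of its transcripts is a true detection — while
the ground truth still records the designated shifted transcript.

## Problem sizes and numerical conventions

The validation suite runs planted-recovery at 20 cohorts of 1020
transcripts and 50+50 samples, null calibration over 3 independent null
cohorts (a single finite null dataset shows chance feature–label
correlations in every CV fold, so the flagged fraction and chance-AUC
are averaged), survival coverage over 200 replicates of 60+60, and the
blind test over 20 two-type cohorts of 120+120 with 30 % blanked
labels; these sizes give stable estimates at desk scale.
Quantile-group sizes use floor(n·fraction); ties in rankings break by
lexicographic sample id and are logged. All randomness flows from
explicit integer seeds; per-iteration streams derive from (seed,
iteration) so subsampling is bit-reproducible. Missing values are a
single reserved token (`NA`) in files and NaN/None in memory. GTF
coordinates are 1-based inclusive. Duplicate clinical rows are rejected
rather than reconciled.

## Known limitations

The LMT is a faithful simplification, not a port; exotic options of the
original (weight trimming, nominal attributes) are absent. Multi-class
(>2 group) comparisons, covariate-adjusted Cox models, competing risks,
and event-level (local splicing) PSI computation are out of scope —
event PSI matrices produced elsewhere flow through the pipeline as
ordinary feature matrices. The generator does not simulate reads; it
starts from abundances.
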