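"""Downstream characterization of signatures: hallmark enrichment,
differential expression, survival comparison, the blind test on
unlabeled samples, and gene-set sample scores.

Survival handling follows the standard right-censored setup: Kaplan-Meier
curves per group and a single binary-covariate Cox proportional-hazards
fit (Efron tie handling) whose Wald p value compares the groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classify import SignatureModel
from .dataio import ComparisonDesign, GeneSetCollection
from .quantify import LOGFC_EPSILON, PsiMatrix

logger = logging.getLogger(__name__)

DE_LOG2FC_THRESHOLD = 0.5
DE_ALPHA = 0.05
ENRICHMENT_FDR = 0.05
BLIND_ELIGIBILITY_ALPHA = 0.05
PREDICTION_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# Hallmark enrichment
# ---------------------------------------------------------------------------


def fisher_enrichment(
    query_genes: set[str],
    background_genes: set[str],
    sets: GeneSetCollection,
    fdr_threshold: float = ENRICHMENT_FDR,
) -> pd.DataFrame:
    """Two-sided Fisher exact test of the query genes against each set.

    The background should be the expressed multi-transcript genes of the
    cohort; the query (genes with selected isoforms) must be a subset of
    it.  Benjamini-Hochberg correction is applied across the tested sets;
    a set with no background overlap is skipped and logged.  Returns one
    row per tested set: a, b, c, d counts, odds_ratio, p, fdr,
    significant.
    """
    if not query_genes <= background_genes:
        raise ValueError("query genes must be a subset of the background")
    if not query_genes:
        logger.info("fisher_enrichment: empty query, no tests performed")
        return _empty_enrichment()
    rows = []
    for name, genes in sets:
        in_bg = genes & background_genes
        if not in_bg:
            logger.info("fisher_enrichment: set %r disjoint from background, skipped", name)
            continue
        a = len(query_genes & in_bg)
        b = len(query_genes - in_bg)
        c = len(in_bg - query_genes)
        d = len(background_genes) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((name, a, b, c, d, float(odds) if np.isfinite(odds) else np.inf, float(p)))
    if not rows:
        return _empty_enrichment()
    out = pd.DataFrame(
        rows, columns=["set_name", "a", "b", "c", "d", "odds_ratio", "p"]
    ).set_index("set_name")
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_threshold
    return out


def _empty_enrichment() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["a", "b", "c", "d", "odds_ratio", "p", "fdr", "significant"],
        index=pd.Index([], name="set_name"),
    )


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------


def differential_expression(
    gene_expr: pd.DataFrame,
    design: ComparisonDesign,
    *,
    log2fc_threshold: float = DE_LOG2FC_THRESHOLD,
    alpha: float = DE_ALPHA,
    epsilon: float = LOGFC_EPSILON,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum contrast between the design groups.

    A gene is flagged differentially expressed when |log2FC| of the group
    means exceeds *log2fc_threshold* and its BH-adjusted p value is below
    *alpha*.  A gene constant across both groups gets p = 1.
    """
    early = gene_expr[list(design.group_early)]
    late = gene_expr[list(design.group_late)]
    if early.shape[1] < 3 or late.shape[1] < 3:
        raise ValueError("differential expression needs >= 3 samples per group")
    mean_early = early.mean(axis=1)
    mean_late = late.mean(axis=1)
    log2fc = np.log2((mean_late + epsilon) / (mean_early + epsilon))
    pvals = np.ones(len(gene_expr))
    e_arr, l_arr = early.to_numpy(), late.to_numpy()
    for i in range(len(gene_expr)):
        x, y = l_arr[i], e_arr[i]
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            continue  # constant in both groups: p stays 1
        pvals[i] = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
    out = pd.DataFrame(
        {"log2fc": log2fc, "p": pvals},
        index=gene_expr.index.rename("gene_id"),
    )
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["de_flag"] = (out["log2fc"].abs() > log2fc_threshold) & (out["p_adj"] < alpha)
    return out


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


@dataclass
class SurvivalComparison:
    """KM curves per group plus a binary-covariate Cox contrast."""

    km_curves: dict[str, pd.DataFrame]  # columns: time, survival, at_risk
    hazard_ratio: float
    cox_p: float
    coef: float
    coef_se: float
    n_per_group: dict[str, int]
    n_events: int
    comparable: bool = True

    @property
    def hr_ci95(self) -> tuple[float, float]:
        lo = self.coef - 1.959963984540054 * self.coef_se
        hi = self.coef + 1.959963984540054 * self.coef_se
        return float(np.exp(lo)), float(np.exp(hi))


def survival_compare(
    clinical: pd.DataFrame,
    group_a: Iterable[str],
    group_b: Iterable[str],
    *,
    group_names: tuple[str, str] = ("a", "b"),
    min_group: int = 5,
) -> SurvivalComparison:
    """Kaplan-Meier curves and Cox PH contrast between two sample groups.

    The hazard ratio is exp(coef) for membership in *group_b* relative to
    *group_a*; the p value is the Wald test of the Cox coefficient with
    Efron tie handling.  Requires *min_group* samples with survival data
    per group and at least one event overall.
    """
    frames = {}
    for name, group in zip(group_names, (group_a, group_b)):
        ids = [s for s in group if s in clinical.index]
        sub = clinical.loc[ids, ["survival_days", "event"]].dropna(subset=["survival_days"])
        if len(sub) < min_group:
            raise ValueError(
                f"group {name!r}: {len(sub)} samples with survival data, need >= {min_group}"
            )
        frames[name] = sub
    total_events = int(sum(f["event"].sum() for f in frames.values()))
    if total_events == 0:
        raise ValueError("no events in either group")

    km_curves = {}
    for name, sub in frames.items():
        kmf = KaplanMeierFitter()
        kmf.fit(sub["survival_days"], event_observed=sub["event"].astype(int))
        table = kmf.event_table
        km_curves[name] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(dtype=float),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
                "at_risk": table["at_risk"].reindex(kmf.survival_function_.index).to_numpy(dtype=float),
            }
        )

    df = pd.concat(
        [f.assign(group=i) for i, (_, f) in enumerate(frames.items())]
    )
    df["event"] = df["event"].astype(int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="survival_days", event_col="event", formula="group")
    coef = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    return SurvivalComparison(
        km_curves=km_curves,
        hazard_ratio=float(np.exp(coef)),
        cox_p=float(cph.summary.loc["group", "p"]),
        coef=coef,
        coef_se=se,
        n_per_group={name: len(f) for name, f in frames.items()},
        n_events=total_events,
    )


# ---------------------------------------------------------------------------
# Blind test
# ---------------------------------------------------------------------------


@dataclass
class BlindTestResult:
    predictions: pd.DataFrame  # sample_id, tumor_type, p_late, predicted
    survival: SurvivalComparison | None
    eligible_types: list[str]
    comparable: bool


def blind_test(
    models: Mapping[str, SignatureModel],
    features_per_type: Mapping[str, PsiMatrix | pd.DataFrame],
    clinical: pd.DataFrame,
    class_name: str,
    eligible_types: Iterable[str],
    *,
    threshold: float = PREDICTION_THRESHOLD,
) -> BlindTestResult:
    """Predict the missing stage of unlabeled samples, then compare
    survival between the aggregated predicted-early and predicted-late
    pools.

    Only samples whose *class_name* label is missing are predicted, and
    only for tumor types in *eligible_types* (types where the labeled
    early/late groups already differ in survival).  Labeled samples are
    never touched.  When either predicted pool is empty the result is
    flagged not comparable.
    """
    col = f"stage_{class_name}" if class_name in set("TNMS") else class_name
    eligible = sorted(set(eligible_types) & set(models))
    rows = []
    for ttype in eligible:
        model = models[ttype]
        feats = features_per_type[ttype]
        values = feats.values if isinstance(feats, PsiMatrix) else feats
        in_type = clinical.index[(clinical["tumor_type"] == ttype)]
        unlabeled = [
            s for s in in_type
            if pd.isna(clinical.at[s, col]) and s in values.columns
        ]
        if not unlabeled:
            continue
        prob = model.predict_proba(values[unlabeled])
        for s in unlabeled:
            rows.append((s, ttype, float(prob[s]), "late" if prob[s] >= threshold else "early"))
    predictions = pd.DataFrame(
        rows, columns=["sample_id", "tumor_type", "p_late", "predicted"]
    ).set_index("sample_id")
    pred_early = predictions.index[predictions["predicted"] == "early"].tolist()
    pred_late = predictions.index[predictions["predicted"] == "late"].tolist()
    if not pred_early or not pred_late:
        logger.info("blind_test: a predicted pool is empty; not comparable")
        return BlindTestResult(predictions, None, eligible, comparable=False)
    try:
        surv = survival_compare(
            clinical, pred_early, pred_late, group_names=("early", "late")
        )
    except ValueError as exc:
        logger.info("blind_test: survival comparison impossible (%s)", exc)
        return BlindTestResult(predictions, None, eligible, comparable=False)
    return BlindTestResult(predictions, surv, eligible, comparable=True)


def eligible_types_for_blind_test(
    clinical: pd.DataFrame,
    designs: Mapping[str, ComparisonDesign],
    alpha: float = BLIND_ELIGIBILITY_ALPHA,
) -> list[str]:
    """Tumor types whose labeled early/late groups differ in survival
    (Cox p < alpha), the gate for running the blind test."""
    eligible = []
    for ttype, design in designs.items():
        try:
            cmp = survival_compare(
                clinical, design.group_early, design.group_late,
                group_names=("early", "late"),
            )
        except ValueError:
            continue
        if cmp.cox_p < alpha:
            eligible.append(ttype)
    return sorted(eligible)


# ---------------------------------------------------------------------------
# Gene-set sample scores and PSI correlation
# ---------------------------------------------------------------------------


def geneset_sample_score(gene_expr: pd.DataFrame, gene_set: set[str]) -> pd.Series:
    """Rank-z gene-set score per sample.

    Each set gene's expression is ranked across the cohort and converted
    to a z-score of the ranks; the sample score is the mean over set
    genes.  The score is invariant to per-gene monotone transforms; it is
    a deliberately simple summary, not a GSVA implementation.
    """
    present = sorted(gene_set & set(gene_expr.index))
    if len(present) < 5:
        raise ValueError(f"only {len(present)} set genes present, need >= 5")
    sub = gene_expr.loc[present]
    ranks = sub.rank(axis=1, method="average")
    sd = ranks.std(axis=1, ddof=1).replace(0.0, np.nan)
    z = ranks.sub(ranks.mean(axis=1), axis=0).div(sd, axis=0)
    return z.mean(axis=0, skipna=True).rename("geneset_score")


def correlate_psi_scores(
    psi: PsiMatrix | pd.DataFrame,
    model_features: Sequence[str],
    scores: pd.Series,
    *,
    min_pairs: int = 10,
) -> pd.Series:
    """Pearson correlation of each model transcript's PSI with the
    per-sample scores; features with < *min_pairs* complete pairs are
    dropped (logged), zero-variance features report NaN."""
    values = psi.values if isinstance(psi, PsiMatrix) else psi
    common = [s for s in scores.index if s in values.columns]
    out = {}
    for fid in model_features:
        if fid not in values.index:
            logger.info("correlate_psi_scores: feature %r absent, dropped", fid)
            continue
        v = values.loc[fid, common].to_numpy(dtype=float)
        s = scores[common].to_numpy(dtype=float)
        mask = np.isfinite(v) & np.isfinite(s)
        if mask.sum() < min_pairs:
            logger.info("correlate_psi_scores: feature %r has %d pairs, dropped", fid, mask.sum())
            continue
        if np.std(v[mask]) == 0 or np.std(s[mask]) == 0:
            out[fid] = np.nan
            continue
        out[fid] = float(stats.pearsonr(v[mask], s[mask]).statistic)
    return pd.Series(out, name="pearson_r", dtype=float)


def robust_zscores(gene_expr: pd.DataFrame) -> pd.DataFrame:
    """Robust z-scores per gene: (x - median) / (1.4826 * MAD) across
    samples, zero where the MAD vanishes."""
    if gene_expr.shape[1] < 3:
        raise ValueError("robust z-scores need >= 3 samples")
    med = gene_expr.median(axis=1)
    mad = (gene_expr.sub(med, axis=0)).abs().median(axis=1) * 1.4826
    z = gene_expr.sub(med, axis=0).div(mad.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)
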