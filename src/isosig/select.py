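"""Permutation-calibrated univariate feature selection and CFS.

The selection procedure compares two patient groups through repeated
balanced subsampling: at each iteration the same number of samples is
drawn from each group (per tumor type for pooled designs), the candidate
features are discretized, and information gain, gain ratio and
symmetrical uncertainty are computed against the group labels.  The
labels of the drawn subset are then permuted and the measures
recalculated, giving a matched null.  A feature is *discriminant* when
its effect size passes the gate (|dPSI| >= 0.1 for isoform features, or
the log-fold threshold for gene features) and its mean observed value
exceeds its mean permuted value for all three measures.

Discriminant features are then reduced to a non-redundant subset with
correlation feature selection (CFS): best-first search over feature
subsets maximizing

    merit(F) = k * mean(r_cf) / sqrt(k + k (k-1) * mean(r_ff)),

with feature-label relevance r_cf and feature-feature redundancy r_ff
both measured as symmetrical uncertainty on the discretized values.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import ComparisonDesign
from .discretize import fit_discretizer
from .infotheory import information_measures, symmetrical_uncertainty
from .quantify import PsiMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of the subsampling selection.

    n_iterations: balanced subsample draws (study value 100).
    min_group: minimum samples per group to attempt selection.
    effect_threshold: |delta| gate — 0.1 on the PSI scale for isoform
        features, 2 (log2 fold) for gene-expression features.
    discretization: 'mdlp' or 'equal_frequency_k3'.
    """

    n_iterations: int = 100
    min_group: int = 10
    effect_threshold: float = 0.1
    discretization: str = "mdlp"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.min_group < 2:
            raise ValueError("min_group must be >= 2")


MEASURES = ("ig", "gr", "su")

STATS_COLUMNS = [
    "delta",
    "obs_ig", "obs_gr", "obs_su",
    "null_ig", "null_gr", "null_su",
    "n_iterations_used",
    "discriminant",
]


def _balanced_draw(
    design: ComparisonDesign, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """One balanced draw: n_sub = min(group sizes) from each group, without
    replacement; pooled designs draw the per-tumor-type minimum from each
    type so every type contributes equally to both groups."""
    types = sorted({design.tumor_type_of.get(s, "") for s in design.samples})
    early, late = [], []
    for t in types:
        e = [s for s in design.group_early if design.tumor_type_of.get(s, "") == t]
        l = [s for s in design.group_late if design.tumor_type_of.get(s, "") == t]
        n_sub = min(len(e), len(l))
        if n_sub == 0:
            continue
        early.extend(rng.choice(np.array(e, dtype=object), size=n_sub, replace=False))
        late.extend(rng.choice(np.array(l, dtype=object), size=n_sub, replace=False))
    return early, late


def subsample_selection(
    features: PsiMatrix | pd.DataFrame,
    design: ComparisonDesign,
    effects: pd.DataFrame,
    cfg: SelectionConfig,
) -> pd.DataFrame:
    """Score effect-gated features over balanced subsample iterations.

    Returns a DataFrame (one row per candidate feature, columns
    ``STATS_COLUMNS``): mean observed and mean permuted IG/GR/SU in bits,
    the full-cohort effect size, the number of iterations in which the
    feature could be scored, and the discriminant flag.  Fully
    reproducible from ``cfg.seed``.
    """
    values = features.values if isinstance(features, PsiMatrix) else features
    n_early, n_late = len(design.group_early), len(design.group_late)
    if min(n_early, n_late) < cfg.min_group:
        raise ValueError(
            f"design {design.class_name}: group sizes {n_early}/{n_late} "
            f"below min_group={cfg.min_group}"
        )
    candidates = effects.index[effects["delta"].abs() >= cfg.effect_threshold]
    candidates = [f for f in candidates if f in values.index]
    stats = pd.DataFrame(
        0.0, index=pd.Index(candidates, name="feature_id"), columns=STATS_COLUMNS
    )
    stats["delta"] = effects.loc[candidates, "delta"]
    stats["n_iterations_used"] = 0
    if not candidates:
        stats["discriminant"] = False
        return stats

    X_full = values.loc[candidates]
    acc = {f"{kind}_{m}": np.zeros(len(candidates)) for kind in ("obs", "null") for m in MEASURES}
    used = np.zeros(len(candidates), dtype=int)

    for it in range(cfg.n_iterations):
        rng = np.random.default_rng((cfg.seed, it))
        early, late = _balanced_draw(design, rng)
        drawn = list(early) + list(late)
        y = np.array([0] * len(early) + [1] * len(late))
        y_perm = rng.permutation(y)
        X = X_full[drawn].to_numpy(dtype=float)
        for j in range(len(candidates)):
            row = X[j]
            finite = np.isfinite(row)
            if finite.sum() < 4:
                continue
            v = row[finite]
            obs = _measures_for(v, y[finite], cfg.discretization)
            null = _measures_for(v, y_perm[finite], cfg.discretization)
            if obs is None or null is None:
                continue
            used[j] += 1
            for m, val in zip(MEASURES, obs):
                acc[f"obs_{m}"][j] += val
            for m, val in zip(MEASURES, null):
                acc[f"null_{m}"][j] += val

    with np.errstate(invalid="ignore"):
        denom = np.where(used > 0, used, 1)
        for key, totals in acc.items():
            stats[key] = totals / denom
    stats["n_iterations_used"] = used
    positive = np.ones(len(candidates), dtype=bool)
    for m in MEASURES:
        positive &= (stats[f"obs_{m}"] - stats[f"null_{m}"]).to_numpy() > 0
    stats["discriminant"] = positive & (used > 0)
    stats["discriminant"] = stats["discriminant"].astype(bool)
    return stats


def _measures_for(
    v: np.ndarray, y: np.ndarray, strategy: str
) -> tuple[float, float, float] | None:
    if len(np.unique(y)) < 2:
        return None
    disc = fit_discretizer(v, y, strategy=strategy)
    return information_measures(disc.transform(v), y)


# ---------------------------------------------------------------------------
# Correlation feature selection
# ---------------------------------------------------------------------------


def cfs_merit(r_cf: np.ndarray, r_ff: np.ndarray, subset: tuple[int, ...]) -> float:
    """CFS merit of a feature subset given relevance and redundancy tables."""
    k = len(subset)
    if k == 0:
        return 0.0
    sum_cf = float(r_cf[list(subset)].sum())
    sum_ff = 0.0
    for a, b in itertools.combinations(subset, 2):
        sum_ff += r_ff[a, b]
    return sum_cf / np.sqrt(k + 2.0 * sum_ff)


def _discretize_matrix(
    X: pd.DataFrame, y: np.ndarray, strategy: str
) -> np.ndarray:
    """Discretize every feature against the labels; missing values get a
    dedicated extra bin so all vectors stay total."""
    bins = np.zeros(X.shape, dtype=np.int64)
    for j, (_, row) in enumerate(X.iterrows()):
        v = row.to_numpy(dtype=float)
        finite = np.isfinite(v)
        if finite.sum() < 4 or np.nanmin(v) == np.nanmax(v):
            bins[j, :] = 0
            bins[j, ~finite] = 1
            continue
        disc = fit_discretizer(v[finite], y[finite], strategy=strategy)
        b = np.empty(len(v), dtype=np.int64)
        b[finite] = disc.transform(v[finite])
        b[~finite] = disc.n_bins  # missing bin
        bins[j] = b
    return bins


def cfs_select(
    candidate_features: pd.DataFrame,
    labels: np.ndarray,
    *,
    strategy: str = "mdlp",
    stall_limit: int = 15,
) -> list[str]:
    """Best-first CFS over discriminant features; returns a non-empty,
    relevance-ordered feature subset.

    The search expands subsets by single-feature additions, keeps the
    best merit seen, and stops after *stall_limit* consecutive expansions
    without improvement.  Correlations are symmetrical uncertainties on
    the full comparison cohort.
    """
    feature_ids = list(candidate_features.index)
    if not feature_ids:
        raise ValueError("cfs_select needs at least one candidate feature")
    y = np.asarray(labels, dtype=np.int64)
    if len(y) != candidate_features.shape[1]:
        raise ValueError("labels length must match number of samples")
    bins = _discretize_matrix(candidate_features, y, strategy)
    p = len(feature_ids)
    r_cf = np.array([symmetrical_uncertainty(bins[j], y) for j in range(p)])
    r_ff = np.full((p, p), np.nan)

    def ff(a: int, b: int) -> float:
        if np.isnan(r_ff[a, b]):
            val = symmetrical_uncertainty(bins[a], bins[b])
            r_ff[a, b] = r_ff[b, a] = val
        return r_ff[a, b]

    def merit(subset: frozenset[int]) -> float:
        k = len(subset)
        if k == 0:
            return 0.0
        sum_cf = float(r_cf[list(subset)].sum())
        sum_ff = sum(ff(a, b) for a, b in itertools.combinations(sorted(subset), 2))
        return sum_cf / float(np.sqrt(k + 2.0 * sum_ff))

    start: frozenset[int] = frozenset()
    best_subset, best_merit = start, 0.0
    frontier: list[tuple[float, tuple[int, ...]]] = [(0.0, ())]
    visited: set[frozenset[int]] = {start}
    stall = 0
    while frontier and stall < stall_limit:
        _, subset_t = heapq.heappop(frontier)
        subset = frozenset(subset_t)
        improved = False
        for j in range(p):
            if j in subset:
                continue
            child = subset | {j}
            if child in visited:
                continue
            visited.add(child)
            m = merit(child)
            heapq.heappush(frontier, (-m, tuple(sorted(child))))
            if m > best_merit + 1e-12:
                best_merit, best_subset = m, child
                improved = True
        stall = 0 if improved else stall + 1

    if not best_subset:
        best_subset = frozenset({int(np.argmax(r_cf))})
    ordered = sorted(best_subset, key=lambda j: (-r_cf[j], feature_ids[j]))
    return [feature_ids[j] for j in ordered]
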