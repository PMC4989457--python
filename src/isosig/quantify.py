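"""Gene construction from transcripts, PSI quantification, and effect sizes.

A *gene* is a maximal set of transcripts that overlap on the same genomic
locus and strand and are transitively connected by sharing at least one
splice-site coordinate.  Gene TPM is the sum of member-transcript TPMs,
and a transcript's PSI (percent spliced in) is its TPM divided by the
gene TPM, defined only where the gene is expressed above a minimum TPM.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataio import ComparisonDesign, TranscriptAnnotation

logger = logging.getLogger(__name__)

#: Minimum gene TPM for PSI to be defined in a sample.
DEFAULT_MIN_GENE_TPM = 0.1

#: Pseudo-count (TPM) for log-fold changes of gene expression.
LOGFC_EPSILON = 0.01


@dataclass(frozen=True)
class GeneGrouping:
    """Partition of transcripts into genes."""

    gene_of: dict[str, str]
    members: dict[str, tuple[str, ...]]

    def __len__(self) -> int:
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.gene_of.items()), columns=["transcript_id", "gene_id"]
        )


@dataclass
class PsiMatrix:
    """Per-transcript relative abundances in [0, 1], NaN where the parent
    gene falls below the expression threshold in that sample."""

    values: pd.DataFrame
    gene_of: dict[str, str]

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_gene_groups(annotations: Sequence[TranscriptAnnotation]) -> GeneGrouping:
    """Merge transcripts into genes by transitive closure of the relation
    "span overlap AND same chrom/strand AND >=1 shared splice-site".

    Mono-exonic or unconnected transcripts form singleton genes.  Gene ids
    are deterministic: ``gene-`` prefixed to the lexicographically smallest
    member transcript id.
    """
    anns = list(annotations)
    uf = _UnionFind(len(anns))
    # A shared splice site lies strictly inside both spans, so sharing a
    # site on the same chrom/strand already implies genomic overlap.
    by_site: dict[tuple[str, str, int], list[int]] = {}
    for i, ann in enumerate(anns):
        for site in ann.splice_sites:
            by_site.setdefault((ann.chrom, ann.strand, site), []).append(i)
    for indices in by_site.values():
        for b in indices[1:]:
            uf.union(indices[0], b)
    clusters: dict[int, list[int]] = {}
    for i in range(len(anns)):
        clusters.setdefault(uf.find(i), []).append(i)
    gene_of: dict[str, str] = {}
    members: dict[str, tuple[str, ...]] = {}
    for idxs in clusters.values():
        tids = sorted(anns[i].transcript_id for i in idxs)
        gid = f"gene-{tids[0]}"
        members[gid] = tuple(tids)
        for tid in tids:
            gene_of[tid] = gid
    return GeneGrouping(gene_of=gene_of, members=members)


def gene_tpm(tx: pd.DataFrame, grouping: GeneGrouping) -> pd.DataFrame:
    """Sum member-transcript TPMs into a genes × samples matrix."""
    unmapped = [t for t in tx.index if t not in grouping.gene_of]
    if unmapped:
        raise ValueError(f"transcripts absent from grouping: {unmapped[:5]}")
    genes = tx.index.map(grouping.gene_of)
    out = tx.groupby(genes).sum()
    out.index.name = "gene_id"
    return out.sort_index()


def compute_psi(
    tx: pd.DataFrame,
    grouping: GeneGrouping,
    min_gene_tpm: float = DEFAULT_MIN_GENE_TPM,
) -> PsiMatrix:
    """Normalize transcript TPM to gene TPM.

    PSI(t, s) = TPM(t, s) / geneTPM(g(t), s) where the gene TPM reaches
    *min_gene_tpm*; below the threshold PSI is missing (NaN).  Where
    present, the PSIs of a gene's transcripts sum to 1 per sample.
    """
    gexpr = gene_tpm(tx, grouping)
    gene_idx = tx.index.map(grouping.gene_of)
    denom = gexpr.loc[gene_idx].to_numpy(dtype=float)
    num = tx.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        psi = np.where(denom >= min_gene_tpm, num / denom, np.nan)
    values = pd.DataFrame(psi, index=tx.index.copy(), columns=tx.columns.copy())
    gene_of = {t: grouping.gene_of[t] for t in tx.index}
    return PsiMatrix(values=values, gene_of=gene_of)


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------

#: A feature must be observed in at least this fraction of each group.
MISSINGNESS_FLOOR = 0.8


def effect_sizes(
    features: PsiMatrix | pd.DataFrame,
    design: ComparisonDesign,
    mode: str = "psi",
    *,
    epsilon: float = LOGFC_EPSILON,
    min_present_fraction: float = MISSINGNESS_FLOOR,
) -> pd.DataFrame:
    """Per-feature group means and effect size for the early/late contrast.

    mode='psi'  -> delta = mean_late - mean_PSI_early (missing excluded)
    mode='gene' -> delta = log2((mean_late + eps) / (mean_early + eps))

    Features observed in fewer than *min_present_fraction* of either
    group's samples are dropped (and logged); no imputation is performed.
    Returns a DataFrame with columns mean_early, mean_late, delta.
    """
    if mode not in {"psi", "gene"}:
        raise ValueError(f"mode must be 'psi' or 'gene', got {mode!r}")
    values = features.values if isinstance(features, PsiMatrix) else features
    early = values[list(design.group_early)]
    late = values[list(design.group_late)]
    present_early = early.notna().mean(axis=1)
    present_late = late.notna().mean(axis=1)
    keep = (present_early >= min_present_fraction) & (present_late >= min_present_fraction)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "effect_sizes: dropped %d/%d features below %.0f%% presence per group",
            n_dropped, len(values), 100 * min_present_fraction,
        )
    mean_early = early[keep].mean(axis=1)
    mean_late = late[keep].mean(axis=1)
    if mode == "psi":
        delta = mean_late - mean_early
    else:
        delta = np.log2((mean_late + epsilon) / (mean_early + epsilon))
    return pd.DataFrame(
        {"mean_early": mean_early, "mean_late": mean_late, "delta": delta}
    )


# ---------------------------------------------------------------------------
# Quantile subgroups
# ---------------------------------------------------------------------------


def rank_subgroups(
    gene_expr: pd.DataFrame, gene_id: str, fraction: float
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Split samples into bottom/top *fraction* sets by one gene's expression.

    Samples are ranked by the gene's TPM (ties broken by lexicographic
    sample id); the interquantile samples are left out.  Returns
    ``(low_set, high_set)``, each of size ``floor(n * fraction)``.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError(f"fraction must be in (0, 0.5], got {fraction}")
    if gene_id not in gene_expr.index:
        raise KeyError(f"gene {gene_id!r} not in expression matrix")
    expr = gene_expr.loc[gene_id]
    order = sorted(expr.index, key=lambda s: (expr[s], s))
    if len(set(expr)) < len(expr):
        logger.info("rank_subgroups: ties in %s broken by sample id", gene_id)
    k = math.floor(len(order) * fraction)
    return tuple(order[:k]), tuple(order[-k:])


def survival_groups(
    clinical: pd.DataFrame, samples: Iterable[str], fraction: float
) -> ComparisonDesign:
    """Bottom/top *fraction* survival groups among *samples*.

    Group 'early' holds the long-surviving samples, group 'late' the
    short-surviving ones, so that 'late' carries the worse prognosis as in
    the stage designs.  Sizes are ``floor(n * fraction)``; ties break by
    sample id.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError(f"fraction must be in (0, 0.5], got {fraction}")
    samples = [s for s in samples if s in clinical.index]
    surv = clinical.loc[samples, "survival_days"].dropna()
    order = sorted(surv.index, key=lambda s: (surv[s], s))
    k = math.floor(len(order) * fraction)
    low = tuple(order[:k])
    high = tuple(order[-k:])
    return ComparisonDesign(
        class_name="survival",
        group_early=high,
        group_late=low,
        tumor_type_of=clinical.loc[samples, "tumor_type"].to_dict(),
    )
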