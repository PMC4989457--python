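"""Synthetic tumor cohorts with known ground truth.

The generator emulates the statistical structure the pipeline assumes:
per-gene multi-isoform proportions with Dirichlet dispersion around a
gene baseline, planted between-group PSI shifts applied on the logit of
the designated transcript's baseline proportion, group-dependent gene
expression changes, exponential survival with a group hazard ratio and
independent exponential censoring, and a fraction of samples with
blanked stage labels.  Transcript annotations are built so that the
intended gene partition is exactly recovered by splice-site grouping:
isoforms of a gene share their first exon's donor site, and no sites are
shared across genes.

Everything is drawn from a single seeded generator, so identical specs
give bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import TranscriptAnnotation


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one simulated cohort.

    Defaults describe a desk-scale TCGA-like cohort: 100 samples per
    stage group, 1000 genes with three isoforms each, 20 genes carrying a
    planted isoform switch of dPSI = 0.3, 20 differentially expressed
    genes (1 log2 unit), lognormal gene expression around ~7 TPM, PSI
    dispersion giving a within-group PSI sd of roughly 0.09, exponential
    survival with a median around 2.8 years for the early group and a
    hazard ratio of 2 for the late group, and mild independent censoring.
    """

    n_early: int = 100
    n_late: int = 100
    n_genes: int = 1000
    isoforms_per_gene: int = 3
    n_planted_psi: int = 20
    delta_psi: float = 0.3
    n_planted_de: int = 20
    log2fc_de: float = 1.0
    gene_tpm_mu: float = 2.0          # ln-TPM location
    gene_tpm_sigma: float = 1.0       # ln-TPM scale across genes
    gene_tpm_sigma_within: float = 0.4  # ln-TPM scale across samples
    psi_concentration: float = 30.0
    baseline_rate: float = 1.0 / 1500.0   # events per day, early group
    hazard_ratio: float = 2.0
    censoring_rate: float = 1.0 / 3000.0
    missing_label_fraction: float = 0.0
    n_tumor_types: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_psi > self.n_genes or self.n_planted_de > self.n_genes:
            raise ValueError("planted counts cannot exceed n_genes")
        if not 0.0 <= self.delta_psi < 1.0:
            raise ValueError("delta_psi must be in [0, 1)")
        if not 0.0 <= self.missing_label_fraction <= 1.0:
            raise ValueError("missing_label_fraction must be in [0, 1]")
        if self.baseline_rate <= 0 or self.hazard_ratio <= 0:
            raise ValueError("survival rates must be positive")


@dataclass
class GroundTruth:
    planted_psi_transcripts: frozenset[str]
    planted_psi_genes: frozenset[str]
    planted_de_genes: frozenset[str]
    true_labels: dict[str, str]          # sample -> early/late
    true_hazard_ratio: float

    def to_dict(self) -> dict:
        return {
            "planted_psi_transcripts": sorted(self.planted_psi_transcripts),
            "planted_psi_genes": sorted(self.planted_psi_genes),
            "planted_de_genes": sorted(self.planted_de_genes),
            "true_labels": dict(sorted(self.true_labels.items())),
            "true_hazard_ratio": self.true_hazard_ratio,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


_EARLY_STAGES = {"stage_T": "T1", "stage_N": "N0", "stage_M": "M0", "stage_S": "S1"}
_LATE_STAGES = {"stage_T": "T3", "stage_N": "N2", "stage_M": "M1", "stage_S": "S3"}


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, list[TranscriptAnnotation], pd.DataFrame, GroundTruth]:
    """Draw one cohort: (transcript TPM matrix, annotations, clinical
    table, ground truth).

    Transcript TPMs are gene TPM times isoform proportion, so summing a
    gene's transcripts reproduces its drawn gene TPM exactly.  The
    planted PSI shift moves the designated transcript's late-group
    baseline proportion by ``delta_psi`` through a logit-scale shift
    (raising an error when the baseline leaves no room), with the
    remaining isoforms renormalized proportionally.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_early + spec.n_late
    width = max(4, len(str(n)))
    samples = [f"S{str(i).zfill(width)}" for i in range(1, n + 1)]
    is_late = np.array([False] * spec.n_early + [True] * spec.n_late)

    k = max(1, spec.isoforms_per_gene)
    gene_names = [f"G{str(i).zfill(4)}" for i in range(1, spec.n_genes + 1)]
    planted_psi = gene_names[: spec.n_planted_psi]
    planted_de = gene_names[spec.n_planted_psi: spec.n_planted_psi + spec.n_planted_de]

    # --- isoform baselines and planted shifts -----------------------------
    baselines: dict[str, np.ndarray] = {}
    late_baselines: dict[str, np.ndarray] = {}
    for g in gene_names:
        if g in planted_psi and k > 1:
            hi = min(0.5, 0.95 - spec.delta_psi)
            if hi <= 0.2:
                raise ValueError(
                    f"gene {g}: delta_psi={spec.delta_psi} leaves no feasible baseline"
                )
            p0 = rng.uniform(0.2, hi)
            base = np.full(k, (1.0 - p0) / (k - 1))
            base[0] = p0
            # logit-scale shift of the designated isoform's baseline, the
            # remaining isoforms renormalized proportionally
            shift = _logit(p0 + spec.delta_psi) - _logit(p0)
            p0_late = _sigmoid(_logit(p0) + shift)
            late = base * ((1.0 - p0_late) / (1.0 - p0))
            late[0] = p0_late
            baselines[g] = base
            late_baselines[g] = late
        else:
            base = rng.dirichlet(np.full(k, 2.0)) if k > 1 else np.ones(1)
            baselines[g] = base
            late_baselines[g] = base

    # --- expression and proportions ---------------------------------------
    tx_ids: list[str] = []
    tx_rows: list[np.ndarray] = []
    annotations: list[TranscriptAnnotation] = []
    mu_g = rng.normal(spec.gene_tpm_mu, spec.gene_tpm_sigma, size=spec.n_genes)
    for gi, g in enumerate(gene_names):
        noise = rng.normal(0.0, spec.gene_tpm_sigma_within, size=n)
        tpm = np.exp(mu_g[gi] + noise)
        if g in planted_de:
            tpm = tpm * np.where(is_late, 2.0 ** spec.log2fc_de, 1.0)
        if k > 1:
            alpha_e = spec.psi_concentration * baselines[g]
            alpha_l = spec.psi_concentration * late_baselines[g]
            gammas = np.where(
                is_late[:, None],
                rng.gamma(np.broadcast_to(alpha_l, (n, k))),
                rng.gamma(np.broadcast_to(alpha_e, (n, k))),
            )
            props = gammas / gammas.sum(axis=1, keepdims=True)
        else:
            props = np.ones((n, 1))
        for j in range(k):
            tx_ids.append(f"{g}.t{j + 1}")
            tx_rows.append(tpm * props[:, j])
        annotations.extend(_gene_annotations(g, gi, k))

    tx = pd.DataFrame(np.vstack(tx_rows), index=pd.Index(tx_ids, name="feature_id"), columns=samples)

    # --- clinical ----------------------------------------------------------
    rate = np.where(is_late, spec.baseline_rate * spec.hazard_ratio, spec.baseline_rate)
    t_event = rng.exponential(1.0 / rate)
    if spec.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censoring_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens

    types = [f"TT{(i % spec.n_tumor_types) + 1}" for i in range(n)]
    clinical = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    clinical["tumor_type"] = types
    for col in ("stage_T", "stage_N", "stage_M", "stage_S"):
        clinical[col] = [
            (_LATE_STAGES if late else _EARLY_STAGES)[col] for late in is_late
        ]
    clinical["survival_days"] = np.round(time, 1)
    clinical["event"] = event

    n_blank = int(round(spec.missing_label_fraction * n))
    blanked = rng.choice(n, size=n_blank, replace=False) if n_blank else np.array([], dtype=int)
    for idx in blanked:
        for col in ("stage_T", "stage_N", "stage_M", "stage_S"):
            clinical.iat[idx, clinical.columns.get_loc(col)] = None

    truth = GroundTruth(
        planted_psi_transcripts=frozenset(f"{g}.t1" for g in planted_psi),
        planted_psi_genes=frozenset(planted_psi),
        planted_de_genes=frozenset(planted_de),
        true_labels={s: ("late" if l else "early") for s, l in zip(samples, is_late)},
        true_hazard_ratio=spec.hazard_ratio,
    )
    return tx, annotations, clinical, truth


def _gene_annotations(gene: str, gene_index: int, k: int) -> list[TranscriptAnnotation]:
    """Exon structures for one gene's isoforms.

    All isoforms share the first exon (hence its donor splice site);
    isoform j has a distinct second exon.  Loci are spaced so genes never
    overlap.
    """
    L = 10_000 * (gene_index + 1)
    anns = []
    for j in range(k):
        exons = ((L, L + 100), (L + 200 + 150 * j, L + 260 + 150 * j))
        anns.append(
            TranscriptAnnotation(
                transcript_id=f"{gene}.t{j + 1}",
                chrom="chr1",
                strand="+",
                exons=exons,
                gene_id=gene,
            )
        )
    return anns


def null_spec(spec: CohortSpec) -> CohortSpec:
    """The same conditions with every planted effect zeroed."""
    return replace(
        spec,
        n_planted_psi=0,
        delta_psi=0.0,
        n_planted_de=0,
        log2fc_de=0.0,
        hazard_ratio=1.0,
    )


def simulate_null_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, list[TranscriptAnnotation], pd.DataFrame, GroundTruth]:
    """Convenience wrapper: all effects zeroed, planted sets empty."""
    return simulate_cohort(null_spec(spec))
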