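"""Signature models: CFS + LMT training, prediction, and repeated
stratified cross-validation with AUC and precision-recall areas.

Classifier accuracy is summarized as the area under the ROC curve (the
Mann-Whitney statistic of the score ranking, ties counted one half) and
the area under the precision-recall curve with step-wise (achievable)
interpolation.  Both are estimated by stratified ten-fold
cross-validation repeated a configurable number of times; missing
feature values are median-imputed from the training folds only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .dataio import ComparisonDesign
from .lmt import LmtConfig, LmtNode, fit_lmt
from .quantify import PsiMatrix
from .select import cfs_select

import logging

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierConfig:
    folds: int = 10
    repeats: int = 10       # study value: 100; desk-scale default 10
    lmt: LmtConfig = field(default_factory=LmtConfig)
    seed: int = 0


@dataclass
class SignatureModel:
    """A fitted LMT over a non-redundant feature subset."""

    feature_ids: list[str]
    tree: LmtNode
    class_labels: tuple[str, str] = ("early", "late")
    medians: dict[str, float] = field(default_factory=dict)
    metadata: dict[str, Any] = field(default_factory=dict)

    def predict_proba(self, features: PsiMatrix | pd.DataFrame) -> pd.Series:
        """Probability of the late class per sample (columns of *features*)."""
        values = features.values if isinstance(features, PsiMatrix) else features
        missing = [f for f in self.feature_ids if f not in values.index]
        if missing:
            raise KeyError(f"matrix lacks model features: {missing}")
        X = values.loc[self.feature_ids].T.to_numpy(dtype=float)
        for j, fid in enumerate(self.feature_ids):
            col = X[:, j]
            col[~np.isfinite(col)] = self.medians.get(fid, 0.0)
        prob = self.tree.predict_proba(X)
        return pd.Series(prob, index=values.columns, name="p_late")

    def to_dict(self) -> dict[str, Any]:
        return {
            "format": "isosig-signature-model",
            "version": 1,
            "feature_ids": list(self.feature_ids),
            "class_labels": list(self.class_labels),
            "medians": {k: float(v) for k, v in self.medians.items()},
            "tree": self.tree.to_dict(),
            "metadata": self.metadata,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SignatureModel":
        return cls(
            feature_ids=list(d["feature_ids"]),
            tree=LmtNode.from_dict(d["tree"]),
            class_labels=tuple(d["class_labels"]),
            medians=dict(d["medians"]),
            metadata=dict(d.get("metadata", {})),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SignatureModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class CvResult:
    """Fold-level AUC and PRC values over folds × repeats."""

    auc_values: list[float]
    prc_values: list[float]
    folds: int
    repeats: int

    def summary(self) -> dict[str, float]:
        out = {}
        for name, vals in (("auc", self.auc_values), ("prc", self.prc_values)):
            arr = np.asarray(vals)
            out[f"{name}_min"] = float(arr.min())
            out[f"{name}_mean"] = float(arr.mean())
            out[f"{name}_max"] = float(arr.max())
        return out

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"auc": self.auc_values, "prc": self.prc_values})


def ranking_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve of a score ranking (Mann-Whitney
    formulation; tied scores count one half per discordant pair)."""
    return float(roc_auc_score(y_true, scores))


def pr_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve with step-wise (achievable)
    interpolation, avoiding the optimistic trapezoid bias."""
    return float(average_precision_score(y_true, scores))


def _impute_train_medians(
    X_train: np.ndarray, X_other: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Median-impute columns using training rows only (no leakage)."""
    med = np.nanmedian(X_train, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    X_train = np.where(np.isfinite(X_train), X_train, med)
    if X_other is not None:
        X_other = np.where(np.isfinite(X_other), X_other, med)
    return X_train, X_other, med


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    repeats: int = 10,
    cfg: LmtConfig = LmtConfig(),
    seed: int = 0,
) -> CvResult:
    """Repeated stratified k-fold CV of the LMT; AUC and PRC per held-out
    fold.

    If the minority class has fewer members than *folds*, the fold count
    is reduced to the minority count (logged).  Sample order does not
    affect the result for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n_min = int(min((y == 0).sum(), (y == 1).sum()))
    if n_min < 2:
        raise ValueError("minority class has fewer than 2 members")
    if n_min < folds:
        logger.info("cross_validate: reducing folds from %d to %d", folds, n_min)
        folds = n_min
    # canonical sample order (label, then feature values) so permuting the
    # input samples leaves the folds, and hence the result, unchanged
    keys = tuple(X[:, j] for j in reversed(range(X.shape[1]))) + (y,)
    order = np.lexsort(keys)
    aucs: list[float] = []
    prcs: list[float] = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=(seed * 1000 + rep) % (2**31))
        for tr_idx, te_idx in skf.split(X[order], y[order]):
            tr, te = order[tr_idx], order[te_idx]
            X_tr, X_te, _ = _impute_train_medians(X[tr], X[te])
            model = fit_lmt(X_tr, y[tr], cfg, seed=seed + rep)
            prob = model.predict_proba(X_te)
            aucs.append(float(roc_auc_score(y[te], prob)))
            prcs.append(float(average_precision_score(y[te], prob)))
    return CvResult(auc_values=aucs, prc_values=prcs, folds=folds, repeats=repeats)


def train_signature(
    features: PsiMatrix | pd.DataFrame,
    design: ComparisonDesign,
    selection: pd.DataFrame,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> tuple[SignatureModel, CvResult]:
    """CFS -> LMT -> repeated CV over the discriminant features.

    *selection* is the output of ``subsample_selection``; only rows with
    ``discriminant == True`` enter CFS.  The operation is agnostic to
    feature provenance: isoform PSI, gene TPM, event PSI or mixed tables
    run identically.
    """
    values = features.values if isinstance(features, PsiMatrix) else features
    discriminant = [
        f for f in selection.index[selection["discriminant"].astype(bool)]
        if f in values.index
    ]
    if not discriminant:
        raise ValueError("no discriminant features")
    samples = list(design.samples)
    y = design.labels().to_numpy()
    cohort = values.loc[discriminant, samples]
    selected = cfs_select(cohort, y)
    X = values.loc[selected, samples].T.to_numpy(dtype=float)
    X_imp, _, med = _impute_train_medians(X)
    tree = fit_lmt(X_imp, y, cfg.lmt, seed=cfg.seed)
    model = SignatureModel(
        feature_ids=selected,
        tree=tree,
        class_labels=("early", "late"),
        medians={f: float(m) for f, m in zip(selected, med)},
        metadata={
            "class_name": design.class_name,
            "n_early": len(design.group_early),
            "n_late": len(design.group_late),
            "n_discriminant": len(discriminant),
            "seed": cfg.seed,
            "folds": cfg.folds,
            "repeats": cfg.repeats,
        },
    )
    cv = cross_validate(
        X, y, folds=cfg.folds, repeats=cfg.repeats, cfg=cfg.lmt, seed=cfg.seed
    )
    return model, cv
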