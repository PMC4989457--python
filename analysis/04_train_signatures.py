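#!/usr/bin/env python
"""Train transcript signatures per tumor type.

Reduces each type's discriminant isoforms to a non-redundant subset with
CFS, fits a logistic model tree, and estimates accuracy by stratified
ten-fold cross-validation repeated ten times.  Writes model_<type>.json
and cv_<type>.tsv under results/train/.
"""

from pathlib import Path

import pandas as pd

import isosig as iso
from isosig.classify import ClassifierConfig, train_signature
from isosig.dataio import read_clinical, read_matrix

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 613

if __name__ == "__main__":
    out = ROOT / "train"
    out.mkdir(parents=True, exist_ok=True)
    psi = read_matrix(ROOT / "quant" / "psi.tsv", allow_missing=True)
    clinical = read_clinical(ROOT / "cohort" / "clinical.tsv")

    for ttype in sorted(clinical["tumor_type"].unique()):
        sub = clinical[clinical["tumor_type"] == ttype]
        design = iso.build_design(sub, "M", {"M0"}, {"M1"})
        stats = pd.read_csv(ROOT / "select" / f"selection_{ttype}.tsv",
                            sep="\t", index_col=0)
        model, cv = train_signature(
            psi, design, stats, ClassifierConfig(folds=10, repeats=10, seed=SEED)
        )
        model.save(out / f"model_{ttype}.json")
        cv.to_frame().to_csv(out / f"cv_{ttype}.tsv", sep="\t", index_label="fold")
        s = cv.summary()
        print(f"{ttype}: signature of {len(model.feature_ids)} isoforms "
              f"({', '.join(model.feature_ids[:4])}{'...' if len(model.feature_ids) > 4 else ''}); "
              f"AUC mean {s['auc_mean']:.3f} [{s['auc_min']:.3f}, {s['auc_max']:.3f}], "
              f"PRC mean {s['prc_mean']:.3f}")
    print(f"wrote {out}")
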