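"""Shared fixtures: small simulated cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import isosig as iso


@pytest.fixture(scope="session")
def planted_cohort():
    """A 50+50 cohort with 5 planted isoform switches (dPSI = 0.3)."""
    spec = iso.CohortSpec(
        n_early=50, n_late=50, n_genes=200, n_planted_psi=5, n_planted_de=5,
        delta_psi=0.3, seed=101,
    )
    tx, annotations, clinical, truth = iso.simulate_cohort(spec)
    grouping = iso.build_gene_groups(annotations)
    psi = iso.compute_psi(tx, grouping)
    design = iso.build_design(clinical, "M", {"M0"}, {"M1"})
    return {
        "spec": spec,
        "tx": tx,
        "annotations": annotations,
        "clinical": clinical,
        "truth": truth,
        "grouping": grouping,
        "psi": psi,
        "design": design,
    }


@pytest.fixture(scope="session")
def null_cohort():
    """A 50+50 cohort with no planted effects of any kind."""
    spec = iso.CohortSpec(n_early=50, n_late=50, n_genes=200, seed=202)
    tx, annotations, clinical, truth = iso.simulate_null_cohort(spec)
    grouping = iso.build_gene_groups(annotations)
    psi = iso.compute_psi(tx, grouping)
    design = iso.build_design(clinical, "M", {"M0"}, {"M1"})
    return {
        "tx": tx,
        "clinical": clinical,
        "truth": truth,
        "psi": psi,
        "design": design,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
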