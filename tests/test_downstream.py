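"""Enrichment, differential expression, survival, blind test, set scores."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import isosig as iso
from isosig.classify import SignatureModel
from isosig.dataio import GeneSetCollection
from isosig.downstream import (
    blind_test,
    correlate_psi_scores,
    differential_expression,
    fisher_enrichment,
    geneset_sample_score,
    robust_zscores,
    survival_compare,
)
from isosig.lmt import LmtNode, SimpleLogistic


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def table_p(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    p_obs = table_p(a)
    lo, hi = max(0, row1 - (n - col1)), min(row1, col1)
    return sum(table_p(x) for x in range(lo, hi + 1) if table_p(x) <= p_obs * (1 + 1e-9))


class TestFisherEnrichment:
    def _collection(self, genes):
        return GeneSetCollection({"SET": frozenset(genes)})

    def test_counts_match_exact_enumeration(self):
        # a=8 query-in-set, b=2 query-out, c=20 bg-in-set, d=70 rest
        background = {f"g{i}" for i in range(100)}
        in_set = {f"g{i}" for i in range(28)}          # 8 query + 20 others
        query = {f"g{i}" for i in range(8)} | {f"g{i}" for i in range(90, 92)}
        res = fisher_enrichment(query, background, self._collection(in_set))
        row = res.loc["SET"]
        assert (row["a"], row["b"], row["c"], row["d"]) == (8, 2, 20, 70)
        assert row["p"] == pytest.approx(fisher_two_sided_oracle(8, 2, 20, 70), abs=1e-12)

    def test_random_tables_match_oracle(self, rng):
        for _ in range(25):
            n_bg = int(rng.integers(20, 300))
            background = {f"g{i}" for i in range(n_bg)}
            set_genes = set(rng.choice(sorted(background), size=rng.integers(5, n_bg // 2), replace=False))
            query = set(rng.choice(sorted(background), size=rng.integers(1, n_bg // 2), replace=False))
            res = fisher_enrichment(query, background, self._collection(set_genes))
            row = res.loc["SET"]
            expected = fisher_two_sided_oracle(*(int(row[k]) for k in "abcd"))
            assert row["p"] == pytest.approx(expected, abs=1e-12)

    def test_query_equal_background_gives_p_one(self):
        background = {f"g{i}" for i in range(30)}
        res = fisher_enrichment(
            background, background, self._collection({f"g{i}" for i in range(10)})
        )
        assert res.loc["SET", "p"] == pytest.approx(1.0)

    def test_disjoint_set_skipped(self):
        background = {"g1", "g2"}
        res = fisher_enrichment({"g1"}, background, self._collection({"x1", "x2"}))
        assert len(res) == 0

    def test_query_must_be_subset(self):
        with pytest.raises(ValueError, match="subset"):
            fisher_enrichment({"zz"}, {"g1"}, self._collection({"g1"}))

    def test_bh_rejections_monotone_in_level(self, rng):
        sets = {f"S{i}": frozenset({f"g{j}" for j in rng.choice(50, 10, replace=False)})
                for i in range(12)}
        background = {f"g{i}" for i in range(50)}
        query = {f"g{i}" for i in range(0, 50, 3)}
        res = fisher_enrichment(query, background, GeneSetCollection(sets))
        for q1, q2 in [(0.01, 0.05), (0.05, 0.2), (0.2, 0.5)]:
            assert (res["fdr"] < q1).sum() <= (res["fdr"] < q2).sum()


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------


def wilcoxon_exact_oracle(x, y):
    """Exact two-sided rank-sum p by enumerating all rank assignments."""
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    nx = len(x)
    rank_of = {v: r for r, v in enumerate(pooled, start=1)}
    u_obs = sum(rank_of[v] for v in x) - nx * (nx + 1) / 2
    n = len(pooled)
    us = [
        sum(ranks) - nx * (nx + 1) / 2
        for ranks in itertools.combinations(range(1, n + 1), nx)
    ]
    mean_u = nx * (n - nx) / 2
    dev = abs(u_obs - mean_u)
    extreme = sum(1 for u in us if abs(u - mean_u) >= dev - 1e-9)
    return extreme / len(us)


def _design(early, late):
    return iso.ComparisonDesign(class_name="M", group_early=early, group_late=late)


class TestDifferentialExpression:
    def test_identical_distributions_not_flagged(self, rng):
        vals = rng.uniform(1, 5, 6)
        m = pd.DataFrame([np.concatenate([vals, vals])],
                         index=["g"], columns=[f"s{i}" for i in range(12)])
        res = differential_expression(m, _design(tuple(f"s{i}" for i in range(6)),
                                                 tuple(f"s{i}" for i in range(6, 12))))
        assert not res.loc["g", "de_flag"]

    def test_log2fc_of_group_means(self):
        m = pd.DataFrame([[2.0] * 3 + [8.0] * 3], index=["g"],
                         columns=[f"s{i}" for i in range(6)])
        res = differential_expression(m, _design(("s0", "s1", "s2"), ("s3", "s4", "s5")))
        assert res.loc["g", "log2fc"] == pytest.approx(2.0, abs=0.01)

    def test_p_matches_exact_rank_sum_enumeration(self, rng):
        for _ in range(5):
            x = list(np.round(rng.uniform(0, 10, 6), 6))
            y = list(np.round(rng.uniform(0, 10, 6), 6))
            m = pd.DataFrame([y + x], index=["g"], columns=[f"s{i}" for i in range(12)])
            res = differential_expression(
                m, _design(tuple(f"s{i}" for i in range(6)), tuple(f"s{i}" for i in range(6, 12)))
            )
            assert res.loc["g", "p"] == pytest.approx(wilcoxon_exact_oracle(x, y), abs=1e-12)

    def test_constant_gene_gets_p_one(self):
        m = pd.DataFrame([[3.0] * 6], index=["g"], columns=[f"s{i}" for i in range(6)])
        res = differential_expression(m, _design(("s0", "s1", "s2"), ("s3", "s4", "s5")))
        assert res.loc["g", "p"] == 1.0

    def test_too_few_samples_rejected(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"],
                         columns=["s0", "s1", "s2", "s3"])
        with pytest.raises(ValueError, match="3 samples"):
            differential_expression(m, _design(("s0", "s1"), ("s2", "s3")))


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


def _clinical(days_a, days_b, events_a=None, events_b=None):
    days = list(days_a) + list(days_b)
    events = list(events_a or [True] * len(days_a)) + list(events_b or [True] * len(days_b))
    ids = [f"a{i}" for i in range(len(days_a))] + [f"b{i}" for i in range(len(days_b))]
    return pd.DataFrame(
        {"tumor_type": "TT1", "survival_days": days, "event": events},
        index=pd.Index(ids, name="sample_id"),
    )


class TestSurvivalCompare:
    def test_identical_groups_hr_near_one(self):
        days = np.arange(10.0, 110.0, 10.0)
        clin = _clinical(days, days)
        cmp = survival_compare(clin, [f"a{i}" for i in range(10)], [f"b{i}" for i in range(10)])
        assert cmp.hazard_ratio == pytest.approx(1.0, abs=0.05)
        assert cmp.cox_p > 0.9

    def test_km_without_censoring_equals_empirical_survival(self):
        days = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        clin = _clinical(days, np.arange(1.0, 7.0))
        cmp = survival_compare(clin, [f"a{i}" for i in range(5)], [f"b{i}" for i in range(6)])
        curve = cmp.km_curves["a"]
        for t, s in zip(curve["time"], curve["survival"]):
            assert s == pytest.approx((days > t).mean())

    def test_simulated_hr_recovered(self):
        spec = iso.CohortSpec(
            n_early=500, n_late=500, n_genes=5, n_planted_psi=0, n_planted_de=0,
            hazard_ratio=3.0, censoring_rate=0.0, seed=31,
        )
        _, _, clin, truth = iso.simulate_cohort(spec)
        early = [s for s, l in truth.true_labels.items() if l == "early"]
        late = [s for s, l in truth.true_labels.items() if l == "late"]
        cmp = survival_compare(clin, early, late)
        assert 2.5 <= cmp.hazard_ratio <= 3.6

    def test_zero_events_rejected(self):
        clin = _clinical([1.0] * 6, [2.0] * 6, [False] * 6, [False] * 6)
        with pytest.raises(ValueError, match="no events"):
            survival_compare(clin, [f"a{i}" for i in range(6)], [f"b{i}" for i in range(6)])

    def test_small_group_rejected(self):
        clin = _clinical([1.0, 2.0], [3.0] * 6)
        with pytest.raises(ValueError, match=">= 5"):
            survival_compare(clin, ["a0", "a1"], [f"b{i}" for i in range(6)])


# ---------------------------------------------------------------------------
# Blind test
# ---------------------------------------------------------------------------


def _constant_model(features, p=0.9):
    # single leaf with strong positive intercept -> predicts late
    coef = np.zeros(len(features) + 1)
    coef[0] = np.log(p / (1 - p))
    return SignatureModel(
        feature_ids=list(features),
        tree=LmtNode(model=SimpleLogistic(coef=coef)),
        medians={f: 0.5 for f in features},
    )


class TestBlindTest:
    def _cohort(self):
        samples = [f"s{i}" for i in range(12)]
        clin = pd.DataFrame(
            {
                "tumor_type": "TT1",
                "stage_M": ["M0"] * 4 + ["M1"] * 4 + [None] * 4,
                "survival_days": np.arange(10.0, 130.0, 10.0),
                "event": True,
            },
            index=pd.Index(samples, name="sample_id"),
        )
        feats = pd.DataFrame(
            np.tile(np.linspace(0.1, 0.9, 12), (2, 1)),
            index=["f1", "f2"], columns=samples,
        )
        return clin, feats

    def test_labeled_samples_never_predicted(self):
        clin, feats = self._cohort()
        res = blind_test(
            {"TT1": _constant_model(["f1", "f2"])}, {"TT1": feats}, clin, "M", ["TT1"]
        )
        assert set(res.predictions.index) == {f"s{i}" for i in range(8, 12)}

    def test_ineligible_type_not_predicted(self):
        clin, feats = self._cohort()
        res = blind_test(
            {"TT1": _constant_model(["f1", "f2"])}, {"TT1": feats}, clin, "M", []
        )
        assert len(res.predictions) == 0
        assert not res.comparable

    def test_no_unlabeled_samples_flagged(self):
        clin, feats = self._cohort()
        clin["stage_M"] = ["M0"] * 6 + ["M1"] * 6
        res = blind_test(
            {"TT1": _constant_model(["f1", "f2"])}, {"TT1": feats}, clin, "M", ["TT1"]
        )
        assert len(res.predictions) == 0 and not res.comparable

    def test_one_sided_predictions_not_comparable(self):
        clin, feats = self._cohort()
        res = blind_test(
            {"TT1": _constant_model(["f1", "f2"], p=0.9)}, {"TT1": feats}, clin, "M", ["TT1"]
        )
        assert (res.predictions["predicted"] == "late").all()
        assert not res.comparable


# ---------------------------------------------------------------------------
# Gene-set scores, correlations, robust z
# ---------------------------------------------------------------------------


class TestGenesetSampleScore:
    def test_uniformly_top_sample_has_max_score(self, rng):
        expr = pd.DataFrame(
            rng.uniform(0, 10, size=(8, 6)),
            index=[f"g{i}" for i in range(8)], columns=[f"s{j}" for j in range(6)],
        )
        expr["s3"] = expr.max(axis=1) + 1.0  # s3 tops every gene
        scores = geneset_sample_score(expr, {f"g{i}" for i in range(5)})
        assert scores.idxmax() == "s3"

    def test_sample_permutation_equivariance(self, rng):
        expr = pd.DataFrame(
            rng.uniform(0, 10, size=(6, 8)),
            index=[f"g{i}" for i in range(6)], columns=[f"s{j}" for j in range(8)],
        )
        gene_set = {f"g{i}" for i in range(5)}
        s1 = geneset_sample_score(expr, gene_set)
        perm = list(rng.permutation(expr.columns))
        s2 = geneset_sample_score(expr[perm], gene_set)
        pd.testing.assert_series_equal(s1.sort_index(), s2.sort_index())

    def test_matches_independent_rank_mean(self, rng):
        expr = pd.DataFrame(
            rng.uniform(0, 100, size=(25, 10)),
            index=[f"g{i}" for i in range(25)], columns=[f"s{j}" for j in range(10)],
        )
        gene_set = {f"g{i}" for i in rng.choice(25, 20, replace=False)}
        scores = geneset_sample_score(expr, gene_set)
        # independent re-implementation: scipy rankdata per gene, z over ranks
        from scipy.stats import rankdata

        acc = np.zeros(10)
        present = sorted(gene_set & set(expr.index))
        for g in present:
            r = rankdata(expr.loc[g])
            acc += (r - r.mean()) / r.std(ddof=1)
        np.testing.assert_allclose(scores.to_numpy(), acc / len(present), atol=1e-12)

    def test_too_few_genes_rejected(self, rng):
        expr = pd.DataFrame(rng.uniform(size=(3, 4)), index=["g1", "g2", "g3"])
        with pytest.raises(ValueError, match=">= 5"):
            geneset_sample_score(expr, {"g1", "g2"})


class TestCorrelatePsiScores:
    def test_self_correlation_is_one(self):
        psi = pd.DataFrame([np.linspace(0.1, 0.9, 12)], index=["f"],
                           columns=[f"s{i}" for i in range(12)])
        scores = pd.Series(np.linspace(0.1, 0.9, 12), index=psi.columns)
        r = correlate_psi_scores(psi, ["f"], scores)
        assert r["f"] == pytest.approx(1.0)

    def test_antiproportional_gives_minus_one(self):
        psi = pd.DataFrame([np.linspace(0.1, 0.9, 12)], index=["f"],
                           columns=[f"s{i}" for i in range(12)])
        scores = pd.Series(-np.linspace(0.1, 0.9, 12), index=psi.columns)
        assert correlate_psi_scores(psi, ["f"], scores)["f"] == pytest.approx(-1.0)

    def test_zero_variance_reported_missing(self):
        psi = pd.DataFrame([[0.5] * 12], index=["f"], columns=[f"s{i}" for i in range(12)])
        scores = pd.Series(np.arange(12.0), index=psi.columns)
        assert np.isnan(correlate_psi_scores(psi, ["f"], scores)["f"])

    def test_independent_scores_mostly_uncorrelated(self, rng):
        n = 200
        psi = pd.DataFrame(
            rng.uniform(0, 1, size=(40, n)),
            index=[f"f{i}" for i in range(40)], columns=[f"s{j}" for j in range(n)],
        )
        scores = pd.Series(rng.normal(size=n), index=psi.columns)
        r = correlate_psi_scores(psi, list(psi.index), scores)
        assert (r.abs() < 0.2).mean() >= 0.95

    def test_insufficient_pairs_dropped(self):
        psi = pd.DataFrame([[0.5, np.nan] * 6], index=["f"],
                           columns=[f"s{i}" for i in range(12)])
        scores = pd.Series(np.arange(12.0), index=psi.columns)
        assert "f" not in correlate_psi_scores(psi, ["f"], scores, min_pairs=10)


class TestRobustZscores:
    def test_symmetric_toy_vector(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=["a", "b", "c"])
        z = robust_zscores(m)
        np.testing.assert_allclose(
            z.loc["g"], [-1 / 1.4826, 0.0, 1 / 1.4826], atol=1e-4
        )

    def test_constant_gene_all_zero(self):
        m = pd.DataFrame([[2.0, 2.0, 2.0]], index=["g"], columns=["a", "b", "c"])
        assert (robust_zscores(m).loc["g"] == 0.0).all()

    def test_location_invariance(self, rng):
        m = pd.DataFrame(rng.uniform(0, 10, size=(4, 6)),
                         index=[f"g{i}" for i in range(4)],
                         columns=[f"s{j}" for j in range(6)])
        pd.testing.assert_frame_equal(robust_zscores(m), robust_zscores(m + 10.0))
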