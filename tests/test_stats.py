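"""Permutation tests, FDR step-up, correlations, subgroup analysis."""

import numpy as np
import pandas as pd
import pytest

import strucnet as sn
from strucnet.core import GraphMetricSet


def _metric_sets(values, schema):
    """Wrap per-subject nodal vectors as GraphMetricSet lists (one metric
    varied, others constant)."""
    out = []
    for v in values:
        v = np.asarray(v, dtype=float)
        out.append(GraphMetricSet(
            nodal_strength=v,
            nodal_clustering=np.zeros_like(v),
            nodal_path_length=np.ones_like(v),
            global_strength=float(v.mean()),
            total_fibers=float(v.sum() / 2),
            gamma=1.0,
            lam=1.0,
        ))
    return out


class TestPermTestMeanDiff:
    def test_identical_groups_p_one(self):
        p = sn.perm_test_mean_diff([3, 3, 3], [3, 3, 3], n_perm=200, seed=0)
        assert p == 1.0

    def test_exhaustive_enumeration_example(self):
        """a = {10,11,12}, b = {0,1,2}: 2 of the C(6,3) = 20 relabelings are
        as extreme two-sided, so p = 0.1 exactly."""
        p = sn.perm_test_mean_diff([10, 11, 12], [0, 1, 2], n_perm=10_000, seed=0)
        assert p == pytest.approx(2 / 20)

    def test_monte_carlo_converges_to_exact(self):
        """For a total size 10 cohort, MC p matches enumeration within 3 s.e."""
        rng = np.random.default_rng(4)
        a, b = rng.normal(1.0, 1, 5), rng.normal(0, 1, 5)
        exact = sn.perm_test_mean_diff(a, b, n_perm=10**9, seed=0)  # enumerated
        n_mc = 4000
        # force the Monte-Carlo path by shrinking n_perm below C(10,5)=252?
        # C(10,5)=252 <= 4000 would enumerate; use a larger cohort instead
        a2 = np.concatenate([a, rng.normal(1.0, 1, 4)])
        b2 = np.concatenate([b, rng.normal(0, 1, 4)])
        exact2 = sn.perm_test_mean_diff(a2, b2, n_perm=10**9, seed=0)
        mc = sn.perm_test_mean_diff(a2, b2, n_perm=n_mc, seed=7)
        se = np.sqrt(exact2 * (1 - exact2) / n_mc)
        assert abs(mc - exact2) <= 3 * se + 1 / n_mc
        assert 0 < exact < 1

    def test_mc_stability_under_doubling(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0.6, 1, 12), rng.normal(0, 1, 12)
        p1 = sn.perm_test_mean_diff(a, b, n_perm=4000, seed=1)
        p2 = sn.perm_test_mean_diff(a, b, n_perm=8000, seed=2)
        se = np.sqrt(p1 * (1 - p1) / 4000)
        assert abs(p1 - p2) < 3 * se + 1e-3


class TestFdrBH:
    def test_all_ones_no_rejections(self):
        flags, _ = sn.fdr_bh(np.ones(6), q=0.05)
        assert not flags.any()

    def test_step_up_rule_hand_case(self):
        """p = {.01,.02,.03,.04}, m=4, q=.05: p_(4)=.04 <= 4*.05/4 -> all rejected."""
        flags, _ = sn.fdr_bh([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert flags.all()

    def test_single_p_reduces_to_threshold(self):
        flags, adj = sn.fdr_bh([0.04], q=0.05)
        assert flags[0]
        assert adj[0] == pytest.approx(0.04)

    def test_hand_computed_mixed_case(self):
        """Step-up applied by hand: p=(.005,.011,.02,.8), q=.05, m=4:
        k=3 is the largest k with p_(k) <= k q / m (.02 <= .0375)."""
        flags, _ = sn.fdr_bh([0.8, 0.005, 0.02, 0.011], q=0.05)
        np.testing.assert_array_equal(flags, [False, True, True, True])

    def test_monotone_in_q(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=30)
        f1, _ = sn.fdr_bh(p, q=0.02)
        f2, _ = sn.fdr_bh(p, q=0.10)
        assert (f2 | ~f1).all()  # rejections only grow with q

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            sn.fdr_bh([0.0, 0.5])


class TestCompareNodalMetrics:
    def test_planted_nodal_deficit_recovered(self):
        """A node whose strength is shifted far below controls is flagged."""
        rng = np.random.default_rng(5)
        schema = sn.generic_schema(20)
        base = rng.uniform(100, 200, 20)
        vals_b = [base + rng.normal(0, 10, 20) for _ in range(20)]
        vals_a = []
        for _ in range(20):
            v = base + rng.normal(0, 10, 20)
            v[7] -= 60  # 6 s.d. deficit on node 7
            vals_a.append(v)
        table = sn.compare_nodal_metrics(
            schema, _metric_sets(vals_a, schema), _metric_sets(vals_b, schema),
            n_perm=2000, seed=1,
        )
        strength = table[table.family == "nodal_strength"]
        flagged = set(strength[strength.p_fdr_pass].node_id)
        assert "n007" in flagged

    def test_null_flag_rate_controlled(self):
        """delta = 0: the FDR family-wise flag rate stays near zero."""
        rng = np.random.default_rng(6)
        schema = sn.generic_schema(15)
        n_flagged = 0
        n_rep = 20
        for _ in range(n_rep):
            vals_a = [rng.normal(100, 10, 15) for _ in range(12)]
            vals_b = [rng.normal(100, 10, 15) for _ in range(12)]
            table = sn.compare_nodal_metrics(
                schema, _metric_sets(vals_a, schema), _metric_sets(vals_b, schema),
                n_perm=500, seed=int(rng.integers(2**31 - 1)),
            )
            fam = table[table.family == "nodal_strength"]
            n_flagged += int(fam.p_fdr_pass.any())
        assert n_flagged / n_rep <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_pooled_fdr_family_option(self):
        """Pooling all nodal tests into one FDR family is more stringent
        than per-metric correction for a deficit confined to one metric."""
        rng = np.random.default_rng(15)
        schema = sn.generic_schema(10)
        vals_a = [rng.normal(100, 10, 10) for _ in range(10)]
        vals_b = [rng.normal(100, 10, 10) for _ in range(10)]
        per = sn.compare_nodal_metrics(
            schema, _metric_sets(vals_a, schema), _metric_sets(vals_b, schema),
            n_perm=400, seed=2, fdr_family="per_metric")
        pooled = sn.compare_nodal_metrics(
            schema, _metric_sets(vals_a, schema), _metric_sets(vals_b, schema),
            n_perm=400, seed=2, fdr_family="all")
        nodal = per.family != "global"
        # identical raw p-values; only the correction family differs
        np.testing.assert_allclose(per[nodal].p_perm, pooled[nodal].p_perm)
        assert pooled[nodal].p_fdr_pass.sum() <= 3 * 10

    def test_global_rows_present(self):
        rng = np.random.default_rng(7)
        schema = sn.generic_schema(8)
        sets_a = _metric_sets([rng.uniform(1, 9, 8) for _ in range(5)], schema)
        sets_b = _metric_sets([rng.uniform(1, 9, 8) for _ in range(5)], schema)
        table = sn.compare_nodal_metrics(schema, sets_a, sets_b, n_perm=300, seed=0)
        assert set(table[table.family == "global"].feature) == {
            "global_strength", "total_fibers", "gamma", "lambda",
        }
        assert len(table[table.family != "global"]) == 3 * 8


class TestCompareVolumes:
    def test_constant_volumes_all_p_one(self):
        a = np.full((10, 6), 1500.0)
        b = np.full((11, 6), 1500.0)
        table = sn.compare_volumes(a, b, n_perm=300, seed=0)
        assert (table.p_perm == 1.0).all()
        assert not table.p_fdr_pass.any()

    def test_inflated_node_detected(self):
        rng = np.random.default_rng(9)
        a = rng.normal(1500, 50, size=(20, 6))
        b = rng.normal(1500, 50, size=(20, 6))
        a[:, 2] += 150  # 3 s.d. inflation
        table = sn.compare_volumes(a, b, n_perm=2000, seed=1)
        assert table.p_fdr_pass.iloc[2]

    def test_matched_distributions_rarely_flag(self):
        rng = np.random.default_rng(10)
        a = rng.normal(1500, 50, size=(15, 8))
        b = rng.normal(1500, 50, size=(15, 8))
        table = sn.compare_volumes(a, b, n_perm=1000, seed=2)
        assert table.p_fdr_pass.sum() == 0


class TestCorrelateClinical:
    def test_feature_equal_to_score(self):
        score = np.arange(20.0)
        features = pd.DataFrame({"f": score})
        scores = pd.DataFrame({"s": score})
        table = sn.correlate_clinical(features, scores)
        assert table.r.iloc[0] == pytest.approx(1.0)
        assert table.p.iloc[0] < 1e-12
        assert table.p_fdr_pass.iloc[0]

    def test_independent_scores_rarely_flag(self):
        rng = np.random.default_rng(11)
        flags = 0
        n_rep = 25
        for _ in range(n_rep):
            features = pd.DataFrame(rng.normal(size=(30, 4)),
                                    columns=list("abcd"))
            scores = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("xyz"))
            table = sn.correlate_clinical(features, scores)
            flags += int(table.p_fdr_pass.any())
        assert flags / n_rep <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_zero_variance_feature_skipped(self):
        features = pd.DataFrame({"flat": np.ones(10), "ok": np.arange(10.0)})
        scores = pd.DataFrame({"s": np.arange(10.0)})
        with pytest.warns(UserWarning, match="zero variance"):
            table = sn.correlate_clinical(features, scores)
        assert set(table.feature) == {"ok"}

    def test_subject_id_alignment(self):
        features = pd.DataFrame({"subject_id": ["a", "b", "c"],
                                 "f": [1.0, 2.0, 3.0]})
        scores = pd.DataFrame({"subject_id": ["c", "a", "b"],
                               "s": [3.0, 1.0, 2.0]})
        table = sn.correlate_clinical(features, scores)
        assert table.r.iloc[0] == pytest.approx(1.0)

    def test_spearman_flag(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=25)
        features = pd.DataFrame({"f": x})
        scores = pd.DataFrame({"s": np.exp(x)})  # monotone, nonlinear
        table = sn.correlate_clinical(features, scores, method="spearman")
        assert table.r.iloc[0] == pytest.approx(1.0)


@pytest.fixture(scope="module")
def effect_study():
    edges = frozenset((f"n{i:03d}", f"n{i + 1:03d}") for i in range(4))
    spec = sn.CohortSpec(n_a=16, n_b=16, n_nodes=15, density=0.5,
                         subject_cv=0.25, seed=31, medicated_fraction=0.5,
                         effect=sn.EffectSpec(edges, reduction=0.3,
                                              reduction_medicated=0.5))
    return sn.sample_cohort(spec)


class TestSubgroupComparison:

    def test_all_flagged_matches_full_analysis(self, effect_study):
        study = sn.GroupStudy(
            group_a=effect_study.group_a, group_b=effect_study.group_b,
            medicated={c.subject_id: True for c in effect_study.group_a},
        )
        sub = sn.subgroup_comparison(study, n_perm_nbs=200, seed=3)
        masked, mask = sn.group_threshold(study)
        full = sn.nbs_test(masked, mask, n_perm=200, seed=3)
        assert [c.size for c in sub["nbs"].components] == \
               [c.size for c in full.components]

    def test_no_flags_rejected(self, effect_study):
        study = sn.GroupStudy(
            group_a=effect_study.group_a, group_b=effect_study.group_b,
            medicated={c.subject_id: False for c in effect_study.group_a},
        )
        with pytest.raises(ValueError, match="at least 3"):
            sn.subgroup_comparison(study, n_perm_nbs=200)

    def test_missing_flags_rejected(self, effect_study):
        study = sn.GroupStudy(group_a=effect_study.group_a,
                              group_b=effect_study.group_b)
        with pytest.raises(ValueError, match="medicated"):
            sn.subgroup_comparison(study, n_perm_nbs=200)

    def test_larger_subgroup_deficit_strengthens_contrast(self, effect_study):
        """Medicated cases carry a deeper planted deficit, so the subgroup
        contrast on planted edges is at least as large as the full one."""
        idx = {nid: i for i, nid in enumerate(effect_study.schema.node_ids)}
        edges = [(idx[f"n{i:03d}"], idx[f"n{i + 1:03d}"]) for i in range(4)]
        sub = sn.subgroup_comparison(effect_study, n_perm_nbs=200, seed=5)
        masked, mask = sn.group_threshold(effect_study)
        full_t = sn.edge_t(masked, mask).t
        sub_t = sn.edge_t(sub["study"], sub["mask"]).t
        full_mean = np.mean([full_t[e] for e in edges])
        sub_mean = np.mean([sub_t[e] for e in edges])
        assert sub_mean > full_mean
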