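import numpy as np
import pytest
from scipy import stats as sps

from octaquant.errors import (
    ConfigError,
    LabelError,
    ModelError,
    ParameterError,
    UndefinedStatisticError,
)
from octaquant.stats import (
    ancova_adjusted_means,
    benjamini_hochberg,
    cohens_d,
    min_sample_size,
    pairwise_posthoc,
    roc_analysis,
    run_cohort_report,
    spearman_stage,
    two_sample_power,
)
from octaquant.synthetic import CohortSpec, generate_cohort


class TestSpearman:
    def test_perfect_negative_trend(self):
        stages = [0, 1, 2, 3, 4]
        values = [50, 45, 40, 35, 30]
        res = spearman_stage(values, stages)
        assert res.rho == pytest.approx(-1.0)

    def test_null_is_near_zero(self):
        rng = np.random.default_rng(0)
        stages = rng.integers(0, 5, 1000)
        values = rng.normal(size=1000)
        assert abs(spearman_stage(values, stages).rho) < 0.1

    def test_matches_brute_force_with_ties(self):
        values = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0]
        stages = [0, 0, 1, 1, 2, 2, 3, 4]
        res = spearman_stage(values, stages)
        rv = sps.rankdata(values)
        rs = sps.rankdata(stages)
        expected = np.corrcoef(rv, rs)[0, 1]
        assert res.rho == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_stage([1.0, 1.0, 1.0], [0, 1, 2])


class TestAncova:
    def test_identical_covariates_give_raw_means(self):
        rng = np.random.default_rng(1)
        age = rng.normal(55, 10, 30)
        q = rng.normal(8, 1, 30)
        y = np.concatenate([rng.normal(10, 1, 30), rng.normal(14, 1, 30)])
        stages = np.array([0] * 30 + [2] * 30)
        res = ancova_adjusted_means(y, stages, np.tile(age, 2), np.tile(q, 2))
        assert res.adjusted_means[0] == pytest.approx(y[:30].mean())
        assert res.adjusted_means[2] == pytest.approx(y[30:].mean())

    def test_two_group_no_covariates_equals_t_test(self):
        rng = np.random.default_rng(2)
        a = rng.normal(10, 2, 18)
        b = rng.normal(11, 2, 25)
        res = ancova_adjusted_means(
            np.concatenate([a, b]), np.array([0] * 18 + [1] * 25)
        )
        _, p = sps.ttest_ind(a, b)
        assert res.overall_p == pytest.approx(p, rel=1e-10)

    def test_recovers_confounded_stage_effects(self):
        effects = {0: 0.0, 1: -2.0, 2: -4.0, 3: -6.0, 4: -8.0}
        spec = CohortSpec(
            n_per_group={s: 30 for s in range(5)},
            param_means={"P": {s: 40.0 + effects[s] for s in range(5)}},
            param_sds={"P": {s: 3.0 for s in range(5)}},
            beta_age=0.25,
            beta_q=1.5,
            rng_seed=17,
        )
        recs = generate_cohort(spec)
        vals = np.array([r.params["P"] for r in recs])
        stages = np.array([r.stage for r in recs])
        ages = np.array([r.age for r in recs])
        qs = np.array([r.q_score for r in recs])
        res = ancova_adjusted_means(vals, stages, ages, qs)
        for s in range(5):
            truth = (
                spec.param_means["P"][s]
                + spec.beta_age * (ages.mean() - spec.age_ref)
                + spec.beta_q * (qs.mean() - spec.q_ref)
            )
            assert abs(res.adjusted_means[s] - truth) <= 2 * res.adjusted_mean_se(s)

    def test_single_stage_rejected(self):
        with pytest.raises(ModelError):
            ancova_adjusted_means([1.0, 2.0, 3.0], [0, 0, 0])

    def test_collinear_design_rejected(self):
        y = np.arange(20.0)
        stages = np.array([0] * 10 + [1] * 10)
        age = stages.astype(float)  # perfectly collinear with the indicator
        with pytest.raises(ModelError):
            ancova_adjusted_means(y, stages, age, None)


class TestBenjaminiHochberg:
    def test_spec_example(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.013]), [0.013])

    def brute_force(self, p):
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        for rank_idx, i in enumerate(order):
            candidates = [
                p[order[j]] * m / (j + 1) for j in range(rank_idx, m)
            ]
            adj[i] = min(1.0, min(candidates))
        return adj

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 25))
        np.testing.assert_allclose(benjamini_hochberg(p), self.brute_force(p))

    def test_rejections_superset_of_bonferroni(self):
        rng = np.random.default_rng(3)
        p = rng.random(50) * 0.2
        q = 0.05
        bh = benjamini_hochberg(p) <= q
        bonf = p * len(p) <= q
        assert (bh | ~bonf).all()

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(4)
        p = rng.random(30)
        assert (benjamini_hochberg(p) >= p - 1e-15).all()


class TestPairwise:
    def test_all_pairs_present_and_monotone(self):
        rng = np.random.default_rng(5)
        y = np.concatenate([rng.normal(m, 2, 20) for m in (10, 10, 9, 7, 5)])
        stages = np.repeat(np.arange(5), 20)
        age = rng.normal(55, 8, 100)
        q = rng.normal(8, 1, 100)
        model = ancova_adjusted_means(y, stages, age, q)
        pw = pairwise_posthoc(model, fdr=0.05)
        assert len(pw.pairs) == 10
        assert all(a >= r - 1e-15 for a, r in zip(pw.adj_p, pw.raw_p))
        assert all(a <= 1.0 for a in pw.adj_p)
        # difference of adjusted means equals the contrast estimate
        for (a, b), diff in zip(pw.pairs, pw.differences):
            assert diff == pytest.approx(
                model.adjusted_means[b] - model.adjusted_means[a]
            )


class TestCohensD:
    def test_unit_effect(self):
        assert cohens_d([10, 12, 14], [8, 10, 12]).d == pytest.approx(1.0)

    def test_identical_groups_zero(self):
        rng = np.random.default_rng(6)
        g = rng.normal(size=30)
        assert cohens_d(g, g).d == pytest.approx(0.0)

    def test_unequal_n_matches_brute_force(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(5, 2, 13), rng.normal(4, 3, 29)
        na, nb = len(a), len(b)
        pooled = np.sqrt(
            ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
            / (na + nb - 2)
        )
        assert cohens_d(a, b).d == pytest.approx((a.mean() - b.mean()) / pooled)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestSampleSize:
    def test_unit_effect_needs_17(self):
        assert min_sample_size(1.0, alpha=0.05, power=0.8) == 17

    def test_huge_effect_boundary(self):
        assert min_sample_size(10.0) == 2

    def test_monotonicity(self):
        assert min_sample_size(0.5) > min_sample_size(0.8)
        assert min_sample_size(0.5, power=0.9) > min_sample_size(0.5, power=0.8)
        assert min_sample_size(0.5, alpha=0.01) > min_sample_size(0.5, alpha=0.05)

    def test_nonpositive_effect_rejected(self):
        with pytest.raises(ParameterError):
            min_sample_size(0.0)

    def test_power_against_simulation(self):
        # independent oracle: simulate two-sample t-tests at d = 1, n = 17
        rng = np.random.default_rng(8)
        n, reps = 17, 20000
        a = rng.normal(1.0, 1.0, size=(reps, n))
        b = rng.normal(0.0, 1.0, size=(reps, n))
        va = a.var(axis=1, ddof=1)
        vb = b.var(axis=1, ddof=1)
        se = np.sqrt((va + vb) / n)
        tstat = (a.mean(axis=1) - b.mean(axis=1)) / se
        crit = sps.t.ppf(0.975, 2 * n - 2)
        sim_power = (np.abs(tstat) > crit).mean()
        assert two_sample_power(1.0, 17) == pytest.approx(sim_power, abs=0.01)


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 10, 11, 12], [True, True, True, False, False, False])
        assert res.auc == 1.0 and res.sensitivity == 1.0 and res.specificity == 1.0

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=2000)
        labels = rng.random(2000) < 0.3
        assert roc_analysis(values, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_matches_pair_enumeration_with_ties(self):
        rng = np.random.default_rng(10)
        values = rng.integers(0, 10, 60).astype(float)
        labels = rng.random(60) < 0.4
        res = roc_analysis(values, labels)
        pos = values[labels]
        neg = values[~labels]
        wins = sum(
            (1.0 if p > n else 0.5 if p == n else 0.0) for p in pos for n in neg
        )
        auc_high = wins / (len(pos) * len(neg))
        assert res.auc == pytest.approx(max(auc_high, 1 - auc_high))

    def test_one_class_empty_rejected(self):
        with pytest.raises(LabelError):
            roc_analysis([1.0, 2.0], [True, True])

    def test_youden_point_is_optimal(self):
        rng = np.random.default_rng(11)
        values = np.concatenate([rng.normal(5, 2, 40), rng.normal(8, 2, 60)])
        labels = np.array([True] * 40 + [False] * 60)
        res = roc_analysis(values, labels)
        best_j = -1.0
        for thr in np.unique(values):
            pred = values <= thr
            j = (pred & labels).sum() / 40 + (~pred & ~labels).sum() / 60 - 1
            best_j = max(best_j, j)
        assert res.sensitivity + res.specificity - 1 == pytest.approx(best_j)


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(CohortSpec(rng_seed=21))


class TestCohortReport:
    def test_report_reflects_generator_ordering(self, cohort):
        report = run_cohort_report(
            cohort, params=["SCP_VD", "SCP_VLD"], roc_params=["SCP_VD"]
        )
        row = report["adjusted_means"][report["adjusted_means"].parameter == "SCP_VD"]
        means = [row[f"stage_{s}_adj_mean"].iloc[0] for s in range(5)]
        assert means[0] > means[2] > means[4]  # declining perfusion with severity
        sp = report["spearman"]
        assert sp[sp.parameter == "SCP_VD"].rho.iloc[0] < -0.3
        assert not report["roc"].empty

    def test_single_group_degrades_gracefully(self):
        recs = generate_cohort(CohortSpec(n_per_group={0: 12}, rng_seed=3))
        report = run_cohort_report(recs, params=["SCP_VD"], roc_params=["SCP_VD"])
        assert not report["errors"].empty
        assert "spearman" in report and "adjusted_means" in report

    def test_deterministic_bytes(self, cohort):
        r1 = run_cohort_report(cohort, params=["SCP_VD"], roc_params=["SCP_VD"])
        r2 = run_cohort_report(cohort, params=["SCP_VD"], roc_params=["SCP_VD"])
        for name in r1:
            assert r1[name].to_csv(index=False) == r2[name].to_csv(index=False)

    def test_unknown_parameter_rejected(self, cohort):
        with pytest.raises(ConfigError):
            run_cohort_report(cohort, params=["NOT_A_PARAM"])
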