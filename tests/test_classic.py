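import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from crt_effects.classic import aug_gee, care, gee, geometric_ttest, unadjusted_contrast
from crt_effects.core import ClusterRecord, CRTData, EstimandSpec, pooled_individual_mean

from conftest import build_trial, toy_trial


def cluster_from_events(cid, arm, n, d):
    y = np.concatenate([np.ones(d), np.zeros(n - d)])
    return ClusterRecord(cid, arm, {}, pd.DataFrame(index=range(n)), y)


def trial_from_means(means1, means0, n=10):
    clusters = [
        cluster_from_events(f"a{i}", 1, n, int(round(m * n))) for i, m in enumerate(means1)
    ] + [cluster_from_events(f"b{i}", 0, n, int(round(m * n))) for i, m in enumerate(means0)]
    return CRTData(clusters)


class TestUnadjusted:
    def test_equal_arm_means_give_null_contrast(self):
        data = trial_from_means([0.2, 0.4], [0.3, 0.3])
        ratio = unadjusted_contrast(data, spec=EstimandSpec(scale="ratio"))
        diff = unadjusted_contrast(data, spec=EstimandSpec(scale="difference"))
        assert ratio.estimate == pytest.approx(1.0)
        assert diff.estimate == pytest.approx(0.0)

    def test_toy_cluster_vs_individual_targets(self):
        # same outcomes, different estimands: 0.31 per-cluster vs 0.748 pooled
        toy = toy_trial()
        mirror = toy_trial()
        for c in mirror.clusters:
            c.arm = 1
            c.cluster_id = "m" + c.cluster_id
        both = CRTData(toy.clusters + mirror.clusters)
        u_c = unadjusted_contrast(both, spec=EstimandSpec(level="cluster"))
        u_i = unadjusted_contrast(both, spec=EstimandSpec(level="individual"))
        assert u_c.psi0 == pytest.approx(0.31, abs=1e-12)
        assert u_i.psi0 == pytest.approx(0.748, abs=5e-4)
        assert u_c.estimate == pytest.approx(1.0) and u_i.estimate == pytest.approx(1.0)

    def test_zero_arm_mean_rejected_on_ratio_scale(self):
        data = trial_from_means([0.0, 0.0], [0.3, 0.2])
        with pytest.raises(ValueError, match="zero arm mean"):
            unadjusted_contrast(data, spec=EstimandSpec(scale="ratio"))


class TestGeometricTTest:
    def test_toy_control_geometric_mean(self):
        toy = toy_trial()
        mirror = toy_trial()
        for c in mirror.clusters:
            c.arm = 1
            c.cluster_id = "m" + c.cluster_id
        est = geometric_ttest(CRTData(toy.clusters + mirror.clusters))
        assert est.psi0 == pytest.approx(0.26, abs=5e-3)

    def test_arithmetic_dominates_geometric(self):
        for seed in range(5):
            data = build_trial(np.random.default_rng(seed), J=10, sizes=np.full(10, 50))
            est = geometric_ttest(data)
            arms = data.arms()
            yc = np.array([c.Y.mean() for c in data.clusters])
            assert est.psi1 <= yc[arms == 1].mean() + 1e-12
            assert est.psi0 <= yc[arms == 0].mean() + 1e-12

    def test_constant_outcomes_are_degenerate(self):
        data = trial_from_means([0.3, 0.3], [0.3, 0.3])
        with pytest.warns(UserWarning, match="zero variance"):
            est = geometric_ttest(data)
        assert est.estimate == pytest.approx(1.0)
        assert np.isnan(est.p)

    def test_zero_cluster_outcome_rejected_with_names(self):
        data = trial_from_means([0.0, 0.2], [0.3, 0.1])
        with pytest.raises(ValueError, match="a0"):
            geometric_ttest(data)


class TestCARE:
    def test_intercept_only_expected_counts(self):
        # logistic MLE intercept = logit(pooled rate), so e_j = N_j * p_bar
        data = build_trial(np.random.default_rng(42), J=10, sizes=np.full(10, 50))
        est = care(data, ())
        frame = data.individual_frame()
        p_bar = frame["Y"].mean()
        arms = data.arms()
        r = []
        for c in data.clusters:
            r.append((c.Y.sum() / (c.size * p_bar)))
        r = np.array(r)
        expected = np.exp(np.log(r[arms == 1]).mean() - np.log(r[arms == 0]).mean())
        assert est.estimate == pytest.approx(expected, abs=1e-10)

    def test_identical_arms_give_unit_ratio(self):
        data = trial_from_means([0.2, 0.5], [0.2, 0.5], n=20)
        est = care(data, ())
        assert est.estimate == pytest.approx(1.0, abs=1e-10)

    def test_treatment_excluded_from_adjustment(self, random_trial):
        with pytest.raises(ValueError, match="never the treatment"):
            care(random_trial, ("A",))

    def test_zero_event_cluster_rejected(self):
        data = trial_from_means([0.0, 0.2], [0.3, 0.1], n=10)
        with pytest.raises(ValueError, match="zero observed events"):
            care(data, ())


class TestGEE:
    def test_unadjusted_log_link_equals_pooled_ratio(self):
        for seed in range(5):
            data = build_trial(np.random.default_rng(seed), J=10)
            fit = gee(data)
            expected = pooled_individual_mean(data, 1) / pooled_individual_mean(data, 0)
            assert fit.estimate == pytest.approx(expected, abs=1e-8)

    def test_small_sample_correction_inflates_se(self):
        for seed in range(5):
            data = build_trial(np.random.default_rng(seed), J=10)
            fit = gee(data, ("W1",))
            assert fit.se_beta_a >= fit.se_beta_a_uncorrected

    def test_ci_and_p_consistent(self, random_trial):
        fit = gee(random_trial, ("W1", "E1"))
        lo, hi = fit.ci
        assert lo < fit.estimate < hi
        assert 0 <= fit.p <= 1


class TestAugGEE:
    def test_no_covariates_reduces_to_gee(self, random_trial):
        g = gee(random_trial)
        ag = aug_gee(random_trial)
        assert ag.estimate == pytest.approx(g.estimate, abs=1e-6)

    def test_arm_relabeling_inverts_estimate(self, rng):
        data = build_trial(rng, J=10)
        est = aug_gee(data, ("W1",)).estimate
        flipped = CRTData(
            [
                ClusterRecord(c.cluster_id, 1 - c.arm, c.covariates, c.W, c.Y, c.pair_id)
                for c in data.clusters
            ]
        )
        est_flipped = aug_gee(flipped, ("W1",)).estimate
        assert est_flipped == pytest.approx(1.0 / est, rel=1e-5)
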