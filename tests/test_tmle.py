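import numpy as np
import pytest

from crt_effects.classic import unadjusted_contrast
from crt_effects.core import EstimandSpec, WeightScheme, pooled_individual_mean
from crt_effects.tmle import (
    RegressionSpec,
    cluster_tmle,
    hierarchical_tmle,
    hybrid_tmle,
)

from conftest import build_trial


def pooled_ratio(data):
    return pooled_individual_mean(data, 1) / pooled_individual_mean(data, 0)


class TestClusterTMLE:
    def test_empty_adjustment_equals_unadjusted(self):
        # the unadjusted contrast is the TMLE special case with empty sets
        for seed in range(10):
            data = build_trial(np.random.default_rng(seed), J=10)
            for level in ("cluster", "individual"):
                spec = EstimandSpec(level=level)
                w = WeightScheme(target=level)
                t = cluster_tmle(data, w, spec)
                u = unadjusted_contrast(data, w, spec)
                assert t.estimate == pytest.approx(u.estimate, abs=1e-10)
                assert t.contrast.se == pytest.approx(u.contrast.se, abs=1e-10)

    def test_individual_target_weights_recover_pooled_ratio(self):
        for seed in range(5):
            data = build_trial(np.random.default_rng(seed), J=12)
            est = cluster_tmle(
                data, WeightScheme(target="individual"), EstimandSpec(level="individual")
            )
            assert est.estimate == pytest.approx(pooled_ratio(data), abs=1e-10)

    def test_score_equations_solved(self, sim1_trial):
        est = cluster_tmle(
            sim1_trial,
            spec=EstimandSpec(),
            outcome_reg=RegressionSpec("outcome", "cluster", ("W1c",)),
            ps_reg=RegressionSpec("propensity", "cluster", ("W2c",)),
        )
        assert abs(est.fluctuation.score1) < 1e-8
        assert abs(est.fluctuation.score0) < 1e-8

    def test_ci_brackets_point_estimate(self, sim1_trial):
        for adj in ((), ("W1c",), ("E1",)):
            est = cluster_tmle(
                sim1_trial, spec=EstimandSpec(), outcome_reg=RegressionSpec("outcome", "cluster", adj)
            )
            assert est.ci[0] < est.estimate < est.ci[1]

    def test_continuous_outcome_rejected(self, random_trial):
        random_trial.clusters[0].Y = random_trial.clusters[0].Y + 2.0
        with pytest.raises(ValueError, match="outside \\[0, 1\\]"):
            cluster_tmle(random_trial)

    def test_matched_analysis_uses_pair_df(self, rng):
        data = build_trial(rng, J=12, pair_ids=True)
        kept = cluster_tmle(data, spec=EstimandSpec(matching="keep"))
        broken = cluster_tmle(data, spec=EstimandSpec(matching="break"))
        assert kept.contrast.df == 5
        assert broken.contrast.df == 10
        assert kept.estimate == pytest.approx(broken.estimate, abs=1e-12)
        assert len(kept.if1) == 6


class TestHierarchicalTMLE:
    def test_empty_adjustment_recovers_pooled_ratio(self):
        for seed in range(5):
            data = build_trial(np.random.default_rng(seed), J=12)
            est = hierarchical_tmle(
                data, WeightScheme(target="individual"), EstimandSpec(level="individual")
            )
            assert est.estimate == pytest.approx(pooled_ratio(data), abs=1e-10)

    def test_cluster_target_empty_adjustment_matches_unadjusted(self, random_trial):
        est = hierarchical_tmle(
            random_trial, WeightScheme(target="cluster"), EstimandSpec(level="cluster")
        )
        u = unadjusted_contrast(random_trial, spec=EstimandSpec(level="cluster"))
        assert est.estimate == pytest.approx(u.estimate, abs=1e-9)

    def test_equal_cluster_sizes_collapse_targets(self, rng):
        data = build_trial(rng, J=10, sizes=np.full(10, 40))
        reg = RegressionSpec("outcome", "individual", ("W1",))
        ps = RegressionSpec("propensity", "individual")
        ec = hierarchical_tmle(data, WeightScheme("cluster"), EstimandSpec(level="cluster"), reg, ps)
        ei = hierarchical_tmle(
            data, WeightScheme("individual"), EstimandSpec(level="individual"), reg, ps
        )
        assert ec.estimate == pytest.approx(ei.estimate, abs=1e-12)

    def test_score_equation_solved(self, sim1_trial):
        est = hierarchical_tmle(
            sim1_trial,
            WeightScheme("individual"),
            EstimandSpec(level="individual"),
            RegressionSpec("outcome", "individual", ("W1",)),
            RegressionSpec("propensity", "individual", ("W2",)),
        )
        assert abs(est.fluctuation.score1) < 1e-8
        assert abs(est.fluctuation.score0) < 1e-8

    def test_if_length_is_cluster_count(self, sim1_trial):
        est = hierarchical_tmle(
            sim1_trial, WeightScheme("individual"), EstimandSpec(level="individual")
        )
        assert len(est.if1) == sim1_trial.J


class TestHybridTMLE:
    def test_empty_adjustment_reduces_to_unadjusted(self, random_trial):
        est = hybrid_tmle(random_trial, spec=EstimandSpec())
        u = unadjusted_contrast(random_trial, spec=EstimandSpec())
        assert est.estimate == pytest.approx(u.estimate, abs=1e-9)

    def test_agrees_with_hierarchical_on_shared_regression(self, sim1_trial):
        reg = RegressionSpec("outcome", "individual", ("W1",))
        hy = hybrid_tmle(sim1_trial, spec=EstimandSpec(), outcome_reg=reg)
        hi = hierarchical_tmle(
            sim1_trial,
            WeightScheme("cluster"),
            EstimandSpec(level="cluster"),
            reg,
            RegressionSpec("propensity", "individual"),
        )
        assert hy.estimate == pytest.approx(hi.estimate, abs=0.02)

    def test_score_equation_solved(self, sim1_trial):
        est = hybrid_tmle(
            sim1_trial,
            spec=EstimandSpec(),
            outcome_reg=RegressionSpec("outcome", "individual", ("W2",)),
        )
        assert abs(est.fluctuation.score1) < 1e-8

    def test_level_mismatch_rejected(self, random_trial):
        with pytest.raises(ValueError, match="individual-level outcome"):
            hybrid_tmle(random_trial, outcome_reg=RegressionSpec("outcome", "cluster"))


def test_separation_falls_back_to_unadjusted(rng):
    # a cluster covariate that perfectly separates arms cannot be used in
    # the propensity model; the known 0.5 is substituted with a warning
    data = build_trial(rng, J=8)
    for c in data.clusters:
        c.covariates["Esep"] = float(c.arm * 10.0)
    with pytest.warns(UserWarning, match="degenerate|truncating"):
        est = cluster_tmle(
            data,
            spec=EstimandSpec(),
            ps_reg=RegressionSpec("propensity", "cluster", ("Esep",)),
        )
    assert np.isfinite(est.estimate)
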