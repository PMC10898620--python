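import numpy as np
import pandas as pd
import pytest

from crt_effects.core import (
    ClusterRecord,
    CRTData,
    WeightScheme,
    aggregate_outcome,
    pooled_individual_mean,
    validate,
)

from conftest import build_trial, toy_trial


def make_cluster(y, arm=0, cid="c0"):
    y = np.asarray(y, dtype=float)
    return ClusterRecord(cid, arm, {}, pd.DataFrame(index=range(len(y))), y)


class TestAggregateOutcome:
    def test_default_weights_give_cluster_proportion(self):
        assert aggregate_outcome(make_cluster([1, 0, 1])) == pytest.approx(2 / 3)
        assert aggregate_outcome(make_cluster([0, 0, 0, 0])) == 0.0

    def test_explicit_weights(self):
        c = make_cluster([1, 0, 1])
        w = WeightScheme(alpha={"c0": np.array([0.5, 0.25, 0.25])})
        assert aggregate_outcome(c, w) == pytest.approx(0.75)

    def test_missing_weights_name_the_cluster(self):
        c = make_cluster([1, 0])
        with pytest.raises(KeyError, match="c0"):
            aggregate_outcome(c, WeightScheme(alpha={"other": np.ones(2)}))
        with pytest.raises(ValueError, match="2 individuals"):
            aggregate_outcome(c, WeightScheme(alpha={"c0": np.ones(3)}))

    def test_toy_study_cluster_level_mean(self, toy):
        # five clusters with wildly varying sizes: equal-cluster average 0.31
        means = [aggregate_outcome(c) for c in toy.clusters]
        assert np.mean(means) == pytest.approx(0.31, abs=5e-3)

    def test_bounded_for_default_weights(self, random_trial):
        for c in random_trial.clusters:
            v = aggregate_outcome(c)
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(c.Y.mean())


class TestPooledIndividualMean:
    def test_toy_study_individual_level_mean(self, toy):
        assert pooled_individual_mean(toy, 0) == pytest.approx(0.748, abs=5e-4)

    def test_single_cluster_all_events(self):
        data = CRTData([make_cluster([1, 1], arm=1), make_cluster([0, 1], arm=0, cid="c1")])
        assert pooled_individual_mean(data, 1) == 1.0

    def test_empty_arm_raises(self, toy):
        with pytest.raises(ValueError, match="arm 1"):
            pooled_individual_mean(toy, 1)

    def test_equal_sizes_match_mean_of_cluster_means(self, rng):
        data = build_trial(rng, J=8, sizes=np.full(8, 25))
        for arm in (0, 1):
            cm = [c.Y.mean() for c in data.clusters if c.arm == arm]
            assert pooled_individual_mean(data, arm) == pytest.approx(np.mean(cm), abs=1e-14)

    def test_weighted_cluster_mean_reproduces_pooled_mean(self, rng):
        # analysis weights J*Nj/NT recover the pooled individual mean exactly
        for seed in range(5):
            data = build_trial(np.random.default_rng(seed), J=10)
            w = WeightScheme(target="individual")
            aw = w.cluster_analysis_weights(data)
            arms = data.arms()
            yc = np.array([c.Y.mean() for c in data.clusters])
            for arm in (0, 1):
                m = arms == arm
                weighted = np.sum(aw[m] * yc[m]) / np.sum(aw[m])
                assert weighted == pytest.approx(pooled_individual_mean(data, arm), abs=1e-12)


class TestWeightScheme:
    def test_cluster_target_weights_are_one(self, random_trial):
        assert np.allclose(WeightScheme().cluster_analysis_weights(random_trial), 1.0)

    def test_individual_target_weights_proportional_to_size(self, random_trial):
        w = WeightScheme(target="individual").cluster_analysis_weights(random_trial)
        sizes = random_trial.sizes()
        assert np.allclose(w, sizes / sizes.mean())

    def test_heterogeneous_alpha_rejected_for_cluster_weights(self):
        c = make_cluster([1, 0, 1])
        data = CRTData([c, make_cluster([0, 1], arm=1, cid="c1"), make_cluster([1], cid="c2"), make_cluster([0], arm=1, cid="c3")])
        scheme = WeightScheme(
            target="individual",
            alpha={"c0": np.array([0.5, 0.3, 0.2]), "c1": np.full(2, 0.5), "c2": np.ones(1), "c3": np.ones(1)},
        )
        with pytest.raises(ValueError, match="varies within"):
            scheme.cluster_analysis_weights(data)


class TestValidate:
    def test_valid_trial_has_no_violations(self, sim1_trial):
        assert validate(sim1_trial) == []

    def test_size_mismatch_reported(self, random_trial):
        random_trial.clusters[0].Y = random_trial.clusters[0].Y[:-1]
        assert any("covariate rows" in v for v in validate(random_trial))

    def test_single_arm_reported(self, toy):
        assert any("arm 1 is empty" in v for v in validate(toy))

    def test_non_binary_outcome_reported(self, random_trial):
        random_trial.clusters[1].Y[0] = 0.5
        assert any("non-binary" in v for v in validate(random_trial))

    def test_unpaired_pair_id_reported(self, rng):
        data = build_trial(rng, J=6, pair_ids=True)
        data.clusters[0].pair_id = "lonely"
        msgs = validate(data)
        assert any("lonely" in v for v in msgs) and any("p0" in v for v in msgs)

    def test_reports_never_raises(self):
        data = CRTData([make_cluster([2, -1])])
        assert validate(data)  # violations reported, no exception


def test_toy_trial_cluster_vs_individual_divergence():
    # the same outcomes, summarized at different levels, tell different stories
    toy = toy_trial()
    cluster_level = np.mean([c.Y.mean() for c in toy.clusters])
    individual_level = pooled_individual_mean(toy, 0)
    assert cluster_level == pytest.approx(0.31)
    assert individual_level == pytest.approx(0.748, abs=5e-4)
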