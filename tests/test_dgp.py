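import numpy as np
import pytest
from scipy import stats

from crt_effects.core import validate
from crt_effects.dgp import DGPConfig, compute_truth, generate_sim1, generate_sim2, pair_match


class TestGenerate:
    @pytest.mark.parametrize("study,gen", [("sim1", generate_sim1), ("sim2", generate_sim2)])
    def test_construction_invariants(self, study, gen):
        data = gen(DGPConfig(study=study, J=20, seed=4))
        assert data.J == 20
        assert all(c.size >= 30 for c in data.clusters)
        assert data.arms().sum() == 10
        pairs = {c.pair_id for c in data.clusters}
        assert len(pairs) == 10
        assert validate(data) == []

    def test_odd_cluster_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            generate_sim1(DGPConfig(study="sim1", J=19, seed=0))

    def test_seed_reproducibility(self):
        a = generate_sim1(DGPConfig(study="sim1", J=20, seed=8))
        b = generate_sim1(DGPConfig(study="sim1", J=20, seed=8))
        for ca, cb in zip(a.clusters, b.clusters):
            assert ca.arm == cb.arm and np.array_equal(ca.Y, cb.Y)
            assert ca.covariates == cb.covariates
        c = generate_sim1(DGPConfig(study="sim1", J=20, seed=9))
        assert not all(np.array_equal(x.Y, y.Y) for x, y in zip(a.clusters, c.clusters))

    def test_w1_marginal_mean_matches_hierarchy(self):
        # E[W1] = 2 * E[UE1] = 2 * 0.65 = 1.3 under the stated latent model
        data = generate_sim1(DGPConfig(study="sim1", J=2000, seed=2))
        cluster_means = [c.W["W1"].mean() for c in data.clusters]
        assert np.mean(cluster_means) == pytest.approx(1.3, abs=0.05)

    def test_sim2_outcome_risk_decreases_with_cluster_size(self):
        # the scaled-size term gives larger clusters lower outcome risk
        data = generate_sim2(DGPConfig(study="sim2", J=1000, seed=3))
        by_arm = {0: ([], []), 1: ([], [])}
        for c in data.clusters:
            by_arm[c.arm][0].append(c.size)
            by_arm[c.arm][1].append(c.Y.mean())
        for arm in (0, 1):
            rho = stats.spearmanr(by_arm[arm][0], by_arm[arm][1]).statistic
            assert rho < -0.2


class TestPairMatch:
    def test_unique_optimum(self):
        assert pair_match([0.0, 0.1, 5.0, 5.2]) == [(0, 1), (2, 3)]

    def test_matches_brute_force_oracle(self):
        def brute(values):
            n = len(values)
            best, best_cost = None, np.inf
            first = 0
            def rec(remaining, pairs, cost):
                nonlocal best, best_cost
                if not remaining:
                    if cost < best_cost:
                        best, best_cost = list(pairs), cost
                    return
                i = remaining[0]
                for j in remaining[1:]:
                    rest = [k for k in remaining if k not in (i, j)]
                    rec(rest, pairs + [(i, j)], cost + abs(values[i] - values[j]))
            rec(list(range(n)), [], 0.0)
            return best_cost

        rng = np.random.default_rng(6)
        for trial in range(5):
            vals = rng.normal(size=8)
            pairs = pair_match(vals)
            cost = sum(abs(vals[i] - vals[j]) for i, j in pairs)
            assert cost == pytest.approx(brute(vals), abs=1e-12)

    def test_one_dimensional_optimum_is_adjacent_pairing(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=20)
        pairs = pair_match(vals)
        cost = sum(abs(vals[i] - vals[j]) for i, j in pairs)
        s = np.sort(vals)
        adjacent = sum(s[i + 1] - s[i] for i in range(0, 20, 2))
        assert cost == pytest.approx(adjacent, abs=1e-12)

    def test_odd_count_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            pair_match([1.0, 2.0, 3.0])


class TestTruth:
    def test_null_truth_is_exactly_one(self):
        # coupled counterfactuals coincide when treatment terms are zeroed
        for study in ("sim1", "sim2"):
            t = compute_truth(DGPConfig(study=study, null_effect=True, seed=5, population_size=300))
            assert t.cluster_ratio == 1.0
            assert t.individual_ratio == 1.0
            assert t.geometric_ratio == 1.0

    def test_truth_stable_across_seeds(self):
        vals = [
            compute_truth(DGPConfig(study="sim1", seed=s, population_size=1500)).cluster_ratio
            for s in (1, 2, 3)
        ]
        assert np.ptp(vals) < 0.02

    def test_sim2_effects_diverge_by_level(self):
        # informative cluster size: individual-level effect is stronger
        t = compute_truth(DGPConfig(study="sim2", seed=1))
        assert t.individual_ratio < t.cluster_ratio - 0.04


def test_pair_match_large_input_uses_sorted_adjacent():
    rng = np.random.default_rng(2)
    vals = rng.normal(size=300)
    pairs = pair_match(vals)
    assert len(pairs) == 150
    cost = sum(abs(vals[i] - vals[j]) for i, j in pairs)
    s = np.sort(vals)
    assert cost == pytest.approx(sum(s[i + 1] - s[i] for i in range(0, 300, 2)), abs=1e-10)
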