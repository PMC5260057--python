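"""γ, the module-level decomposition, and the attractor similarity H."""

import math

import numpy as np
import pytest

from modrob import (
    Attractor,
    BooleanNetwork,
    GeneratorSpec,
    Partition,
    SignedDigraph,
    assign_update_rules,
    attractor_similarity,
    find_attractor,
    generate_random_network,
    module_robustness,
    network_robustness,
    project_attractor,
)
from modrob.dynamics import AttractorCache, state_to_int

from conftest import (
    oracle_H,
    oracle_gamma,
    oracle_module_robustness,
    random_partition,
)


def _att(n, *states):
    return Attractor.from_cycle([state_to_int(s, n) for s in states], n)


class TestAttractorSimilarity:
    def test_identical_attractors(self):
        a = _att(3, (0, 1, 1), (1, 0, 1))
        assert attractor_similarity(a, a, 3) == pytest.approx(1.0)

    def test_complementary_fixed_points(self):
        a = _att(4, (0, 0, 1, 1))
        b = _att(4, (1, 1, 0, 0))
        assert attractor_similarity(a, b, 4) == pytest.approx(0.0)

    def test_fixed_point_vs_two_cycle_sharing_state(self):
        a = _att(3, (0, 1, 0))
        b = _att(3, (0, 1, 0), (1, 1, 1))
        assert attractor_similarity(a, b, 3) == pytest.approx(0.5)

    def test_symmetric_in_arguments(self):
        a = _att(3, (0, 0, 1))
        b = _att(3, (0, 1, 0), (1, 0, 0))
        assert attractor_similarity(a, b, 3) == attractor_similarity(b, a, 3)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            attractor_similarity(_att(2, (0, 1)), _att(3, (0, 1, 1)), 3)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_literal_formula(self, seed):
        rng = np.random.default_rng(seed)
        n = 5
        la, lb = int(rng.integers(1, 4)), int(rng.integers(1, 4))
        sa = [tuple(int(x) for x in rng.integers(0, 2, n)) for _ in range(la)]
        sb = [tuple(int(x) for x in rng.integers(0, 2, n)) for _ in range(lb)]
        if len(set(sa)) < la or len(set(sb)) < lb:
            pytest.skip("degenerate draw")
        a, b = _att(n, *sa), _att(n, *sb)
        assert attractor_similarity(a, b, n) == pytest.approx(
            oracle_H(list(a.states), list(b.states), n)
        )


class TestProjectAttractor:
    def test_length_preserved_with_duplicates(self):
        a = _att(3, (1, 0, 1), (0, 1, 1))
        assert project_attractor(a, {"c"}, ("a", "b", "c")) == ((1,), (1,))

    def test_full_subset_is_identity(self):
        a = _att(3, (1, 0, 1), (0, 1, 1))
        assert project_attractor(a, {"a", "b", "c"}, ("a", "b", "c")) == a.states

    def test_fixed_point_projection(self):
        a = _att(3, (1, 0, 1))
        assert project_attractor(a, {"a", "c"}, ("a", "b", "c")) == ((1, 1),)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            project_attractor(_att(2, (0, 1)), set(), ("a", "b"))


class TestNetworkRobustness:
    def test_isolated_identity_nodes_gamma_zero(self):
        net = SignedDigraph(("a", "b", "c"), ())
        bn = BooleanNetwork(net, ("identity",) * 3)
        assert network_robustness(bn, sample_size=8) == 0.0

    def test_copy_or_network_quarter(self, copy_or_net):
        bn = BooleanNetwork(copy_or_net, ("identity", "disjunction"))
        assert network_robustness(bn, sample_size=4) == pytest.approx(0.25)

    def test_single_global_attractor_fully_robust(self):
        # A'=not B, B'=A drives all four states around one cycle
        net = SignedDigraph.from_arcs([("B", "A", -1), ("A", "B", 1)])
        bn = BooleanNetwork(net, ("conjunction", "conjunction"))
        assert network_robustness(bn, sample_size=4) == 1.0

    def test_full_sample_equals_exhaustive(self):
        net = generate_random_network(GeneratorSpec(model="er", n=5, m=10, seed=3))
        bn = assign_update_rules(net, 4)
        exact = network_robustness(bn, sample_size=32, seed=0)
        # any seed gives the same value once the sample covers the space
        assert network_robustness(bn, sample_size=32, seed=99) == exact
        assert network_robustness(bn, sample_size=10**6, seed=5) == exact

    @pytest.mark.parametrize("seed", range(10))
    def test_exhaustive_matches_literal_oracle(self, seed):
        net = generate_random_network(
            GeneratorSpec(model="er", n=5, m=int(8 + seed), seed=600 + seed)
        )
        bn = assign_update_rules(net, seed)
        rules = {v: bn.rules[i] for i, v in enumerate(net.nodes)}
        assert network_robustness(bn, sample_size=32) == pytest.approx(
            oracle_gamma(net, rules), abs=1e-12
        )

    def test_worker_count_does_not_change_result(self):
        net = generate_random_network(GeneratorSpec(model="er", n=6, m=12, seed=8))
        bn = assign_update_rules(net, 9)
        assert network_robustness(bn, sample_size=12, seed=1, workers=1) == \
            network_robustness(bn, sample_size=12, seed=1, workers=2)


class TestModuleRobustness:
    def test_disconnected_components_out_robustness_one(self, two_triangles):
        bn = assign_update_rules(two_triangles, seed=0)
        part = Partition((frozenset("ABC"), frozenset("DEF")))
        res = module_robustness(bn, part, sample_size=64, seed=0)
        assert res.per_module_out == (1.0, 1.0)

    def test_single_module_partition_out_missing(self, triangle):
        bn = assign_update_rules(triangle, seed=1)
        res = module_robustness(bn, Partition((frozenset("ABC"),)), sample_size=8)
        assert len(res.per_module_in) == 1
        assert math.isnan(res.per_module_out[0]) and math.isnan(res.gamma_out)
        assert res.gamma_in == pytest.approx(res.per_module_in[0])

    def test_single_global_attractor_all_ones(self):
        net = SignedDigraph.from_arcs([("B", "A", -1), ("A", "B", 1)])
        bn = BooleanNetwork(net, ("conjunction", "conjunction"))
        part = Partition((frozenset({"A"}), frozenset({"B"})))
        res = module_robustness(bn, part, sample_size=4)
        assert res.gamma == 1.0
        assert res.per_module_in == (1.0, 1.0)
        assert res.per_module_out == (1.0, 1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_exhaustive_matches_literal_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net = generate_random_network(
            GeneratorSpec(model="er", n=4, m=int(rng.integers(4, 9)), seed=700 + seed)
        )
        bn = assign_update_rules(net, seed)
        rules = {v: bn.rules[i] for i, v in enumerate(net.nodes)}
        part = random_partition(net.nodes, 2, rng)
        res = module_robustness(bn, part, sample_size=16, seed=0)
        exp_in, exp_out = oracle_module_robustness(
            net, rules, [sorted(m) for m in part.modules]
        )
        assert res.per_module_in == pytest.approx(exp_in, abs=1e-12)
        for got, exp in zip(res.per_module_out, exp_out):
            if math.isnan(exp):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(exp, abs=1e-12)
        assert res.gamma == pytest.approx(oracle_gamma(net, rules), abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_ranges_and_equality_bound(self, seed):
        """All values in [0,1]; exact-equality γ never exceeds mean whole-network H."""
        rng = np.random.default_rng(seed)
        net = generate_random_network(
            GeneratorSpec(model="er", n=6, m=14, seed=800 + seed)
        )
        bn = assign_update_rules(net, seed)
        part = random_partition(net.nodes, 3, rng)
        res = module_robustness(bn, part, sample_size=64, seed=0)
        for x in (res.gamma, res.gamma_in, *res.per_module_in):
            assert 0.0 <= x <= 1.0
        # H-based whole-network similarity average over the same pairs
        cache = AttractorCache(bn)
        total = 0.0
        n = net.n_nodes
        for s in range(2**n):
            a0 = cache.attractor_of(s)
            for i in range(n):
                a1 = cache.attractor_of(s ^ (1 << (n - 1 - i)))
                total += attractor_similarity(a0, a1, n)
        mean_h = total / (n * 2**n)
        assert res.gamma <= mean_h + 1e-12

    def test_shared_sample_between_gamma_and_modules(self):
        net = generate_random_network(GeneratorSpec(model="er", n=10, m=20, seed=9))
        bn = assign_update_rules(net, 2)
        part = random_partition(net.nodes, 3, np.random.default_rng(0))
        res = module_robustness(bn, part, sample_size=20, seed=5)
        assert res.gamma == pytest.approx(
            network_robustness(bn, sample_size=20, seed=5)
        )

    def test_worker_count_does_not_change_result(self):
        net = generate_random_network(GeneratorSpec(model="er", n=8, m=16, seed=10))
        bn = assign_update_rules(net, 11)
        part = random_partition(net.nodes, 3, np.random.default_rng(1))
        a = module_robustness(bn, part, sample_size=16, seed=2, workers=1)
        b = module_robustness(bn, part, sample_size=16, seed=2, workers=3)
        assert a == b


class TestSampling:
    def test_sampling_consistency_small_network(self):
        """Sampled γ is unbiased: mean over many seeds ≈ exhaustive γ."""
        net = generate_random_network(GeneratorSpec(model="er", n=6, m=12, seed=12))
        bn = assign_update_rules(net, 13)
        exact = network_robustness(bn, sample_size=64)
        vals = [network_robustness(bn, sample_size=12, seed=s) for s in range(100)]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - exact) <= 3 * max(se, 1e-12)
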