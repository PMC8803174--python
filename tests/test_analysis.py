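"""Robustness, bistability, graph censuses and reweighting, checked against
brute-force oracles (networkx reachability/path enumeration, itertools
subgraph scans) on all networks small enough to enumerate."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grnevo import (
    LOOSE,
    STRICT,
    FitnessBinning,
    ModelParams,
    RegulatoryNetwork,
    bistable_fraction,
    classify_switch,
    count_motifs,
    count_paths,
    effective_node_count,
    essential_edge_count,
    fitness,
    hysteresis_sweep,
    random_network,
    reweight_histogram,
    robustness,
)
from grnevo.analysis import BistabilityReport
from grnevo.fixtures import handcrafted_bistable, handcrafted_chain


def to_digraph(net):
    g = nx.DiGraph()
    g.add_nodes_from(range(net.n_nodes))
    g.add_edges_from(zip(net.src.tolist(), net.dst.tolist()))
    return g


class TestRobustness:
    def test_chain_deletions_disconnect(self):
        # 0 -> 1 -> 2: deleting either edge cuts the only input-output path
        net = handcrafted_chain(3)
        result = robustness(net)
        assert result.r == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(result.per_edge_fitness, 0.0, atol=1e-9)
        assert result.essential_count == 2

    def test_r_is_mean_of_deletion_fitnesses(self, rng):
        net = random_network(ModelParams(n_nodes=6, n_edges=10), rng)
        result = robustness(net)
        assert result.r == pytest.approx(result.per_edge_fitness.mean())
        assert 0.0 <= result.r <= 1.0
        assert 0 <= result.essential_count <= net.n_edges

    def test_neutral_edges_leave_r_at_f(self, rng):
        # edges entirely outside the input-output component are neutral
        params = ModelParams(n_nodes=6, n_edges=3)
        net = RegulatoryNetwork(
            params,
            np.array([0, 3, 4]),
            np.array([5, 4, 3]),
            np.array([1, 1, -1]),
        )
        f = fitness(net)
        result = robustness(net)
        # deleting 3<->4 edges changes nothing; deleting 0->5 zeroes fitness
        assert result.per_edge_fitness[1] == pytest.approx(f, abs=1e-9)
        assert result.per_edge_fitness[2] == pytest.approx(f, abs=1e-9)
        assert result.per_edge_fitness[0] == pytest.approx(0.0, abs=1e-9)

    def test_essential_count_monotone_in_threshold(self, rng):
        net = random_network(ModelParams(n_nodes=8, n_edges=16), rng)
        counts = [
            essential_edge_count(net, threshold=t)
            for t in (0.2, 0.5, 0.8, 0.95)
        ]
        assert counts == sorted(counts)


class TestHysteresis:
    def test_unregulated_output_is_monostable_at_half(self):
        params = ModelParams(n_nodes=3, n_edges=1)
        net = RegulatoryNetwork(
            params, np.array([1]), np.array([0]), np.array([1])
        )
        rep = hysteresis_sweep(net, LOOSE)
        assert rep.verdict == "monostable"
        np.testing.assert_allclose(rep.up_branch, 0.5, atol=1e-8)
        np.testing.assert_allclose(rep.down_branch, 0.5, atol=1e-8)

    def test_handcrafted_toggle_is_bistable_under_both_criteria(self):
        net = handcrafted_bistable()
        strict = hysteresis_sweep(net, STRICT)
        loose = hysteresis_sweep(net, LOOSE)
        assert strict.verdict == "bistable"
        assert loose.verdict == "bistable"
        assert strict.max_gap > 0.5
        assert strict.subtype == "toggle"

    def test_loose_bistability_implies_strict(self, rng):
        # scan random steep-response networks; every loose-bistable genotype
        # must also be strict-bistable
        params = ModelParams(n_nodes=5, n_edges=10, beta=6.0, mu=0.5)
        found = 0
        for seed in range(40):
            net = random_network(params, np.random.default_rng(seed))
            loose = hysteresis_sweep(net, LOOSE, classify=False)
            if loose.verdict == "bistable":
                found += 1
                strict = hysteresis_sweep(net, STRICT, classify=False)
                assert strict.verdict == "bistable"
        assert found >= 1, "scan should find at least one bistable genotype"

    def test_classify_requires_bistable(self):
        rep = BistabilityReport(
            criterion=STRICT,
            I_grid=np.linspace(0, 1, 11),
            up_branch=np.full(11, 0.5),
            down_branch=np.full(11, 0.5),
            max_gap=0.0,
            verdict="monostable",
        )
        with pytest.raises(ValueError):
            classify_switch(rep)

    @pytest.mark.parametrize(
        "up_jump,down_jump,expected",
        [(True, True, "toggle"), (True, False, "one_way"),
         (False, True, "one_way"), (False, False, "unswitchable")],
    )
    def test_switch_classification_rules(self, up_jump, down_jump, expected):
        grid = np.linspace(0, 1, 101)
        up = np.where(grid > 0.6, 0.9, 0.1) if up_jump else np.full(101, 0.1)
        down = np.where(grid > 0.4, 0.9, 0.2) if down_jump else np.full(101, 0.9)
        rep = BistabilityReport(
            criterion=STRICT, I_grid=grid, up_branch=up, down_branch=down,
            max_gap=float(np.max(np.abs(up - down))), verdict="bistable",
        )
        assert classify_switch(rep) == expected


class TestEffectiveNodes:
    def test_no_edges_into_output_leaves_only_output(self):
        params = ModelParams(n_nodes=4, n_edges=1)
        net = RegulatoryNetwork(
            params, np.array([0]), np.array([1]), np.array([1])
        )
        assert effective_node_count(net) == 1

    def test_full_chain_counts_all_nodes(self):
        assert effective_node_count(handcrafted_chain(5)) == 5

    @given(seed=st.integers(0, 2_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_networkx_ancestors(self, seed):
        params = ModelParams(n_nodes=6, n_edges=9)
        net = random_network(params, np.random.default_rng(seed))
        g = to_digraph(net)
        expected = len(nx.ancestors(g, net.params.output_index)) + 1
        assert effective_node_count(net) == expected


class TestPathCount:
    def test_disconnected_and_single_chain(self):
        assert count_paths(handcrafted_chain(4)) == (1, False)
        params = ModelParams(n_nodes=3, n_edges=1)
        net = RegulatoryNetwork(
            params, np.array([1]), np.array([0]), np.array([1])
        )
        assert count_paths(net) == (0, False)

    def test_layered_digraph_has_four_paths(self):
        # 0->1, 0->2, 0->3, 1->3, 2->3, 1->2: paths 0-3, 0-1-3, 0-2-3, 0-1-2-3
        params = ModelParams(n_nodes=4, n_edges=6)
        net = RegulatoryNetwork(
            params,
            np.array([0, 0, 0, 1, 2, 1]),
            np.array([1, 2, 3, 3, 3, 2]),
            np.ones(6, dtype=int),
        )
        assert count_paths(net) == (4, False)

    def test_cap_saturates(self):
        params = ModelParams(n_nodes=4, n_edges=6)
        net = RegulatoryNetwork(
            params,
            np.array([0, 0, 0, 1, 2, 1]),
            np.array([1, 2, 3, 3, 3, 2]),
            np.ones(6, dtype=int),
        )
        assert count_paths(net, cap=2) == (2, True)

    @given(seed=st.integers(0, 2_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_networkx_simple_paths(self, seed):
        params = ModelParams(n_nodes=6, n_edges=12)
        net = random_network(params, np.random.default_rng(seed))
        g = to_digraph(net)
        expected = sum(
            1 for _ in nx.all_simple_paths(g, 0, net.params.output_index)
        )
        count, saturated = count_paths(net)
        assert not saturated
        assert count == expected

    def test_positive_fitness_implies_a_path(self, rng):
        for seed in range(30):
            net = random_network(
                ModelParams(n_nodes=6, n_edges=8), np.random.default_rng(seed)
            )
            if fitness(net) > 1e-6:
                assert count_paths(net)[0] >= 1


def brute_force_motifs(net):
    """Exhaustive subgraph scan oracle (independent of the implementation)."""
    sign = {}
    for s, d, g in zip(net.src.tolist(), net.dst.tolist(), net.sign.tolist()):
        sign[(s, d)] = g
    n = net.n_nodes
    auto_act = sum(1 for i in range(n) if sign.get((i, i), 0) > 0)
    auto_rep = sum(1 for i in range(n) if sign.get((i, i), 0) < 0)
    mut_act = mut_rep = maa = mra = 0
    for i, j in itertools.combinations(range(n), 2):
        a, b = sign.get((i, j)), sign.get((j, i))
        if a is None or b is None:
            continue
        auto_both = sign.get((i, i), 0) > 0 and sign.get((j, j), 0) > 0
        if a > 0 and b > 0:
            mut_act += 1
            maa += auto_both
        if a < 0 and b < 0:
            mut_rep += 1
            mra += auto_both
    ffl = 0
    for j, k, i in itertools.permutations(range(n), 3):
        g1, g2, g3 = sign.get((j, k)), sign.get((k, i)), sign.get((j, i))
        if None not in (g1, g2, g3) and g3 == g1 * g2:
            ffl += 1
    fbl = 0
    for trio in itertools.combinations(range(n), 3):
        for a, b, c in [trio, (trio[0], trio[2], trio[1])]:
            g1, g2, g3 = sign.get((a, b)), sign.get((b, c)), sign.get((c, a))
            if None not in (g1, g2, g3) and g1 * g2 * g3 > 0:
                fbl += 1
    return dict(
        auto_activation=auto_act, auto_repression=auto_rep,
        mutual_activation=mut_act, mutual_repression=mut_rep,
        ffl_coherent=ffl, fbl_positive=fbl,
        mutual_activation_with_auto=maa, mutual_repression_with_auto=mra,
    )


class TestMotifs:
    def test_empty_network_like_counts(self):
        # a single isolated edge has no motifs at all
        params = ModelParams(n_nodes=4, n_edges=1)
        net = RegulatoryNetwork(
            params, np.array([2]), np.array([1]), np.array([1])
        )
        assert vars(count_motifs(net)) == dict.fromkeys(
            vars(count_motifs(net)), 0
        )

    def test_two_gene_mutual_activation_with_autos(self):
        params = ModelParams(n_nodes=2, n_edges=4)
        net = RegulatoryNetwork(
            params,
            np.array([0, 1, 0, 1]),
            np.array([1, 0, 0, 1]),
            np.array([1, 1, 1, 1]),
        )
        m = count_motifs(net)
        assert m.mutual_activation == 1
        assert m.auto_activation == 2
        assert m.mutual_activation_with_auto == 1
        assert m.mutual_repression == 0

    @given(seed=st.integers(0, 3_000))
    @settings(max_examples=80, deadline=None)
    def test_matches_brute_force_scan(self, seed):
        params = ModelParams(n_nodes=6, n_edges=10)
        net = random_network(params, np.random.default_rng(seed))
        assert vars(count_motifs(net)) == brute_force_motifs(net)


class TestReweighting:
    def test_identical_distributions_give_uniform_weights(self, rng):
        f = rng.uniform(0.5, 0.51, size=400)
        stat = rng.normal(size=400)
        out = reweight_histogram((f, stat), f, (0.5, 0.51))
        np.testing.assert_allclose(out.weights, 1.0 / 400, rtol=1e-9)
        assert not out.coverage_gap

    def test_weights_sum_to_one(self, rng):
        f_es = rng.uniform(0.5, 0.505, size=300)  # concentrated low
        f_ref = rng.uniform(0.5, 0.51, size=500)  # uniform
        out = reweight_histogram(
            (f_es, rng.normal(size=300)), f_ref, (0.5, 0.51)
        )
        assert out.weights.sum() == pytest.approx(1.0)
        assert out.coverage_gap  # upper sub-bins have no ES samples

    def test_deterministic_statistic_recovers_reference(self, rng):
        # statistic = known function of f: reweighted ES histogram must
        # match the reference's statistic distribution
        f_ref = rng.uniform(0.0, 1.0, size=20_000)
        f_es = rng.beta(0.5, 2.0, size=20_000)
        stat = lambda f: np.floor(f * 4)  # 4 discrete statistic levels
        out = reweight_histogram((f_es, stat(f_es)), f_ref, (0.0, 1.0), n_sub=4)
        got, _ = out.histogram(bins=np.arange(-0.5, 4.6))
        want = np.histogram(stat(f_ref), bins=np.arange(-0.5, 4.6))[0] / 20_000
        np.testing.assert_allclose(got, want, atol=0.02)

    def test_empty_overlap_rejected(self, rng):
        with pytest.raises(ValueError):
            reweight_histogram(
                (np.array([0.2]), np.array([1.0])),
                np.array([0.9]),
                (0.5, 0.6),
            )


class TestBistableFraction:
    def test_all_monostable_toy_set(self, rng):
        params = ModelParams(n_nodes=3, n_edges=2)
        samples = []
        for seed in range(10):
            net = random_network(params, np.random.default_rng(seed))
            samples.append((net, fitness(net)))
        df = bistable_fraction(samples, FitnessBinning(), LOOSE)
        assert (df["p2"] == 0).all()
        assert df["n"].sum() == 10

    def test_mixed_set_counts_handcrafted_toggle(self):
        net = handcrafted_bistable()
        f = fitness(net)
        mono = handcrafted_chain(3)
        df = bistable_fraction(
            [(net, f), (mono, fitness(mono))], FitnessBinning(), STRICT
        )
        by_bin = df.set_index("bin")
        assert by_bin.loc[FitnessBinning().bin_of(f), "p2"] == 1.0
        # empty bins are absent, not zero
        assert len(df) == 2
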