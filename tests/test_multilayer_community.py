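import numpy as np
import pytest

from conftest import random_adjacency, two_cliques_adjacency
from helpers import brute_force_multilayer_quality
from dynmod._seeds import derive_seeds
from dynmod.multilayer_community import (MultilayerCommunities,
                                         MultilayerNetwork,
                                         generalized_louvain,
                                         multilayer_quality, omega_for_pair,
                                         run_ensemble)
from dynmod.static_community import best_of_runs, louvain, modularity_score


class TestOmegaForPair:
    def test_same_condition_couples_at_one(self):
        assert omega_for_pair("1-back", "1-back") == 1.0

    def test_different_conditions_couple_at_half(self):
        assert omega_for_pair("1-back", "2-back") == 0.5

    def test_zero_couplings_decouple_everything(self):
        assert omega_for_pair("1-back", "2-back", 0.0, 0.0) == 0.0
        assert omega_for_pair("1-back", "1-back", 0.0, 0.0) == 0.0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            omega_for_pair("1-back", "3-back",
                           known_labels=("1-back", "2-back"))


def _network(layers, conditions=None, **kw):
    layers = np.asarray(layers, float)
    if conditions is None:
        conditions = ["1-back", "2-back"] * (layers.shape[0] // 2 + 1)
        conditions = conditions[: layers.shape[0]]
    return MultilayerNetwork(layers=layers, layer_conditions=conditions,
                             **kw)


class TestMultilayerQuality:
    @pytest.mark.parametrize("seed", range(10))
    def test_single_layer_reduces_to_static_modularity(self, seed):
        rng = np.random.default_rng(seed)
        A = random_adjacency(rng, 10)
        net = _network(A[None], ["1-back"])
        g = rng.integers(0, 3, 10)
        assert multilayer_quality(net, g[:, None]) == pytest.approx(
            modularity_score(A, g), abs=1e-12)

    def test_decoupled_all_in_one_layers_score_zero(self):
        rng = np.random.default_rng(1)
        layers = np.stack([random_adjacency(rng, 8) for _ in range(3)])
        net = _network(layers, ["a", "b", "c"], omega_same=0.0,
                       omega_diff=0.0)
        g = np.zeros((8, 3), dtype=int)
        assert multilayer_quality(net, g) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_summation(self, seed):
        rng = np.random.default_rng(seed)
        layers = np.stack([random_adjacency(rng, 4) for _ in range(3)])
        conditions = ["1-back", "2-back", "1-back"]
        net = _network(layers, conditions)
        g = rng.integers(0, 3, (4, 3))
        expected = brute_force_multilayer_quality(layers, conditions, g)
        assert multilayer_quality(net, g) == pytest.approx(expected,
                                                           abs=1e-12)

    def test_two_node_toy_matched_against_explicit_sum(self):
        layers = np.array([[[0.0, 0.8], [0.8, 0.0]],
                           [[0.0, 0.2], [0.2, 0.0]]])
        conditions = ["1-back", "2-back"]
        net = _network(layers, conditions)
        g = np.array([[0, 0], [0, 1]])
        expected = brute_force_multilayer_quality(layers, conditions, g)
        assert multilayer_quality(net, g) == pytest.approx(expected,
                                                           abs=1e-14)


class TestGeneralizedLouvain:
    def test_strong_coupling_on_identical_layers_is_column_constant(self):
        A = two_cliques_adjacency(4)
        net = _network(np.stack([A] * 4), ["1-back", "2-back"] * 2,
                       omega_same=100.0, omega_diff=100.0)
        part = generalized_louvain(net, seed=0)
        for i in range(8):
            assert len(set(part.assignment[i])) == 1

    def test_zero_coupling_equals_independent_layer_runs(self):
        rng = np.random.default_rng(3)
        layers = np.stack([random_adjacency(rng, 12) for _ in range(3)])
        net = _network(layers, ["a", "b", "a"], omega_same=0.0,
                       omega_diff=0.0)
        part = generalized_louvain(net, seed=17)
        for t, child in enumerate(derive_seeds(17, 3)):
            labels, q = louvain(layers[t], seed=int(child))
            col = part.assignment[:, t]
            # identical partitions up to global relabeling
            assert len(set(zip(col, labels))) == len(set(col))
            assert len(set(col)) == len(set(labels))

    def test_planted_two_node_swap_moves_exactly_those_nodes(self):
        # two 4-cliques; in layer 2, nodes 3 and 7 trade cliques
        perm = np.array([0, 1, 2, 7, 4, 5, 6, 3])
        A1 = two_cliques_adjacency(4)
        A2 = A1[np.ix_(perm, perm)]
        net = _network(np.stack([A1, A2]), ["1-back", "2-back"],
                       omega_same=0.3, omega_diff=0.3)
        part = generalized_louvain(net, seed=2)
        g = part.assignment
        changed = np.flatnonzero(g[:, 0] != g[:, 1])
        np.testing.assert_array_equal(changed, [3, 7])
        # both layers keep two modules of four
        for t in range(2):
            assert len(set(g[:, t])) == 2

    def test_quality_consistent_with_direct_evaluation(self):
        rng = np.random.default_rng(5)
        layers = np.stack([random_adjacency(rng, 10) for _ in range(4)])
        net = _network(layers)
        part = generalized_louvain(net, seed=9)
        assert part.quality == pytest.approx(
            multilayer_quality(net, part.assignment), abs=1e-10)

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(6)
        layers = np.stack([random_adjacency(rng, 8) for _ in range(3)])
        net = _network(layers)
        p1 = generalized_louvain(net, seed=4)
        p2 = generalized_louvain(net, seed=4)
        np.testing.assert_array_equal(p1.assignment, p2.assignment)

    @pytest.mark.parametrize("seed", range(5))
    def test_single_layer_optimizer_agrees_with_static(self, seed):
        A = random_adjacency(np.random.default_rng(seed), 12)
        net = _network(A[None], ["1-back"])
        part = generalized_louvain(net, seed=seed)
        _, q_static = louvain(A, seed=seed)
        assert part.quality == pytest.approx(q_static, abs=1e-10)

    def test_between_layer_agreement_monotone_in_coupling(self):
        # two layers with conflicting planted structure: stronger coupling
        # can only increase cross-layer label persistence
        rng = np.random.default_rng(12)
        A1 = two_cliques_adjacency(4) + 0.05 * random_adjacency(rng, 8)
        perm = np.array([0, 1, 4, 5, 2, 3, 6, 7])
        A2 = A1[np.ix_(perm, perm)]
        agreements = []
        for omega in (0.0, 0.05, 0.5, 5.0):
            net = _network(np.stack([A1, A2]), ["a", "b"],
                           omega_same=omega, omega_diff=omega)
            parts = run_ensemble(net, n_opt=10, seed=0)
            agree = np.mean([np.mean(p.assignment[:, 0] == p.assignment[:, 1])
                             for p in parts])
            agreements.append(agree)
        assert all(b >= a - 1e-9 for a, b in zip(agreements, agreements[1:]))


class TestEnsemble:
    def test_ensemble_size_and_determinism(self):
        rng = np.random.default_rng(7)
        layers = np.stack([random_adjacency(rng, 8) for _ in range(2)])
        net = _network(layers)
        e1 = run_ensemble(net, n_opt=5, seed=3)
        e2 = run_ensemble(net, n_opt=5, seed=3)
        assert len(e1) == 5
        for p1, p2 in zip(e1, e2):
            np.testing.assert_array_equal(p1.assignment, p2.assignment)

    def test_all_members_beat_the_singleton_assignment(self):
        rng = np.random.default_rng(8)
        layers = np.stack([random_adjacency(rng, 8) for _ in range(3)])
        net = _network(layers)
        N, T = 8, 3
        singletons = np.arange(N * T).reshape(T, N).T
        q_singleton = multilayer_quality(net, singletons)
        for part in run_ensemble(net, n_opt=5, seed=1):
            assert part.quality >= q_singleton - 1e-12

    def test_estimator_interface_selects_best_member(self):
        rng = np.random.default_rng(9)
        layers = np.stack([random_adjacency(rng, 8) for _ in range(2)])
        est = MultilayerCommunities(n_optimizations=6, random_state=0)
        est.fit(_network(layers))
        assert est.assignment_.shape == (8, 2)
        assert est.quality_ == pytest.approx(est.qualities_.max())
        assert est.get_params()["n_optimizations"] == 6
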