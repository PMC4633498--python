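"""Bayesian-network core: joint model, BIC, MH search, MAP fitting, inference."""

import math

import numpy as np
import pytest

from petcad import (
    LABEL_APS,
    LABEL_PD,
    CPTSet,
    DAGStructure,
    DiscreteDataset,
    bic_score,
    classify,
    enumerate_dags,
    fit_cpts_map,
    joint_probability,
    markov_equivalent,
    mh_structure_search,
    naive_cpts_from_accuracies,
    naive_structure,
    posterior_label,
    simulate_decision_table,
)
from petcad.bayesnet import _apply_move, family_bic


def random_cpts(structure, rng):
    parents = {v: structure.parents(v) for v in range(structure.n_nodes)}
    tables = {}
    for v, pa in parents.items():
        p1 = rng.uniform(0.05, 0.95, size=(2,) * len(pa))
        tables[v] = np.stack([1.0 - p1, p1], axis=-1)
    return CPTSet(parents=parents, tables=tables)


def uniform_cpts(structure):
    parents = {v: structure.parents(v) for v in range(structure.n_nodes)}
    tables = {v: np.full((2,) * len(pa) + (2,), 0.5) for v, pa in parents.items()}
    return CPTSet(parents=parents, tables=tables)


def brute_joint(structure, cpts, assignment):
    """Independent oracle: multiply CPT lookups without the package helper."""
    p = 1.0
    for v in range(structure.n_nodes):
        idx = tuple(assignment[q] for q in structure.parents(v)) + (assignment[v],)
        p *= float(cpts.tables[v][idx])
    return p


class TestStructures:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            DAGStructure(3, [(0, 1), (1, 2), (2, 0)])

    def test_parents_sorted(self):
        g = DAGStructure(4, [(2, 0), (1, 0), (3, 2)])
        assert g.parents(0) == (1, 2)
        assert g.parents(2) == (3,)
        assert g.parents(1) == ()

    def test_json_roundtrip(self):
        g = DAGStructure(4, [(3, 0), (3, 1), (1, 2)])
        assert DAGStructure.from_json(g.to_json()) == g

    @pytest.mark.parametrize("n,count", [(2, 3), (3, 25), (4, 543)])
    def test_enumerate_dags_counts(self, n, count):
        dags = list(enumerate_dags(n))
        assert len(dags) == count
        assert len(set(dags)) == count

    def test_markov_equivalence(self):
        fork = DAGStructure(3, [(2, 0), (2, 1)])
        chain = DAGStructure(3, [(0, 2), (2, 1)])
        collider = DAGStructure(3, [(0, 2), (1, 2)])
        assert markov_equivalent(fork, chain)
        assert not markov_equivalent(fork, collider)
        assert not markov_equivalent(fork, DAGStructure(3, [(2, 0)]))


class TestJointProbability:
    def test_uniform_empty_graph_is_flat(self):
        g = DAGStructure(3)  # M=2 regions + label
        cpts = uniform_cpts(g)
        for bits in range(8):
            assign = [(bits >> k) & 1 for k in range(3)]
            assert joint_probability(g, cpts, assign) == pytest.approx(1 / 8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_joint_sums_to_one_by_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        dags = list(enumerate_dags(4))
        g = dags[rng.integers(len(dags))]
        cpts = random_cpts(g, rng)
        total = sum(
            joint_probability(g, cpts, [(b >> k) & 1 for k in range(4)])
            for b in range(16)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_chain_concentrates_on_one_assignment(self):
        # y -> x1 -> x2 with copy CPTs and y fixed at 1
        g = DAGStructure(3, [(2, 0), (0, 1)])
        copy = np.array([[1.0, 0.0], [0.0, 1.0]])
        cpts = CPTSet(
            parents={0: (2,), 1: (0,), 2: ()},
            tables={0: copy.copy(), 1: copy.copy(), 2: np.array([0.0, 1.0])},
        )
        assert joint_probability(g, cpts, [1, 1, 1]) == 1.0
        assert joint_probability(g, cpts, [0, 1, 1]) == 0.0

    def test_partial_assignment_rejected(self):
        g = DAGStructure(3)
        with pytest.raises(ValueError):
            joint_probability(g, uniform_cpts(g), [0, 1])


class TestBicScore:
    def test_single_binary_node_constant_data(self):
        # all four observations identical: MLE likelihood 1, one free parameter
        data = DiscreteDataset(np.ones((4, 2), dtype=np.uint8))
        score = family_bic(0, (), data)
        assert score == pytest.approx(-0.5 * math.log(4))

    def test_score_decomposes_over_families(self, rng):
        data = DiscreteDataset(rng.integers(0, 2, size=(40, 4)).astype(np.uint8))
        g = DAGStructure(4, [(3, 0), (3, 1), (0, 1), (1, 2)])
        total = bic_score(g, data)
        per_family = sum(family_bic(v, g.parents(v), data) for v in range(4))
        assert total == pytest.approx(per_family, rel=1e-12)

    def test_adding_an_edge_changes_only_the_childs_family(self, rng):
        data = DiscreteDataset(rng.integers(0, 2, size=(30, 3)).astype(np.uint8))
        g0 = DAGStructure(3, [(2, 0)])
        g1 = DAGStructure(3, [(2, 0), (2, 1)])
        delta = bic_score(g1, data) - bic_score(g0, data)
        family_delta = family_bic(1, (2,), data) - family_bic(1, (), data)
        assert delta == pytest.approx(family_delta, rel=1e-12)

    def test_bic_prefers_independence_on_independent_data(self):
        rng = np.random.default_rng(3)
        n = 500
        data = DiscreteDataset(
            np.column_stack([rng.integers(0, 2, n), rng.integers(0, 2, n)]).astype(np.uint8)
        )
        empty = DAGStructure(2)
        dependent = DAGStructure(2, [(0, 1)])
        assert bic_score(empty, data) > bic_score(dependent, data)


class TestFitCptsMap:
    def test_laplace_counting_example(self):
        # binary node, no parents, 3 of 4 observations in state 1, alpha=1
        data = DiscreteDataset(np.array([[1, 1], [1, 1], [1, 1], [0, 1]], dtype=np.uint8))
        cpts = fit_cpts_map(DAGStructure(2), data, alpha=1.0)
        assert cpts.tables[0][1] == pytest.approx((3 + 1) / (4 + 2))

    def test_empty_dataset_gives_uniform_prior(self):
        data = DiscreteDataset(np.zeros((0, 3), dtype=np.uint8))
        g = DAGStructure(3, [(2, 0)])
        cpts = fit_cpts_map(g, data, alpha=1.0)
        for v in range(3):
            np.testing.assert_allclose(cpts.tables[v], 0.5)

    def test_alpha_zero_recovers_mle(self):
        data = DiscreteDataset(
            np.array([[1, 1], [1, 1], [0, 1], [0, 0], [1, 0]], dtype=np.uint8)
        )
        cpts = fit_cpts_map(DAGStructure(2, [(1, 0)]), data, alpha=0.0)
        # given y=1: x is 1,1,0 -> p(x=1|y=1) = 2/3
        assert cpts.tables[0][1, 1] == pytest.approx(2 / 3)

    def test_alpha_zero_unseen_config_falls_back_to_uniform(self):
        data = DiscreteDataset(np.array([[1, 1], [0, 1]], dtype=np.uint8))  # y always 1
        cpts = fit_cpts_map(DAGStructure(2, [(1, 0)]), data, alpha=0.0)
        np.testing.assert_allclose(cpts.tables[0][0], 0.5)

    def test_cpt_rows_always_sum_to_one(self, rng):
        data = DiscreteDataset(rng.integers(0, 2, size=(25, 4)).astype(np.uint8))
        g = DAGStructure(4, [(3, 0), (3, 1), (3, 2), (0, 1)])
        cpts = fit_cpts_map(g, data, alpha=1.0)
        for v in range(4):
            np.testing.assert_allclose(cpts.tables[v].sum(axis=-1), 1.0, atol=1e-12)

    def test_parameter_recovery_on_naive_structure(self):
        acc = np.array([0.9, 0.8, 0.7, 0.6])
        data = simulate_decision_table(2000, 4, acc, label_prevalence=0.5, seed=21)
        cpts = fit_cpts_map(naive_structure(4), data, alpha=1.0)
        # a region's accuracy is its agreement probability P(x_m = y); the
        # generator makes it label-independent, so the recovered value is the
        # label-frequency-weighted diagonal of the fitted CPT
        p1 = np.mean(data.labels)
        for m, a in enumerate(acc):
            recovered = (1 - p1) * cpts.tables[m][0, 0] + p1 * cpts.tables[m][1, 1]
            assert recovered == pytest.approx(a, abs=0.03)


class TestPosteriorAndClassify:
    def test_disconnected_label_posterior_is_its_marginal(self):
        g = DAGStructure(3)
        parents = {0: (), 1: (), 2: ()}
        tables = {0: np.array([0.4, 0.6]), 1: np.array([0.9, 0.1]),
                  2: np.array([0.3, 0.7])}
        cpts = CPTSet(parents=parents, tables=tables)
        assert posterior_label(g, cpts, [0, 1]) == pytest.approx(0.7)

    @pytest.mark.parametrize("seed", range(5))
    def test_posterior_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dags = list(enumerate_dags(4))
        g = dags[rng.integers(len(dags))]
        cpts = random_cpts(g, rng)
        for bits in range(8):
            ev = [(bits >> k) & 1 for k in range(3)]
            num = brute_joint(g, cpts, ev + [1])
            den = num + brute_joint(g, cpts, ev + [0])
            assert posterior_label(g, cpts, ev) == pytest.approx(num / den, abs=1e-12)

    def test_deterministic_agreeing_cpts_give_certainty(self):
        structure, cpts = naive_cpts_from_accuracies([1.0, 1.0], prevalence=0.5)
        assert posterior_label(structure, cpts, [1, 1]) == pytest.approx(1.0)
        assert posterior_label(structure, cpts, [0, 0]) == pytest.approx(0.0)

    def test_naive_fusion_equals_weighted_evidence_product_rule(self):
        # conditionally independent detectors: posterior odds = prior odds times
        # the product of per-region likelihood ratios
        acc = [0.9, 0.7, 0.6]
        prev = 0.45
        structure, cpts = naive_cpts_from_accuracies(acc, prevalence=prev)
        for bits in range(8):
            ev = [(bits >> k) & 1 for k in range(3)]
            odds = prev / (1 - prev)
            for a, x in zip(acc, ev):
                odds *= (a / (1 - a)) if x == 1 else ((1 - a) / a)
            assert posterior_label(structure, cpts, ev) == pytest.approx(
                odds / (1 + odds), abs=1e-12
            )

    def test_argmax_posterior(self):
        structure, cpts = naive_cpts_from_accuracies([0.7], prevalence=0.5)
        assert classify(structure, cpts, [1]) == LABEL_PD
        assert classify(structure, cpts, [0]) == LABEL_APS

    def test_exact_tie_falls_back_to_majority_vote(self):
        # all regions disconnected from a fair label: posterior exactly 0.5
        g = DAGStructure(5)
        parents = {v: () for v in range(5)}
        tables = {v: np.array([0.5, 0.5]) for v in range(5)}
        cpts = CPTSet(parents=parents, tables=tables)
        assert posterior_label(g, cpts, [1, 1, 1, 0]) == pytest.approx(0.5)
        assert classify(g, cpts, [1, 1, 1, 0]) == LABEL_PD
        # tied vote resolved by the most accurate region's decision
        assert classify(g, cpts, [1, 1, 0, 0],
                        region_accuracies=[0.9, 0.6, 0.7, 0.5]) == LABEL_PD
        assert classify(g, cpts, [0, 1, 1, 0],
                        region_accuracies=[0.9, 0.6, 0.7, 0.5]) == LABEL_APS


class TestMHStructureSearch:
    def test_identical_seed_identical_trace_and_structure(self):
        data = simulate_decision_table(80, 3, [0.9, 0.8, 0.7], seed=2)
        g1, t1 = mh_structure_search(data, n_iter=300, burn_in=50, seed=9)
        g2, t2 = mh_structure_search(data, n_iter=300, burn_in=50, seed=9)
        assert g1 == g2
        assert t1.moves == t2.moves
        assert t1.accepted == t2.accepted
        np.testing.assert_array_equal(t1.scores, t2.scores)

    def test_zero_iterations_returns_initial_empty_structure(self):
        data = simulate_decision_table(30, 2, [0.9, 0.8], seed=0)
        g, trace = mh_structure_search(data, n_iter=0, burn_in=0, seed=0)
        assert g == DAGStructure(3)
        assert trace.n_iterations == 0

    def test_acceptance_ratio_in_unit_interval(self):
        data = simulate_decision_table(60, 3, [0.9, 0.6, 0.7], seed=4)
        _, trace = mh_structure_search(data, n_iter=400, burn_in=100, seed=1)
        assert 0.0 <= trace.acceptance_ratio <= 1.0
        assert len(trace.cumulative_acceptance()) == 400

    def test_flat_score_visits_dags_uniformly(self):
        # pure Hastings sampler: the stationary law over the 25 three-node DAGs
        # must be uniform when the score is constant
        _, trace = mh_structure_search(
            None, n_iter=30000, burn_in=0, seed=42, score=lambda g: 0.0, n_nodes=3
        )
        adj = np.zeros((3, 3), dtype=bool)
        counts = {}
        for mv, acc in zip(trace.moves, trace.accepted):
            if acc:
                _apply_move(adj, mv)
            key = adj.tobytes()
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 25
        freqs = np.array(list(counts.values())) / trace.n_iterations
        assert np.max(np.abs(freqs - 1 / 25)) < 0.01

    def test_recovers_generating_equivalence_class(self):
        # strong y -> x1, y -> x2 dependence; verify against exhaustive scoring
        data = simulate_decision_table(500, 2, [0.9, 0.85], label_prevalence=0.5,
                                       seed=17)
        generator = naive_structure(2)
        best_exhaustive = max(enumerate_dags(3), key=lambda g: bic_score(g, data))
        assert markov_equivalent(best_exhaustive, generator)
        found, _ = mh_structure_search(data, n_iter=1000, burn_in=200, seed=3)
        assert markov_equivalent(found, generator)
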