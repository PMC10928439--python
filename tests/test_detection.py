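import itertools

import numpy as np
import pytest

from lepin import (Complex, ComplexSet, DetectionParams, WeightedPIN,
                   complex_score, deduplicate, detect_complexes, inflate,
                   shrink)
from lepin.detection import CandidateComplex, _search_from_seed


class TestComplexScore:
    def test_isolated_unit_clique_attains_maximum(self):
        pin = WeightedPIN.from_edges(
            [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])
        D, M, F = complex_score(pin, {"a", "b", "c"})
        assert (D, M, F) == (1.0, 1.0, 1.5)

    def test_worked_four_node_instance(self, worked_pin):
        D, M, F = complex_score(worked_pin, {"a", "b", "c"})
        assert D == pytest.approx(2.6 / 3)
        assert M == pytest.approx(2.6 / 2.9)
        assert F == pytest.approx(1.3222871615, abs=1e-9)

    def test_singleton_scores_zero(self, worked_pin):
        assert complex_score(worked_pin, {"a"})[2] == 0.0

    def test_zero_internal_weight_scores_zero(self):
        pin = WeightedPIN.from_edges([("a", "b", 0.5)])
        pin.add_node("c")
        assert complex_score(pin, {"a", "c"})[2] == 0.0

    def test_unknown_member_rejected(self, worked_pin):
        with pytest.raises(KeyError):
            complex_score(worked_pin, {"a", "zz"})

    def test_f_bounds_on_random_subgraphs(self):
        import networkx as nx
        rng = np.random.default_rng(0)
        for trial in range(50):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(1 << 30)))
            pin = WeightedPIN()
            for n in g:
                pin.add_node(f"n{n:02d}")
            for u, v in g.edges():
                pin.add_edge(f"n{u:02d}", f"n{v:02d}", float(rng.random()))
            nodes = sorted(pin.nodes)
            for _ in range(20):
                k = int(rng.integers(1, 6))
                members = set(rng.choice(nodes, size=k, replace=False))
                D, M, F = complex_score(pin, members)
                assert 0.0 <= F <= 1.5
                if F == 1.5:
                    assert D == 1.0 and M == 1.0


class TestInflate:
    def test_full_trace_on_worked_instance(self, worked_pin):
        cc = CandidateComplex.from_members(worked_pin, {"a"})
        grown = inflate(worked_pin, cc)
        assert grown.members == {"a", "b", "c"}
        assert grown.F == pytest.approx(1.3222871615, abs=1e-9)

    def test_first_addition_prefers_b_over_c(self, worked_pin):
        # F({a,b}) ≈ 0.8731 beats F({a,c}) ≈ 0.7430
        _, _, f_ab = complex_score(worked_pin, {"a", "b"})
        _, _, f_ac = complex_score(worked_pin, {"a", "c"})
        assert f_ab == pytest.approx(0.873077, abs=1e-5)
        assert f_ac == pytest.approx(0.743059, abs=1e-5)
        assert f_ab > f_ac

    def test_weak_neighbor_blocked_by_weight_gate(self):
        pin = WeightedPIN.from_edges([("a", "b", 0.4)])
        cc = inflate(pin, CandidateComplex.from_members(pin, {"a"}))
        assert cc.members == {"a"}

    def test_isolated_unit_triangle_grows_fully(self):
        pin = WeightedPIN.from_edges(
            [("n0", "n1", 1.0), ("n1", "n2", 1.0), ("n0", "n2", 1.0)])
        cc = inflate(pin, CandidateComplex.from_members(pin, {"n0"}))
        assert cc.members == {"n0", "n1", "n2"}
        assert cc.F == pytest.approx(1.5)

    def test_expectation_gate_caps_growth_once_f_exceeds_one(self):
        # the expected-edges criterion demands >= F * |V_SG| links into
        # the subgraph; a candidate has at most |V_SG| links, so growth
        # halts as soon as F > 1 — a unit-weight 5-clique stops at 4
        nodes = [f"n{i}" for i in range(5)]
        pin = WeightedPIN.from_edges(
            [(u, v, 1.0) for u, v in itertools.combinations(nodes, 2)])
        cc = inflate(pin, CandidateComplex.from_members(pin, {"n0"}))
        assert len(cc.members) == 4
        assert cc.F > 1.0

    def test_never_decreases_f(self, worked_pin):
        for seed in worked_pin.nodes:
            cc = CandidateComplex.from_members(worked_pin, {seed})
            assert inflate(worked_pin, cc).F >= cc.F


class TestShrink:
    def test_no_removal_improves_worked_instance(self, worked_pin):
        cc = CandidateComplex.from_members(worked_pin, {"a", "b", "c"})
        assert shrink(worked_pin, cc).members == {"a", "b", "c"}

    def _weak_member_instance(self):
        edges = [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
                 ("a", "x", 0.51)]
        edges += [("x", f"e{i}", 0.9) for i in range(4)]
        return WeightedPIN.from_edges(edges)

    def test_weak_member_removed_without_expectation_gate(self):
        pin = self._weak_member_instance()
        cc = CandidateComplex.from_members(pin, {"a", "b", "c", "x"})
        params = DetectionParams(shrink_requires_eq29=False)
        out = shrink(pin, cc, params)
        assert out.members == {"a", "b", "c"}
        assert out.F > cc.F

    def test_expectation_gate_blocks_single_link_removal(self):
        # as printed, the removal candidate must itself satisfy the
        # expected-edges criterion against the remaining subgraph; a
        # single-link node cannot, so it stays
        pin = self._weak_member_instance()
        cc = CandidateComplex.from_members(pin, {"a", "b", "c", "x"})
        out = shrink(pin, cc, DetectionParams(shrink_requires_eq29=True))
        assert out.members == {"a", "b", "c", "x"}

    def test_isolated_component_unchanged(self):
        pin = WeightedPIN.from_edges(
            [("a", "b", 0.9), ("b", "c", 0.9), ("a", "c", 0.9)])
        cc = CandidateComplex.from_members(pin, {"a", "b", "c"})
        assert shrink(pin, cc).members == {"a", "b", "c"}

    def test_never_decreases_f(self, worked_pin):
        for members in [{"a", "b", "c", "d"}, {"a", "b", "d"}, {"c", "d"}]:
            cc = CandidateComplex.from_members(worked_pin, members)
            assert shrink(worked_pin, cc).F >= cc.F


class TestDetectComplexes:
    def test_seed_search_on_worked_instance(self, worked_pin):
        cc = _search_from_seed(worked_pin, "a", DetectionParams())
        assert cc.members == {"a", "b", "c"}
        assert cc.F == pytest.approx(1.3222871615, abs=1e-9)

    def test_two_cliques_with_weak_bridge(self):
        from lepin import evaluate
        c1 = [f"a{i}" for i in range(4)]
        c2 = [f"b{i}" for i in range(4)]
        edges = [(u, v, 0.9) for u, v in itertools.combinations(c1, 2)]
        edges += [(u, v, 0.9) for u, v in itertools.combinations(c2, 2)]
        edges += [("a0", "b0", 0.1)]
        found = detect_complexes(WeightedPIN.from_edges(edges))
        # the bridge fails the weight gate: no prediction mixes the cliques
        assert all(c.members <= frozenset(c1) or c.members <= frozenset(c2)
                   for c in found)
        truth = ComplexSet.from_iterable([c1, c2])
        rep = evaluate(found, truth, threshold=0.2)
        assert rep.Recall == 1.0 and rep.Precision == 1.0

    def test_empty_graph(self):
        assert len(detect_complexes(WeightedPIN())) == 0

    def test_single_isolated_edge(self):
        pin = WeightedPIN.from_edges([("u", "v", 0.9)])
        found = detect_complexes(pin)
        assert len(found) == 1
        assert found[0].members == frozenset(("u", "v"))
        assert found[0].score == pytest.approx(1.4236842105, abs=1e-9)

    def test_small_planted_pair_recovered_amid_weak_background(self):
        edges = [("p1", "p2", 0.9),
                 ("p1", "q1", 0.2), ("p2", "q2", 0.15), ("q1", "q2", 0.1)]
        found = detect_complexes(WeightedPIN.from_edges(edges))
        assert frozenset(("p1", "p2")) in {c.members for c in found}

    def test_deterministic_across_workers_and_repeats(self):
        from lepin import PlantedNetworkSpec, generate_planted_pin
        truth = generate_planted_pin(PlantedNetworkSpec(
            n_complexes=10, background_edge_probability=0.02, seed=5))
        runs = [detect_complexes(truth.pin, workers=w) for w in (1, 1, 4)]
        as_tuples = [
            [(c.sorted_members(), round(c.score, 12)) for c in r]
            for r in runs]
        assert as_tuples[0] == as_tuples[1] == as_tuples[2]


class TestDeduplicate:
    def test_identical_sets_keep_one(self):
        cs = ComplexSet([Complex(frozenset("abc"), 1.2)] * 3)
        assert len(deduplicate(cs)) == 1

    def test_subset_is_not_a_duplicate(self):
        cs = ComplexSet([Complex(frozenset("ab"), 1.0),
                         Complex(frozenset("abc"), 1.2)])
        assert len(deduplicate(cs)) == 2

    def test_idempotent_and_canonically_sorted(self):
        cs = ComplexSet([Complex(frozenset("ab"), 1.0),
                         Complex(frozenset("cd"), 1.4),
                         Complex(frozenset("ab"), 1.0)])
        once = deduplicate(cs)
        twice = deduplicate(once)
        assert [c.members for c in once] == [c.members for c in twice]
        assert [c.score for c in once] == [1.4, 1.0]
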