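import numpy as np
import pytest

from cyprodent.mk import MkModel, marginal_ancestral_states
from cyprodent.parsimony import compare_ml_parsimony, fitch, sankoff
from cyprodent.trees import assign_branch_lengths, node_signature, parse_newick

from ._oracles import enumerate_parsimony
from .conftest import random_instance

STATES3 = ("A", "B", "C")
UNIT3 = np.ones((3, 3)) - np.eye(3)


class TestFitch:
    def test_constant_character(self):
        t = parse_newick("((A,B),(C,D));")
        res = fitch(t, {x: "A" for x in "ABCD"}, states=("A", "B"))
        assert res.changes == 0
        assert all(s == frozenset({"A"}) for s in res.node_sets.values() if s)

    def test_two_tip_conflict(self):
        t = parse_newick("(A,B);")
        res = fitch(t, {"A": "A", "B": "B"}, states=("A", "B"))
        assert res.changes == 1
        assert res.node_sets[node_signature(t.seed_node)] == frozenset({"A", "B"})

    def test_missing_tips_never_force_changes(self):
        t = parse_newick("((A,B),(C,D));")
        res = fitch(t, {"A": "A", "B": "?", "C": "?", "D": "A"}, states=("A", "B"))
        assert res.changes == 0

    def test_no_scored_tips_rejected(self):
        t = parse_newick("(A,B);")
        with pytest.raises(ValueError):
            fitch(t, {"A": "?", "B": "?"}, states=("A", "B"))

    def test_matches_enumeration(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            n = int(rng.integers(4, 7))
            k = int(rng.integers(2, 4))
            tree, tips, states = random_instance(rng, n, k)
            if not any(v != "?" for v in tips.values()):
                continue
            res = fitch(tree, tips, states=states)
            want_cost, want_sets = enumerate_parsimony(tree, tips, states)
            assert res.changes == int(want_cost)
            for sig, ss in want_sets.items():
                assert res.node_sets[sig] == ss

    def test_child_order_invariance(self):
        rng = np.random.default_rng(37)
        tree, tips, states = random_instance(rng, 7, 3)
        if not any(v != "?" for v in tips.values()):
            tips[next(iter(tips))] = "A"
        before = fitch(tree, tips, states=states)
        for node in tree.preorder_node_iter():
            node.set_child_nodes(list(reversed(node.child_nodes())))
        after = fitch(tree, tips, states=states)
        assert before.changes == after.changes
        assert before.node_sets == after.node_sets

    def test_duplicating_a_tip_never_adds_changes(self):
        rng = np.random.default_rng(41)
        for _ in range(5):
            tree, tips, states = random_instance(rng, 6, 3, missing=False)
            before = fitch(tree, tips, states=states).changes
            leaf = next(tree.leaf_node_iter())
            label = leaf.taxon.label
            import dendropy

            twin = dendropy.Node()
            twin.taxon = tree.taxon_namespace.new_taxon(label=label + "_twin")
            leaf.add_child(twin)
            sister = dendropy.Node()
            sister.taxon = leaf.taxon
            leaf.add_child(sister)
            leaf.taxon = None
            tips[label + " twin"] = tips[label]
            after = fitch(tree, tips, states=states).changes
            assert after == before


class TestSankoff:
    def test_unit_costs_reproduce_fitch(self):
        rng = np.random.default_rng(43)
        for _ in range(20):
            n = int(rng.integers(4, 8))
            k = int(rng.integers(2, 4))
            tree, tips, states = random_instance(rng, n, k)
            if not any(v != "?" for v in tips.values()):
                continue
            unit = np.ones((k, k)) - np.eye(k)
            f = fitch(tree, tips, states=states)
            s = sankoff(tree, tips, unit, states=states)
            assert f.changes == int(round(s.total_cost))
            assert f.node_sets == s.node_sets

    def test_matches_enumeration_with_general_costs(self):
        rng = np.random.default_rng(47)
        for _ in range(10):
            tree, tips, states = random_instance(rng, 5, 3)
            if not any(v != "?" for v in tips.values()):
                continue
            costs = rng.integers(1, 5, size=(3, 3)).astype(float)
            np.fill_diagonal(costs, 0.0)
            got = sankoff(tree, tips, costs, states=states)
            want_cost, want_sets = enumerate_parsimony(tree, tips, states, costs)
            assert got.total_cost == pytest.approx(want_cost)
            for sig, ss in want_sets.items():
                assert got.node_sets[sig] == ss

    def test_prohibitive_cost_steers_reconstruction(self):
        t = parse_newick("((A,B),(C,D));")
        tips = {"A": "A", "B": "A", "C": "B", "D": "B"}
        costs = np.array([[0.0, 1e9], [1.0, 0.0]])  # A->B essentially forbidden
        res = sankoff(t, tips, costs, states=("A", "B"))
        root_set = res.node_sets[node_signature(t.seed_node)]
        assert root_set == frozenset({"B"})  # B->A is cheap, A->B is not

    def test_all_missing_costs_nothing(self):
        t = parse_newick("(A,B);")
        res = sankoff(t, {"A": "?", "B": "?"}, UNIT3, states=STATES3)
        assert res.total_cost == 0.0

    def test_invalid_costs_rejected(self):
        t = parse_newick("(A,B);")
        with pytest.raises(ValueError):
            sankoff(t, {"A": "A", "B": "B"}, -UNIT3[:2, :2], states=("A", "B"))


class TestAgreement:
    def test_identical_reconstructions(self):
        t = assign_branch_lengths(parse_newick("((A,B),(C,D));"), "unit")
        tips = {x: "A" for x in "ABCD"}
        ml = marginal_ancestral_states(t, tips, MkModel(states=("A", "B"), rates=0.1))
        mp = fitch(t, tips, states=("A", "B"))
        report = compare_ml_parsimony(ml, mp)
        assert report.agreement == 1.0

    def test_disjoint_toy_case(self):
        t = assign_branch_lengths(parse_newick("((A,B),(C,D));"), "unit")
        tips = {"A": "A", "B": "A", "C": "A", "D": "A"}
        ml = marginal_ancestral_states(
            t, tips, MkModel(states=("A", "B"), rates=0.1)
        )
        # adversarial parsimony result claiming only state B everywhere
        mp = fitch(t, tips, states=("A", "B"))
        forced = {
            sig: frozenset({"B"}) if "|" in sig else ss
            for sig, ss in mp.node_sets.items()
        }
        mp.node_sets = forced
        assert compare_ml_parsimony(ml, mp).agreement == 0.0

    def test_mismatched_nodes_rejected(self):
        t1 = assign_branch_lengths(parse_newick("((A,B),(C,D));"), "unit")
        t2 = assign_branch_lengths(parse_newick("((A,C),(B,D));"), "unit")
        tips = {x: "A" for x in "ABCD"}
        ml = marginal_ancestral_states(t1, tips, MkModel(states=("A", "B"), rates=0.1))
        mp = fitch(t2, tips, states=("A", "B"))
        with pytest.raises(ValueError):
            compare_ml_parsimony(ml, mp)
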