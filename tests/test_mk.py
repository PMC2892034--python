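import numpy as np
import pytest
from scipy import linalg as sla

from cyprodent.mk import (
    MkModel,
    PruningEngine,
    fit_rates,
    likelihood_ratio_test,
    log_likelihood,
    marginal_ancestral_states,
    transition_probabilities,
)
from cyprodent.trees import assign_branch_lengths, node_signature, parse_newick

from ._oracles import enumerate_likelihood, er_closed_form, two_tip_er_likelihood
from .conftest import random_instance

STATES3 = ("A", "B", "C")


def er(q, states=STATES3):
    return MkModel(states=states, parameterization="ER", rates=q)


class TestModel:
    def test_rate_matrix_rows_sum_to_zero(self):
        m = MkModel(states=STATES3, parameterization="ARD", rates=(1, 2, 3, 4, 5, 6))
        Q = m.rate_matrix()
        assert np.allclose(Q.sum(axis=1), 0.0)
        assert Q[0, 1] == 1 and Q[2, 1] == 6

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            MkModel(states=("A",))
        with pytest.raises(ValueError):
            MkModel(states=STATES3, parameterization="ARD", rates=(1.0, 2.0))
        with pytest.raises(ValueError):
            MkModel(states=STATES3, rates=-0.1)
        with pytest.raises(ValueError):
            MkModel(states=STATES3, root_prior=(0.5, 0.6, 0.2))


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self):
        assert np.allclose(transition_probabilities(er(0.7), 0.0), np.eye(3))

    @pytest.mark.parametrize("k", [2, 3])
    def test_er_closed_form_matches_matrix_exponential(self, k):
        states = tuple("AB C".split()[0][:k]) if k == 2 else STATES3
        states = ("A", "B") if k == 2 else STATES3
        for q in (0.01, 0.3, 1.5):
            for t in (0.0, 0.1, 1.0, 7.0):
                closed = transition_probabilities(er(q, states), t)
                # independent routes: closed form vs expm of the same Q
                ard = MkModel(
                    states=states, parameterization="ARD", rates=(q,) * (k * (k - 1))
                )
                viaexp = sla.expm(ard.rate_matrix() * t)
                assert np.abs(closed - viaexp).max() < 1e-10
                assert np.abs(closed - er_closed_form(k, q, t)).max() < 1e-12
                assert np.allclose(closed.sum(axis=1), 1.0)

    def test_long_branch_reaches_uniform(self):
        P = transition_probabilities(er(1.0), 50.0)
        assert np.abs(P - 1.0 / 3).max() < 1e-9

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_probabilities(er(1.0), -0.5)


class TestLogLikelihood:
    def test_no_change_limit(self):
        t = assign_branch_lengths(parse_newick("(A,B);"), "unit")
        tips = {"A": "A", "B": "A"}
        lnl = log_likelihood(t, tips, er(1e-9, ("A", "B")))
        assert lnl == pytest.approx(np.log(0.5), abs=1e-6)

    def test_all_missing_gives_zero(self):
        t = assign_branch_lengths(parse_newick("((A,B),C);"), "unit")
        assert log_likelihood(t, {}, er(0.3)) == pytest.approx(0.0, abs=1e-12)

    def test_unassigned_lengths_rejected(self):
        t = parse_newick("((A,B),C);")
        with pytest.raises(ValueError, match="branch length"):
            log_likelihood(t, {"A": "A"}, er(0.3))

    def test_unknown_state_rejected(self):
        t = assign_branch_lengths(parse_newick("(A,B);"), "unit")
        with pytest.raises(ValueError, match="state"):
            log_likelihood(t, {"A": "Z"}, er(0.3))

    @pytest.mark.parametrize("param", ["ER", "ARD"])
    def test_pruning_matches_enumeration(self, param):
        rng = np.random.default_rng(42)
        for _ in range(15):
            n = int(rng.integers(4, 7))
            k = int(rng.integers(2, 4))
            tree, tips, states = random_instance(rng, n, k)
            if param == "ER":
                model = er(float(rng.uniform(0.05, 1.5)), states)
            else:
                model = MkModel(
                    states=states,
                    parameterization="ARD",
                    rates=tuple(rng.uniform(0.05, 1.5, size=k * (k - 1))),
                )
            want, _ = enumerate_likelihood(
                tree,
                tips,
                lambda t, m=model: transition_probabilities(m, t),
                model.pi,
                states,
            )
            got = log_likelihood(tree, tips, model)
            assert got == pytest.approx(np.log(want), abs=1e-10)

    def test_polytomy_supported(self):
        tree = assign_branch_lengths(parse_newick("(A,B,C,D);"), "unit")
        tips = {"A": "A", "B": "A", "C": "B", "D": "?"}
        model = er(0.4)
        want, _ = enumerate_likelihood(
            tree, tips, lambda t: transition_probabilities(model, t), model.pi, STATES3
        )
        assert log_likelihood(tree, tips, model) == pytest.approx(np.log(want), abs=1e-10)

    def test_invariance_to_child_order_and_relabeling(self):
        rng = np.random.default_rng(3)
        tree, tips, states = random_instance(rng, 6, 3)
        model = er(0.5, states)
        base = log_likelihood(tree, tips, model)
        # reverse children everywhere
        for node in tree.preorder_node_iter():
            node.set_child_nodes(list(reversed(node.child_nodes())))
        assert log_likelihood(tree, tips, model) == pytest.approx(base, abs=1e-12)
        # relabel taxa consistently
        mapping = {lbl: f"sp{i}" for i, lbl in enumerate(sorted(tips))}
        for lf in tree.leaf_node_iter():
            lf.taxon.label = mapping[lf.taxon.label]
        new_tips = {mapping[lbl]: s for lbl, s in tips.items()}
        assert log_likelihood(tree, new_tips, model) == pytest.approx(base, abs=1e-12)


class TestMarginals:
    def test_two_tip_symmetry(self):
        t = assign_branch_lengths(parse_newick("(A,B);"), "unit")
        res = marginal_ancestral_states(t, {"A": "A", "B": "B"}, er(0.5, ("A", "B")))
        root = res.node_marginals[node_signature(t.seed_node)]
        assert np.allclose(root, [0.5, 0.5], atol=1e-12)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            n = int(rng.integers(4, 7))
            k = int(rng.integers(2, 4))
            tree, tips, states = random_instance(rng, n, k)
            model = er(float(rng.uniform(0.05, 1.5)), states)
            _, want = enumerate_likelihood(
                tree, tips, lambda t: transition_probabilities(model, t), model.pi, states
            )
            res = marginal_ancestral_states(tree, tips, model)
            for sig, vec in want.items():
                assert np.abs(res.node_marginals[sig] - vec).max() < 1e-10

    def test_vectors_sum_to_one(self):
        rng = np.random.default_rng(5)
        tree, tips, states = random_instance(rng, 8, 3)
        res = marginal_ancestral_states(tree, tips, er(0.7, states))
        for vec in res.node_marginals.values():
            assert abs(vec.sum() - 1.0) < 1e-9

    def test_all_missing_returns_prior(self):
        t = assign_branch_lengths(parse_newick("((A,B),(C,D));"), "unit")
        res = marginal_ancestral_states(t, {}, er(0.4))
        for sig, vec in res.node_marginals.items():
            if "|" in sig:
                assert np.allclose(vec, 1.0 / 3, atol=1e-12)


class TestFitRates:
    def test_two_tip_matches_grid_search(self):
        # two conflicting tips: the ER likelihood is monotone in q, so the
        # meaningful check is that the fit attains the grid-search optimum
        t = parse_newick("(A:0.7,B:1.3);")
        res = fit_rates(t, {"A": "A", "B": "B"}, "ER", states=("A", "B"))
        grid = np.exp(np.linspace(np.log(1e-6), np.log(1e3), 40001))
        best_grid = max(two_tip_er_likelihood(2, q, 0.7, 1.3, 0, 1) for q in grid)
        fitted = two_tip_er_likelihood(2, float(res.model.rates), 0.7, 1.3, 0, 1)
        assert np.log(fitted) >= np.log(best_grid) - 1e-8
        assert res.log_likelihood == pytest.approx(np.log(fitted), abs=1e-9)

    def test_interior_optimum_matches_grid_search(self):
        # mixed 4-tip pattern with an interior ML optimum: argmax well defined
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        tips = {"A": "A", "B": "A", "C": "B", "D": "B"}
        res = fit_rates(tree, tips, "ER", states=("A", "B"))

        def grid_lik(q):
            model = er(q, ("A", "B"))
            lik, _ = enumerate_likelihood(
                tree, tips, lambda t: transition_probabilities(model, t),
                model.pi, ("A", "B"),
            )
            return lik

        grid = np.exp(np.linspace(np.log(1e-4), np.log(50), 3001))
        vals = [grid_lik(q) for q in grid]
        q_grid = grid[int(np.argmax(vals))]
        assert 1e-3 < q_grid < 1e2  # interior, not a bound
        assert float(res.model.rates) == pytest.approx(q_grid, rel=5e-3)

    def test_ard_never_worse_than_er(self):
        rng = np.random.default_rng(19)
        for _ in range(3):
            tree, tips, states = random_instance(rng, 10, 3)
            if len({v for v in tips.values() if v != "?"}) < 3:
                continue
            er_fit = fit_rates(tree, tips, "ER", states=states, seed=1)
            ard_fit = fit_rates(tree, tips, "ARD", states=states, seed=1)
            assert ard_fit.log_likelihood >= er_fit.log_likelihood - 1e-6

    def test_identical_tips_hit_lower_bound(self):
        t = assign_branch_lengths(parse_newick("((A,B),C);"), "unit")
        with pytest.warns(RuntimeWarning):
            res = fit_rates(t, {"A": "A", "B": "A", "C": "A"}, "ER", states=("A", "B"))
        assert res.at_bound
        assert float(res.model.rates) < 1e-6

    def test_too_few_scored_tips_rejected(self):
        t = assign_branch_lengths(parse_newick("(A,B);"), "unit")
        with pytest.raises(ValueError):
            fit_rates(t, {"A": "A"}, "ER", states=("A", "B"))


class TestLRT:
    def test_identical_likelihoods(self):
        t = assign_branch_lengths(parse_newick("((A,B),C);"), "unit")
        tips = {"A": "A", "B": "B", "C": "C"}
        er_fit = fit_rates(t, tips, "ER", states=STATES3)
        lrt = likelihood_ratio_test(er_fit, er_fit)
        assert lrt.statistic == 0.0
        assert lrt.pvalue == 1.0
        assert lrt.df == 5  # k=3: 6 ARD factors - 1 ER factor

    def test_mismatched_state_spaces_rejected(self):
        t = assign_branch_lengths(parse_newick("((A,B),C);"), "unit")
        f1 = fit_rates(t, {"A": "A", "B": "B"}, "ER", states=("A", "B"))
        f2 = fit_rates(t, {"A": "A", "B": "B", "C": "C"}, "ER", states=STATES3)
        with pytest.raises(ValueError):
            likelihood_ratio_test(f1, f2)


class TestEngineBatch:
    def test_batched_ard_equals_scalar_path(self):
        rng = np.random.default_rng(23)
        tree, tips, states = random_instance(rng, 12, 3)
        eng = PruningEngine(tree, tips, states)
        R = rng.uniform(0.05, 2.0, size=(6, 6))
        batch = eng._ard_loglik_batch(R, np.full(3, 1 / 3))
        for row, want in zip(R, batch):
            model = MkModel(states=states, parameterization="ARD", rates=tuple(row))
            assert eng.log_likelihood(model) == pytest.approx(want, abs=1e-11)
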