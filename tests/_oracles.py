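"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's pruning/DP code paths: likelihoods
and marginals come from explicit summation over every ancestral state
assignment, parsimony scores from explicit minimisation, and the ER
transition matrix from its closed form.
"""
from __future__ import annotations

import itertools

import numpy as np

from cyprodent.formulae import MISSING
from cyprodent.trees import node_signature


def er_closed_form(k: int, q: float, t: float) -> np.ndarray:
    e = np.exp(-k * q * t)
    P = np.full((k, k), (1.0 - e) / k)
    np.fill_diagonal(P, 1.0 / k + (k - 1.0) / k * e)
    return P


def _edges_and_free_nodes(tree, tips, states):
    """Edge list plus the nodes whose states must be summed over."""
    state_idx = {s: i for i, s in enumerate(states)}
    nodes = list(tree.postorder_node_iter())
    fixed = {}
    free = []
    for n in nodes:
        if n.is_leaf():
            s = tips.get(n.taxon.label.replace("_", " "), MISSING)
            if s == MISSING:
                free.append(n)
            else:
                fixed[id(n)] = state_idx[s]
        else:
            free.append(n)
    edges = [(n.parent_node, n, n.edge.length) for n in nodes if n.parent_node is not None]
    return edges, free, fixed


def enumerate_likelihood(tree, tips, P_of, pi, states):
    """Total likelihood and per-node marginals by exhaustive enumeration.

    ``P_of(t)`` supplies the transition matrix for a branch of length t.
    Returns (likelihood, {node_signature: probability vector}) where the
    marginals cover internal nodes and the root.
    """
    k = len(states)
    edges, free, fixed = _edges_and_free_nodes(tree, tips, states)
    P = {id(child): P_of(t) for _, child, t in edges}
    root = tree.seed_node
    internal = [n for n in free if not n.is_leaf()]
    total = 0.0
    marg = {id(n): np.zeros(k) for n in internal}
    for assign in itertools.product(range(k), repeat=len(free)):
        state = dict(fixed)
        for n, s in zip(free, assign):
            state[id(n)] = s
        prob = pi[state[id(root)]]
        for parent, child, _ in edges:
            prob *= P[id(child)][state[id(parent)], state[id(child)]]
        total += prob
        for n in internal:
            marg[id(n)][state[id(n)]] += prob
    marginals = {
        node_signature(n): marg[id(n)] / total if total > 0 else marg[id(n)]
        for n in internal
    }
    return total, marginals


def enumerate_parsimony(tree, tips, states, costs=None):
    """Minimum change cost and per-node optimal state sets by enumeration."""
    k = len(states)
    if costs is None:
        costs = np.ones((k, k)) - np.eye(k)
    edges, free, fixed = _edges_and_free_nodes(tree, tips, states)
    internal = [n for n in free if not n.is_leaf()]
    best = np.inf
    per_node_best = {id(n): np.full(k, np.inf) for n in internal}
    for assign in itertools.product(range(k), repeat=len(free)):
        state = dict(fixed)
        for n, s in zip(free, assign):
            state[id(n)] = s
        cost = sum(costs[state[id(p)], state[id(c)]] for p, c, _ in edges)
        best = min(best, cost)
        for n in internal:
            s = state[id(n)]
            per_node_best[id(n)][s] = min(per_node_best[id(n)][s], cost)
    node_sets = {
        node_signature(n): frozenset(
            states[s] for s in range(k) if per_node_best[id(n)][s] <= best + 1e-9
        )
        for n in internal
    }
    return best, node_sets


def two_tip_er_likelihood(k: int, q: float, t1: float, t2: float, s1: int, s2: int) -> float:
    """Closed-form likelihood of a two-tip tree under ER with uniform prior."""
    P1, P2 = er_closed_form(k, q, t1), er_closed_form(k, q, t2)
    return float(np.sum((1.0 / k) * P1[:, s1] * P2[:, s2]))
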