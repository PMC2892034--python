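"""Parsimony ancestral-state reconstruction: Fitch/Hartigan and Sankoff.

Fitch counting is generalised to multifurcating rooted trees following
Hartigan's rule: a node's preliminary state set is the set of states that
occur in the largest number of its children's sets, and each child beyond
that majority contributes one state change.  With unit costs this yields the
same minimum change count as Sankoff's dynamic programme, which is also
implemented (for arbitrary non-negative cost matrices) and serves as the
cross-check.  Per-node sets of most-parsimonious states come from an
upward refinement pass that combines each node's subtree costs with the
cost of the rest of the tree, so a state is reported exactly when some
globally optimal assignment uses it at that node.

Missing tips contribute the full state space (they never force a change).
"""
from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .formulae import MISSING
from .mk import ReconstructionResult
from .trees import node_signature

__all__ = ["ParsimonyResult", "AgreementReport", "fitch", "sankoff", "compare_ml_parsimony"]

_INF = np.inf


@dataclass
class ParsimonyResult:
    """Minimum change count/cost and per-node most-parsimonious state sets."""

    states: tuple[str, ...]
    total_cost: float
    node_sets: dict[str, frozenset[str]]
    cost_matrix: np.ndarray

    @property
    def changes(self) -> int:
        return int(round(self.total_cost))


@dataclass
class AgreementReport:
    """Per-node agreement between an ML argmax and the MP state sets."""

    per_node: dict[str, bool]
    agreement: float


def _flatten(
    tree: dendropy.Tree, tips: dict[str, str], states: tuple[str, ...]
) -> tuple[list[list[int]], list[int | None], list[str], np.ndarray]:
    """Postorder children lists, tip state indices (None = unscored), signatures."""
    state_index = {s: i for i, s in enumerate(states)}
    nodes = list(tree.postorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    children = []
    tip_state: list[int | None] = []
    signatures = []
    is_leaf = np.zeros(len(nodes), dtype=bool)
    for i, node in enumerate(nodes):
        children.append([index[id(c)] for c in node.child_nodes()])
        signatures.append(node_signature(node))
        if node.is_leaf():
            is_leaf[i] = True
            label = node.taxon.label.replace("_", " ")
            s = tips.get(label, MISSING)
            if s == MISSING:
                tip_state.append(None)
            else:
                if s not in state_index:
                    raise ValueError(f"tip {label!r} has state {s!r} not in {states}")
                tip_state.append(state_index[s])
        else:
            tip_state.append(None)
    return children, tip_state, signatures, is_leaf


def _subtree_costs(
    children: list[list[int]],
    tip_state: list[int | None],
    is_leaf: np.ndarray,
    k: int,
    cost: np.ndarray,
) -> np.ndarray:
    """Sankoff downward pass: g[v, s] = min cost of v's subtree given v = s."""
    n = len(children)
    g = np.zeros((n, k))
    for v in range(n):
        if is_leaf[v]:
            if tip_state[v] is not None:
                g[v] = _INF
                g[v, tip_state[v]] = 0.0
            continue
        acc = np.zeros(k)
        for c in children[v]:
            acc += (cost + g[c][None, :]).min(axis=1)
        g[v] = acc
    return g


def _mp_state_sets(
    children: list[list[int]],
    g: np.ndarray,
    cost: np.ndarray,
    states: tuple[str, ...],
    signatures: list[str],
) -> tuple[dict[str, frozenset[str]], float]:
    """Upward pass: per-node sets of states used by some optimal assignment."""
    n, k = g.shape
    root = n - 1  # postorder: root last
    d = np.zeros((n, k))
    total = float(g[root].min())
    node_sets: dict[str, frozenset[str]] = {}
    tol = 1e-9 * max(1.0, abs(total))
    for v in range(n - 1, -1, -1):
        h = d[v] + g[v]
        best = h.min()
        node_sets[signatures[v]] = frozenset(
            states[s] for s in range(k) if h[s] <= best + tol
        )
        if not children[v]:
            continue
        contribs = [(cost + g[c][None, :]).min(axis=1) for c in children[v]]
        acc = d[v] + np.sum(contribs, axis=0)
        for pos, c in enumerate(children[v]):
            rest = acc - contribs[pos]  # cost of everything outside c, per parent state
            d[c] = (rest[:, None] + cost).min(axis=0)
    return node_sets, total


def sankoff(
    tree: dendropy.Tree,
    tips: dict[str, str],
    costs: np.ndarray,
    states: tuple[str, ...] | None = None,
) -> ParsimonyResult:
    """Minimum-cost ancestral reconstruction under an arbitrary step matrix.

    ``costs[i, j]`` is the cost of a change from state i to state j along an
    edge; the diagonal must be zero and all entries non-negative.
    """
    if states is None:
        states = tuple(sorted({v for v in tips.values() if v != MISSING}))
    costs = np.asarray(costs, dtype=float)
    k = len(states)
    if costs.shape != (k, k):
        raise ValueError(f"cost matrix must be {k}x{k} for {k} states")
    if np.any(costs < 0):
        raise ValueError("costs must be non-negative")
    if np.any(np.diag(costs) != 0):
        raise ValueError("cost matrix diagonal must be zero")
    children, tip_state, signatures, is_leaf = _flatten(tree, tips, states)
    if all(s is None for s in tip_state):
        if not any(v != MISSING for v in tips.values()):
            # no scored tips: zero cost, every node may take any state
            return ParsimonyResult(
                states=states,
                total_cost=0.0,
                node_sets={sig: frozenset(states) for sig in signatures},
                cost_matrix=costs,
            )
    g = _subtree_costs(children, tip_state, is_leaf, k, costs)
    node_sets, total = _mp_state_sets(children, g, costs, states, signatures)
    return ParsimonyResult(
        states=states, total_cost=total, node_sets=node_sets, cost_matrix=costs
    )


def fitch(
    tree: dendropy.Tree,
    tips: dict[str, str],
    states: tuple[str, ...] | None = None,
) -> ParsimonyResult:
    """Unordered unit-cost parsimony on a rooted tree (Fitch/Hartigan).

    The change count comes from Hartigan's majority rule over each node's
    children (which handles polytomies exactly); the per-node sets of
    most-parsimonious states come from the unit-cost upward refinement.
    Raises if no tip is scored.
    """
    if states is None:
        states = tuple(sorted({v for v in tips.values() if v != MISSING}))
    if not states or not any(v != MISSING for v in tips.values()):
        raise ValueError("fitch needs at least one scored tip")
    k = len(states)
    children, tip_state, signatures, is_leaf = _flatten(tree, tips, states)

    # Hartigan down-pass: majority state sets and change count
    n = len(children)
    sets = np.zeros((n, k), dtype=bool)
    changes = 0
    for v in range(n):
        if is_leaf[v]:
            if tip_state[v] is None:
                sets[v] = True
            else:
                sets[v, tip_state[v]] = True
            continue
        counts = np.sum([sets[c] for c in children[v]], axis=0)
        top = counts.max()
        sets[v] = counts == top
        changes += len(children[v]) - int(top)

    unit = np.ones((k, k)) - np.eye(k)
    g = _subtree_costs(children, tip_state, is_leaf, k, unit)
    node_sets, total = _mp_state_sets(children, g, unit, states, signatures)
    if int(round(total)) != changes:  # both routes are exact; disagreement is a bug
        raise AssertionError(
            f"Hartigan count {changes} != unit-cost DP count {total}"
        )
    return ParsimonyResult(
        states=states, total_cost=float(changes), node_sets=node_sets, cost_matrix=unit
    )


def compare_ml_parsimony(
    ml: ReconstructionResult, mp: ParsimonyResult
) -> AgreementReport:
    """Fraction of internal nodes whose ML argmax state is most parsimonious.

    Both reconstructions must cover the same tree: nodes are matched by
    their sorted-tip-set signatures, and only internal nodes (signatures
    spanning more than one tip) are compared.
    """
    if ml.node_marginals is None:
        raise ValueError("ML result carries no node marginals")
    ml_internal = {sig for sig in ml.node_marginals if "|" in sig}
    mp_internal = {sig for sig in mp.node_sets if "|" in sig}
    if ml_internal != mp_internal:
        raise ValueError(
            "ML and parsimony reconstructions cover different node sets"
        )
    per_node = {
        sig: ml.argmax_state(sig) in mp.node_sets[sig] for sig in sorted(ml_internal)
    }
    agreement = sum(per_node.values()) / len(per_node) if per_node else 1.0
    return AgreementReport(
        per_node=per_node,
        agreement=agreement,
    )
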