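"""Momentary-Information Weighted Transitive Reduction (MIWTR).

An edge of the unrolled lagged-node graph is *redundant* when some indirect
directed path between its endpoints has a bottleneck (minimum edge weight)
strictly larger than the edge's own weight: the indirect channel can carry
everything the direct one does.  Removing such edges, with momentary
information transfer as the weight, and then dropping distant-history nodes
that no longer feed the immediate history directly, shrinks the conditioning
set W without (by assumption) materially changing the measured information.

Edges are tested in ascending weight order against the current, partially
reduced graph, so an already-removed weak edge can never justify keeping or
removing another; one pass is a fixpoint.  Ties (bottleneck equal to the edge
weight) are kept — the rule uses a strict inequality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Set, Tuple

from .estimators import EstimatorConfig, mit_edge_weight
from .tsdag import (
    BundleSpec,
    ConditionSets,
    EdgeTemplate,
    LaggedNode,
    TimeSeriesDAG,
    condition_sets,
)

__all__ = ["WeightedUnrolledGraph", "weighted_transitive_reduction", "reduce_condition_set"]

logger = logging.getLogger(__name__)

Edge = Tuple[LaggedNode, LaggedNode]


@dataclass(frozen=True)
class WeightedUnrolledGraph:
    """Acyclic graph over lagged nodes with non-negative edge weights (nats)."""

    nodes: FrozenSet[LaggedNode]
    weight: Dict[Edge, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (u, v), w in self.weight.items():
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u}, {v}) has endpoint outside node set")
            if w < 0:
                raise ValueError("edge weights must be >= 0")
        if self._has_cycle():
            raise ValueError("graph must be acyclic")

    @property
    def edges(self) -> Set[Edge]:
        return set(self.weight)

    def _has_cycle(self) -> bool:
        succ: Dict[LaggedNode, list] = {}
        for u, v in self.weight:
            succ.setdefault(u, []).append(v)
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {n: WHITE for n in self.nodes}
        for start in self.nodes:
            if color[start] != WHITE:
                continue
            stack = [(start, iter(succ.get(start, ())))]
            color[start] = GRAY
            while stack:
                node, it = stack[-1]
                advanced = False
                for nxt in it:
                    if color[nxt] == GRAY:
                        return True
                    if color[nxt] == WHITE:
                        color[nxt] = GRAY
                        stack.append((nxt, iter(succ.get(nxt, ()))))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()
        return False


def _reachable_over(
    succ: Dict[LaggedNode, list], start: LaggedNode, goal: LaggedNode
) -> bool:
    """Depth-first reachability start -> goal over the given successor map."""
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in succ.get(u, ()):
            if v == goal:
                return True
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


def weighted_transitive_reduction(g: WeightedUnrolledGraph) -> WeightedUnrolledGraph:
    """Drop every edge dominated by a strictly stronger indirect path.

    Edge (u, v, w) is removed when, in the current graph without (u, v), v is
    reachable from u using only edges of weight strictly greater than w — that
    path's bottleneck then exceeds w.  Candidates are processed in ascending
    weight order (ties broken by node labels for determinism).
    """
    current = dict(g.weight)
    # ascending weight; deterministic label order within ties
    schedule = sorted(current, key=lambda e: (current[e], e))
    for edge in schedule:
        if edge not in current:
            continue
        u, v = edge
        w = current[edge]
        succ: Dict[LaggedNode, list] = {}
        for (a, b), wt in current.items():
            if (a, b) != edge and wt > w:
                succ.setdefault(a, []).append(b)
        if _reachable_over(succ, u, v):
            del current[edge]
            logger.debug("MIWTR removed edge %s -> %s (weight %.4g)", u, v, w)
    return WeightedUnrolledGraph(nodes=g.nodes, weight=current)


def _unrolled_subgraph(
    dag: TimeSeriesDAG,
    nodes: Set[LaggedNode],
    template_weight: Dict[EdgeTemplate, float],
) -> WeightedUnrolledGraph:
    """Induced unrolled graph on ``nodes`` with stationary per-template weights."""
    weight: Dict[Edge, float] = {}
    node_set = frozenset(nodes)
    for e in dag.edges:
        for v in node_set:
            if v.variable != e.target:
                continue
            u = LaggedNode(e.source, v.lag + e.lag_gap)
            if u in node_set:
                weight[(u, v)] = max(template_weight[e], 0.0)
    return WeightedUnrolledGraph(nodes=node_set, weight=weight)


def reduce_condition_set(
    dag: TimeSeriesDAG,
    spec: BundleSpec,
    tau_c: int,
    data,
    cfg: EstimatorConfig,
    order: int = 0,
) -> ConditionSets:
    """Shrink W by MIWTR on the unrolled subgraph over W ∪ immediate history.

    Every template edge appearing in the subgraph is weighted once by its
    momentary information transfer (clamped at 0), the weighted transitive
    reduction is applied, and W keeps only the nodes retaining at least one
    direct edge into an immediate-history node.  V and F are unchanged.
    """
    sets = condition_sets(dag, spec, tau_c, order)
    from .tsdag import bundled_history_nodes

    immediate, _ = bundled_history_nodes(spec, tau_c, tau_c + max(dag.max_lag, 1))
    sub_nodes = set(sets.W) | immediate

    needed_templates = {
        e
        for e in dag.edges
        for v in sub_nodes
        if v.variable == e.target and LaggedNode(e.source, v.lag + e.lag_gap) in sub_nodes
    }
    template_weight = {
        e: mit_edge_weight(dag, e, data, cfg) for e in sorted(needed_templates)
    }
    g = _unrolled_subgraph(dag, sub_nodes, template_weight)
    reduced = weighted_transitive_reduction(g)

    removed = g.edges - reduced.edges
    for u, v in sorted(removed):
        logger.info("MIWTR: removed redundant edge %s -> %s", u, v)

    kept_W = frozenset(
        w for w in sets.W if any((w, v) in reduced.weight for v in immediate)
    )
    dropped = sets.W - kept_W
    if dropped:
        logger.info(
            "MIWTR: |W| %d -> %d (dropped %s)",
            len(sets.W), len(kept_W), sorted(dropped),
        )
    return ConditionSets(V=sets.V, W=kept_W, F=sets.F, tau_c=tau_c, order=order)
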