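"""Time-series DAG model and finite conditioning sets.

A stationary multivariate stochastic process with lagged causal links is
represented by a *template* graph: one node per variable, one edge template
per (source, target, lag) triple, repeated at every reference time.  Unrolling
the templates over a time window yields a directed acyclic graph over lagged
variable copies; acyclicity is guaranteed because every lag gap is >= 1 (no
contemporaneous edges).

The graphical Markov property (a node is independent of its non-descendants
given its parents) lets the infinite causal history of a target variable be
replaced by three finite lagged-node sets relative to the reference time t:

* ``V``  — parents of the target inside the *immediate* bundled history
  (bundle variables at lags 1..tau_c),
* ``W``  — parents of the immediate bundled history that lie in the *distant*
  bundled history (bundle variables at lags > tau_c),
* ``F``  — the approximation of the conditioning set: empty at Order-0, the
  target's non-bundle parents at Order-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import FrozenSet, Iterable, NamedTuple, Sequence, Set, Tuple


class GraphError(ValueError):
    """Invalid graph structure or unknown variable."""


class LaggedNode(NamedTuple):
    """A variable copy ``lag`` steps before the reference time (lag 0 = present)."""

    variable: str
    lag: int


class EdgeTemplate(NamedTuple):
    """Stationary edge: ``source`` influences ``target`` ``lag_gap`` steps later."""

    source: str
    target: str
    lag_gap: int


@dataclass(frozen=True)
class TimeSeriesDAG:
    """Stationary lagged-edge causal graph over a fixed variable set."""

    variables: Tuple[str, ...]
    edges: FrozenSet[EdgeTemplate]

    def __post_init__(self) -> None:
        if len(set(self.variables)) != len(self.variables):
            raise GraphError("duplicate variable names")
        vset = set(self.variables)
        for e in self.edges:
            if e.source not in vset or e.target not in vset:
                raise GraphError(f"edge {e} refers to unknown variable")
            if e.lag_gap < 1:
                raise GraphError(
                    f"edge {e}: lag_gap must be >= 1 (no contemporaneous edges)"
                )

    @property
    def max_lag(self) -> int:
        return max((e.lag_gap for e in self.edges), default=0)

    @classmethod
    def from_edges(
        cls, variables: Sequence[str], edges: Iterable[Tuple[str, str, int]]
    ) -> "TimeSeriesDAG":
        return cls(tuple(variables), frozenset(EdgeTemplate(*e) for e in edges))


@dataclass(frozen=True)
class BundleSpec:
    """Target variable and the two disjoint variable bundles."""

    target: str
    bundle_m: FrozenSet[str]
    bundle_n: FrozenSet[str]

    def __init__(self, target: str, bundle_m: Iterable[str], bundle_n: Iterable[str]):
        object.__setattr__(self, "target", target)
        object.__setattr__(self, "bundle_m", frozenset(bundle_m))
        object.__setattr__(self, "bundle_n", frozenset(bundle_n))
        if not self.bundle_m or not self.bundle_n:
            raise ValueError("both bundles must be nonempty")
        if self.bundle_m & self.bundle_n:
            raise ValueError("bundles must be disjoint")

    @property
    def bundled(self) -> FrozenSet[str]:
        return self.bundle_m | self.bundle_n

    def validate_against(self, dag: TimeSeriesDAG) -> None:
        vset = set(dag.variables)
        missing = ({self.target} | self.bundled) - vset
        if missing:
            raise GraphError(f"variables not in graph: {sorted(missing)}")


@dataclass(frozen=True)
class ConditionSets:
    """The finite node sets V, W, F of the Markov-reduced information measures."""

    V: FrozenSet[LaggedNode]
    W: FrozenSet[LaggedNode]
    F: FrozenSet[LaggedNode]
    tau_c: int
    order: int

    def __post_init__(self) -> None:
        if self.order not in (0, 1):
            raise ValueError("order must be 0 or 1")
        if self.order == 0 and self.F:
            raise ValueError("Order-0 requires empty F")
        if self.V & self.W:
            raise ValueError("V and W must be disjoint")


def parents(dag: TimeSeriesDAG, node: LaggedNode) -> Set[LaggedNode]:
    """Parent set of a lagged node under the stationary edge templates.

    Parents of ``(v, tau)`` are ``(source, tau + lag_gap)`` for every template
    targeting ``v``; all parent lags strictly exceed the node's own lag.
    """
    if node.variable not in dag.variables:
        raise GraphError(f"unknown variable {node.variable!r}")
    return {
        LaggedNode(e.source, node.lag + e.lag_gap)
        for e in dag.edges
        if e.target == node.variable
    }


def bundled_history_nodes(
    spec: BundleSpec, tau_c: int, horizon: int
) -> Tuple[Set[LaggedNode], Set[LaggedNode]]:
    """Partition the bundled causal history at lag ``tau_c``.

    Returns ``(immediate, distant)``: bundle-variable nodes at lags 1..tau_c
    and tau_c+1..horizon respectively.  ``horizon`` is the finite truncation
    used when an explicit window is needed.
    """
    if not 1 <= tau_c < horizon:
        raise ValueError(f"need 1 <= tau_c < horizon, got {tau_c}, {horizon}")
    immediate = {
        LaggedNode(v, lag) for v in spec.bundled for lag in range(1, tau_c + 1)
    }
    distant = {
        LaggedNode(v, lag) for v in spec.bundled for lag in range(tau_c + 1, horizon + 1)
    }
    return immediate, distant


def condition_sets(
    dag: TimeSeriesDAG, spec: BundleSpec, tau_c: int, order: int
) -> ConditionSets:
    """Derive the finite sets V, W, F for one partition lag.

    ``V`` collects the target's parents lying in the immediate bundled history;
    ``W`` collects parents of immediate-history nodes lying in the distant
    bundled history; ``F`` is empty (Order-0) or the target's parents outside
    both bundles (Order-1).
    """
    if tau_c < 1:
        raise ValueError("tau_c must be >= 1")
    spec.validate_against(dag)
    bundled = spec.bundled
    target_parents = parents(dag, LaggedNode(spec.target, 0))

    V = frozenset(
        p for p in target_parents if p.variable in bundled and p.lag <= tau_c
    )
    immediate, _ = bundled_history_nodes(spec, tau_c, tau_c + max(dag.max_lag, 1))
    W = frozenset(
        p
        for u in immediate
        for p in parents(dag, u)
        if p.variable in bundled and p.lag > tau_c
    )
    if order == 0:
        F: FrozenSet[LaggedNode] = frozenset()
    elif order == 1:
        F = frozenset(p for p in target_parents if p.variable not in bundled)
    else:
        raise ValueError("order must be 0 or 1")
    return ConditionSets(V=V, W=W, F=F, tau_c=tau_c, order=order)


def unroll(
    dag: TimeSeriesDAG, window: int
) -> Tuple[Set[LaggedNode], Set[Tuple[LaggedNode, LaggedNode]]]:
    """Materialize the lagged-copy graph over lags 0..window.

    Edges run from the higher-lag (earlier) copy to the lower-lag (later) one.
    """
    nodes = {LaggedNode(v, lag) for v in dag.variables for lag in range(window + 1)}
    edges = {
        (LaggedNode(e.source, lag + e.lag_gap), LaggedNode(e.target, lag))
        for e in dag.edges
        for lag in range(window + 1)
        if lag + e.lag_gap <= window
    }
    return nodes, edges


def load_graph(path: str | Path, variables: Sequence[str] | None = None) -> TimeSeriesDAG:
    """Read an edge-list file: header line, then ``source,target,lag`` rows.

    Lines starting with ``#`` are comments.  When ``variables`` is given
    (typically the series header) edge endpoints are validated against it and
    the returned graph uses that variable ordering; otherwise the variable set
    is inferred from the edges.
    """
    path = Path(path)
    edges = []
    seen_vars: list[str] = []
    with path.open() as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise GraphError(f"empty graph file {path}")
    for ln in lines[1:]:  # first non-comment line is the header
        parts = [p.strip() for p in ln.split(",")]
        if len(parts) != 3:
            raise GraphError(f"malformed edge line {ln!r}")
        src, tgt, lag_s = parts
        try:
            lag = int(lag_s)
        except ValueError as exc:
            raise GraphError(f"non-integer lag in {ln!r}") from exc
        if lag < 1:
            raise GraphError(f"lag must be a positive integer in {ln!r}")
        edges.append((src, tgt, lag))
        for v in (src, tgt):
            if v not in seen_vars:
                seen_vars.append(v)
    if variables is not None:
        unknown = set(seen_vars) - set(variables)
        if unknown:
            raise GraphError(f"graph variables not in series header: {sorted(unknown)}")
        var_order: Sequence[str] = variables
    else:
        var_order = seen_vars
    return TimeSeriesDAG.from_edges(var_order, edges)


def write_graph(
    dag: TimeSeriesDAG, path: str | Path, weights: dict[EdgeTemplate, float] | None = None
) -> None:
    """Write the edge list, optionally with a weight column (nats)."""
    path = Path(path)
    with path.open("w") as fh:
        if weights is None:
            fh.write("source,target,lag\n")
            for e in sorted(dag.edges):
                fh.write(f"{e.source},{e.target},{e.lag_gap}\n")
        else:
            fh.write("source,target,lag,weight\n")
            for e in sorted(dag.edges):
                fh.write(f"{e.source},{e.target},{e.lag_gap},{weights.get(e, float('nan')):.6g}\n")
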