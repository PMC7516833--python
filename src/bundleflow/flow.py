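"""Bundled causal-history information measures and the tau_c sweep.

For a target variable and two disjoint variable bundles, three conditional
mutual informations summarize how the bundles' evolutionary histories shape
the target's present state:

* ``T = I(target; V | F)``       — the whole bundled history,
* ``J = I(target; V | F, W)``    — the immediate history (lags <= tau_c),
* ``D = I(target; W | F)``       — the distant history (lags > tau_c),

with V, W, F the Markov-reduced node sets of :mod:`bundleflow.tsdag`.  The
chain rule gives T = J + D; the identity is exact for the model distribution
whenever the conditioning captures every parent of the target (Order-1 with
tau_c at least the graph's maximum lag) and holds within estimator noise
otherwise.  J and D are each decomposed into redundant / synergistic / unique
parts with the bundle-m and bundle-n node subsets of V (resp. W) as the two
sources; the components of T are the component-wise sums.

All measures for one tau_c are estimated on a single common gap-free embedded
sample so the additivity diagnostic compares like with like.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .estimators import EstimatorConfig, knn_cmi
from .pid import PIDResult, pid_decompose
from .tsdag import BundleSpec, ConditionSets, LaggedNode, TimeSeriesDAG, condition_sets

__all__ = [
    "SeriesMatrix",
    "DataError",
    "embed",
    "estimate_tjd",
    "InfoDecomposition",
    "bundle_information",
    "sweep",
    "results_table",
]

logger = logging.getLogger(__name__)


class DataError(ValueError):
    """Series too short, all-gap, or otherwise unusable."""


@dataclass
class SeriesMatrix:
    """An n_time x n_var real matrix with NaN gap markers and variable names."""

    values: np.ndarray
    names: Tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (time x variables)")
        if self.values.shape[1] != len(self.names):
            raise ValueError("column count does not match names")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate variable names")
        self.names = tuple(self.names)

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


def embed(
    data: SeriesMatrix, nodes: Iterable[LaggedNode]
) -> Tuple[np.ndarray, List[LaggedNode]]:
    """Lag-embed the series on the requested nodes.

    One row per admissible reference time t (cell value = series[t - lag]);
    any row touching a gap in any requested cell is dropped.  Columns are
    ordered by (variable, lag) for determinism.  Returns the matrix and the
    column node order.
    """
    node_list = sorted(set(nodes))
    if not node_list:
        raise ValueError("nodes must be nonempty")
    unknown = {n.variable for n in node_list} - set(data.names)
    if unknown:
        raise DataError(f"unknown variables in embedding: {sorted(unknown)}")
    max_lag = max(n.lag for n in node_list)
    if data.n_time <= max_lag:
        raise DataError(f"series length {data.n_time} <= max requested lag {max_lag}")
    t_ref = np.arange(max_lag, data.n_time)
    cols = []
    for node in node_list:
        col = data.column(node.variable)
        cols.append(col[t_ref - node.lag])
    mat = np.column_stack(cols)
    keep = ~np.isnan(mat).any(axis=1)
    mat = mat[keep]
    if mat.shape[0] == 0:
        raise DataError("no gap-free embedded rows")
    return mat, node_list


@dataclass(frozen=True)
class InfoDecomposition:
    """T, J, D (nats) at one tau_c with their PID components."""

    tau_c: int
    order: int
    T: float
    J: float
    D: float
    pid_J: PIDResult
    pid_D: PIDResult
    n_effective: int
    sets: ConditionSets
    additivity_gap: float  # unclamped T - (J + D), diagnostic only

    @property
    def pid_T(self) -> PIDResult:
        """Component-wise sum of the immediate and distant decompositions."""
        j, d = self.pid_J, self.pid_D
        return PIDResult(
            total=j.total + d.total,
            redundant=j.redundant + d.redundant,
            synergistic=j.synergistic + d.synergistic,
            unique_m=j.unique_m + d.unique_m,
            unique_n=j.unique_n + d.unique_n,
            r_min=j.r_min + d.r_min,
            r_mmi=j.r_mmi + d.r_mmi,
            source_dependency=max(j.source_dependency, d.source_dependency),
        )


def _split_columns(
    mat: np.ndarray, cols: Sequence[LaggedNode], wanted: Iterable[LaggedNode]
) -> Optional[np.ndarray]:
    wanted = sorted(set(wanted))
    if not wanted:
        return None
    col_of = {c: i for i, c in enumerate(cols)}
    return mat[:, [col_of[w] for w in wanted]]


def estimate_tjd(
    dag: TimeSeriesDAG,
    spec: BundleSpec,
    tau_c: int,
    order: int,
    data: SeriesMatrix,
    cfg: EstimatorConfig,
    use_miwtr: bool = False,
) -> Tuple[float, float, float, int]:
    """The aggregate measures (T, J, D, n_effective) without their PIDs.

    Same condition sets, embedding and estimator calls as
    :func:`bundle_information`, skipping the decomposition — the economical
    path when only the totals are needed (e.g. large-n validation sweeps).
    Values are clamped at 0.
    """
    if use_miwtr:
        from .miwtr import reduce_condition_set

        sets = reduce_condition_set(dag, spec, tau_c, data, cfg, order=order)
    else:
        sets = condition_sets(dag, spec, tau_c, order)
    tar_node = LaggedNode(spec.target, 0)
    mat, cols = embed(data, {tar_node} | sets.V | sets.W | sets.F)
    n_eff = mat.shape[0]
    if n_eff <= 10 * cfg.k:
        raise DataError(f"n_effective={n_eff} too small for k={cfg.k}")
    tar = _split_columns(mat, cols, [tar_node])
    V = _split_columns(mat, cols, sets.V)
    W = _split_columns(mat, cols, sets.W)
    F = _split_columns(mat, cols, sets.F)

    def fw():
        if F is None and W is None:
            return None
        return np.hstack([b for b in (F, W) if b is not None])

    T = max(knn_cmi(V, tar, F, cfg), 0.0) if V is not None else 0.0
    J = max(knn_cmi(V, tar, fw(), cfg), 0.0) if V is not None else 0.0
    D = max(knn_cmi(W, tar, F, cfg), 0.0) if W is not None else 0.0
    return T, J, D, n_eff


def bundle_information(
    dag: TimeSeriesDAG,
    spec: BundleSpec,
    tau_c: int,
    order: int,
    data: SeriesMatrix,
    cfg: EstimatorConfig,
    use_miwtr: bool = False,
) -> InfoDecomposition:
    """Estimate T, J, D and their PIDs at one partition lag.

    With ``use_miwtr`` the distant-history conditioning set W is first pruned
    by momentary-information weighted transitive reduction.  Degenerate set
    configurations (empty V or W) collapse to the corresponding
    zero-information cases and are logged, not fatal.
    """
    if use_miwtr:
        from .miwtr import reduce_condition_set

        sets = reduce_condition_set(dag, spec, tau_c, data, cfg, order=order)
    else:
        sets = condition_sets(dag, spec, tau_c, order)

    tar_node = LaggedNode(spec.target, 0)
    all_nodes = {tar_node} | sets.V | sets.W | sets.F
    mat, cols = embed(data, all_nodes)
    n_eff = mat.shape[0]
    if n_eff <= 10 * cfg.k:
        raise DataError(f"n_effective={n_eff} too small for k={cfg.k}")

    tar = _split_columns(mat, cols, [tar_node])
    V_m = _split_columns(mat, cols, (v for v in sets.V if v.variable in spec.bundle_m))
    V_n = _split_columns(mat, cols, (v for v in sets.V if v.variable in spec.bundle_n))
    W_m = _split_columns(mat, cols, (w for w in sets.W if w.variable in spec.bundle_m))
    W_n = _split_columns(mat, cols, (w for w in sets.W if w.variable in spec.bundle_n))
    V_all = _split_columns(mat, cols, sets.V)
    W_all = _split_columns(mat, cols, sets.W)
    F_all = _split_columns(mat, cols, sets.F)

    def hstack(*blocks: Optional[np.ndarray]) -> Optional[np.ndarray]:
        live = [b for b in blocks if b is not None]
        return np.hstack(live) if live else None

    if V_all is None:
        logger.info("tau_c=%d: V empty — T = J = 0", tau_c)
        T_raw, pid_J = 0.0, PIDResult.zero()
    else:
        T_raw = knn_cmi(V_all, tar, F_all, cfg)
        pid_J = pid_decompose(tar, V_m, V_n, hstack(F_all, W_all), cfg)
    if W_all is None:
        logger.info("tau_c=%d: W empty — D = 0", tau_c)
        pid_D = PIDResult.zero()
    else:
        pid_D = pid_decompose(tar, W_m, W_n, F_all, cfg)

    # J and D are the same CMIs the PID layer computes (clamped there), so the
    # decomposition totals match J and D exactly.
    J, D = pid_J.total, pid_D.total
    gap = T_raw - (J + D)
    logger.debug(
        "tau_c=%d order=%d: unclamped T=%.4f, J=%.4f, D=%.4f, T-(J+D)=%.4f",
        tau_c, order, T_raw, J, D, gap,
    )
    T = max(T_raw, 0.0)
    return InfoDecomposition(
        tau_c=tau_c,
        order=order,
        T=T,
        J=J,
        D=D,
        pid_J=pid_J,
        pid_D=pid_D,
        n_effective=n_eff,
        sets=sets,
        additivity_gap=gap,
    )


def sweep(
    dag: TimeSeriesDAG,
    spec: BundleSpec,
    tau_c_grid: Sequence[int],
    order: int,
    data: SeriesMatrix,
    cfg: EstimatorConfig,
    use_miwtr: bool = False,
) -> List[InfoDecomposition]:
    """One InfoDecomposition per partition lag in the (strictly increasing) grid.

    Partition lags whose gap-free embeddable sample is too small are skipped
    with a warning; usable sample sizes shrink as tau_c grows when the series
    has gaps.
    """
    grid = list(tau_c_grid)
    if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("tau_c grid must be nonempty and strictly increasing")
    out = []
    for tau_c in grid:
        try:
            rec = bundle_information(dag, spec, tau_c, order, data, cfg, use_miwtr)
        except DataError as exc:
            logger.warning("tau_c=%d skipped: %s", tau_c, exc)
            continue
        logger.info(
            "tau_c=%d order=%d: T=%.4f J=%.4f D=%.4f (n_effective=%d)",
            tau_c, order, rec.T, rec.J, rec.D, rec.n_effective,
        )
        out.append(rec)
    return out


def results_table(records: Iterable[InfoDecomposition], cfg: EstimatorConfig) -> pd.DataFrame:
    """Long-format results: one row per (tau_c, order)."""
    rows = []
    for r in records:
        t = r.pid_T
        rows.append(
            {
                "tau_c": r.tau_c,
                "order": r.order,
                "T": r.T,
                "J": r.J,
                "D": r.D,
                "RJ": r.pid_J.redundant,
                "SJ": r.pid_J.synergistic,
                "UmJ": r.pid_J.unique_m,
                "UnJ": r.pid_J.unique_n,
                "RD": r.pid_D.redundant,
                "SD": r.pid_D.synergistic,
                "UmD": r.pid_D.unique_m,
                "UnD": r.pid_D.unique_n,
                "RT": t.redundant,
                "ST": t.synergistic,
                "UmT": t.unique_m,
                "UnT": t.unique_n,
                "n_effective": r.n_effective,
                "k": cfg.k,
                "seed": cfg.seed,
            }
        )
    return pd.DataFrame(rows)
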