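"""k-nearest-neighbor mutual-information estimators.

Implements the Kraskov–Stögbauer–Grassberger estimator (variant 1) for mutual
information and its Frenzel–Pompe extension to conditional mutual information,
both under the maximum (Chebyshev) norm.  These nonparametric estimators are
preferred over binning and kernel density estimation on short records.

Preprocessing, applied identically before every estimate:

1. each column is z-scored, so the max norm treats heterogeneous units evenly;
2. a small uniform jitter (``jitter_scale`` times the column SD, drawn from the
   seeded generator) breaks distance ties from repeated values.

Negative estimates are returned as-is; clamping is the PID layer's job.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy.special import digamma

from .tsdag import EdgeTemplate, LaggedNode, TimeSeriesDAG, parents

__all__ = ["EstimatorConfig", "knn_mi", "knn_cmi", "mit_edge_weight"]


@njit(cache=True)
def _kth_neighbor_distance(data: np.ndarray, k: int) -> np.ndarray:
    """Max-norm distance to the k-th nearest neighbor (self excluded).

    Brute force with an early exit over coordinates once the running maximum
    reaches the current k-th best; in the moderate dimensions used here this
    outperforms spatial trees, whose pruning collapses as dimension grows.
    """
    n, d = data.shape
    eps = np.empty(n)
    for i in range(n):
        best = np.full(k, np.inf)
        worst = np.inf
        for j in range(n):
            if j == i:
                continue
            m = 0.0
            for c in range(d):
                diff = abs(data[j, c] - data[i, c])
                if diff > m:
                    m = diff
                    if m >= worst:
                        break
            if m < worst:
                pos = k - 1
                while pos > 0 and best[pos - 1] > m:
                    best[pos] = best[pos - 1]
                    pos -= 1
                best[pos] = m
                worst = best[k - 1]
        eps[i] = best[k - 1]
    return eps


@njit(cache=True)
def _count_strictly_within(data: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Per point: how many *other* points lie strictly within its radius."""
    n, d = data.shape
    out = np.empty(n, np.int64)
    for i in range(n):
        r = radii[i]
        count = 0
        for j in range(n):
            if j == i:
                continue
            inside = True
            for c in range(d):
                if abs(data[j, c] - data[i, c]) >= r:
                    inside = False
                    break
            if inside:
                count += 1
        out[i] = count
    return out


class EstimatorError(ValueError):
    """Degenerate input to a kNN estimate."""


@dataclass(frozen=True)
class EstimatorConfig:
    """Settings shared by all kNN estimates in a run.

    k            : neighbor count (the sensitivity range 5..15 is typical).
    jitter_scale : tie-breaking noise amplitude as a fraction of column SD.
    seed         : seed for the jitter generator; fixes every estimate.
    """

    k: int = 5
    jitter_scale: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.jitter_scale < 0:
            raise ValueError("jitter_scale must be >= 0")


def _as_matrix(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ValueError("expected a 1-D or 2-D array")
    return a


def _prepare(blocks: Sequence[np.ndarray], cfg: EstimatorConfig) -> list[np.ndarray]:
    """Z-score every column and add seeded tie-breaking jitter.

    The jitter stream is consumed over the concatenated blocks in order, so a
    given (cfg, shapes, data) triple always yields the same prepared sample.
    """
    rng = np.random.default_rng(cfg.seed)
    out = []
    for b in blocks:
        b = _as_matrix(b).copy()
        if b.shape[1] == 0:
            out.append(b)
            continue
        if np.isnan(b).any():
            raise EstimatorError("NaN in estimator input; drop gap rows upstream")
        sd = b.std(axis=0, ddof=0)
        if cfg.jitter_scale == 0 and np.any(sd == 0):
            raise EstimatorError("constant column without jitter")
        mean = b.mean(axis=0)
        safe_sd = np.where(sd > 0, sd, 1.0)
        b = (b - mean) / safe_sd
        if cfg.jitter_scale > 0:
            # post-z-scoring the column SD is 1 (or the column is constant 0)
            b = b + rng.uniform(-1.0, 1.0, size=b.shape) * cfg.jitter_scale
        out.append(b)
    return out


def knn_mi(x: np.ndarray, y: np.ndarray, cfg: EstimatorConfig) -> float:
    """KSG-1 mutual information I(X;Y) in nats under the max norm.

    psi(k) + psi(n) - <psi(n_x + 1) + psi(n_y + 1)>, with n_x, n_y the counts
    of marginal points strictly within the joint-space k-NN distance.
    """
    xb, yb = _prepare([x, y], cfg)
    n = xb.shape[0]
    if yb.shape[0] != n:
        raise EstimatorError("row-count mismatch")
    if n <= cfg.k:
        raise EstimatorError(f"need n > k, got n={n}, k={cfg.k}")
    joint = np.ascontiguousarray(np.hstack([xb, yb]))
    eps = _kth_neighbor_distance(joint, cfg.k)
    nx = _count_strictly_within(np.ascontiguousarray(xb), eps)
    ny = _count_strictly_within(np.ascontiguousarray(yb), eps)
    return float(
        digamma(cfg.k) + digamma(n) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    )


def knn_cmi(
    x: np.ndarray, y: np.ndarray, z: Optional[np.ndarray], cfg: EstimatorConfig
) -> float:
    """Frenzel–Pompe conditional mutual information I(X;Y|Z) in nats.

    psi(k) - <psi(n_xz + 1) + psi(n_yz + 1) - psi(n_z + 1)> under the max
    norm.  With an empty conditioning block this *is* ``knn_mi`` bit-for-bit.
    """
    if z is None or _as_matrix(z).shape[1] == 0 or _as_matrix(z).size == 0:
        return knn_mi(x, y, cfg)
    xb, yb, zb = _prepare([x, y, z], cfg)
    n = xb.shape[0]
    if yb.shape[0] != n or zb.shape[0] != n:
        raise EstimatorError("row-count mismatch")
    if n <= cfg.k:
        raise EstimatorError(f"need n > k, got n={n}, k={cfg.k}")
    joint = np.ascontiguousarray(np.hstack([xb, yb, zb]))
    eps = _kth_neighbor_distance(joint, cfg.k)
    n_xz = _count_strictly_within(np.ascontiguousarray(np.hstack([xb, zb])), eps)
    n_yz = _count_strictly_within(np.ascontiguousarray(np.hstack([yb, zb])), eps)
    n_z = _count_strictly_within(np.ascontiguousarray(zb), eps)
    return float(
        digamma(cfg.k)
        - np.mean(digamma(n_xz + 1) + digamma(n_yz + 1) - digamma(n_z + 1))
    )


def mit_edge_weight(
    dag: TimeSeriesDAG,
    edge: EdgeTemplate,
    data,
    cfg: EstimatorConfig,
) -> float:
    """Momentary information transfer along one stationary edge, in nats.

    The shared dependency between the linked lagged nodes given the parents of
    both: I(source; target | P(target) \\ {source} ∪ P(source)), estimated on
    the lag-embedded, gap-free sample.  ``data`` is a SeriesMatrix.
    """
    from .flow import embed  # local import: flow depends on estimators

    if edge not in dag.edges:
        raise ValueError(f"{edge} is not an edge of the graph")
    src = LaggedNode(edge.source, edge.lag_gap)
    tgt = LaggedNode(edge.target, 0)
    cond = (parents(dag, tgt) - {src}) | parents(dag, src)
    nodes = sorted({src, tgt} | cond)
    mat, cols = embed(data, nodes)
    if mat.shape[0] < 10 * cfg.k:
        raise EstimatorError(
            f"only {mat.shape[0]} usable rows after embedding; need >= {10 * cfg.k}"
        )
    col_of = {node: i for i, node in enumerate(cols)}
    xcol = mat[:, [col_of[src]]]
    ycol = mat[:, [col_of[tgt]]]
    zcols = mat[:, [col_of[c] for c in sorted(cond)]] if cond else None
    return knn_cmi(xcol, ycol, zcols, cfg)
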