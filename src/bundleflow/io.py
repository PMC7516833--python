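"""Run configuration, series I/O and the analysis driver.

The run config is one flat YAML (or JSON) mapping; CLI flags override config
keys.  A run writes the long-format results CSV, a JSON sidecar recording the
condition sets per tau_c (V, W before/after MIWTR, F) together with every
effective setting for provenance, and a log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .estimators import EstimatorConfig
from .flow import SeriesMatrix, results_table, sweep
from .miwtr import reduce_condition_set
from .tsdag import BundleSpec, TimeSeriesDAG, condition_sets, load_graph

__all__ = ["RunConfig", "load_series", "write_series", "run_analysis"]

logger = logging.getLogger(__name__)

_NA_TOKENS = {"", "na", "nan", "null", "none"}


class FormatError(ValueError):
    """Malformed series or config file."""


@dataclass
class RunConfig:
    series_path: str
    graph_path: str
    target: str
    bundle_m: List[str]
    bundle_n: List[str]
    tau_c_grid: List[int] = field(default_factory=lambda: list(range(5, 151, 5)))
    order: str = "both"  # "0" | "1" | "both"
    k: List[int] = field(default_factory=lambda: [5])
    seed: int = 0
    jitter_scale: float = 1e-8
    use_miwtr: bool = True
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.tau_c_grid:
            raise ValueError("tau_c grid must be nonempty")
        if isinstance(self.k, int):
            self.k = [self.k]
        if any(k < 1 for k in self.k):
            raise ValueError("k must be >= 1")
        if str(self.order) not in {"0", "1", "both"}:
            raise ValueError("order must be 0, 1 or both")
        self.order = str(self.order)
        # delegates bundle validation (disjoint, nonempty)
        BundleSpec(self.target, self.bundle_m, self.bundle_n)

    @property
    def orders(self) -> List[int]:
        return [0, 1] if self.order == "both" else [int(self.order)]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        path = Path(path)
        with path.open() as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise FormatError(f"config {path} is not a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def load_series(path: str | Path) -> SeriesMatrix:
    """Read a CSV time series: header of variable names, NaN/NA/empty = gap.

    An optional first column named ``time``/``timestamp``/``date`` is dropped
    after a monotonicity check; it plays no role in the analysis.
    """
    path = Path(path)
    with path.open() as fh:
        header = [h.strip() for h in fh.readline().rstrip("\n").split(",")]
    if len(set(header)) != len(header):
        raise FormatError(f"duplicate column names in {path}")
    df = pd.read_csv(path, na_values=sorted(_NA_TOKENS), keep_default_na=True)
    first = df.columns[0].strip().lower()
    if first in {"time", "timestamp", "date", "t"}:
        ts = df.iloc[:, 0]
        order_vals = pd.to_datetime(ts, errors="coerce") if ts.dtype == object else ts
        if order_vals.notna().all() and not order_vals.is_monotonic_increasing:
            raise FormatError("timestamp column is not monotone increasing")
        df = df.iloc[:, 1:]
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
    return SeriesMatrix(values, tuple(str(c) for c in df.columns))


def write_series(data: SeriesMatrix, path: str | Path) -> None:
    pd.DataFrame(data.values, columns=list(data.names)).to_csv(path, index=False)


def _nodes_json(nodes) -> List[Tuple[str, int]]:
    return [[n.variable, n.lag] for n in sorted(nodes)]


def run_analysis(cfg: RunConfig) -> pd.DataFrame:
    """Execute the full sweep for every requested order and k.

    Returns the combined results table; also writes ``results.csv`` and the
    ``condition_sets.json`` sidecar into ``cfg.output_dir``.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = load_series(cfg.series_path)
    dag = load_graph(cfg.graph_path, variables=data.names)
    spec = BundleSpec(cfg.target, cfg.bundle_m, cfg.bundle_n)
    spec.validate_against(dag)

    est0 = EstimatorConfig(k=cfg.k[0], jitter_scale=cfg.jitter_scale, seed=cfg.seed)
    sidecar = {
        "config": {
            "series_path": str(cfg.series_path),
            "graph_path": str(cfg.graph_path),
            "target": cfg.target,
            "bundle_m": sorted(cfg.bundle_m),
            "bundle_n": sorted(cfg.bundle_n),
            "tau_c_grid": list(cfg.tau_c_grid),
            "order": cfg.order,
            "k": list(cfg.k),
            "seed": cfg.seed,
            "jitter_scale": cfg.jitter_scale,
            "use_miwtr": cfg.use_miwtr,
        },
        "condition_sets": [],
    }
    for order in cfg.orders:
        for tau_c in cfg.tau_c_grid:
            entry = {"tau_c": tau_c, "order": order}
            full = condition_sets(dag, spec, tau_c, order)
            entry["V"] = _nodes_json(full.V)
            entry["F"] = _nodes_json(full.F)
            entry["W"] = _nodes_json(full.W)
            if cfg.use_miwtr:
                reduced = reduce_condition_set(dag, spec, tau_c, data, est0, order=order)
                entry["W_reduced"] = _nodes_json(reduced.W)
            sidecar["condition_sets"].append(entry)

    tables = []
    for order in cfg.orders:
        for k in cfg.k:
            est = EstimatorConfig(k=k, jitter_scale=cfg.jitter_scale, seed=cfg.seed)
            records = sweep(dag, spec, cfg.tau_c_grid, order, data, est, cfg.use_miwtr)
            tables.append(results_table(records, est))
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()

    table.to_csv(out_dir / "results.csv", index=False)
    with (out_dir / "condition_sets.json").open("w") as fh:
        json.dump(sidecar, fh, indent=2)
    logger.info("wrote %s and %s", out_dir / "results.csv", out_dir / "condition_sets.json")
    return table
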