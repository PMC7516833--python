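"""Synthetic fixtures with known ground truth.

Stationary linear-Gaussian vector autoregressions (VARs) built directly on a
:class:`~bundleflow.tsdag.TimeSeriesDAG` are the primary validation target:
their stationary autocovariance sequence follows from a discrete Lyapunov
equation in companion form, so every conditional mutual information between
lagged nodes has an exact closed form against which the kNN estimators can be
checked.  A noisy coupled logistic-map generator provides a nonlinear variant
validated only through invariants (non-negativity, additivity), not closed
forms.

Fixture builders at the bottom emulate the study conditions: a seven-variable
system with a three-variable and a two-variable bundle, a two-variable rest
(the target among them), series length about 2000, plus small purpose-built
systems (causally disconnected bundles, finite memory depth, slow
autoregressive memory).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .flow import SeriesMatrix
from .tsdag import BundleSpec, EdgeTemplate, LaggedNode, TimeSeriesDAG

__all__ = [
    "VARSpec",
    "generate_var",
    "generate_gapped",
    "generate_logistic",
    "gaussian_cmi_oracle",
    "fixture_seven_var",
    "fixture_disconnected",
    "fixture_finite_memory",
    "fixture_miwtr",
    "fixture_slow_ar",
]


class StationarityError(ValueError):
    """Companion-matrix spectral radius >= 1."""


@dataclass(frozen=True)
class VARSpec:
    """A linear-Gaussian VAR whose nonzero coefficients sit on declared edges.

    X_t = sum over edge templates of coeff[e] * X_{t-lag_gap}[source] + eps_t,
    with independent Gaussian noise of per-variable standard deviation
    ``noise_sd``.  Stationarity (companion spectral radius < 1) is checked at
    construction.
    """

    dag: TimeSeriesDAG
    coeff: Mapping[EdgeTemplate, float]
    noise_sd: Mapping[str, float]
    n: int = 2000
    burn_in: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        extra = set(self.coeff) - set(self.dag.edges)
        if extra:
            raise ValueError(f"coefficients on undeclared edges: {sorted(extra)}")
        for v, sd in self.noise_sd.items():
            if sd <= 0:
                raise ValueError(f"noise_sd[{v!r}] must be positive")
        rho = self.spectral_radius()
        if rho >= 1.0:
            raise StationarityError(f"companion spectral radius {rho:.4f} >= 1")

    @property
    def order(self) -> int:
        return max(self.dag.max_lag, 1)

    def coefficient_matrices(self) -> np.ndarray:
        """Stack of lag matrices A_1..A_p, shape (p, N, N)."""
        names = list(self.dag.variables)
        idx = {v: i for i, v in enumerate(names)}
        N, p = len(names), self.order
        A = np.zeros((p, N, N))
        for e, c in self.coeff.items():
            A[e.lag_gap - 1, idx[e.target], idx[e.source]] = c
        return A

    def companion(self) -> np.ndarray:
        A = self.coefficient_matrices()
        p, N, _ = A.shape
        comp = np.zeros((N * p, N * p))
        comp[:N] = np.hstack(list(A))
        if p > 1:
            comp[N:, : N * (p - 1)] = np.eye(N * (p - 1))
        return comp

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def noise_cov(self) -> np.ndarray:
        sds = np.array([self.noise_sd[v] for v in self.dag.variables])
        return np.diag(sds**2)


def generate_var(spec: VARSpec) -> SeriesMatrix:
    """Simulate the VAR; the first ``burn_in`` rows are discarded."""
    names = list(spec.dag.variables)
    idx = {v: i for i, v in enumerate(names)}
    N, p = len(names), spec.order
    rng = np.random.default_rng(spec.seed)
    total = spec.burn_in + spec.n
    sds = np.array([spec.noise_sd[v] for v in names])
    X = np.zeros((total + p, N))
    noise = rng.normal(size=(total + p, N)) * sds
    terms = [(idx[e.target], idx[e.source], e.lag_gap, c) for e, c in spec.coeff.items()]
    for t in range(p, total + p):
        row = noise[t].copy()
        for ti, si, lag, c in terms:
            row[ti] += c * X[t - lag, si]
        X[t] = row
    return SeriesMatrix(X[p + spec.burn_in :], tuple(names))


def generate_gapped(spec: VARSpec, gap_fraction: float, seed: int) -> SeriesMatrix:
    """VAR series with random NaN row blocks totaling ``gap_fraction`` of rows.

    Blocks have geometric length (mean 5 rows) and may overlap; placement uses
    its own seed so the underlying series matches :func:`generate_var`.
    """
    if not 0 <= gap_fraction < 0.5:
        raise ValueError("gap_fraction must be in [0, 0.5)")
    series = generate_var(spec)
    if gap_fraction == 0:
        return series
    rng = np.random.default_rng(seed)
    n = series.n_time
    gapped = np.zeros(n, dtype=bool)
    target_rows = int(round(gap_fraction * n))
    while gapped.sum() < target_rows:
        start = int(rng.integers(0, n))
        length = 1 + int(rng.geometric(1 / 5.0))
        gapped[start : start + length] = True
    vals = series.values.copy()
    vals[gapped] = np.nan
    return SeriesMatrix(vals, series.names)


def generate_logistic(
    dag: TimeSeriesDAG,
    coupling: Mapping[EdgeTemplate, float],
    n: int = 2000,
    burn_in: int = 500,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> SeriesMatrix:
    """Noisy coupled logistic maps on the declared edge structure.

    Each variable follows x -> 4x(1-x) mixed with its declared lagged drivers;
    values stay in (0, 1) by clipping after the additive observation noise.
    Nonlinear fixture: no closed-form information values, invariants only.
    """
    names = list(dag.variables)
    idx = {v: i for i, v in enumerate(names)}
    N, p = len(names), max(dag.max_lag, 1)
    rng = np.random.default_rng(seed)
    total = burn_in + n
    X = np.zeros((total + p, N))
    X[:p] = rng.uniform(0.2, 0.8, size=(p, N))
    terms = [(idx[e.target], idx[e.source], e.lag_gap, c) for e, c in coupling.items()]
    cin = np.zeros(N)
    for ti, _, _, c in terms:
        cin[ti] += abs(c)
    own = 1.0 / (1.0 + cin)  # weight of a variable's own logistic drive
    for t in range(p, total + p):
        drive = np.zeros(N)
        for ti, si, lag, c in terms:
            drive[ti] += c * 4.0 * X[t - lag, si] * (1.0 - X[t - lag, si])
        self_map = 4.0 * X[t - 1] * (1.0 - X[t - 1])
        row = own * self_map + (1.0 - own) * np.abs(drive) / np.maximum(cin, 1e-12)
        row = np.where(cin > 0, row, self_map)
        row = row + rng.normal(scale=noise_sd, size=N)
        X[t] = np.clip(row, 1e-6, 1 - 1e-6)
    return SeriesMatrix(X[p + burn_in :], tuple(names))


# ---------------------------------------------------------------------------
# Exact Gaussian information oracle


def _autocovariances(spec: VARSpec, max_h: int) -> np.ndarray:
    """Gamma(h) = Cov(X_t, X_{t-h}) for h = 0..max_h, shape (max_h+1, N, N)."""
    comp = spec.companion()
    N, p = len(spec.dag.variables), spec.order
    Q = np.zeros_like(comp)
    Q[:N, :N] = spec.noise_cov()
    sigma_s = solve_discrete_lyapunov(comp, Q)
    sigma_s = (sigma_s + sigma_s.T) / 2
    gammas = np.zeros((max(max_h, p - 1) + 1, N, N))
    for h in range(p):
        gammas[h] = sigma_s[:N, h * N : (h + 1) * N]
    A = spec.coefficient_matrices()
    for h in range(p, max_h + 1):
        # Yule-Walker recursion; h >= p so every h-j is >= 0
        gammas[h] = sum(A[j - 1] @ gammas[h - j] for j in range(1, p + 1))
    return gammas[: max_h + 1]


def stationary_node_cov(spec: VARSpec, nodes: Sequence[LaggedNode]) -> np.ndarray:
    """Exact joint covariance of the requested lagged nodes."""
    if not nodes:
        return np.zeros((0, 0))
    idx = {v: i for i, v in enumerate(spec.dag.variables)}
    max_h = max(abs(a.lag - b.lag) for a in nodes for b in nodes)
    gammas = _autocovariances(spec, max_h)
    S = np.empty((len(nodes), len(nodes)))
    for i, a in enumerate(nodes):
        for j, b in enumerate(nodes):
            h = b.lag - a.lag  # Cov(X_{t-a}, X_{t-b}) = Gamma(b-a) for b >= a
            if h >= 0:
                S[i, j] = gammas[h][idx[a.variable], idx[b.variable]]
            else:
                S[i, j] = gammas[-h][idx[b.variable], idx[a.variable]]
    return S


def _logdet(S: np.ndarray) -> float:
    if S.shape[0] == 0:
        return 0.0
    sign, val = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("singular or indefinite covariance in oracle")
    return float(val)


def gaussian_cmi_oracle(
    spec: VARSpec,
    x_nodes: Iterable[LaggedNode],
    y_nodes: Iterable[LaggedNode],
    z_nodes: Iterable[LaggedNode] = (),
) -> float:
    """Exact I(X;Y|Z) in nats between lagged-node blocks of the VAR.

    0.5 * (ln det S_xz + ln det S_yz - ln det S_z - ln det S_xyz) computed
    from the stationary autocovariance; with empty Z this is the Gaussian
    mutual information.  Returns exactly 0 for structurally independent
    blocks.
    """
    x = sorted(set(x_nodes))
    y = sorted(set(y_nodes))
    z = sorted(set(z_nodes))
    if not x or not y:
        return 0.0
    overlap = (set(x) & set(y)) - set(z)
    if overlap:
        raise ValueError(f"x and y blocks overlap: {sorted(overlap)}")

    def cov(nodes: Sequence[LaggedNode]) -> np.ndarray:
        return stationary_node_cov(spec, nodes)

    val = 0.5 * (
        _logdet(cov(x + z)) + _logdet(cov(y + z)) - _logdet(cov(z)) - _logdet(cov(x + y + z))
    )
    return max(float(val), 0.0) if abs(val) < 1e-12 else float(val)


def oracle_tjd(
    spec: VARSpec, target: str, sets, *, union_total: bool = False
) -> Tuple[float, float, float]:
    """Exact (T, J, D) for given condition sets on the VAR.

    T = I(tar; V|F), J = I(tar; V|F,W), D = I(tar; W|F).  With
    ``union_total=True`` T is I(tar; V ∪ W | F), which equals J + D exactly
    by the chain rule regardless of the graph.
    """
    tar = [LaggedNode(target, 0)]
    V, W, F = sorted(sets.V), sorted(sets.W), sorted(sets.F)
    t_src = sorted(set(V) | set(W)) if union_total else V
    T = gaussian_cmi_oracle(spec, t_src, tar, F) if t_src else 0.0
    J = gaussian_cmi_oracle(spec, V, tar, F + W) if V else 0.0
    D = gaussian_cmi_oracle(spec, W, tar, F) if W else 0.0
    return T, J, D


# ---------------------------------------------------------------------------
# Fixture builders (study-scale defaults)


def _spec(
    variables: Sequence[str],
    entries: Sequence[Tuple[str, str, int, float]],
    noise_sd: Dict[str, float] | float = 1.0,
    n: int = 2000,
    seed: int = 0,
) -> VARSpec:
    edges = [(s, t, lag) for s, t, lag, _ in entries]
    dag = TimeSeriesDAG.from_edges(variables, edges)
    coeff = {EdgeTemplate(s, t, lag): c for s, t, lag, c in entries}
    if not isinstance(noise_sd, dict):
        noise_sd = {v: float(noise_sd) for v in variables}
    return VARSpec(dag=dag, coeff=coeff, noise_sd=noise_sd, n=n, seed=seed)


def fixture_seven_var(n: int = 2000, seed: int = 0) -> Tuple[VARSpec, BundleSpec]:
    """Seven-variable system: bundles of size 3 and 2, target in the rest.

    Mirrors the study's application scale: three "cation-like" drivers m1-m3,
    two "anion-like" drivers a1-a2, the target tar, and one further rest
    variable r that drives both the target and members of each bundle, so
    Order-1 conditioning genuinely removes information.

    The topology is chosen so the Markov-reduced conditioning sets stay
    compact (|V| = 3, |W| = 3, |F1| = 2, total embedding dimension <= 9):
    within-bundle influence flows through a few hub variables rather than
    giving every variable its own memory.  This keeps the kNN estimates of
    T, J, D at n ~ 10^4 inside the bias band the Gaussian oracle validation
    uses — the same dimensionality pressure that motivates the graph-based
    reduction in the first place.
    """
    variables = ["m1", "m2", "m3", "a1", "a2", "tar", "r"]
    entries = [
        # memory carried by hub variables
        ("m1", "m1", 1, 0.45),
        ("a1", "a1", 1, 0.4),
        ("tar", "tar", 1, 0.25),
        ("r", "r", 1, 0.55),
        # within-bundle couplings (m2 feeds the m-hub; a2 is a bundle sink)
        ("m2", "m1", 1, 0.3),
        ("a1", "a2", 1, 0.3),
        # cross-bundle coupling
        ("m1", "a2", 1, 0.25),
        # rest variable confounds both bundles and the target
        ("r", "m1", 1, 0.3),
        ("r", "a1", 1, 0.3),
        ("r", "tar", 1, 0.4),
        # bundle -> target couplings
        ("m1", "tar", 1, 0.35),
        ("m3", "tar", 2, 0.35),
        ("a1", "tar", 1, 0.3),
    ]
    spec = _spec(variables, entries, noise_sd=1.0, n=n, seed=seed)
    bundles = BundleSpec(target="tar", bundle_m=["m1", "m2", "m3"], bundle_n=["a1", "a2"])
    return spec, bundles


def fixture_miwtr(n: int = 4000, seed: int = 0) -> Tuple[VARSpec, BundleSpec]:
    """Bundle-heavy system on which MIWTR provably shrinks W.

    The bundle variable h reaches the immediate history both through a weak
    direct lag-3 link into q and through the strictly stronger two-edge
    pathway h -> p -> q; the weighted transitive reduction therefore removes
    the weak direct edges, after which the deepest h copies in the distant
    history lose their last direct link into the immediate history and are
    dropped from W (5 -> 3 nodes at tau_c = 3).
    """
    variables = ["p", "h", "q", "tar", "r"]
    entries = [
        ("p", "p", 1, 0.45),
        ("h", "p", 1, 0.5),    # strong pathway, first hop
        ("p", "q", 2, 0.5),    # strong pathway, second hop
        ("h", "q", 3, 0.15),   # weak direct channel, dominated by h->p->q
        ("p", "tar", 1, 0.3),
        ("q", "tar", 1, 0.5),
        ("tar", "tar", 1, 0.3),
        ("r", "tar", 1, 0.4),
        ("r", "r", 1, 0.5),
    ]
    spec = _spec(variables, entries, noise_sd=1.0, n=n, seed=seed)
    return spec, BundleSpec(target="tar", bundle_m=["p", "h"], bundle_n=["q"])


def fixture_disconnected(n: int = 10000, seed: int = 0) -> Tuple[VARSpec, BundleSpec]:
    """Bundles causally disconnected from the target (null fixture).

    The graph still declares candidate bundle -> target edges — with zero
    coefficients, as spurious links from an upstream graph-estimation step
    would appear — so V and W are nonempty and the information measures are
    genuinely *estimated* on independent data rather than structurally zero.
    """
    variables = ["m1", "a1", "tar", "r"]
    entries = [
        ("m1", "m1", 1, 0.6),
        ("a1", "a1", 1, 0.5),
        ("m1", "a1", 1, 0.3),
        ("m1", "tar", 1, 0.0),  # spurious: declared but inactive
        ("a1", "tar", 2, 0.0),  # spurious: declared but inactive
        ("tar", "tar", 1, 0.5),
        ("r", "tar", 1, 0.4),
        ("r", "r", 1, 0.6),
    ]
    spec = _spec(variables, entries, noise_sd=1.0, n=n, seed=seed)
    return spec, BundleSpec(target="tar", bundle_m=["m1"], bundle_n=["a1"])


def fixture_finite_memory(n: int = 10000, seed: int = 0) -> Tuple[VARSpec, BundleSpec]:
    """All causal lags <= 3 and memoryless bundle sources.

    The bundle variables are driven by white noise through a short chain, so
    once tau_c exceeds the total causal depth the distant history carries no
    information about the target at all (oracle D identically 0).
    """
    variables = ["a", "b", "c", "tar", "r"]
    entries = [
        ("a", "b", 2, 0.7),   # a is white noise feeding b with lag 2
        ("b", "tar", 1, 0.6),
        ("c", "tar", 3, 0.5),  # second bundle: white noise, direct lag-3 drive
        ("r", "tar", 1, 0.4),
        ("r", "r", 1, 0.5),
        ("tar", "tar", 1, 0.3),
    ]
    spec = _spec(variables, entries, noise_sd=1.0, n=n, seed=seed)
    return spec, BundleSpec(target="tar", bundle_m=["a", "b"], bundle_n=["c"])


def fixture_slow_ar(n: int = 10000, seed: int = 0) -> Tuple[VARSpec, BundleSpec]:
    """A slow autoregressive bundle component producing long-range memory.

    The bundle variable s (AR coefficient 0.95) drives the target, so the
    distant-history information D decays so slowly over the usual tau_c range
    that it sits on a positive quasi-plateau predicted exactly by the oracle.
    """
    variables = ["s", "q", "tar", "r"]
    entries = [
        ("s", "s", 1, 0.98),
        ("s", "tar", 1, 0.5),
        ("q", "q", 1, 0.9),
        ("q", "tar", 1, 0.35),
        ("r", "tar", 1, 0.3),
        ("r", "r", 1, 0.5),
        ("tar", "tar", 1, 0.2),
    ]
    spec = _spec(
        variables, entries, noise_sd={"s": 0.3, "q": 0.4, "tar": 1.0, "r": 1.0},
        n=n, seed=seed,
    )
    return spec, BundleSpec(target="tar", bundle_m=["s"], bundle_n=["q"])
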