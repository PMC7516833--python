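# Methods

## The problem and the measures

Given a multivariate stationary time series, a target variable `tar`, and two
disjoint variable bundles **m** and **n** (for instance, cation and anion
concentrations jointly shaping stream pH), the package quantifies how the
*evolutionary histories* of the two bundles determine the present state of the
target. Three conditional mutual informations (all in nats) carry the
analysis, parameterized by a partition lag τ_C that splits each bundle's
history into an *immediate* part (lags 1..τ_C) and a *distant* part
(lags > τ_C):

- `T` — information from the whole bundled history,
- `J` — information from the immediate history, conditioned also on the
  distant part,
- `D` — information from the distant history.

The chain rule of conditional mutual information gives `T = J + D`. Sweeping
τ_C profiles the memory of the target on the bundles: a `D` that decays to
zero signals finite memory; a `D` that plateaus at a positive value signals
long-range dependence.

`J` and `D` are each split by partial information decomposition (PID) into
redundant, synergistic and unique components with the two bundles as sources;
the decomposition of `T` is defined as the component-wise sum of the two, so
its additivity is exact by construction.

## Graphical reduction

The naive definitions condition on infinitely many lagged states. Two
reductions make estimation tractable:

1. **Markov reduction.** The system's causal structure is given as a
   stationary lagged-edge DAG (an edge template `source → target` at lag ≥ 1,
   repeated at every reference time; contemporaneous edges are rejected).
   Under the graphical Markov property the infinite histories collapse to
   three finite node sets:
   - `V` — parents of the target inside the immediate bundled history,
   - `W` — parents of immediate-history nodes inside the distant bundled
     history (all members have lag ≤ τ_C + max-lag, so `W` is finite),
   - `F` — the conditioning approximation: empty at **Order-0**, the target's
     non-bundle parents at **Order-1**.

   Order-0 reads as a generalized mutual information (the rest of the system
   is free to contribute), Order-1 as a generalized transfer entropy (direct
   influence of the rest on the target is blocked). Higher orders are not
   defined here. With Order-1 conditioning and τ_C at least the graph's
   maximum lag, `V ∪ F` contains every parent of the target, so the target is
   independent of `W` given `V ∪ F` and `T = J + D` holds *exactly* for the
   model distribution; at Order-0, unblocked paths through the rest variables
   open a small analytic gap, and the identity holds only within estimator
   tolerance.

2. **MIWTR.** When the graph is dense, `W` can still be large. Momentary
   Information Weighted Transitive Reduction weights every edge of the
   unrolled subgraph over `W ∪ immediate history` by its momentary information
   transfer — `I(source; target | parents(target) \ {source} ∪
   parents(source))` — and removes any edge strictly dominated by an indirect
   path whose bottleneck (minimum edge weight) exceeds the edge's own weight.
   Nodes of `W` left without a direct edge into the immediate history are then
   dropped. Edges are tested in ascending weight order against the current,
   partially reduced graph (ties broken by node labels); with this schedule a
   single pass is a fixpoint, which the test suite asserts by idempotence, and
   removal never enlarges any set. Ties in bottleneck weight do not remove an
   edge (strict inequality). Negative estimated edge weights are clamped to 0
   before reduction. Pruning `W` perturbs `J` and `D` slightly; the package
   assumes (and the tests check on fixtures) that this perturbation is small
   against the dimensionality-induced estimation bias it avoids.

## Estimation

Mutual information uses the Kraskov–Stögbauer–Grassberger estimator
(variant 1) and conditional mutual information its Frenzel–Pompe extension,
both under the maximum norm, with neighbor counts done by exact
early-exit brute force (compiled with numba) — in the moderate-to-high
dimensions typical of the conditioning sets, spatial-tree pruning collapses
and brute force is faster; the counting kernels are cross-checked against a
spatial tree in the tests. Defaults: `k = 5` neighbors (the study settings
use `k = 10` for Order-0 and `k = 5` for Order-1; sensitivity sweeps over
`k ∈ {5,…,15}` are supported), jitter of `1e-8` × column SD from the run
seed to break distance ties, and per-column z-scoring so the max norm treats
heterogeneous units evenly. Every estimate is bit-for-bit reproducible given
the seed. Estimator outputs may be slightly negative; they are reported
as-is and clamped only downstream.

Known estimator artifacts, measured in the test suite: a negative bias that
grows with the total embedding dimension and the strength of dependence
(≈0.03–0.04 nats at 9 dimensions, n = 10⁴, k = 5 on the shipped fixture),
and a ≈−0.05 nat bias when the conditioning block duplicates a source
coordinate exactly (I(X;Y|X)).

## PID with rescaled redundancy

With `I_m`, `I_n`, `I_mn` the conditional informations of the two source
blocks and their union (clamped at 0, and `I_mn` raised to
`max(I_mn, I_m, I_n)` so estimator noise cannot break monotonicity), the
redundancy is interpolated between its classical brackets
`R_min = max(0, I_m + I_n − I_mn)` and `R_MMI = min(I_m, I_n)`:

    R = R_min + s · (R_MMI − R_min),   s ∈ [0, 1]

and `S = I_mn − I_m − I_n + R`, `U_m = I_m − R`, `U_n = I_n − R`. The
bracketing guarantees all four components non-negative and exactly additive.

**The main methodological judgment call** is the source-dependency factor
`s` for continuous variables: discrete formulations normalize source
dependence by a minimum marginal entropy, which has no well-defined
differential analogue. The package uses the Gaussian correlation mapping

    s = clamp(1 − exp(−2·I(src_m; src_n)), 0, 1),

which equals ρ² for jointly Gaussian sources, is exactly 0 for independent
sources, and approaches 1 as the dependence becomes deterministic.
Degenerate cases: one empty source block collapses to the single-source
limit (all information unique to the live block); both empty give the zero
decomposition.

## Synthetic fixtures and what they do (not) show

Linear-Gaussian VARs declared on a `TimeSeriesDAG` are the primary
validation target because their stationary autocovariances — and hence every
conditional mutual information between lagged nodes — follow exactly from a
companion-form discrete Lyapunov equation. Fixtures:

- **seven-var** (default study-scale system, n = 2000): three
  "cation-like" and two "anion-like" bundle variables, a target and one more
  rest variable confounding both bundles and the target (so Order-0 totals
  genuinely exceed Order-1). The topology routes within-bundle influence
  through hub variables so the Markov sets stay compact (|V| = 3, |W| = 3,
  |F₁| = 2, ≤ 9 embedding dimensions): this keeps the kNN estimates within
  the closed-form validation band at n = 10⁴ — the same dimensionality
  pressure that motivates the graphical reduction itself. Coupling
  coefficients (0.25–0.55) describe a moderately coupled, clearly stationary
  system (spectral radius 0.65).
- **disconnected**: the graph declares bundle → target edges with zero
  generating coefficients (as spurious links from upstream graph estimation
  would appear), so the null behavior of the estimator is genuinely measured.
- **finite-memory**: white-noise bundle sources acting through lags ≤ 3;
  the oracle `D` is identically zero once τ_C exceeds the causal depth.
- **slow-ar**: a bundle variable with AR coefficient 0.98 produces a `D`
  that decays so slowly it sits on a positive quasi-plateau across the usual
  τ_C range, matching the oracle throughout.
- **miwtr**: a weak direct lag-3 channel strictly dominated by a two-edge
  pathway; MIWTR provably shrinks `W` from 5 to 3 nodes at τ_C = 3.
- A noisy coupled logistic-map generator provides a nonlinear variant,
  validated only through invariants (boundedness, information transfer,
  reproducibility) since no closed form exists.

Gap handling is emulated by NaN row blocks of geometric length; embedding
drops every reference time whose window touches a gap, so usable sample
sizes shrink as τ_C grows, as in gappy field records.

These fixtures validate the estimators and the reduction machinery under
known ground truth. They do not emulate real biogeochemical dynamics:
passing tests shows correctness of the computation, not that a particular
field system satisfies the stationarity, Markov and no-contemporaneous-edge
assumptions, and the causal graph itself is always an *input* — estimating
it is out of scope.

## Numerical choices and degenerate inputs

- All information in nats; natural logarithms throughout.
- One common gap-free embedded sample per τ_C backs T, J, D and the PIDs, so
  the additivity diagnostic compares like with like; the unclamped
  `T − (J + D)` is logged before T is clamped at 0.
- `J` and `D` are taken as the totals of their PIDs (the same CMI calls), so
  `pid.total` matches the reported measure bit-for-bit.
- Empty `V` ⇒ T = J = 0; empty `W` ⇒ D = 0; both logged, never fatal. τ_C
  values whose usable sample is ≤ 10·k are skipped with a warning during
  sweeps.
- Constant columns are rejected unless jitter is enabled (the default).
- The target may itself belong to a bundle: its lagged copies then
  participate in V/W like any bundle node while the lag-0 copy remains the
  outcome, and F₁ keeps only non-bundle parents.

## Problem sizes used in validation

Closed-form agreement and null checks run at n = 10⁴, k = 5, averaged over
10 seeds; study-scale demonstrations (the τ_C sweep with full PID profiles)
run at n = 2000, mirroring the short records the method targets. MIWTR
correctness is checked against an independent path-enumeration oracle on 200
random weighted DAGs of up to 8 nodes.

## Known limitations

- The kNN bias grows with conditioning dimension; on dense graphs the
  reported J can be biased low even after MIWTR. The k-sensitivity sweep is
  the practical diagnostic.
- The rescaled-redundancy factor `s` is one defensible choice among several;
  `R_min` and `R_MMI` are exposed on every result for bracket diagnostics.
- Only two bundles are supported; no surrogate-based significance testing is
  provided.
- Contemporaneous or cyclic dependence is rejected at graph load.
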