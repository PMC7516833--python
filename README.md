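# bundleflow

Information-theoretic analysis of **bundled causal histories** in
multivariate time series: how do the evolutionary histories of two disjoint
groups of variables jointly, redundantly, synergistically and uniquely
determine the present state of a target variable?

The motivating setting is systems biology and environmental biogeochemistry
— e.g. how the histories of cation and anion concentrations jointly shape
stream pH — but the machinery applies to any stationary multivariate series
with a known lagged causal structure (the causal graph is an *input*,
typically estimated upstream by a time-series causal-discovery algorithm;
estimating it is out of scope here).

## The measures

For a target X<sup>tar</sup><sub>t</sub>, bundles **m** and **n**, and a
partition lag τ<sub>C</sub>, three conditional mutual informations (nats)
quantify the influence of the bundled histories, reduced to finite node sets
V, W, F via the graphical Markov property:

- T<sup>mn</sup> = I(X<sup>tar</sup><sub>t</sub>; V | F) — the whole bundled history,
- J<sup>mn</sup> = I(X<sup>tar</sup><sub>t</sub>; V | F, W<sub>τC</sub>) — the immediate history (lags ≤ τ<sub>C</sub>),
- D<sup>mn</sup> = I(X<sup>tar</sup><sub>t</sub>; W<sub>τC</sub> | F) — the distant history (lags > τ<sub>C</sub>),

with T<sup>mn</sup> = J<sup>mn</sup> + D<sup>mn</sup> by the chain rule.
Here V are the target's parents in the immediate bundled history, W the
parents of the immediate history lying in the distant bundled history, and F
the conditioning approximation: empty (**Order-0**, a generalized mutual
information) or the target's non-bundle parents (**Order-1**, a generalized
transfer entropy). Each measure is split by partial information
decomposition, J<sup>mn</sup> = R<sub>J</sub> + S<sub>J</sub> +
U<sup>m</sup><sub>J</sub> + U<sup>n</sup><sub>J</sub> (likewise D), with a
rescaled redundancy interpolating between the interaction-information lower
bound and the minimum-mutual-information upper bound.

Estimation uses Kraskov–Stögbauer–Grassberger / Frenzel–Pompe k-nearest-
neighbor estimators (max norm, z-scored columns, seeded tie-breaking
jitter). When the conditioning set W grows large, **MIWTR** (momentary-
information weighted transitive reduction) prunes edges dominated by
strictly stronger indirect pathways and drops W nodes left without a direct
link into the immediate history. Full details and design rationale:
[docs/methods.md](docs/methods.md).

## Worked example

Simulate the bundled seven-variable stationary VAR fixture (three
"cation-like" drivers m1–m3, two "anion-like" drivers a1–a2, target `tar`,
confounding rest variable `r`) and analyze it at τ<sub>C</sub> = 5 under
Order-1 conditioning:

```python
import bundleflow as bf

var_spec, bundles = bf.fixture_seven_var(n=2000, seed=1)
series = bf.generate_var(var_spec)
cfg = bf.EstimatorConfig(k=5, seed=1)

rec = bf.bundle_information(var_spec.dag, bundles, tau_c=5, order=1,
                            data=series, cfg=cfg)
print(f"T = {rec.T:.3f} nats   J = {rec.J:.3f}   D = {rec.D:.3f}")
p = rec.pid_J
print(f"immediate PID: R = {p.redundant:.3f}  S = {p.synergistic:.3f}  "
      f"Um = {p.unique_m:.3f}  Un = {p.unique_n:.3f}")

sets = bf.condition_sets(var_spec.dag, bundles, 5, 1)
print("oracle T,J,D:", [round(v, 3) for v in bf.oracle_tjd(var_spec, "tar", sets)])
```

prints

```
T = 0.138 nats   J = 0.125   D = 0.003
immediate PID: R = 0.012  S = 0.001  Um = 0.078  Un = 0.034
oracle T,J,D: [0.176, 0.176, 0.0]
```

Reading: at this partition lag essentially all bundled-history information
is immediate (J ≈ T, D ≈ 0 — the fixture's memory is short), and it is
carried mostly as unique contributions of the two bundles, the m-bundle
dominating (U<sub>m</sub> > U<sub>n</sub>) because it holds two of the three
parents of the target in V. The exact Gaussian values from the fixture's
Lyapunov-equation oracle (last line) show the kNN estimates' small negative
bias at n = 2000.

The same analysis runs from the shell on CSV inputs:

```bash
bundleflow simulate --fixture seven-var --n 2000 --seed 1 \
    --out series.csv --graph-out graph.csv
bundleflow graph-check graph.csv series.csv
bundleflow run --config run.yaml --order both --tau-c-grid 5:150:15
```

where `run.yaml` names the series/graph files, target, bundles, τ<sub>C</sub>
grid, k, seed and output directory. A run writes a long-format `results.csv`
(T, J, D and all PID components per τ<sub>C</sub>, order and k) and a JSON
sidecar recording the condition sets (V, W before/after MIWTR, F) and every
effective setting.

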