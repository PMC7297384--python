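# coopdiscern

Tools for deciding whether a two-site ligand-binding dataset comes from
**negative cooperativity** (NC: two identical sites, the second association
rate reduced by a factor ω < 1) or from **independent binding** (IB: two
non-interacting sites with different affinities K₁₀ ≠ K₀₁).

At equilibrium these two mechanisms are *indistinguishable*: for every NC
model (K, ω) with ω < 1 there is an IB pair

    K₁₀, K₀₁ = (K/ω) · (1 ± √(1 − ω)),

with exactly the same dose-response curve θ(L).  The package discriminates
them from the **temporal evolution of the dynamic range**:

    DynR(t) = log₁₀( EC₉₀(t) / EC₁₀(t) ),

where ECₓ(t) is the dose giving x% absolute site occupancy at time t after a
ligand step.  A single site spans DynR = log₁₀ 81 ≈ 1.9; negative
cooperativity widens it.  DynR(t) — the *target curve* — behaves differently
in the two mechanisms even when their equilibria coincide: for NC it always
increases with time, its early limit DynR(t→0) is set by ω alone, and its
inflection time t_ip is set by the unbinding rate l; for IB it can increase,
decrease or be biphasic, and DynR(t→0) is set by the rate ratio k₁₀/k₀₁.

The discrimination cascade (TC+DR):

1. **TC** — fit the equilibrium curve for (K̂, ω̂), then fit the whole
   θ(L, t) surface with both models under the dissociation-constant
   constraints (one free unbinding rate for NC, two for IB), and score the
   two residuals with an F-statistic C ∈ [0, 1] (≈1 → IB, ≈0 → NC, ≈½ →
   undecided; verdict thresholds 1/3 and 2/3);
2. **Checkpoint 1** — a decreasing or biphasic target curve can only be IB;
3. **Checkpoint 2** — compare the observed DynR(t→0) with database
   predictions at ω̂ (miss → IB) and at k̂₁₀/k̂₀₁ (miss → NC);
4. **Checkpoint 3** — compare the observed t_ip with the database prediction
   at l̂; outside the band → IB, inside → NC (terminal).

The database predictions are numerical lookup curves built from a Latin
hypercube scan of paired (NC, IB) parameter sets on the non-identifiability
manifold, simulated deterministically; acceptance bands are calibrated on
stochastic (Gillespie) simulations at a reference receptor count R₀ = 1000
and widened ∝ 1/√R₀ for noisier data.

## Worked example

```python
from coopdiscern import (NCParams, SimulationGrid, build_database,
                         calibrate_thresholds, default_doses, default_times,
                         discriminate, lhs_scan, simulate_gillespie)

db = build_database(lhs_scan(300, seed=1))
db.thresholds = calibrate_thresholds(db, r0=1000, n_cal=20, seed=2)

truth = NCParams(k=2.0, l=0.5, omega=0.08)           # K = 0.25
grid = SimulationGrid(default_doses(20, 1e-3, 1e7),
                      default_times(50), r0=1000)
data = simulate_gillespie(truth, grid, seed=7)
decision = discriminate(data, db)
print(decision.verdict)
print(decision.analysis.tc.omega_hat)
```

prints

```
NC
0.0759...
```

— the cascade recovers the mechanism and the cooperativity factor (true
ω = 0.08) from one noisy simulated experiment of 1000 receptors.  The
decision's `path` records every stage traversed: here C ≈ 0.35 (both
kinetic fits comparable → undecided), an increasing target curve, DynR(t→0)
inside both bands, and finally t_ip within 0.15 decades of the database
prediction at l̂ → NC.  The scripts in `examples/` walk through the
equilibrium indistinguishability, target-curve features, single-dataset
discrimination, and the noise benchmark, each printing the numbers it
computes.

A thin CLI mirrors the library (`coopdiscern simulate | target-curve |
build-db | tc | discriminate | benchmark | make-fixture`); datasets travel
as long-format CSV (`time,ligand,theta`) with a JSON provenance sidecar.

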