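"""The dynamic range of the dose-response curve evolves in time.

Simulates both members of a manifold pair (same equilibrium curve,
different microscopic mechanism) and extracts the DynR-versus-time target
curve from each.  The curves agree at equilibrium but differ before it —
that temporal difference is what the discrimination method exploits.
"""

import numpy as np

from coopdiscern import (
    IBParams,
    NCParams,
    SimulationGrid,
    default_doses,
    default_times,
    nc_to_ib,
    simulate_ode,
    target_curve,
)

K, omega, l = 1.0, 0.05, 1.0
K10, K01 = nc_to_ib(K, omega)
nc = NCParams(k=l / K, l=l, omega=omega)
ib = IBParams(k10=20.0 / K10, k01=0.05 / K01, l10=20.0, l01=0.05)

grid = SimulationGrid(default_doses(200), default_times(60))
for name, model in (("NC", nc), ("IB", ib)):
    curve = target_curve(simulate_ode(model, grid))
    print(f"{name}: shape = {curve.shape}")
    print(f"    DynR(t->0)   = {curve.dynr_initial:.3f}"
          f"  (reliable early plateau: {curve.dynr_initial_reliable})")
    print(f"    DynR(t->inf) = {curve.dynr_final:.3f}")
    print(f"    t_ip         = {curve.t_ip:.3g}" if np.isfinite(curve.t_ip)
          else "    t_ip         = undefined")
print()
print("Both mechanisms end at the same equilibrium DynR, but their early")
print("dynamic ranges and time courses differ: omega sets DynR(t->0) for")
print("NC, the rate ratio k10/k01 sets it for IB, and the unbinding rate l")
print("sets the inflection time of an increasing NC curve.")
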