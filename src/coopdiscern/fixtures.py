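"""Labelled synthetic datasets for tests and demos.

The four kinds mirror the four corners of the two-binding-site space: truly
negatively cooperative identical sites (``nc``), independent different sites
(``ib``), a single Langmuir site (``single_site``) and identical independent
sites (``equal_sites``, the omega = 1 corner where NC and IB coincide).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .binding_models import IBParams, NCParams
from .database import lhs_scan
from .kinetics import (
    SimulationGrid,
    TimeCourseDataset,
    default_doses,
    default_times,
    simulate_gillespie,
    simulate_ode,
)

__all__ = ["make_fixture"]

KINDS = ("nc", "ib", "single_site", "equal_sites")


def make_fixture(
    kind: str,
    noise_r0: Optional[int] = None,
    seed: int = 0,
    grid: Optional[SimulationGrid] = None,
) -> TimeCourseDataset:
    """Generate a labelled occupancy dataset.

    ``nc``/``ib`` draw manifold-consistent parameters from an LHS scan seeded
    by ``seed``; ``single_site`` and ``equal_sites`` use unit rates.
    ``noise_r0=None`` gives the deterministic limit; otherwise a Gillespie
    realisation at that receptor count.  Deterministic under fixed seed.
    """
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}")
    if grid is None:
        grid = SimulationGrid(
            default_doses(20, 1e-3, 1e7), default_times(50), r0=noise_r0
        )
    elif grid.r0 != noise_r0:
        grid = SimulationGrid(grid.doses, grid.times, r0=noise_r0)
    if kind in ("nc", "ib"):
        pair = lhs_scan(1, seed=seed)[0]
        model = pair.nc if kind == "nc" else pair.ib
    elif kind == "equal_sites":
        model = IBParams(k10=1.0, k01=1.0, l10=1.0, l01=1.0)
    else:  # single_site: identical independent sites behave as one Langmuir site
        model = NCParams(k=1.0, l=1.0, omega=1.0)
    if noise_r0 is None:
        data = simulate_ode(model, grid)
    else:
        data = simulate_gillespie(model, grid, seed=seed)
    data.provenance["fixture_kind"] = kind
    return data
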