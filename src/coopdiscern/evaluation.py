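"""Benchmark harness: accuracy of TC-alone and TC+DR across noise levels.

Datasets are generated from fresh LHS draws on the non-identifiability
manifold, simulated either stochastically at a given receptor count R0 or
deterministically (R0 = None), and pushed through both algorithms:

* **TC** — the C-score verdict alone (undecided counts as incorrect);
* **TC+DR** — the full checkpoint cascade.

The harness also isolates the cascade's known failure mode: IB-generated
datasets that survive to checkpoint 3 and are (wrongly) concluded NC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .checkpoints import analyze, decide_from_analysis
from .database import ManifoldDatabase, lhs_scan
from .kinetics import (
    SimulationGrid,
    default_doses,
    default_times,
    simulate_gillespie,
    simulate_ode,
)

__all__ = [
    "LevelResult",
    "BenchmarkReport",
    "benchmark",
    "checkpoint3_error",
    "checkpoint2_power",
]


def benchmark_grid(r0: Optional[int]) -> SimulationGrid:
    """The benchmark sampling layout: 20 log-spaced doses over [1e-3, 1e7]
    and 50 log-spaced times over [1e-4, 1e4] (plus t = 0)."""
    return SimulationGrid(default_doses(20, 1e-3, 1e7), default_times(50), r0=r0)


@dataclass
class LevelResult:
    """Per-(algorithm x R0) tally."""

    r0: Optional[int]
    n_datasets: int
    n_correct_tc: int
    n_correct_tcdr: int
    stage_counts: dict = field(default_factory=dict)
    cp3_wrong_nc: int = 0
    cp3_reached: int = 0
    records: list = field(default_factory=list)  # per-dataset audit rows

    @property
    def accuracy_tc(self) -> float:
        return self.n_correct_tc / self.n_datasets

    @property
    def accuracy_tcdr(self) -> float:
        return self.n_correct_tcdr / self.n_datasets

    @property
    def cp3_error_rate(self) -> float:
        """Wrong-NC conclusions among datasets reaching checkpoint 3."""
        if self.cp3_reached == 0:
            return float("nan")
        return self.cp3_wrong_nc / self.cp3_reached

    @property
    def cp3_error_rate_overall(self) -> float:
        """Same numerator over all datasets (the alternative denominator)."""
        return self.cp3_wrong_nc / self.n_datasets


@dataclass
class BenchmarkReport:
    levels: list[LevelResult]
    seed: int
    n_per_model: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_per_model": self.n_per_model,
            "levels": [
                {
                    "r0": lv.r0,
                    "n_datasets": lv.n_datasets,
                    "accuracy_tc": lv.accuracy_tc,
                    "accuracy_tcdr": lv.accuracy_tcdr,
                    "stage_counts": lv.stage_counts,
                    "cp3_error_rate": lv.cp3_error_rate,
                    "cp3_error_rate_overall": lv.cp3_error_rate_overall,
                }
                for lv in self.levels
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    def table(self) -> str:
        """Plain-text accuracy table (rows: R0 levels)."""
        lines = [f"{'R0':>8} {'n':>5} {'TC':>7} {'TC+DR':>7}"]
        for lv in self.levels:
            r0 = "inf" if lv.r0 is None else str(lv.r0)
            lines.append(
                f"{r0:>8} {lv.n_datasets:>5} {lv.accuracy_tc:>7.3f} "
                f"{lv.accuracy_tcdr:>7.3f}"
            )
        return "\n".join(lines)


def _final_stage(decision) -> str:
    return decision.path[-1]["stage"]


def run_level(
    db: ManifoldDatabase,
    r0: Optional[int],
    n_per_model: int,
    seed: int,
    grid: Optional[SimulationGrid] = None,
) -> LevelResult:
    """Simulate and classify n_per_model pairs (both members) at one R0."""
    if grid is None:
        grid = benchmark_grid(r0)
    elif grid.r0 != r0:
        grid = SimulationGrid(grid.doses, grid.times, r0=r0)
    pairs = lhs_scan(n_per_model, seed=seed)
    rng = np.random.default_rng(seed + 1)
    result = LevelResult(
        r0=r0, n_datasets=0, n_correct_tc=0, n_correct_tcdr=0,
        stage_counts={s: 0 for s in ("tc", "cp1", "cp2", "cp3", "failed")},
    )
    for pair in pairs:
        for truth, model in (("NC", pair.nc), ("IB", pair.ib)):
            result.n_datasets += 1
            try:
                if r0 is None:
                    data = simulate_ode(model, grid)
                else:
                    data = simulate_gillespie(
                        model, grid, seed=int(rng.integers(2**31))
                    )
                a = analyze(data, db)
                decision = decide_from_analysis(a, db)
            except (ValueError, RuntimeError) as exc:
                result.stage_counts["failed"] += 1
                result.records.append(
                    {"truth": truth, "verdict": "undecided", "stage": "failed",
                     "error": str(exc)}
                )
                continue  # counted as undecided -> incorrect
            stage = _final_stage(decision)
            result.stage_counts[stage] += 1
            result.records.append(
                {
                    "truth": truth,
                    "verdict": decision.verdict,
                    "stage": stage,
                    "C": a.tc.C,
                    "omega": pair.omega,
                    "omega_hat": a.tc.omega_hat,
                    "shape": a.shape,
                    "d_dynr0_nc": a.d_dynr0_nc,
                    "d_dynr0_ib": a.d_dynr0_ib,
                    "d_log_tip": a.d_log_tip,
                }
            )
            if a.tc_verdict == truth:
                result.n_correct_tc += 1
            if decision.verdict == truth:
                result.n_correct_tcdr += 1
            if stage == "cp3":
                result.cp3_reached += 1
                if truth == "IB" and decision.verdict == "NC":
                    result.cp3_wrong_nc += 1
    return result


def benchmark(
    n_per_model: int,
    r0_levels: Sequence[Optional[int]],
    db: ManifoldDatabase,
    seed: int,
    grid: Optional[SimulationGrid] = None,
) -> BenchmarkReport:
    """Accuracy of TC and TC+DR per noise level; fully seeded."""
    if n_per_model < 1:
        raise ValueError("n_per_model must be >= 1")
    levels = [
        run_level(db, r0, n_per_model, seed=seed + 7919 * (i + 1), grid=grid)
        for i, r0 in enumerate(r0_levels)
    ]
    return BenchmarkReport(levels=levels, seed=seed, n_per_model=n_per_model)


def checkpoint2_power(
    n_pairs: int,
    db: ManifoldDatabase,
    seed: int,
    grid: Optional[SimulationGrid] = None,
) -> dict:
    """Fraction of manifold cases the early-DynR comparison resolves alone.

    Both members of ``n_pairs`` fresh LHS pairs are simulated
    deterministically; for each dataset the checkpoint-2 band test (observed
    DynR(t→0) against the database prediction at the fitted omega, then at
    the fitted k10/k01) is applied in isolation — ignoring the C score and
    the other checkpoints.  Returns the resolved-and-correct fraction over
    all datasets, plus the resolved fraction and the accuracy among resolved.
    """
    from .checkpoints import analyze, checkpoint2

    if grid is None:
        # the scan's own deterministic layout: wide dose range so the
        # early-time EC levels stay on the grid for all sampled rates
        grid = SimulationGrid(default_doses(60, 1e-3, 1e8), default_times(50))
    pairs = lhs_scan(n_pairs, seed=seed)
    n_total = n_band = n_cascade = n_resolved = 0
    for pair in pairs:
        for truth, model in (("NC", pair.nc), ("IB", pair.ib)):
            n_total += 1
            try:
                a = analyze(simulate_ode(model, grid), db)
            except (ValueError, RuntimeError):
                continue
            if a.dynr0_reliable and np.isfinite(a.d_dynr0_nc):
                # the omega-band comparison as a complete binary classifier:
                # early DynR consistent with the NC prediction at the fitted
                # omega -> NC, otherwise -> IB
                band_verdict = (
                    "IB" if a.d_dynr0_nc > db.thresholds.dynr0_nc else "NC"
                )
                if band_verdict == truth:
                    n_band += 1
            # the same quantities run through the full two-band stage rule
            cascade_verdict = checkpoint2(
                a.d_dynr0_nc, a.d_dynr0_ib, a.dynr0_reliable, db.thresholds
            )
            if cascade_verdict in ("IB", "NC"):
                n_resolved += 1
                if cascade_verdict == truth:
                    n_cascade += 1
    return {
        "omega_band_correct_fraction": n_band / n_total,
        "two_band_resolved_fraction": n_resolved / n_total,
        "two_band_resolved_correct_fraction": n_cascade / n_total,
        "n_datasets": n_total,
    }


def checkpoint3_error(
    n_per_model: int,
    r0: Optional[int],
    db: ManifoldDatabase,
    seed: int,
    grid: Optional[SimulationGrid] = None,
) -> dict:
    """Rate of wrong terminal-NC conclusions at checkpoint 3.

    Returns the error fraction among datasets reaching checkpoint 3 (the
    primary denominator), the same numerator over all datasets, and a
    binomial standard error.  ``error_rate`` is nan when no dataset reaches
    checkpoint 3.
    """
    level = run_level(db, r0, n_per_model, seed=seed, grid=grid)
    rate = level.cp3_error_rate
    se = (
        float(np.sqrt(rate * (1 - rate) / level.cp3_reached))
        if level.cp3_reached
        else float("nan")
    )
    return {
        "error_rate": rate,
        "error_rate_overall": level.cp3_error_rate_overall,
        "n_reaching_cp3": level.cp3_reached,
        "n_datasets": level.n_datasets,
        "binomial_se": se,
    }
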