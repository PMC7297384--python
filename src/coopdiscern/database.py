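"""Parameter scan on the non-identifiability manifold and the lookup database.

A Latin-hypercube scan draws NC parameter sets (k, l, omega) together with IB
unbinding rates (l10, l01); the IB association rates are completed from the
manifold conditions (k10 = l10/K10, k01 = l01/K01 with (K10, K01) the IB
counterpart of (K = l/k, omega)), so every pair shares one equilibrium
dose-response curve and the discrimination problem genuinely exists.

Simulating both members of every pair deterministically and extracting their
target-curve features yields three numerical lookup curves:

* ``dynr0_nc``  — DynR(t→0) versus omega (NC members),
* ``dynr0_ib``  — DynR(t→0) versus |log10(k10/k01)| (IB members; the curve is
  symmetric under k10/k01 ↔ k01/k10, the site-swap symmetry),
* ``tip_nc``    — log10 t_ip versus log10 l (NC members).

Each lookup is a binned-median interpolant with 5th-95th percentile envelope
bands.  The acceptance thresholds used by the checkpoint cascade are either
envelope-derived defaults or calibrated by grid search on simulated data at a
reference receptor count (R0 = 1000 by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .binding_models import IBParams, NCParams, nc_to_ib
from .kinetics import (
    SimulationGrid,
    default_doses,
    default_times,
    simulate_gillespie,
    simulate_ode,
)
from .metrics import target_curve

__all__ = [
    "ManifoldPair",
    "LookupCurve",
    "Thresholds",
    "ManifoldDatabase",
    "lhs_scan",
    "build_database",
    "calibrate_thresholds",
]

# LHS sampling ranges (log10): rates span 4 decades, omega the negative-
# cooperativity range.
RATE_RANGE = (-2.0, 2.0)
OMEGA_RANGE = (-2.0, 0.0)


@dataclass(frozen=True)
class ManifoldPair:
    """An NC model and the IB model sharing its equilibrium curve."""

    nc: NCParams
    ib: IBParams

    @property
    def omega(self) -> float:
        return self.nc.omega


def lhs_scan(n: int, seed: int) -> list[ManifoldPair]:
    """Draw ``n`` manifold pairs by Latin hypercube sampling.

    k, l, l10, l01 are log10-uniform on [1e-2, 1e2] and omega log10-uniform
    on [1e-2, 1]; k10 and k01 follow from the manifold conditions.
    Deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=5, seed=seed)
    u = sampler.random(n)
    lo = np.array([RATE_RANGE[0]] * 4 + [OMEGA_RANGE[0]])
    hi = np.array([RATE_RANGE[1]] * 4 + [OMEGA_RANGE[1]])
    k, l, l10, l01, omega = (10 ** (lo + u * (hi - lo))).T
    pairs = []
    for ki, li, l10i, l01i, wi in zip(k, l, l10, l01, omega):
        K10, K01 = nc_to_ib(li / ki, min(wi, 1.0))
        pairs.append(
            ManifoldPair(
                nc=NCParams(k=ki, l=li, omega=wi),
                ib=IBParams(k10=l10i / K10, k01=l01i / K01, l10=l10i, l01=l01i),
            )
        )
    return pairs


@dataclass
class LookupCurve:
    """Binned-median interpolant with percentile envelope bands."""

    x: np.ndarray  # bin centers
    median: np.ndarray
    lo: np.ndarray  # 5th percentile
    hi: np.ndarray  # 95th percentile

    @classmethod
    def fit(cls, x: np.ndarray, y: np.ndarray, n_bins: int = 25) -> "LookupCurve":
        x, y = np.asarray(x, float), np.asarray(y, float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 4:
            raise ValueError("too few points to fit a lookup curve")
        edges = np.linspace(x.min(), x.max(), min(n_bins, max(2, x.size // 4)) + 1)
        idx = np.clip(np.digitize(x, edges) - 1, 0, edges.size - 2)
        centers, med, lo, hi = [], [], [], []
        for b in range(edges.size - 1):
            yb = y[idx == b]
            if yb.size == 0:
                continue
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            med.append(np.median(yb))
            lo.append(np.percentile(yb, 5))
            hi.append(np.percentile(yb, 95))
        return cls(np.array(centers), np.array(med), np.array(lo), np.array(hi))

    def __call__(self, x) -> np.ndarray | float:
        out = np.interp(x, self.x, self.median)
        return float(out) if np.ndim(x) == 0 else out

    def band(self, x) -> tuple:
        return np.interp(x, self.x, self.lo), np.interp(x, self.x, self.hi)

    def half_width(self) -> float:
        """Median half-width of the envelope band, a fallback threshold."""
        return float(np.median(self.hi - self.lo) / 2.0)

    def to_dict(self) -> dict:
        return {k: getattr(self, k).tolist() for k in ("x", "median", "lo", "hi")}

    @classmethod
    def from_dict(cls, d: dict) -> "LookupCurve":
        return cls(**{k: np.asarray(v, float) for k, v in d.items()})


@dataclass
class Thresholds:
    """Acceptance half-widths for the checkpoint band comparisons.

    ``dynr0_nc`` and ``dynr0_ib`` are in DynR (log10-dose) units; ``tip`` is
    in log10-time units.
    """

    dynr0_nc: float
    dynr0_ib: float
    tip: float
    calibrated_at_r0: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.dynr0_nc, self.dynr0_ib, self.tip) <= 0:
            raise ValueError("thresholds must be strictly positive")

    def scaled_for(self, r0: Optional[int]) -> "Thresholds":
        """Bands matched to a dataset's noise level.

        The bands are tolerance regions for feature-estimation error, whose
        stochastic component scales like the binomial occupancy noise,
        ~1/sqrt(R0).  Applying bands calibrated at one receptor count to
        noisier data therefore widens them by sqrt(r0_cal / r0_data); data
        at or above the calibration count (or deterministic data) keeps the
        calibrated bands unchanged.
        """
        if (
            self.calibrated_at_r0 is None
            or r0 is None
            or r0 >= self.calibrated_at_r0
        ):
            return self
        s = float(np.sqrt(self.calibrated_at_r0 / r0))
        return Thresholds(
            dynr0_nc=self.dynr0_nc * s,
            dynr0_ib=self.dynr0_ib * s,
            tip=self.tip * s,
            calibrated_at_r0=self.calibrated_at_r0,
        )


@dataclass
class ManifoldDatabase:
    """Paired feature tables, lookup curves, and calibrated thresholds."""

    pairs: list[ManifoldPair]
    features: pd.DataFrame  # one row per (pair, model)
    dynr0_nc: LookupCurve
    dynr0_ib: LookupCurve
    tip_nc: LookupCurve
    thresholds: Thresholds
    meta: dict = field(default_factory=dict)

    def predict_dynr0_nc(self, omega: float) -> float:
        return float(self.dynr0_nc(np.log10(np.clip(omega, 1e-12, None))))

    def predict_dynr0_ib(self, ratio: float) -> float:
        return float(self.dynr0_ib(abs(np.log10(ratio))))

    def predict_log_tip_nc(self, l: float) -> float:
        return float(self.tip_nc(np.log10(l)))

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = [
            {
                "k": p.nc.k, "l": p.nc.l, "omega": p.nc.omega,
                "k10": p.ib.k10, "k01": p.ib.k01,
                "l10": p.ib.l10, "l01": p.ib.l01,
            }
            for p in self.pairs
        ]
        pd.DataFrame(rows).to_csv(directory / "pairs.csv", index=False)
        self.features.to_csv(directory / "features.csv", index=False)
        payload = {
            "lookups": {
                "dynr0_nc": self.dynr0_nc.to_dict(),
                "dynr0_ib": self.dynr0_ib.to_dict(),
                "tip_nc": self.tip_nc.to_dict(),
            },
            "thresholds": {
                "dynr0_nc": self.thresholds.dynr0_nc,
                "dynr0_ib": self.thresholds.dynr0_ib,
                "tip": self.thresholds.tip,
                "calibrated_at_r0": self.thresholds.calibrated_at_r0,
            },
            "meta": self.meta,
        }
        (directory / "lookups.json").write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "ManifoldDatabase":
        directory = Path(directory)
        params = pd.read_csv(directory / "pairs.csv")
        pairs = [
            ManifoldPair(
                nc=NCParams(k=r.k, l=r.l, omega=r.omega),
                ib=IBParams(k10=r.k10, k01=r.k01, l10=r.l10, l01=r.l01),
            )
            for r in params.itertuples()
        ]
        payload = json.loads((directory / "lookups.json").read_text())
        thr = payload["thresholds"]
        return cls(
            pairs=pairs,
            features=pd.read_csv(directory / "features.csv"),
            dynr0_nc=LookupCurve.from_dict(payload["lookups"]["dynr0_nc"]),
            dynr0_ib=LookupCurve.from_dict(payload["lookups"]["dynr0_ib"]),
            tip_nc=LookupCurve.from_dict(payload["lookups"]["tip_nc"]),
            thresholds=Thresholds(
                dynr0_nc=thr["dynr0_nc"], dynr0_ib=thr["dynr0_ib"],
                tip=thr["tip"], calibrated_at_r0=thr["calibrated_at_r0"],
            ),
            meta=payload.get("meta", {}),
        )


def _feature_row(pair_index: int, pair: ManifoldPair, model_tag: str, curve) -> dict:
    model = pair.nc if model_tag == "NC" else pair.ib
    return {
        "pair": pair_index,
        "model": model_tag,
        "omega": pair.omega,
        "l": pair.nc.l,
        "log_ratio": np.log10(pair.ib.ratio),
        "dynr0": curve.dynr_initial,
        "dynr0_reliable": curve.dynr_initial_reliable,
        "dynr_final": curve.dynr_final,
        "final_time_valid": bool(curve.valid[-1]),
        "t_ip": curve.t_ip,
        "shape": curve.shape,
    }


def build_database(
    pairs: Sequence[ManifoldPair],
    grid: Optional[SimulationGrid] = None,
    thresholds: Optional[Thresholds] = None,
) -> ManifoldDatabase:
    """Simulate every pair deterministically and fit the lookup curves.

    The default grid (200 log-spaced doses over [1e-3, 1e8], 60 log-spaced
    times over [1e-4, 1e4]) is wide enough that the top dose saturates and
    the earliest times sit on the DynR(t→0) plateau for all scanned rates.
    Feature-extraction failures are recorded per pair, not fatal.
    """
    if grid is None:
        grid = SimulationGrid(default_doses(), default_times())
    rows = []
    for i, pair in enumerate(pairs):
        for tag, model in (("NC", pair.nc), ("IB", pair.ib)):
            try:
                curve = target_curve(simulate_ode(model, grid))
                rows.append(_feature_row(i, pair, tag, curve))
            except (ValueError, RuntimeError) as exc:
                rows.append(
                    {"pair": i, "model": tag, "omega": pair.omega,
                     "l": pair.nc.l, "log_ratio": np.log10(pair.ib.ratio),
                     "error": str(exc)}
                )
    features = pd.DataFrame(rows)
    usable = features.dynr0.notna() & features.get("dynr0_reliable", True)
    nc_rows = features[(features.model == "NC") & usable]
    ib_rows = features[(features.model == "IB") & usable]
    tip_rows = nc_rows[nc_rows.t_ip.notna()]
    dynr0_nc = LookupCurve.fit(np.log10(nc_rows.omega), nc_rows.dynr0)
    dynr0_ib = LookupCurve.fit(np.abs(ib_rows.log_ratio), ib_rows.dynr0)
    tip_nc = LookupCurve.fit(np.log10(tip_rows.l), np.log10(tip_rows.t_ip))
    if thresholds is None:
        thresholds = Thresholds(
            dynr0_nc=dynr0_nc.half_width(),
            dynr0_ib=dynr0_ib.half_width(),
            tip=tip_nc.half_width(),
        )
    return ManifoldDatabase(
        pairs=list(pairs),
        features=features,
        dynr0_nc=dynr0_nc,
        dynr0_ib=dynr0_ib,
        tip_nc=tip_nc,
        thresholds=thresholds,
        meta={"n_pairs": len(pairs), "n_doses": int(grid.doses.size),
              "n_times": int(grid.times.size)},
    )


def calibrate_thresholds(
    db: ManifoldDatabase,
    r0: Optional[int] = 1000,
    n_cal: int = 40,
    seed: int = 0,
    grid: Optional[SimulationGrid] = None,
    n_candidates: int = 20,
) -> Thresholds:
    """Choose checkpoint thresholds by grid search on simulated data.

    Draws ``n_cal`` fresh manifold pairs, simulates both members at receptor
    count ``r0`` (deterministically if ``r0`` is None), runs the analysis
    stages once per dataset, then sweeps a log-spaced grid of candidate
    threshold triples and keeps the one maximising balanced classification
    accuracy of the full cascade.  Falls back to envelope half-widths when
    there are too few usable calibration datasets.
    """
    from .checkpoints import analyze  # imported here to avoid a module cycle

    if grid is None:
        grid = SimulationGrid(
            default_doses(20, 1e-3, 1e7), default_times(50), r0=r0
        )
    elif grid.r0 != r0:
        grid = SimulationGrid(grid.doses, grid.times, r0=r0)
    pairs = lhs_scan(n_cal, seed=seed + 104729)
    analyses, truths = [], []
    rng = np.random.default_rng(seed)
    for pair in pairs:
        for truth, model in (("NC", pair.nc), ("IB", pair.ib)):
            try:
                if r0 is None:
                    data = simulate_ode(model, grid)
                else:
                    data = simulate_gillespie(
                        model, grid, seed=int(rng.integers(2**31))
                    )
                analyses.append(analyze(data, db))
                truths.append(truth)
            except (ValueError, RuntimeError):
                continue
    if len(analyses) < 10:
        return Thresholds(
            dynr0_nc=db.dynr0_nc.half_width(),
            dynr0_ib=db.dynr0_ib.half_width(),
            tip=db.tip_nc.half_width(),
            calibrated_at_r0=r0,
        )
    truths_arr = np.array(truths)
    is_nc, is_ib = truths_arr == "NC", truths_arr == "IB"
    # threshold-independent stage outcomes, vectorised over datasets
    tc_v = np.array([a.tc_verdict for a in analyses])
    shape_ib = np.array(
        [a.shape in ("decreasing", "biphasic") for a in analyses]
    )
    shape_bad = np.array([a.shape is None for a in analyses])
    rel = np.array(
        [a.dynr0_reliable and np.isfinite(a.d_dynr0_nc) for a in analyses]
    )
    d_nc_arr = np.array([a.d_dynr0_nc for a in analyses])
    d_ib_arr = np.array([a.d_dynr0_ib for a in analyses])
    d_tip_arr = np.array([a.d_log_tip for a in analyses])
    tip_ok = np.isfinite(d_tip_arr)

    def cascade(dn: float, di: float, dt: float) -> np.ndarray:
        v = tc_v.copy()
        und = v == "undecided"
        v[und & shape_ib] = "IB"
        open_ = und & ~shape_ib & ~shape_bad
        cp2_ib = open_ & rel & (d_nc_arr > dn)
        cp2_nc = open_ & rel & ~(d_nc_arr > dn) & (d_ib_arr > di)
        v[cp2_ib] = "IB"
        v[cp2_nc] = "NC"
        cp3 = open_ & ~cp2_ib & ~cp2_nc
        v[cp3 & tip_ok & (d_tip_arr > dt)] = "IB"
        v[cp3 & tip_ok & ~(d_tip_arr > dt)] = "NC"
        return v

    # Tolerance-region construction: each band is the q-quantile of the
    # TRUE model's feature deviation from the database prediction at this
    # noise level (the NC band must contain NC data, the IB band IB data,
    # the t_ip band NC data).  A free per-band grid search degenerates (it
    # can disable a band outright whenever the TC stage already separates
    # the calibration set), so the search is over the common coverage q.
    d_nc_true = d_nc_arr[is_nc & rel]
    d_ib_true = d_ib_arr[is_ib & rel]
    d_tip_true = d_tip_arr[is_nc & tip_ok]
    if min(d_nc_true.size, d_ib_true.size, d_tip_true.size) < 5:
        return Thresholds(
            dynr0_nc=db.dynr0_nc.half_width(),
            dynr0_ib=db.dynr0_ib.half_width(),
            tip=db.tip_nc.half_width(),
            calibrated_at_r0=r0,
        )
    best, best_score = None, -1.0
    for q in np.linspace(0.5, 0.995, n_candidates):
        dn = max(float(np.quantile(d_nc_true, q)), 1e-3)
        di = max(float(np.quantile(d_ib_true, q)), 1e-3)
        dt = max(float(np.quantile(d_tip_true, q)), 1e-3)
        v = cascade(dn, di, dt)
        score = float(
            0.5 * np.mean(v[is_nc] == "NC") + 0.5 * np.mean(v[is_ib] == "IB")
        )
        if score > best_score:
            best, best_score = (dn, di, dt), score
    return Thresholds(*best, calibrated_at_r0=r0)
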