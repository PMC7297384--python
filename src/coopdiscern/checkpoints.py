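"""The TC+DR decision cascade: C score first, then target-curve checkpoints.

When the constrained kinetic fits alone cannot separate the models (C between
1/3 and 2/3), three sequential checkpoints interrogate the DynR-versus-time
target curve:

1. **shape** — a decreasing or biphasic target curve can only come from IB
   (the NC database is exclusively increasing);
2. **DynR(t→0)** — compare the observed early-time dynamic range with the
   database prediction at the fitted omega (NC band; a miss means IB) and
   then at the fitted k10/k01 (IB band; a miss means NC);
3. **t_ip** — compare the observed inflection time with the NC database
   prediction at the fitted unbinding rate l, on a log10-time axis.  This
   checkpoint is terminal: inside the band means NC, outside means IB.  The
   terminal NC conclusion is the cascade's only systematic failure mode (IB
   data that mimics NC through every band).

Every stage logs the quantities it compared, so a Decision carries a full
audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .database import ManifoldDatabase, Thresholds
from .kinetics import TimeCourseDataset
from .metrics import TargetCurve, target_curve
from .tc import TCFitResult, run_tc, tc_decide

__all__ = [
    "Analysis",
    "Decision",
    "analyze",
    "checkpoint1",
    "checkpoint2",
    "checkpoint3",
    "decide_from_analysis",
    "discriminate",
]


@dataclass
class Analysis:
    """Threshold-independent quantities extracted once per dataset."""

    tc: TCFitResult
    curve: Optional[TargetCurve]  # None when no EC pair was extractable
    # absolute deviations from the database predictions (nan when undefined)
    d_dynr0_nc: float
    d_dynr0_ib: float
    d_log_tip: float
    r0: Optional[int] = None  # receptor count of the analysed dataset

    @property
    def tc_verdict(self) -> str:
        return tc_decide(self.tc.C)

    @property
    def shape(self) -> Optional[str]:
        return self.curve.shape if self.curve is not None else None

    @property
    def dynr0_reliable(self) -> bool:
        return self.curve is not None and self.curve.dynr_initial_reliable


@dataclass
class Decision:
    """Cascade verdict with an audit trail of every traversed stage."""

    verdict: str  # "IB" | "NC" | "undecided"
    path: list[dict] = field(default_factory=list)
    analysis: Optional[Analysis] = None

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "path": self.path,
            "tc": self.analysis.tc.to_dict() if self.analysis else None,
        }


def analyze(data: TimeCourseDataset, db: ManifoldDatabase) -> Analysis:
    """Run the TC fits and target-curve feature extraction for one dataset.

    A dataset whose dose range never brackets the EC levels has no target
    curve; the TC fits still run and the checkpoints degrade gracefully.
    """
    tc = run_tc(data)
    try:
        curve = target_curve(data)
    except ValueError:
        curve = None
    d_nc = d_ib = d_tip = float("nan")
    if curve is not None:
        if np.isfinite(curve.dynr_initial) and curve.dynr_initial_reliable:
            d_nc = abs(curve.dynr_initial - db.predict_dynr0_nc(tc.omega_hat))
            d_ib = abs(curve.dynr_initial - db.predict_dynr0_ib(tc.ratio_hat))
        if np.isfinite(curve.t_ip) and curve.t_ip > 0:
            d_tip = abs(np.log10(curve.t_ip) - db.predict_log_tip_nc(tc.l_hat))
    return Analysis(tc=tc, curve=curve, d_dynr0_nc=d_nc, d_dynr0_ib=d_ib,
                    d_log_tip=d_tip, r0=data.grid.r0)


def checkpoint1(shape: Optional[str]) -> str:
    """Shape test: decreasing/biphasic → IB; increasing → continue."""
    if shape in ("decreasing", "biphasic"):
        return "IB"
    if shape == "increasing":
        return "continue"
    return "undecided"


def checkpoint2(
    d_dynr0_nc: float, d_dynr0_ib: float, reliable: bool, thresholds: Thresholds
) -> str:
    """Early-DynR band test.

    Outside the NC band at the fitted omega → IB; inside it but outside the
    IB band at the fitted k10/k01 → NC; inside both → continue.  Skipped when
    DynR(t→0) could not be reliably estimated.
    """
    if not reliable or not np.isfinite(d_dynr0_nc):
        return "skip"
    if d_dynr0_nc > thresholds.dynr0_nc:
        return "IB"
    if d_dynr0_ib > thresholds.dynr0_ib:
        return "NC"
    return "continue"


def checkpoint3(d_log_tip: float, thresholds: Thresholds) -> str:
    """Terminal inflection-time test: outside the band → IB, inside → NC."""
    if not np.isfinite(d_log_tip):
        return "undecided"
    return "IB" if d_log_tip > thresholds.tip else "NC"


def decide_from_analysis(
    analysis: Analysis,
    db: ManifoldDatabase,
    thresholds: Optional[Thresholds] = None,
) -> Decision:
    """Apply the full cascade to precomputed analysis quantities.

    Bands are noise-matched to the dataset via ``Thresholds.scaled_for``.
    """
    thr = thresholds if thresholds is not None else db.thresholds
    thr = thr.scaled_for(analysis.r0)
    path: list[dict] = []
    tc_verdict = analysis.tc_verdict
    path.append({"stage": "tc", "C": analysis.tc.C, "verdict": tc_verdict})
    if tc_verdict != "undecided":
        return Decision(verdict=tc_verdict, path=path, analysis=analysis)

    cp1 = checkpoint1(analysis.shape)
    path.append({"stage": "cp1", "shape": analysis.shape, "verdict": cp1})
    if cp1 in ("IB", "undecided"):
        return Decision(verdict=cp1, path=path, analysis=analysis)

    cp2 = checkpoint2(
        analysis.d_dynr0_nc,
        analysis.d_dynr0_ib,
        analysis.dynr0_reliable,
        thr,
    )
    path.append(
        {
            "stage": "cp2",
            "dynr0_data": analysis.curve.dynr_initial if analysis.curve else None,
            "d_dynr0_nc": analysis.d_dynr0_nc,
            "d_dynr0_ib": analysis.d_dynr0_ib,
            "band_nc": thr.dynr0_nc,
            "band_ib": thr.dynr0_ib,
            "verdict": cp2,
        }
    )
    if cp2 in ("IB", "NC"):
        return Decision(verdict=cp2, path=path, analysis=analysis)

    cp3 = checkpoint3(analysis.d_log_tip, thr)
    path.append(
        {
            "stage": "cp3",
            "t_ip_data": analysis.curve.t_ip if analysis.curve else None,
            "d_log_tip": analysis.d_log_tip,
            "band_tip": thr.tip,
            "verdict": cp3,
        }
    )
    return Decision(verdict=cp3, path=path, analysis=analysis)


def discriminate(
    data: TimeCourseDataset,
    db: ManifoldDatabase,
    thresholds: Optional[Thresholds] = None,
) -> Decision:
    """End-to-end IB/NC discrimination of one occupancy dataset.

    Deterministic given data, database and thresholds; every traversed stage
    and the quantities it compared are recorded in ``Decision.path``.
    """
    return decide_from_analysis(analyze(data, db), db, thresholds)
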