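"""File formats and run configuration.

Occupancy data travels as long-format CSV (comma-separated, ``.`` decimal,
mandatory header ``time,ligand,theta``) with an optional JSON sidecar holding
provenance — the long format loads ragged dose/time coverage (as exported by
SPR instruments) cleanly; missing cells are masked as NaN.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .kinetics import SimulationGrid, TimeCourseDataset

__all__ = ["read_timecourse", "write_timecourse", "RunConfig"]

_COLUMNS = ["time", "ligand", "theta"]


def write_timecourse(data: TimeCourseDataset, path: str | Path) -> None:
    """Write theta(L, t) as long-format CSV plus a JSON provenance sidecar."""
    path = Path(path)
    doses, times = data.grid.doses, data.grid.times
    frame = pd.DataFrame(
        {
            "time": np.repeat(times, doses.size),
            "ligand": np.tile(doses, times.size),
            "theta": data.theta.T.ravel(),
        }
    )
    frame.to_csv(path, index=False)
    sidecar = {"r0": data.grid.r0, **data.provenance}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, default=str))


def read_timecourse(path: str | Path) -> TimeCourseDataset:
    """Read a long-format occupancy table back into a dataset.

    Validates the header, numeric cells and theta range (reporting the first
    offending row), pivots onto the sorted (dose x time) grid, and masks
    missing cells as NaN.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: malformed header, missing columns {missing}")
    for col in _COLUMNS:
        bad = pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based incl. header
            raise ValueError(f"{path}: non-numeric value in '{col}' at line {row}")
        frame[col] = pd.to_numeric(frame[col])
    out_of_range = (frame["theta"] < 0) | (frame["theta"] > 1)
    if out_of_range.any():
        row = int(np.flatnonzero(out_of_range)[0]) + 2
        raise ValueError(f"{path}: theta out of [0, 1] at line {row}")
    pivot = frame.pivot_table(index="ligand", columns="time", values="theta")
    pivot = pivot.sort_index(axis=0).sort_index(axis=1)
    r0 = None
    sidecar = path.with_suffix(".json")
    provenance: dict = {}
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text())
        r0 = provenance.pop("r0", None)
        r0 = int(r0) if r0 is not None else None
    grid = SimulationGrid(
        doses=pivot.index.to_numpy(float),
        times=pivot.columns.to_numpy(float),
        r0=r0,
    )
    return TimeCourseDataset(theta=pivot.to_numpy(float), grid=grid,
                             provenance=provenance)


@dataclass
class RunConfig:
    """Validated run configuration shared by the CLI commands."""

    dose_min: float = 1e-3
    dose_max: float = 1e7
    n_doses: int = 20
    time_min: float = 1e-4
    time_max: float = 1e4
    n_times: int = 50
    r0: Optional[int] = None
    seed: int = 0
    smoothing_window: int = 5
    database_path: Optional[str] = None
    threshold_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dose_min <= 0 or self.dose_max <= self.dose_min:
            raise ValueError("need 0 < dose_min < dose_max")
        if self.time_min <= 0 or self.time_max <= self.time_min:
            raise ValueError("need 0 < time_min < time_max")
        if self.n_doses < 5 or self.n_times < 5:
            raise ValueError("need at least 5 doses and 5 times")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")

    def grid(self) -> SimulationGrid:
        doses = np.logspace(
            np.log10(self.dose_min), np.log10(self.dose_max), self.n_doses
        )
        times = np.concatenate(
            [[0.0], np.logspace(np.log10(self.time_min), np.log10(self.time_max),
                                self.n_times)]
        )
        return SimulationGrid(doses, times, r0=self.r0)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        obj = yaml.safe_load(text) or {}
        return cls(**obj)

    def hash(self) -> str:
        """Short provenance hash of the canonical configuration."""
        canonical = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
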