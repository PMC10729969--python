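"""Optical-density growth curves and the instrument conventions around them.

OD600 is a turbidity proxy for cell density: on the reference
instrument 1 OD corresponds to roughly 7e7 cells/ml, readings below 0.001 are
below the machine's sensitivity (and are clamped to 0.001), and the
OD–density relationship is nonlinear above OD 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .units import CELLS_PER_OD, OD_LINEAR_LIMIT, OD_SENSITIVITY_FLOOR

__all__ = [
    "GrowthCurve",
    "NonlinearityMap",
    "od_to_cells",
    "cells_to_od",
    "apply_sensitivity_floor",
    "read_growth_csv",
    "write_growth_csv",
]


def od_to_cells(od):
    """Convert OD600 to cells/ml via the linear calibration 1 OD = 7e7 cells/ml."""
    od = np.asarray(od, dtype=float)
    if np.any(od < 0):
        raise ValueError("OD must be >= 0")
    out = od * CELLS_PER_OD
    return float(out) if out.ndim == 0 else out


def cells_to_od(cells):
    """Inverse of :func:`od_to_cells`."""
    cells = np.asarray(cells, dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell density must be >= 0")
    out = cells / CELLS_PER_OD
    return float(out) if out.ndim == 0 else out


def apply_sensitivity_floor(od, floor: float = OD_SENSITIVITY_FLOOR):
    """Clamp OD readings below the instrument sensitivity up to the floor.

    Elementwise ``max(od, floor)``; idempotent and order-preserving.
    """
    od = np.asarray(od, dtype=float)
    if np.any(od < 0):
        raise ValueError("OD must be >= 0")
    out = np.maximum(od, floor)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class NonlinearityMap:
    """Monotone correction from measured OD to linear-equivalent OD.

    The instrument under-reports density above ``breakpoint``; a
    calibration table of (measured, corrected) pairs defines a
    piecewise-linear correction there.  Below the breakpoint the map is
    the identity, and with no table it is the identity everywhere (a
    warning is emitted when readings above the breakpoint are passed
    through uncorrected — a fabricated correction would be worse than
    none).
    """

    table: tuple[tuple[float, float], ...] = ()
    breakpoint: float = OD_LINEAR_LIMIT

    def __post_init__(self) -> None:
        if self.table:
            meas = np.array([m for m, _ in self.table])
            corr = np.array([c for _, c in self.table])
            if np.any(np.diff(meas) <= 0) or np.any(np.diff(corr) < 0):
                raise ValueError("calibration table must be monotone in both columns")

    def __call__(self, od):
        od = np.asarray(od, dtype=float)
        if np.any(od < 0):
            raise ValueError("OD must be >= 0")
        if not self.table:
            if np.any(od > self.breakpoint):
                warnings.warn(
                    f"OD readings above {self.breakpoint} passed through an "
                    "identity nonlinearity map; supply a calibration table "
                    "for corrected high-OD values",
                    stacklevel=2,
                )
            out = od.copy()
        else:
            meas = np.array([m for m, _ in self.table])
            corr = np.array([c for _, c in self.table])
            out = np.where(
                od <= self.breakpoint, od, np.interp(od, meas, corr)
            )
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GrowthCurve:
    """One observed OD600 time series with sample metadata."""

    sample_id: str
    times: np.ndarray          # hours since inoculation, strictly increasing
    od: np.ndarray             # OD600 readings
    strain: str = ""
    x0_nominal: float | None = None  # intended inoculum density, OD units
    sealed: bool | None = None
    vessel: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        if len(t) != len(od):
            raise ValueError(f"sample {self.sample_id!r}: times/od length mismatch")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"sample {self.sample_id!r}: times not strictly increasing")
        if np.any(od < 0):
            raise ValueError(f"sample {self.sample_id!r}: negative OD")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", od)

    def floored(self) -> "GrowthCurve":
        """Copy with the instrument sensitivity floor applied to the ODs."""
        return GrowthCurve(
            sample_id=self.sample_id,
            times=self.times,
            od=apply_sensitivity_floor(self.od),
            strain=self.strain,
            x0_nominal=self.x0_nominal,
            sealed=self.sealed,
            vessel=self.vessel,
        )


_REQUIRED = ("sample_id", "time_h", "od")
_OPTIONAL_META = ("strain", "x0_nominal", "sealed", "vessel")


def read_growth_csv(path, *, blank_column: str | None = None) -> list[GrowthCurve]:
    """Read long-format growth curves (sample_id, time_h, od [+metadata]).

    Rows are grouped by ``sample_id`` and sorted by time.  If
    ``blank_column`` names a column, its value is subtracted from ``od``
    row-wise (a constant-blank scheme); by default no blanking is done.
    Duplicate (sample, time) rows and non-numeric fields are parse errors
    naming the offending sample.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if blank_column is not None:
        if blank_column not in df.columns:
            raise ValueError(f"{path}: no blank column {blank_column!r}")
        df = df.assign(od=df["od"] - df[blank_column])
    curves = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("time_h")
        if grp["time_h"].duplicated().any():
            raise ValueError(f"{path}: duplicated time point in sample {sid!r}")
        meta = {}
        for col in _OPTIONAL_META:
            if col in grp.columns:
                val = grp[col].iloc[0]
                if pd.notna(val):
                    meta[col] = bool(val) if col == "sealed" else val
        curves.append(
            GrowthCurve(
                sample_id=str(sid),
                times=grp["time_h"].to_numpy(float),
                od=grp["od"].to_numpy(float),
                **meta,
            )
        )
    return curves


def write_growth_csv(curves: list[GrowthCurve], path) -> None:
    """Write curves in the long format that :func:`read_growth_csv` reads."""
    frames = []
    for c in curves:
        d = pd.DataFrame({"sample_id": c.sample_id, "time_h": c.times, "od": c.od})
        if c.strain:
            d["strain"] = c.strain
        if c.x0_nominal is not None:
            d["x0_nominal"] = c.x0_nominal
        if c.sealed is not None:
            d["sealed"] = c.sealed
        if c.vessel:
            d["vessel"] = c.vessel
        frames.append(d)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
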