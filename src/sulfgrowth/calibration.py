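"""Parameter measurement and inference for the population–sulfide model.

Three parameters are measured directly from standard experiments:

* ``g_max`` — slope of ln(OD) against time, restricted to the OD window
  where the instrument is linear and growth is exponential (0.1–0.5);
* ``c`` — through-origin slope of added sulfide dose against the cell
  yield it supports (Δx = dose / c after unit conversion);
* ``K`` — stationary-phase OD, corrected for instrument nonlinearity
  and converted to cells/ml.

The remaining two, the release rate ``r`` and the effective Monod
constant ``k_s``, are inferred by least squares on ln(OD): growth curves
started at several inoculum densities are jointly fit to the simulated
model with the measured parameters held fixed, using deterministic
multi-start bounded local optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .model import IntegrationError, ModelParams, SimulationSpec, simulate
from .od_data import GrowthCurve, NonlinearityMap, apply_sensitivity_floor, od_to_cells
from .units import CELLS_PER_OD, UM_PER_FMOLE_PER_ML

__all__ = [
    "DoseYieldTable",
    "FitResult",
    "estimate_growth_rate",
    "estimate_consumption_c",
    "predict_yield",
    "estimate_K",
    "infer_r_ks",
    "InsufficientDataError",
]

#: Default search box for the inferred parameters (log-uniform starts).
R_BOUNDS = (1e-3, 10.0)     # fmole/cell/h
KS_BOUNDS = (1e-2, 1e3)     # μM

#: Profile-curvature ratio below which k_s is flagged as poorly identified.
IDENTIFIABILITY_THRESHOLD = 1e-2


class InsufficientDataError(ValueError):
    """Raised when a curve or table has too few usable points for a fit."""


@dataclass(frozen=True)
class DoseYieldTable:
    """Rows of (sulfide dose added, increase in cell density supported)."""

    dose_uM: np.ndarray          # μM sulfide added
    delta_density: np.ndarray    # cells/ml gained

    def __post_init__(self) -> None:
        d = np.asarray(self.dose_uM, dtype=float)
        y = np.asarray(self.delta_density, dtype=float)
        if len(d) != len(y):
            raise ValueError("dose and yield columns must have equal length")
        if np.any(d < 0):
            raise ValueError("doses must be >= 0")
        object.__setattr__(self, "dose_uM", d)
        object.__setattr__(self, "delta_density", y)


@dataclass
class FitResult:
    """Outcome of a model fit: estimates, objective value and diagnostics."""

    params: dict[str, float]
    sse: float
    n_points: int
    converged: bool
    starts_tried: int = 1
    poorly_identified: bool = False
    start_results: list = field(default_factory=list)


def estimate_growth_rate(
    curve: GrowthCurve, od_window: tuple[float, float] = (0.1, 0.5)
) -> float:
    """Maximal growth rate as the OLS slope of ln(OD) vs time, in 1/h.

    Only readings with OD inside ``od_window`` (inclusive) are used:
    below it growth may not yet be exponential, above it the instrument
    response is nonlinear.

    Raises
    ------
    InsufficientDataError
        If fewer than 3 readings fall inside the window.
    """
    lo, hi = od_window
    mask = (curve.od >= lo) & (curve.od <= hi)
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"sample {curve.sample_id!r}: only {int(mask.sum())} OD readings in "
            f"[{lo}, {hi}]; need >= 3"
        )
    res = stats.linregress(curve.times[mask], np.log(curve.od[mask]))
    return float(res.slope)


def estimate_consumption_c(table: DoseYieldTable) -> float:
    """Sulfide consumed per cell birth, in fmole/cell.

    Fits the through-origin relation Δx = dose / c by least squares:
    the slope b of Δx on dose (in fmole/ml) is 1/c.  A zero-dose,
    zero-yield row does not affect the fit.
    """
    dose_fm = table.dose_uM / UM_PER_FMOLE_PER_ML  # μM -> fmole/ml
    denom = float(np.sum(dose_fm**2))
    if denom == 0.0:
        raise ValueError("all doses are zero; consumption is not identifiable")
    slope = float(np.sum(dose_fm * table.delta_density)) / denom  # cells per fmole
    if slope <= 0:
        raise ValueError("non-positive dose-yield slope; cannot form c")
    return 1.0 / slope


def predict_yield(dose_uM: float, c: float) -> float:
    """Forward prediction: cell-density increase supported by a sulfide dose."""
    return dose_uM / UM_PER_FMOLE_PER_ML / c


def estimate_K(
    stationary_ods: list[float],
    calibration: NonlinearityMap | None = None,
) -> float:
    """Carrying capacity from stationary-phase OD readings, in cells/ml.

    Each OD is corrected for instrument nonlinearity, the corrected
    values are averaged, and the mean is converted with 1 OD = 7e7
    cells/ml.
    """
    ods = np.asarray(stationary_ods, dtype=float)
    if ods.size == 0:
        raise ValueError("need at least one stationary-phase OD reading")
    calibration = calibration or NonlinearityMap()
    corrected = np.asarray(calibration(ods), dtype=float)
    return od_to_cells(float(corrected.mean()))


def _joint_sse(
    log10_rk: np.ndarray,
    curves: list[GrowthCurve],
    fixed: dict[str, float],
    solver_rel_tol: float,
) -> float:
    """Sum over curves of squared ln(OD) residuals for candidate (r, k_s)."""
    r, k_s = 10.0 ** log10_rk
    try:
        p = ModelParams(
            g_max=fixed["g_max"], k_s=k_s, r=r, c=fixed["c"], K=fixed["K"],
            delta=fixed.get("delta", 0.0),
        )
    except ValueError:
        return np.inf
    sse = 0.0
    for curve in curves:
        x0_od = curve.x0_nominal if curve.x0_nominal is not None else curve.od[0]
        try:
            traj = simulate(
                p,
                SimulationSpec(
                    x0=x0_od * CELLS_PER_OD,
                    t_end=float(curve.times[-1]),
                    n_points=max(len(curve.times), 101),
                    rel_tol=solver_rel_tol,
                    abs_tol=solver_rel_tol * 1e-2,
                ),
            )
        except IntegrationError:
            return np.inf
        # interpolate on ln(x): exact under locally exponential growth
        model_od = (
            np.exp(np.interp(curve.times, traj.times, np.log(traj.x))) / CELLS_PER_OD
        )
        obs = apply_sensitivity_floor(curve.od)
        resid = np.log(obs) - np.log(np.maximum(model_od, 1e-300))
        sse += float(np.sum(resid**2))
    return sse


def infer_r_ks(
    curves: list[GrowthCurve],
    fixed: dict[str, float],
    *,
    bounds: tuple[tuple[float, float], tuple[float, float]] = (R_BOUNDS, KS_BOUNDS),
    n_starts: int = 16,
    seed: int = 0,
    solver_rel_tol: float = 1e-7,
) -> FitResult:
    """Infer (r, k_s) by multi-start least squares on ln(OD).

    The objective is the joint sum of squared residuals between the
    logged (floor-applied) observed ODs and the logged model ODs, over
    all curves and timepoints, with ``g_max``, ``c``, ``K`` and
    ``delta`` held at the values in ``fixed``.  Optimization runs in
    log10-parameter space (both parameters are positive scale
    parameters) from ``n_starts`` log-uniform starting points drawn
    deterministically from ``seed``, using bounded L-BFGS-B.

    The returned :class:`FitResult` flags poor identifiability when the
    objective's profile curvature in log k_s is below 1e-2 of that in
    log r — the situation of, e.g., a single dense inoculum whose curve
    shows no lag, which constrains r but barely constrains k_s.
    """
    if not curves:
        raise InsufficientDataError("need at least one growth curve")
    (r_lo, r_hi), (ks_lo, ks_hi) = bounds
    log_bounds = [
        (np.log10(r_lo), np.log10(r_hi)),
        (np.log10(ks_lo), np.log10(ks_hi)),
    ]
    rng = np.random.default_rng(seed)
    starts = np.column_stack(
        [rng.uniform(lo, hi, size=n_starts) for lo, hi in log_bounds]
    )
    n_points = int(sum(len(c.times) for c in curves))

    best = None
    start_results = []
    for x0 in starts:
        res = optimize.minimize(
            _joint_sse,
            x0,
            args=(curves, fixed, solver_rel_tol),
            method="L-BFGS-B",
            bounds=log_bounds,
        )
        start_results.append(
            {"start": tuple(10.0**x0), "fun": float(res.fun), "success": bool(res.success)}
        )
        if res.success and np.isfinite(res.fun):
            if best is None or res.fun < best.fun:
                best = res

    if best is None:
        return FitResult(
            params={"r": np.nan, "k_s": np.nan},
            sse=np.inf,
            n_points=n_points,
            converged=False,
            starts_tried=n_starts,
            start_results=start_results,
        )

    r_hat, ks_hat = 10.0**best.x
    # Profile curvatures by central finite differences in log10 space.
    h = 0.05
    f0 = float(best.fun)

    def _curv(axis: int) -> float:
        e = np.zeros(2)
        e[axis] = h
        fp = _joint_sse(best.x + e, curves, fixed, solver_rel_tol)
        fm = _joint_sse(best.x - e, curves, fixed, solver_rel_tol)
        return max((fp - 2 * f0 + fm) / h**2, 0.0)

    curv_r, curv_ks = _curv(0), _curv(1)
    poorly = curv_r > 0 and (curv_ks / curv_r) < IDENTIFIABILITY_THRESHOLD

    return FitResult(
        params={"r": float(r_hat), "k_s": float(ks_hat)},
        sse=f0,
        n_points=n_points,
        converged=True,
        starts_tried=n_starts,
        poorly_identified=poorly,
        start_results=start_results,
    )
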