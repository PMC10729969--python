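"""Synthetic data with the statistical structure the analysis assumes.

Generators for the three experiment designs the pipeline consumes:
Monod-limited growth curves at a range of inoculum densities (with
multiplicative OD noise and the 0.001 instrument floor), linear
cell-yield versus sulfide-dose tables, and two-genotype coculture count
series with additive genotype + fluorophore rate effects and Poisson
counting noise.  All generators are deterministic given their seed, and
with noise switched off their outputs are exact fixed points of the
corresponding estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import DoseYieldTable
from .competition import CompetitionSeries
from .model import ModelParams, SimulationSpec, simulate
from .od_data import GrowthCurve, apply_sensitivity_floor
from .units import CELLS_PER_OD, UM_PER_FMOLE_PER_ML

__all__ = [
    "NoiseSpec",
    "gen_growth_curves",
    "gen_dose_yield",
    "gen_competition",
    "gen_delta_ensemble",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model for synthetic observations.

    OD readings carry multiplicative lognormal noise with coefficient of
    variation ``od_cv`` (default 5%, a typical tube-spectrophotometer
    repeatability); cytometry events are Poisson.  ``seed`` makes every
    generator bit-reproducible.
    """

    od_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.od_cv < 0:
            raise ValueError("od_cv must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


def gen_growth_curves(
    p: ModelParams,
    x0_list_od: list[float],
    sample_times: np.ndarray,
    noise: NoiseSpec = NoiseSpec(),
    *,
    strain: str = "met17d",
) -> list[GrowthCurve]:
    """Simulated OD600 growth curves at the given inoculum densities.

    Each curve integrates the population–sulfide model from the OD
    equivalent of ``x0`` (cells/ml via 1 OD = 7e7 cells/ml), converts
    density back to OD, applies lognormal noise and then the 0.001
    sensitivity floor.  The nominal inoculum is recorded in the curve
    metadata as the generating truth.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    rng = noise.rng()
    curves = []
    for i, x0_od in enumerate(x0_list_od):
        traj = simulate(
            p,
            SimulationSpec(
                x0=x0_od * CELLS_PER_OD,
                t_end=float(sample_times[-1]),
                n_points=max(len(sample_times) * 4, 401),
            ),
        )
        x = np.exp(np.interp(sample_times, traj.times, np.log(traj.x)))
        od = x / CELLS_PER_OD
        od = od * _lognormal_factor(rng, noise.od_cv, od.shape)
        od = apply_sensitivity_floor(od)
        curves.append(
            GrowthCurve(
                sample_id=f"x0od{x0_od:g}_rep{i}",
                times=sample_times,
                od=od,
                strain=strain,
                x0_nominal=x0_od,
                sealed=True,
                vessel="tube13mm",
            )
        )
    return curves


def gen_dose_yield(
    c: float,
    doses_uM: list[float],
    yield_cv: float = 0.0,
    seed: int = 0,
) -> DoseYieldTable:
    """Cell yield supported by each sulfide dose: Δx = dose / c (+ noise)."""
    if c <= 0:
        raise ValueError("c must be > 0")
    doses = np.asarray(doses_uM, dtype=float)
    rng = np.random.default_rng(seed)
    delta_x = doses / UM_PER_FMOLE_PER_ML / c
    delta_x = delta_x * _lognormal_factor(rng, yield_cv, delta_x.shape)
    return DoseYieldTable(dose_uM=doses, delta_density=delta_x)


def gen_competition(
    rate_A: float,
    rate_B: float,
    fluor_effects: dict[str, float],
    x0: float,
    times: np.ndarray,
    *,
    bead_conc: float = 1e5,
    sampled_volume_ml: float = 1e-4,
    noise: NoiseSpec = NoiseSpec(),
    n_replicates: int = 3,
    condition: str = "sulfate",
    count_noise: bool = True,
) -> tuple[list[CompetitionSeries], list[CompetitionSeries]]:
    """Two-orientation coculture count series under the additive model.

    Genotypes A and B start at ``x0/2`` cells/ml each and grow
    exponentially; in orientation 1, A carries the red fluorophore and B
    the blue one (rates ``rate_A + fluor_effects['red']`` and
    ``rate_B + fluor_effects['blue']``), and orientation 2 swaps the
    labels.  Expected cell events are density × sampled volume, drawn
    Poisson; bead events are Poisson around ``bead_conc × volume``.
    ``sampled_volume_ml`` defaults to 0.1 μl so that a dense coculture
    yields on the order of 1e4 cell events per sample, the scale at
    which cytometric counting noise becomes negligible.  With
    ``count_noise=False`` the Poisson draws are replaced by their means
    (the infinite-count limit), and the ratio slope recovers
    ``rate_A - rate_B`` exactly.

    Returns ``(orientation1, orientation2)``, each a list of
    ``n_replicates`` series.
    """
    times = np.asarray(times, dtype=float)
    rng = noise.rng()
    expected_beads = bead_conc * sampled_volume_ml

    def _make(orient: str, rep: int) -> CompetitionSeries:
        if orient == "A=red":
            rA = rate_A + fluor_effects["red"]
            rB = rate_B + fluor_effects["blue"]
        else:
            rA = rate_A + fluor_effects["blue"]
            rB = rate_B + fluor_effects["red"]
        dens_A = x0 / 2.0 * np.exp(rA * times)
        dens_B = x0 / 2.0 * np.exp(rB * times)
        if count_noise:
            ev_A = rng.poisson(dens_A * sampled_volume_ml).astype(float)
            ev_B = rng.poisson(dens_B * sampled_volume_ml).astype(float)
            beads = rng.poisson(expected_beads, size=times.shape).astype(float)
            beads = np.maximum(beads, 1.0)
        else:
            ev_A = dens_A * sampled_volume_ml
            ev_B = dens_B * sampled_volume_ml
            beads = np.full(times.shape, expected_beads)
        od = (dens_A + dens_B) / CELLS_PER_OD
        od = od * _lognormal_factor(rng, noise.od_cv, od.shape)
        return CompetitionSeries(
            times=times,
            events_A=ev_A,
            events_B=ev_B,
            bead_events=beads,
            bead_conc=bead_conc,
            od=od,
            condition=condition,
            orientation=orient,
            replicate=rep,
        )

    orient1 = [_make("A=red", k) for k in range(n_replicates)]
    orient2 = [_make("A=blue", k) for k in range(n_replicates)]
    return orient1, orient2


def gen_delta_ensemble(
    p: ModelParams,
    x0_od: float,
    delta_mean: float,
    delta_spread: float,
    n: int,
    seed: int = 0,
    *,
    sample_times: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
) -> tuple[list[GrowthCurve], np.ndarray]:
    """Ensemble of curves, each with an independent sulfide loss rate δ.

    Emulates tube-to-tube variability: small differences in sealing give
    each tube its own gas-escape rate, drawn here from a normal
    distribution truncated at zero.  Lag-time dispersion across the
    ensemble grows as the inoculum density shrinks.  Returns the curves
    and the δ draws used.
    """
    rng = np.random.default_rng(seed)
    deltas = np.maximum(rng.normal(delta_mean, delta_spread, size=n), 0.0)
    if sample_times is None:
        sample_times = np.linspace(0.0, 150.0, 151)
    curves = []
    od_cv = noise.od_cv if noise is not None else 0.0
    base_seed = noise.seed if noise is not None else seed
    for k, d in enumerate(deltas):
        (curve,) = gen_growth_curves(
            p.replace(delta=float(d)), [x0_od], sample_times,
            NoiseSpec(od_cv=od_cv, seed=base_seed + k + 1),
        )
        curves.append(
            GrowthCurve(
                sample_id=f"tube{k}_x0od{x0_od:g}",
                times=curve.times,
                od=curve.od,
                strain=curve.strain,
                x0_nominal=x0_od,
                sealed=True,
                vessel="tube13mm",
            )
        )
    return curves, deltas
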