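"""Coculture competition fitness from bead-calibrated flow-cytometry counts.

Two fluorescently tagged genotypes are cocultured; at each sampling
time, cytometry gives per-genotype cell event counts alongside counting
beads of known concentration, so absolute densities are
``events / bead_events * bead_conc``.  The growth-rate difference
between the genotypes is the OLS slope of the log density ratio over
time, and is reported as a percentage of the coculture's overall growth
rate (from OD).

Because the fluorophore itself can carry a growth cost, each
competition is repeated with the labels swapped.  Under an additive
genotype + fluorophore model, the label effect cancels from the *sum*
of the rate differences measured in the two orientations, which yields
a t-test for a pure genotype effect (see :func:`fluorophore_swap_test`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CompetitionSeries",
    "FitnessEstimate",
    "SwapTestResult",
    "beads_to_density",
    "ratio_slope",
    "percent_fitness",
    "estimate_fitness",
    "fluorophore_swap_test",
    "one_sample_fitness_test",
]


def beads_to_density(cell_events, bead_events, bead_conc):
    """Absolute cell density (cells/ml) from event counts and bead spike-in.

    ``cell_events / bead_events * bead_conc``: the ratio of cell to bead
    events equals the ratio of their densities in the sampled volume.
    """
    cell_events = np.asarray(cell_events, dtype=float)
    bead_events = np.asarray(bead_events, dtype=float)
    if np.any(bead_events <= 0):
        raise ValueError("bead_events must be > 0 at every used timepoint")
    out = cell_events / bead_events * bead_conc
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CompetitionSeries:
    """Count time series for one coculture (one label orientation)."""

    times: np.ndarray        # hours
    events_A: np.ndarray     # cell events, genotype A
    events_B: np.ndarray     # cell events, genotype B
    bead_events: np.ndarray
    bead_conc: float         # beads/ml
    od: np.ndarray           # culture OD600 per timepoint
    condition: str = ""      # e.g. sulfate | methionine | SMM
    orientation: str = ""    # which fluorophore marks which genotype
    replicate: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        arrays = {
            "events_A": np.asarray(self.events_A, dtype=float),
            "events_B": np.asarray(self.events_B, dtype=float),
            "bead_events": np.asarray(self.bead_events, dtype=float),
            "od": np.asarray(self.od, dtype=float),
        }
        for name, a in arrays.items():
            if len(a) != len(t):
                raise ValueError(f"{name} length does not match times")
            if np.any(a < 0):
                raise ValueError(f"{name} has negative entries")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        for name, a in arrays.items():
            object.__setattr__(self, name, a)

    def densities(self):
        """(density_A, density_B) in cells/ml at each timepoint."""
        dA = beads_to_density(self.events_A, self.bead_events, self.bead_conc)
        dB = beads_to_density(self.events_B, self.bead_events, self.bead_conc)
        return dA, dB


@dataclass(frozen=True)
class FitnessEstimate:
    """Growth-rate difference of A over B and its percent-fitness scaling."""

    rate_diff: float       # 1/h, genotype A - genotype B
    total_rate: float      # 1/h, coculture growth rate from OD
    percent_fitness: float  # 100 * rate_diff / total_rate
    n_timepoints: int


def ratio_slope(series: CompetitionSeries) -> float:
    """Growth-rate difference (A - B, 1/h) as the slope of ln(A/B) vs time.

    Timepoints where either genotype has zero events are excluded with a
    warning (the log ratio is undefined there); at least 2 usable
    timepoints are required.  The bead calibration cancels from the
    ratio, so the slope is invariant to per-timepoint density rescaling
    applied to both genotypes.
    """
    usable = (series.events_A > 0) & (series.events_B > 0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        warnings.warn(
            f"excluded {n_dropped} timepoint(s) with zero events for one genotype",
            stacklevel=2,
        )
    if usable.sum() < 2:
        raise ValueError("need >= 2 timepoints with both genotypes detected")
    dA, dB = series.densities()
    log_ratio = np.log(dA[usable] / dB[usable])
    res = stats.linregress(series.times[usable], log_ratio)
    return float(res.slope)


def percent_fitness(rate_diff: float, total_rate: float) -> float:
    """Rate difference as a percentage of the overall population growth rate."""
    if total_rate <= 0:
        raise ValueError(f"total_rate must be > 0, got {total_rate}")
    return 100.0 * rate_diff / total_rate


def estimate_fitness(series: CompetitionSeries, total_rate: float) -> FitnessEstimate:
    """Convenience wrapper: ratio slope plus percent-fitness scaling."""
    diff = ratio_slope(series)
    usable = int(((series.events_A > 0) & (series.events_B > 0)).sum())
    return FitnessEstimate(
        rate_diff=diff,
        total_rate=total_rate,
        percent_fitness=percent_fitness(diff, total_rate),
        n_timepoints=usable,
    )


@dataclass(frozen=True)
class SwapTestResult:
    """Outcome of the fluorophore-swap test for a pure genotype effect."""

    t: float
    p: float
    df: int
    genotype_effect: float   # 1/h, implied (A - B) rate difference
    mean_orient1: float
    mean_orient2: float


def fluorophore_swap_test(
    deltas_orient1, deltas_orient2
) -> SwapTestResult:
    """Test for a genotype growth-rate effect net of fluorophore effects.

    Under the additive model, the rate difference measured with one
    label orientation is (genotype effect) + (fluorophore effect), and
    with the swapped orientation it is (genotype effect) - (fluorophore
    effect).  If the genotype effect is zero the two orientations give
    equal and opposite differences, so the null is
    ``mean(deltas_orient1) == -mean(deltas_orient2)``, tested with a
    two-tailed pooled-variance two-sample t test of ``deltas_orient1``
    against ``-deltas_orient2`` (df = n1 + n2 - 2).  Inputs must be
    absolute growth-rate differences in 1/h, not percent fitness.

    The implied genotype effect is
    ``(mean(deltas_orient1) + mean(deltas_orient2)) / 2``: the
    fluorophore term cancels from the sum.
    """
    d1 = np.asarray(deltas_orient1, dtype=float)
    d2 = np.asarray(deltas_orient2, dtype=float)
    if len(d1) < 2 or len(d2) < 2:
        raise ValueError("need >= 2 replicates per orientation")
    res = stats.ttest_ind(d1, -d2, equal_var=True)
    return SwapTestResult(
        t=float(res.statistic),
        p=float(res.pvalue),
        df=len(d1) + len(d2) - 2,
        genotype_effect=float((d1.mean() + d2.mean()) / 2.0),
        mean_orient1=float(d1.mean()),
        mean_orient2=float(d2.mean()),
    )


def one_sample_fitness_test(pooled_fitness) -> tuple[float, float]:
    """One-sample two-tailed t test of pooled percent-fitness values vs 0.

    Returns ``(t, p)``.  Pools data points across independent assays;
    a constant input of exactly 0 deviation gives t = 0, p = 1.
    """
    x = np.asarray(pooled_fitness, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 pooled fitness values")
    if np.all(x == x[0]):
        # zero variance: the test statistic is +/-inf unless the mean is 0
        if x[0] == 0.0:
            return 0.0, 1.0
        return float(np.inf * np.sign(x[0])), 0.0
    res = stats.ttest_1samp(x, 0.0)
    return float(res.statistic), float(res.pvalue)
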