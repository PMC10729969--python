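# Methods

## Model

The package models a yeast population whose growth substrate is a
volatile metabolite the population itself releases. Two state
variables: population density x (cells/ml) and dissolved sulfide
s (μM),

    dx/dt = g_max · s/(k_s + s) · (1 − x/K) · x
    ds/dt = r·x − c·dx/dt − δ·s

with the assumptions that (i) all cells are growth-competent, capped by
a logistic carrying-capacity factor (no death term, so x is
nondecreasing); (ii) the per-capita growth rate is Monod in sulfide —
k_s is a whole-cell growth constant, not an enzyme Michaelis constant,
and is numerically much smaller than the millimolar in-vitro Michaelis
constants reported for the relevant enzymes; (iii) sulfide is released
at a constant per-cell rate r, consumed in a fixed amount c per birth,
and removed by first-order loss δ. Liquid–gas partitioning of H₂S is
not modeled explicitly; k_s and δ are effective, partition-absorbed
quantities. Sulfide toxicity at high dose is deliberately outside the
model. Units are cells/ml, μM, hours; the conversions 1 μM = 10⁶
fmole/ml and 1 OD = 7×10⁷ cells/ml are named constants
(`sulfgrowth.units`), never inlined.

### Balanced growth rate and the lag statistic

When x ≪ K and sulfide is not lost, s relaxes to the level where
release balances consumption, r·x = c·dx/dt, pinning the realized
growth rate at r/c (capped at g_max when r/c ≥ g_max or c = 0). With
the reference parameters r/c = 0.13/h = g_max/2, independent of k_s.

Lag is an operational statistic: the first time the trajectory reaches
`fold`·x0 (default fold = 10, interpolated linearly on ln x) minus
ln(fold)/rate for a reference exponential rate. `lag_time` takes the
reference rate as an argument; the sweep functions use the balanced
growth rate, not g_max. The reason is structural: every culture in
this model eventually grows at r/c, so a g_max-referenced lag carries a
constant offset ln(fold)·(c/r − 1/g_max) ≈ 8.9 h that no parameter
change can remove, which would mask the collapse of lags under
improved assimilation (k_s/50). Referenced to the balanced rate, an
ideal culture that ramps up instantly has lag ≈ 0 and the statistic
isolates the density-dependent delay. A trajectory that never reaches
the threshold gets lag = +inf (`NOT_REACHED`), which keeps lag
monotonicity in δ well-ordered.

### Numerics

`scipy.integrate.solve_ivp` with LSODA (the sulfide equation is mildly
stiff when r·x is large relative to s), rtol 1e-8 / atol 1e-10 by
default. Tiny negative solver excursions in s are clamped to 0 inside
the right-hand side and in the returned trajectory. Halving the
tolerances moves reported lags by < 0.5% (tested). Model densities are
interpolated onto observation times on ln x, which is exact under
locally exponential growth.

## Calibration

Three parameters are measured by their own procedures:

* **g_max** — OLS slope of ln OD vs time restricted to OD ∈ [0.1, 0.5]
  (below 0.1 growth may not be exponential; above 0.5 the instrument is
  nonlinear). At least 3 in-window points are required.
* **c** — through-origin least squares of cell yield on sulfide dose in
  fmole/ml; the reciprocal slope is c. A zero-dose/zero-yield row is
  harmless by construction.
* **K** — mean stationary-phase OD, corrected for high-OD nonlinearity,
  × 7×10⁷ cells/ml. The instrument's correction function is not
  published, so the default `NonlinearityMap` is the identity with a
  warning above OD 0.5 and accepts a user-supplied piecewise-linear
  calibration table; fabricating a correction would be worse than none.

**r and k_s** are inferred jointly by minimizing the sum over curves
and timepoints of [ln OD_obs − ln OD_model]², with g_max, c, K, δ held
fixed. Least squares on ln OD (not raw OD) weighs the low-density lag
phase — which carries most of the information about k_s — comparably
to the high-density phase; the observation floor (OD 0.001) is applied
before the log. Optimization runs in log10-parameter space with
bounded L-BFGS-B from 16 log-uniform starts in r ∈ [10⁻³, 10]
fmole/cell/h × k_s ∈ [10⁻², 10³] μM, deterministic given the seed; all
starts' outcomes are kept in the `FitResult`. Identifiability is
flagged by the ratio of the objective's finite-difference profile
curvature in log k_s to that in log r: below 10⁻² the fit is marked
poorly identified (e.g., a single dense inoculum with no visible lag
constrains r but leaves k_s nearly flat).

## Competition statistics

Absolute densities come from counting beads:
cells/ml = cell_events / bead_events × bead concentration. The
genotype growth-rate difference is the OLS slope of ln(density ratio)
vs time — the bead calibration cancels in the ratio — and is reported
as a percentage of the coculture's overall growth rate measured from
OD. Timepoints with zero events for either genotype are dropped with a
warning rather than pseudocounted: log-ratio slopes cannot absorb
zeros, and at ~10⁴ events per sample a true zero means the genotype is
effectively absent.

The fluorophore-swap test assumes genotype and label effects on growth
rate are additive. Writing δr₁ and δr₂ for the rate differences
measured in the two label orientations, the label effect cancels from
δr₁ + δr₂ = 2·(genotype effect), so "no genotype effect" is the null
δr₁ = −δr₂, tested by a classical pooled-variance two-sample two-tailed
t test of the δr₁ replicates against the negated δr₂ replicates
(df = n₁ + n₂ − 2), on absolute rate differences, never on percent
fitness. The simpler one-sample test pools percent-fitness points
across assays and t-tests them against 0.

## Synthetic data

The generators emulate the reference experimental designs so every
stage is testable without downloads: growth curves at OD-equivalents 0.001/0.01/0.1
(the reference density design) produced by the ODE model, converted to
OD, with multiplicative lognormal noise (default CV 5%, a typical tube
spectrophotometer repeatability) and then the 0.001 floor; dose–yield
tables from Δx = dose/c with lognormal noise; coculture counts with
per-orientation rates (genotype + label effect), Poisson cell and bead
events at a sampled volume (default 0.1 μl at 10⁵ beads/ml) chosen so
a dense coculture yields ~10⁴ events per sample; and per-tube δ draws
from a truncated normal to emulate variable tube sealing. The noise
families are modeling choices (no noise model is published for these
instruments) and are all overridable; zero-noise outputs are exact
fixed points of the corresponding estimators.

What the generators do **not** emulate: instrument nonlinearity above
OD 0.5 (curves are produced in true-density units), sulfide toxicity,
shared-headspace coupling between vessels, cytometry gating artifacts,
or dead cells. Passing tests on synthetic data therefore validate the
estimators under the model's own assumptions, not the upstream
measurement steps of real experiments.

## Problem sizes and defaults in tests

The test suite runs the parameter-recovery study at 20 noise
replicates with 2-hourly sampling to 80 h and 3–4 optimizer starts,
and the swap-test calibration at 1000 simulated assays of 3 replicates
per orientation; the acceptance script uses hourly sampling to 100 h
and the full 16 starts. Sweeps use a δ grid of 0–0.3/h, spanning
no-loss to loss strong enough that the sparsest inoculum never grows
out.

## Known limitations

* δ is never fitted, only held fixed or swept; the data to identify it
  (paired sealed/unsealed curves) are not part of the calibration
  design.
* The lag statistic needs the trajectory to span the fold-threshold;
  for very short horizons it returns +inf rather than extrapolating.
* The swap test inherits the equal-variance assumption of the
  classical pooled t test; with two replicates per orientation its df
  is small and power is limited.
* `estimate_K` is only as good as the supplied high-OD calibration
  table; with the identity default it understates K on instruments
  that saturate.
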