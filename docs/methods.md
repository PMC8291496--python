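# Methods

## Kinetic model

Aggregation is modeled as an autocatalytic two-step reaction: slow
nucleation of monomers (rate constant `k_n`, s⁻¹) and fast elongation of
existing aggregates (rate constant `k_e`, M⁻¹ s⁻¹).  With `a` the
initial monomer concentration, `k = k_e·a` and `ρ = k_n/k`, the fraction
aggregated obeys

    df/dt = k (1 − f)(ρ + f),   f(0) = 0,

with closed-form solution

    f(t) = ρ (e^{(1+ρ)k t} − 1) / (1 + ρ e^{(1+ρ)k t}).

Small `ρ` gives a pronounced lag phase; `ρ ≥ 1` removes the lag entirely
(the inflection moves to t ≤ 0) — such parameters are representable but
flagged, and the lag time is clamped at 0.

**Numerical evaluation.**  The closed form is computed as
`f = ρ(1 − e^{−x}) / (e^{−x} + ρ)` with `x = (1+ρ)kt`, which only
exponentiates non-positive arguments and therefore cannot overflow for
any time; `1 − e^{−x}` uses `expm1` to keep precision at small `x`.  An
independent oracle (`ode_oracle`) integrates the rate law with
`scipy.integrate.solve_ivp` (DOP853, rtol 1e−12, atol 1e−14) and agrees
with the closed form to better than 1e−8 across `ρ ∈ [1e−8, 1]`; the
high-order explicit method was chosen because the problem is smooth and
non-stiff on the solution trajectory and LSODA's step control saturated
near the inflection at ~1e−7 accuracy.

**Characteristic times.**  The inflection sits at
`t_i = ln(1/ρ)/((1+ρ)k)` with `f_i = (1−ρ)/2` and maximum slope
`v_max = k(1+ρ)²/4`.  The tangent there, extrapolated to `f = 0` and to
the normalized plateau `f = 1`, gives the lag and end times

    t0 = t_i − f_i/v_max,    t1 = t_i + (1 − f_i)/v_max.

The tangent construction is evaluated analytically rather than by a
windowed linear regression on sampled data: it is deterministic and
reproduces the midpoint identity `(t0 + t1)/2 = t_i + (1 − 2f_i)/(2v_max)`
exactly.  Two half-times coexist in the literature and differ at O(ρ³):
the solution of `f(t) = 1/2` (reported as `t_half`, the definition used
for half-aggregation times) and the tangent midpoint `(t0+t1)/2`
(reported separately as `t_half_tangent`).  For published parameter
sets of this system the two differ by well under a second; published
half-times equal the rounded midpoint of the published lag/end times,
confirming they came from the tangent construction on fitted curves.
Note that characteristic times printed alongside published rate
constants are read off fits to experimental data: the analytic
half-time computed from the published uninhibited constants (~1035 s)
deviates by ~4.6% from the printed 989 s.  This deviation is expected
and documented, not an error, so no test asserts agreement between
analytic times and printed times for the same column.

Units are fixed — seconds and molar — with no auto-detection; minutes
are accepted at the CSV parsing layer via an explicit flag and
converted once.

## Trace normalization and fitting

Raw ThT fluorescence is mapped to fraction aggregated by a two-anchor
affine map: `f = (F − F_base)/(F_plateau − F_base)` with `F_base` the
mean of the first 3 samples and `F_plateau` the mean of the last 3.
This absorbs instrument gain and offset exactly (any affine transform of
the fluorescence axis leaves the normalized trace unchanged) and the
anchors are recorded for reporting.

(ρ, k) are then estimated by unweighted bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective, ftol/xtol/gtol
1e−12) in normalized-fraction space — the model stays 2-parameter;
baseline and amplitude are never free parameters.  Bounds:
`ρ ∈ [1e−10, 10]`, `k ∈ [1e−8, 1] s⁻¹`.  Initialization is geometric and
deterministic: `k⁰ = 4 × (max finite-difference slope)` (the slope of
this sigmoid at its inflection is ≈ k/4 for small ρ), and `ρ⁰ =
exp(−k⁰·t⁰_half)` from the first empirical half-max crossing, clipped to
[1e−8, 1].  On optimizer failure up to three restarts run from
geometrically perturbed starting points (×0.3, ×3, ×0.1); everything is
deterministic, so identical inputs give bitwise-identical fits.

**Anchor-consistent residuals.**  When the observed trace was normalized
from raw fluorescence, the model prediction is pushed through the *same*
first-3/last-3 anchor map before residuals are formed.  Without this,
any curvature inside the anchor windows (e.g. a lag phase shorter than
three sampling intervals) biases the estimates — for the uninhibited
condition sampled at 300 s the bias on `k_e` would be ~9%.  With
anchor-consistent residuals the noise-free closure
(generate → normalize → fit) recovers generator constants to machine
precision, and the estimator's error is driven by noise alone.  Traces
supplied directly as fractions (no anchor record) are fitted against the
plain closed form.

Triplicates are combined by fitting the pointwise-mean trace by default
(one parameter set per condition, matching how replicate kinetic assays
are conventionally reported); a pooled strategy that stacks all
replicate points into one joint residual is available for replicates on
mismatched time grids.  Fits failing to converge still report residual
RMS and carry a `converged = False` flag; traces with fewer than 3
points beyond half-maximum are rejected as unable to constrain the
plateau.  Unweighted least squares is assumed throughout; no weighting
scheme is applied to match any particular commercial fitting product.

Reported values are rounded only at the report layer: rate constants to
4 significant figures, percents to 1 decimal, times to integer seconds
(half rounds up).  Full-precision columns are written alongside so that
downstream fold-change arithmetic never consumes rounded values.

## Endpoint metrics

All three screen families are linear two-point normalizations,
`percent = 100 (C₀ − F) / (C₀ − C₁₀₀)`, between an explicit 0% control
and a 100% anchor:

| metric | 0% anchor | 100% anchor |
|---|---|---|
| in vitro inhibition | aggregated DMSO control | monomer/ThT blank (default 0 a.u. if none run) |
| fibril disaggregation | untreated fibril control | monomer control |
| in cellulo ThS screen | induced DMSO culture | non-induced culture |

Percents are never clipped, so aggregation promoters appear as negative
values.  Replicates are summarized as mean ± SEM with the n−1 sample
standard deviation (the convention behind "mean of three experiments ±
SEM"); a single replicate reports SEM 0 with a flag.  Bacterial-growth
toxicity is flagged when a compound's OD620 falls below 0.8× the control
mean — the threshold is configurable; growth monitoring is standard but
no published cutoff exists, and 0.8 (a 20% growth deficit, beyond
typical OD620 triplicate scatter) is the package's default.

Condition-vs-control kinetic comparisons report fold decreases
`k_n(control)/k_n(treated)` and `k_e(control)/k_e(treated)` and absolute
time increments (treated − control); folds compose multiplicatively
along chains of conditions.

## Synthetic data

The generator reproduces the study conditions of the assays it stands in
for: ThT readings every 300 s (5 min), triplicates, and multiplicative
Gaussian noise with a 5% coefficient of variation — the level below
which replicate standard errors stayed in the reference assays.  A trace
value is `baseline + amplitude·f(t)·(1 + ε)`, `ε ~ N(0, cv)` independent
per point, plus a small additive floor (SD = 0.05·cv·amplitude) so
pre-lag points are not artificially noise-free.  Baseline 100 a.u. and
amplitude 1000 a.u. are arbitrary plate-reader levels, configurable;
every analysis result is invariant to them by construction.  One master
seed spawns per-replicate substreams (`SeedSequence.spawn`), so output
is reproducible regardless of replicate count.

Endpoint plates are built by inverting the metric: a compound with true
percent `p` gets fluorescence `C₀ − (p/100)(C₀ − C₁₀₀)` before noise, so
the zero-noise plate scores exactly `p`.  Requested percents outside
[−100, 200] are rejected as unphysical for a generator (the metrics
themselves are unbounded).  Disaggregation dose series scale the
fraction of signal removed with the fibril:compound ratio as
`1 − (1 − e)^r`, a monotone law that is 0 at no effect and saturates at
complete disaggregation.

**What the generator does not emulate:** drift and photobleaching,
well-to-well gain variation, evaporation, secondary nucleation or
fragmentation kinetics (the model is strictly two-step), bacterial
growth dynamics behind the OD620 readout, and non-Gaussian outliers.
Passing closure tests therefore demonstrate correctness of the analysis
arithmetic and estimator under the stated noise model, not robustness to
every artifact of real plates.

**Replicate statistics.**  With triplicates, the ±2·SEM interval around
a plate mean covers the true percent with probability ≈82% (the pivot is
Student t with 2 degrees of freedom), not 95%; recovery of true effect
sizes is therefore validated on the grand mean over many seeded plates
(200), whose 2·SEM band is a proper ~95% normal interval.

## Problem sizes

Validation fits use the native assay geometry: 11–22 points per trace
(300 s sampling over twice the end time), triplicates, 100–200 seeds for
Monte-Carlo statistics, 500 seeds for SEM-scaling checks.  These sizes
make every estimator property measurable while keeping the whole suite
fast.

## Known limitations

* The model assumes a closed system reaching full conversion (f → 1);
  substoichiometric plateaus are absorbed by normalization, not modeled.
* `k_n` is weakly identified when the lag phase is barely sampled; its
  Monte-Carlo spread under 5% noise is several-fold larger than that of
  `k_e`.
* No confidence intervals on fitted parameters (no bootstrap or profile
  likelihood); comparisons are point estimates.
* Dose–response (IC50) fitting and alternative aggregation models
  (Oosawa, secondary-nucleation) are out of scope.
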