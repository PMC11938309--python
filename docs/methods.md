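# Methods

This note documents the models, conventions and design choices behind
`survcea`, in the order the pipeline runs. Time is in **months** in the
statistical modules and **years** in the economic module; costs are USD
(a CNY input mode applies the 0.14235 CNY→USD rate once at load).

## Synthetic trial generator

Two-arm trials are simulated from a piecewise-constant reference hazard
`h_ref(t)` (events/month on a breakpoint grid). The treatment arm's hazard
is `h_ref(t)·exp(d0 + d1·t^p)`, the first-order fractional-polynomial (FP)
form used throughout, with `p = 0` meaning `log t`. Event times are drawn
by inverting the cumulative hazard: exact piecewise-exponential inversion
when `d1 = 0`, otherwise numerical inversion on a fine trapezoid grid
(≥ 8193 nodes up to the data cutoff; draws beyond the grid map to +∞ and
are administratively censored). Accrual is uniform over the accrual window;
administrative censoring happens at `cutoff − entry`; optional dropout is
exponential. The same seed yields bit-identical tables.

**Small-t floor.** `t^p` with `p < 0` diverges at 0, so it is evaluated as
`max(t, ε)^p`. The package default is ε = 0.01 months, but ε is
configurable per trial spec and per fit because published-scale contrasts
(e.g. `d1 = 2.76` at `p = −2`) make `exp(d1·ε^−2)` astronomically large at
ε = 0.01 — the integrand genuinely diverges and the generator raises
instead of silently producing a cohort that dies at t ≈ 0. Studies that
recover a simulated truth use ε = 1 month (the first monthly interval) on
*both* the generator and the FP likelihood, so the truth and the fitted
covariate agree; this is a property of the model definition, not a tuning
knob.

**Digitization artifacts.** `make_km_artifacts` samples the KM estimate on
a grid and optionally rounds survival to 3 decimals (the only noise model —
keeping reconstruction tests deterministic). A curve grid with one point
per visible KM step plus a sparse (e.g. 7–13 row) at-risk table emulates
how published figures are actually digitized; a deliberately coarse curve
grid can be used to study information loss, but lumps events and inflates
interval-level overdispersion downstream.

What the generator does *not* emulate: patient covariates, PD-L1
subgroups, treatment switching, digitizer jitter beyond rounding, and
spline-shaped reference hazards. Passing tests therefore demonstrate the
correctness of the machinery under a known, well-behaved truth — not the
adequacy of any particular extrapolation for real trial data.

## KM reconstruction (Guyot algorithm)

Inputs are the digitized curve (time, survival; monotonicity violations up
to 0.005 are clipped isotonically as digitization jitter, larger ones are
errors) and the at-risk table. Within each inter-risk-time interval the
censoring count is iterated (≤ 60 passes) until the implied number entering
the next interval matches the printed at-risk count; event counts at each
curve step follow from the running KM product (ties event-first; censoring
times uniform within the interval). The at-risk count is **carried
forward** between intervals rather than reset to the table value: resetting
injects phantom patients whenever an interval cannot be reconciled exactly
and the KM error compounds. With `total_events` supplied, censoring in the
final interval is increased until the cumulative event count matches;
without it the final interval is censoring-free.

Validation: a Cox proportional-hazards fit (Efron ties, 95% Wald CI —
conventional defaults) of reconstructed two-arm data against the trial's
reported HR interval. Non-PH diagnostics compute `log(−log S)` per arm on a
shared grid; the crossing flag requires the between-arm difference to
exceed +0.05 somewhere *and* fall below −0.05 somewhere after the first
decile of event times (the ±0.05 band and 10% burn-in absorb small-sample
noise). Hazards are smoothed with an Epanechnikov kernel on the
Nelson–Aalen increments, default bandwidth 1/8 of the inspected time range.

## Survival fitting and selection

All models are fitted by MLE on right-censored data with L-BFGS-B, five
restarts (fixed restart seed, perturbation SD 0.25) and relative tolerance
1e-8; non-convergence raises with optimizer diagnostics.

* **Parametric families** — exponential, Weibull, Gompertz, gamma,
  log-logistic, log-normal, generalized gamma (flexsurv-style (μ, σ, Q)
  parameterization, with |Q| < 1e-6 branched to the log-normal form for
  stability). Scale/shape parameters are optimized on the log scale.
* **Royston–Parmar splines** — `g(S(t))` is a restricted cubic spline in
  `log t`, with `g` = log cumulative hazard, log cumulative odds, or
  −probit. Boundary knots at the extreme uncensored log event times,
  internal knots (1–3) at equally spaced event-time centiles. Starting
  values regress `g(KM)` on the basis at event times; a smooth penalty
  keeps the spline slope positive at events, and a fit whose final slope
  is non-positive anywhere at the event times raises.
* **RCS hazard models** — `log h(t)` is a restricted cubic spline in `t`
  with 3–5 total knots; the cumulative hazard uses composite 24-node
  Gauss–Legendre quadrature split at the knots (agrees with a 300k-node
  trapezoid refinement to < 1e-6).

Selection is minimum AIC, ties broken by BIC then by parameter count. The
BIC sample-size convention is the number of **subjects**, matching common
survival-package defaults; it only affects tie-breaking.

## Fractional-polynomial NMA

Follow-up is discretized into intervals (default: monthly to the last
event, then one interval to the cutoff; recovery studies refine the first
4 months to 0.25-month widths because `t^p` with `p = −2` varies fastest
there). Per interval the event count given the number at risk is binomial
with `cloglog(P) = ln h(t_mid) + ln Δt`, so the linear predictor is the log
hazard at the interval midpoint. The linear predictor carries
trial-specific baseline coefficients (β0, β1 per trial — each trial's
chemotherapy arm is its own reference) plus fixed treatment contrasts
(d0_k, d1_k shared across trials), estimated with a statsmodels binomial
GLM; expected fractional counts (from the Ouwens-style construction) enter
un-rounded via variance weights. Wald 95% CIs come from the observed
information; d0 and d1 are reported per treatment. An arm with zero events
anywhere (separation) is a named error.

Order-2 fits add a second power column (repeated powers use the
conventional `t^p·log t` term); an empty power tuple gives the order-0
proportional-hazards special case. The power scan fits one model per grid
cell (default order-1 over {−2, −1, −0.5, 0, 0.5, 1, 2, 3}), ranks by AIC,
records non-convergent cells rather than aborting, and lets the caller
override the winner (extrapolation plausibility can trump in-sample AIC).

I² is computed in the GLM overdispersion form: `Q` = interval-level
Pearson χ², `df` = residual degrees of freedom,
`I² = max(0, (Q − df)/Q)·100`.

`apply_contrast` projects a comparator curve as
`S_k(t) = exp(−∫ h_ref(u)·exp(d0 + d1·u^p) du)` by composite Gauss–Legendre
quadrature over the grid cells, with the ε point inserted as a node
boundary. Month-scale ε is required for strongly negative powers with
`d1 > 0` (see the floor discussion above); the pipeline default is 1 month.

## Partitioned survival model

State occupancy on the cycle grid (21-day cycles, final fractional cycle
landing exactly on the 5-year horizon, 88 boundaries): progression-free
= S_PFS, progressed = S_OS − S_PFS, dead = 1 − S_OS. Where S_PFS > S_OS
(possible after independent extrapolation) PFS is clamped to S_OS so rows
still sum to one; the clamp count is reported, never silently dropped.
Half-cycle correction averages memberships over cycle endpoints (life-table
convention); discounting uses `(1.05)^(−t)` at the cycle midpoint. LYs are
discounted at the same rate by default, with an undiscounted switch.

Costing (healthcare-system perspective): progression-free cycles accrue
drug acquisition plus administration, laboratory/radiology, supportive
care, hospitalization and routine follow-up; drug cost is vial-level —
required mg from the dose rule (flat, per kg × 65, per m² × 1.72), vials
rounded up with no sharing, times administrations per 21-day cycle (a
14-day schedule contributes 1.5). Progressed cycles accrue a treatment
mixture (all progressed patients keep receiving treatment) over
chemotherapy (paclitaxel liposome 135 mg/m² q3w), targeted therapy
(anlotinib 12 mg/day × 14 days — the targeted drug actually priced in the
parameter table), traditional herbal medicine and supportive care; the
default mixture proportions (0.30/0.15/0.35/0.20) are assumptions, as the
trial's post-line distribution is not public. Adverse-event costs and
(negative) disutilities are one-off at model start — incidence × value over
the whole cohort — which is the reading of "costs counted once per cycle"
that avoids double counting; the per-strategy incidence defaults are
synthetic plausible values because the trial-level table is not public.

The ICER table ranks strategies by ICER among those with positive
incremental QALYs, flags dominated/equivalent/dominant cases instead of
dividing, and reports the count below the WTP threshold ($36,598.19/QALY,
three times 2022 per-capita GDP).

## Sensitivity analysis

One-way: each parameter perturbed alone over [low, high] (default ±20%;
drug prices only downward to 80% — list prices are a ceiling), tornado
sorted by ICER span; a perturbation that removes the QALY gain is recorded
as dominated (NaN), not raised. Ranges printed with typos in the source
table (a positive "minimum" for a disutility, a negative BSA bound) are
rebuilt as ±20% around baseline.

Probabilistic: costs and body weight are gamma (shape = (mean/SE)², scale
= SE²/mean); utilities, BSA and the discount rate are beta moment-matched
on their supports ([0,1], ±20% band, [0, 0.08] respectively); disutilities
are sampled on the magnitude scale and negated; FP contrasts are
independent normals with SE = CI half-width / 1.96 (the d0–d1 covariance is
not published — a documented limitation); the post-progression mixture is
Dirichlet (α = 100 × proportions). SEs where unpublished are 20% of
baseline / 1.96, i.e. the one-way range read as a 95% interval. A relative
SE below 1e-8 is treated as degenerate (draws equal the mean). A draw is
cost-effective when its incremental net monetary benefit vs chemotherapy is
**strictly** positive (`WTP·ΔQALY − ΔCost > 0`; a draw whose ICER equals
the WTP counts as not cost-effective). The pairwise rule is the default
because published per-strategy probabilities sum to more than 100%, ruling
out a pick-the-best multinomial curve; a best-strategy CEAC is available
behind a flag. Failed draws are excluded and counted; more than 5% failing
aborts.

## Pipeline

One global seed fans out to the seven stages (simulate, reconstruct, fit,
nma, econ, dsa, psa) through a `SeedSequence` spawn in that fixed order, so
stages can be re-run in isolation; every CSV carries the config hash
(SHA-256 of the canonical YAML, excluding the output directory) and its
stage seed in a `#` header line, and `manifest.json` records stage
timings, seeds and outputs. Reruns with the same config and seed are
byte-identical.

## Problem sizes used in validation

The shipped checks run at: n = 5000/arm for Cox/Weibull/spline recovery;
n = 300 with ~20% dropout and a 7-row risk table for reconstruction
fidelity (< 0.02 sup-norm); 50 replicates of a 6-trial star network at
n = 2000/arm for FP contrast recovery (joint 95%-CI coverage ≥ 90%);
100,000 draws for PSA moment checks. These sizes make the Monte Carlo
error small relative to each tolerance while keeping the whole suite under
a minute apart from the optimizer-heavy survival-fit module.

## Known limitations

* The source analysis's reference-curve spline coefficients, AE incidence
  and dosing tables are not public: absolute cost/QALY totals under the
  bundled defaults are illustrative, and the published base-case totals are
  shipped as data for the ICER-assembly layer instead.
* d0 and d1 are sampled independently in the PSA.
* Interval-midpoint evaluation of `t^p` biases FP estimates when the
  hazard ratio varies strongly within an interval; refine early breaks (as
  the recovery studies do) when `p ≤ −1` effects matter near t = 0.
* The Guyot reconstruction assumes uniform censoring within risk
  intervals; with very coarse digitization grids the KM between curve
  points is interpolated as a late step.
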