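# Methods

## The model in brief

`wptaxsim` implements a cross-sectional, arithmetic excise-tax simulation in
the TETSiM (Tobacco Excise Tax Simulation Model) tradition.  A market is a
small set of segments, each with an observed consumption share, retail price
per 20 g unit, own-price elasticity of demand and tax rules.  A candidate
policy replaces the specific excise (and, under the *simple* structure,
removes the ad valorem excise); prices move one-for-one with the per-unit
tax change (full pass-through: CIF/ex-factory cost and industry margin held
fixed); quantities respond through constant-elasticity demand; and the
market-weighted tax burden, revenue and deaths averted are read off the new
equilibrium.  The model is deliberately static: one year's consumption,
no dynamics, no cross-price substitution between segments.

## Price decomposition and tax rules

Baseline decomposition of segment *m*'s observed price:
`duty = duty_rate × CIF`, `adval = advalorem_rate × (CIF + duty)`,
`margin = P0 − CIF − duty − specific0 − adval`.  A negative implied margin is
a data error and is rejected.  In the packaged Egyptian market the flavoured
(imported, premium) segments carry a 16.7% import duty and a 200% ad valorem
rate; unflavoured (domestic) segments carry no duty and a 165% rate.  The
16.7% duty rate is the one consistent with the published market-weighted
duty column (a 2.4% rate, which also appears in the source narrative,
reproduces none of the weighted figures).

Policy application keeps CIF and duty fixed, sets the specific excise, keeps
or drops the ad valorem amount, and leaves the margin unchanged under full
pass-through.  `TaxPolicy.shift_rate` optionally moves the margin by a
fraction of the per-unit tax change (floored at zero with a warning); this
generic over/undershifting mechanism is available but is *not* what the
sensitivity analysis uses (below).

## Solving for a target burden

The burden uses post-change quantity weights: cheap segments are suppressed
hardest by a uniform specific excise, so the consumption mix shifts toward
premium segments as the excise rises, and the weighted CIF/duty columns of a
scenario table drift upward.  Only this weighting reproduces the published
weighted price components.  The resulting fixed-point problem is solved by
bracketed Brent root-finding (`scipy.optimize.brentq`, bracket grown
geometrically, `xtol = 1e-12`), and the solution is verified to satisfy
`|burden − target| ≤ 1e-8`.  The burden is strictly increasing in the excise
(property-tested), so the root is unique.  Scenario outcomes are computed
from the unrounded solved excise; published tables round the excise to
cents, which the reproduction tolerances absorb.

## Outcomes

* **Consumption**: sum of post-change segment quantities.
* **Revenue**: post-change quantities × per-unit tax (duty + specific +
  ad valorem), summed.  The identity `revenue = burden × weighted price ×
  quantity` (all with post-change weights) holds to machine precision and is
  tested.
* **Deaths averted**: `quit_fraction (0.5) × mortality_fraction (0.35) ×
  smoker_base × Σ_m (1 − Q1_m/Q0_m)`.  The per-segment relative reductions
  enter *unweighted* by share, and reductions from price falls enter with
  negative sign; the aggregate is floored at zero.  This aggregation is the
  one that reproduces the published deaths counts: regressing the ten
  published per-scenario counts on the summed relative reductions from our
  solved scenarios (through the origin) recovers the theoretical factor
  `0.175 × smoker_base` within 1%.  An intensity-based alternative (deriving
  quitters from sessions per smoker) does not reproduce the published
  counts and is not implemented.

Two population counts appear in the source data and both are kept as named
inputs: the >15-years census population (67,589,102), whose 4.5% smoking
prevalence gives the smoker base (≈3.04 million) used by the four-segment
battery, and the World Bank population matched to the STEPS survey age range
(60,409,575), which feeds the annual-units product formula.  The single-share
(WHO tax-structure) secondary analysis scales deaths by the smoker base
implied by the *World Bank* count (≈2.72 million): with the census-based
base its deaths-averted figure overshoots the published count by ~16%,
while the World Bank base lands within 4%, indicating that is the base the
original analysis used for that run.

## Calibration

The raw annual-unit count is the product formula
`units/session × sessions/day × daily prevalence × population × 365.25`
(≈6.67 billion 20 g units for the packaged inputs).  The base scenario is
calibrated by a single multiplicative factor applied before the share split;
the packaged market pins the calibrated total to the published 3.67 billion
units, making all downstream published values reproducible.  The implied
factor (≈0.550) is not derivable from the stated anchors — it matches
neither the illicit-use adjustment (0.965) nor a pure revenue anchoring
(≈0.80) — so it is stored as data, not recomputed.  Baseline revenue
computed from the calibrated market is 0.7% below the published figure;
no re-tuning is applied.

## Sensitivity analysis

One-at-a-time perturbations at a solved scenario, reported as relative
percent differences in consumption, deaths and revenue:

* **Elasticities** replaced by per-segment confidence bounds, one segment at
  a time (the published per-segment outcome ranges imply per-segment runs);
  a joint mode is available.  The packaged bounds are ±20% placeholders,
  clearly labelled as such, because the published bounds are not available
  in machine-readable form; user-supplied bounds are accepted.
* **CIF ±50%**: duty is recomputed from the perturbed CIF; the margin is
  held at its original estimate; baseline observed prices and quantities are
  never perturbed — only the scenario-side price build-up changes.
* **Industry ±10% over/undershift**: the margin itself is scaled by
  1 ± 0.10.

By default the *original solved* excise is held fixed under perturbation
(the statutory tax is what it is; the question is how wrong the projections
would be).  This convention — fixed excise, scenario-side perturbation,
margin scaling for shift — is the one that reproduces the published
sensitivity magnitudes: CIF ±50% moves outcomes by 0.8–1.9% and a ±10%
shift by 0.7–1.1%.  Re-solving the excise under each perturbation
(available via `resolve=True`) is a different question — how would the
*policy* change — and yields effects an order of magnitude larger (3–20%);
likewise a Δtax-proportional shift moves outcomes by several percent.
Neither matches the published ranges, which is why they are not defaults.

## Synthetic markets

`wptaxsim.synth` samples parameter sets, not microdata, because the model
consumes only aggregates.  Distributional commitments: shares uniform on
the simplex (flat Dirichlet); prices, elasticities, duty and ad valorem
rates uniform on configurable ranges; CIF drawn so the baseline margin is at
least a configurable fraction of the price; total quantity uniform on a
wide range.  All draws are seeded.  What synthetic markets do *not* emulate:
the empirical correlation between price level and elasticity, the extreme
share concentration of real markets, or measurement error in any input —
passing synthetic-market tests therefore demonstrates numerical correctness
of the machinery, not robustness to real-data pathologies.

`generate_scenario_truth` provides an independent oracle: the excise hitting
a target burden located by geometric bracketing plus iterative grid
refinement over a self-contained numpy restatement of the arithmetic
(`grid_burden`), never touching the production solver.  Refinement stops at
the larger of the requested tolerance and 8 ulps of the bracket magnitude.

## Numerical choices

* Burden solve tolerance 1e-8 (achieved ~1e-12); bracket growth ×2 from 1.0,
  at most 200 doublings.
* Price-decomposition component-sum identity enforced at 1e-9 in the
  constructor, so it cannot silently drift through any pipeline.
* Share-sum validation tolerance 1e-6 on load; 1e-9 invariant internally.
* Degenerate inputs: single-segment markets are first-class; a target burden
  equal to the zero-excise burden returns exactly 0; targets below it raise
  with the achievable range; margins floored at zero only under explicit
  undershifting, with a warning.
* Scenario tables: base row weighted by baseline quantities, scenario rows
  by post-change quantities.

## Problem sizes

The full reproduction battery is desk-scale: ten scenario solves on a
four-segment market complete in well under a second, and the complete test
suite — including a 100-market solver-vs-grid-search cross-check at 1e-4
grid resolution and a 1000-seed generator fuzz — runs in a few seconds on
one CPU.

## Known limitations

* Cross-price elasticities are zero by design: smokers do not substitute
  between segments or products, which overstates suppression if substitution
  is material.
* Elasticities are constant over arbitrarily large price changes; the 75%
  scenarios multiply the cheapest segment's price ~30-fold, far outside the
  range any elasticity was estimated on.
* The illicit-consumption share is fixed; large tax rises plausibly expand
  it.  `apply_illicit_downscale` is a reporting utility, off by default
  because the calibrated baseline already embeds the published adjustments.
* Deaths averted use a fixed 0.5 × 0.35 quit/mortality assumption borrowed
  from cigarette modelling; no life tables, lags or morbidity.
* Single-year, comparative-static results only; no projection over time.
* The reconstructed premium-segment margins (~50% of retail) sit slightly
  above the 15–45% range quoted in the source narrative, and the published
  84.3–86% suppression band for the cheapest segment is not exactly
  attainable from the published inputs (the faithful computation gives
  86.7–86.8% under the simple approach); both discrepancies are inherited
  from the source tables and are documented rather than patched.
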