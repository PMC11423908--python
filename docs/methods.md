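# Methods

## Scope and data model

The package analyses single-dose IV-bolus concentration–time studies
with two matrices (plasma, milk) and a two-period crossover between two
dose levels. The atom of computation is one subject × matrix × dose
profile: strictly increasing times in decimal hours post-dose,
concentrations in µg/mL, and a below-LLOQ (BLQ) flag per observation.
BLQ values are stored as flags with the value withheld — never as 0 or
LLOQ/2 — and each stage applies its own censoring policy (every stage
here simply drops BLQ points, so analyses run on the quantifiable span).
Pre-dose time-0 samples are controls: the reader accepts and counts
them but excludes them from every profile.

The MRL is configured in µg/kg and converted to a concentration cutoff
through an explicit milk density (default 1.0 kg/L), so
50 µg/kg → 0.05 µg/mL. Making the density a parameter keeps that unit
bridge auditable rather than implicit.

## Non-compartmental analysis

For a profile with quantifiable points (tᵢ, Cᵢ):

* **λz** — ordinary least squares of ln C on t over a terminal window.
  Window selection follows the de-facto automatic standard: every
  candidate window that ends at the last quantifiable point, starts
  strictly after Tmax and holds ≥ `lambda_z_min_points` (default 3)
  points is scored by adjusted R²; the best window wins, and a
  non-negative best slope or too few points raises a not-estimable
  signal (downstream extrapolated parameters become NaN while
  AUC₀₋last, Cmax and Tmax are still reported). A `manual` rule accepts
  an explicit window so any published fit can be reproduced. The scan is
  computed from suffix sums, so dense profiles (thousands of points)
  cost O(n).
* **AUC/AUMC** — linear trapezoid by default; the
  `linear_up_log_down` option applies the log-trapezoid
  Δt·(C₁−C₂)/ln(C₁/C₂) and its moment analogue
  (t₁C₁−t₂C₂)/k + (C₁−C₂)/k² on strictly decreasing intervals, falling
  back to linear (and logging) on intervals containing zeros. The
  default is linear because that matches the historical default of the
  widely used NCA software this workflow mirrors; the config makes the
  choice explicit.
* **C0 policy** — `first_observed` (default) takes the concentration at
  the first post-dose sample and starts integration there, matching a
  design whose first sample is at 0.08 h and which defines C0 at that
  time; `back_extrapolate` prepends a synthetic t=0 point from the
  log-linear extrapolation through the first two quantifiable points,
  the conventional IV-bolus treatment.
* **Derived parameters** — AUC₀₋∞ = AUC₀₋last + C_last/λz;
  AUMC₀₋∞ = AUMC₀₋last + C_last·t_last/λz + C_last/λz²;
  MRT = AUMC₀₋∞/AUC₀₋∞; Cl_T = dose/AUC₀₋∞; V_dss = Cl_T·MRT;
  t½λz = ln 2/λz. Cmax/Tmax are read directly off the data with ties
  broken by the earliest time.

Across-subject summaries are geometric means with (min–max), except
Tmax, which is summarized by the median — the convention for a
bounded-by-design sampling grid. Geometric summarization makes the
group-level identities exact: geomean(dose/AUCᵢ) = dose/geomean(AUCᵢ),
and the group milk/plasma ratio equals the ratio of group geometric
means.

## Milk penetration

Exposure ratios are formed per subject (AUC_milk/AUC_plasma, last and
infinity) and summarized geometrically, not as a ratio of group means.
Time-matched concentration ratios are only computed at times sampled
and quantifiable in both matrices — no interpolation, because the
design samples both matrices on one shared nominal grid. Dose
normalization is linear (value·ref_dose/dose); any true
supra-proportionality therefore survives normalization and is what the
dose-comparison test detects.

## Withdrawal time

All animals' quantifiable milk ln-concentrations for one dose are
pooled into a single OLS regression of ln C on time (no per-animal fits:
the tolerance-limit construction describes one pooled curve of
individual observations). The upper one-sided tolerance limit for the
p-quantile at confidence γ is

U(x₀) = b₀ + b₁x₀ + k(x₀)·s, k(x₀) = √d · t′₍n−2, δ₎(γ),
d = 1/n + (x₀−x̄)²/Sxx, δ = z_p/√d,

with s² = SSE/(n−2). Defaults p = γ = 0.95 ("95/95"). The WT estimate is
the **supremum** of {t : U(t) ≥ ln(MRL concentration)}: because the
leverage term grows away from x̄, U(t) need not be monotone, and the
supremum definition prevents a premature crossing from being reported.
The search brackets the supremum on a 4097-point grid over
[0, t_max_search] (default 4× the data span, with a clear error
suggesting a larger window when U never falls below the cutoff) and
bisects to 10⁻⁶ h, returning the last point verified inside the
exceedance set so the estimate never overshoots — which matters exactly
at whole-hour crossings under the reporting rule. Reported WT rounds the
estimate up to the next whole reporting unit (1 h default; configurable
to e.g. a 12 h milking interval).

The pooled design is capped at 7 distinct sampling times, the input
limit of the regulatory WT tool this reproduces. When quantifiable data
span more times and no exclusion list is supplied, the code raises an
error listing the candidates instead of inventing a selection heuristic
— the study itself chose which two mid-curve times to drop at the high
dose, and that choice is the analyst's. The pipeline applies a supplied
exclusion list only when the uncapped selection actually overflows,
mirroring how the study handled its two doses (no exclusions at
2 mg/kg, exclusions at 4 mg/kg). `default_wt_exclusions` encodes that
per-dose choice for the built-in design: the study's mid-curve
exclusions plus all nominal times beyond the dose's depletion window,
where a quantifiable observation can only be assay noise.

Out of scope by design: any further internals of the regulatory tool
(variance-homogeneity pre-tests, outlier rules), tissue withdrawal
periods, multi-dose depletion, Bayesian WT methods.

## Dose comparison

With n = 8 paired animals, asymptotic rank tests are unreliable, so
p-values are exact: the signed-rank null distribution is built over all
2ⁿ sign assignments of the observed |differences| (a subset-sum
convolution over doubled mid-ranks, exact under ties), the rank-sum
null over all C(n_a+n_b, n_a) group assignments. Two-sided
p = 2·min(lower tail, upper tail), tails inclusive, capped at 1. The
signed-rank test is the default for the crossover pairing; the rank-sum
test is provided as the literally named alternative, selectable by
config. Enumeration is used up to n = 20 (signed-rank) / 22 pooled
(rank-sum); beyond that a tie-corrected normal approximation takes over
and is flagged in the result. Normality and variance-homogeneity
pre-tests are deliberately not run: the nonparametric test is applied
unconditionally.

## Synthetic study generator

The generator emulates the study's statistical structure, not its
physiology:

* **Plasma**: C(t) = A·e^(−αt) + B·e^(−βt). Bi-exponential is the
  minimal adequate shape — the reported MRT (2.04 h at the low dose) is
  far below t½/ln 2 (3.48 h), which a mono-exponential cannot produce.
* **Milk**: M(t) = scale·(e^(−k_out·t) − e^(−k_in·t)), a Bateman curve,
  the simplest shape with a finite peak. The complete-udder-emptying
  protocol of the study is not mechanistically modelled.
* **Calibration** solves the macro-constants from the reported summary
  targets instead of hand-tuning. Per dose: β = ln 2/t½; the AUC and
  AUMC constraints are imposed on the observation window [0.08 h, ∞) —
  because the reported targets are themselves NCA outputs whose
  integration starts at the first sample — and C(0.08 h) equals the
  reported C0, which the study defines at 0.08 h. For given α the
  remaining pair is linear, and a 1-D bracketed root search closes the
  system; infeasible targets raise a calibration error naming the
  violated constraint. The milk triple (scale, k_in, k_out) is solved
  from the reported peak (Tmax 0.25 h, Cmax) plus a depletion anchor:
  M(t_last) = LLOQ at the last time milk stayed quantifiable (1.5 h at
  2 mg/kg, 3 h at 4 mg/kg). Anchoring the milk terminal rate to the
  observed depletion window — rather than forcing it parallel to plasma
  β — is what reproduces both the short quantifiable milk span and the
  reported milk AUCs (noise-free 0.23/0.60 h·µg/mL against reported
  0.28/0.55).
* **Variability**: per-subject log-normal random effects, one factor on
  the concentration scale and one on the rate constants (drawn
  separately for plasma and milk so V_dss and MRT vary between
  subjects), plus multiplicative log-normal assay error per
  observation. Both CVs default to 0.10, consistent with the assay's
  reported intra/inter-day precision (≤7.4% plasma, ≤8.4% milk) plus
  biological scatter; no replicate data exist to estimate them, so they
  are stated defaults, not estimates. σ = √ln(1+CV²) makes the CV exact
  on the natural scale.
* **Censoring**: observations below 0.04 µg/mL are BLQ-flagged with the
  value withheld.
* **Randomness**: one root seed feeds a `SeedSequence` spawn tree
  (per subject, then per arm), so identical seeds give bitwise-identical
  datasets and subjects are statistically independent streams. In the
  crossover, subject effects are drawn independently per arm: the two
  arms are calibrated separately (the dose-dependence is empirical, not
  mechanistic), so no shared frailty is imposed.

What passing tests on this generator do **not** show: robustness to
real-world features it omits — sampling-time deviations, correlated
assay drift, milking-interval accumulation, nonlinear protein binding,
or any mechanistic dose-dependence (supra-proportionality enters only
through the separate per-dose calibrations).

## Numerical choices

* λz windows need ≥ 3 points; degenerate (zero-variance) windows score
  NaN and are skipped; a flat or rising best window is "not estimable".
* Log-trapezoid intervals with a zero endpoint fall back to linear.
* The tolerance factor uses `scipy.stats.nct.ppf`; non-finite quantiles
  raise with the inputs echoed.
* WT search: 4097-point bracket grid, bisection to 10⁻⁶ h, supremum
  convention, round-up with a 10⁻⁹-relative guard so exact whole-hour
  estimates are not bumped to the next hour.
* Exact-test tails compare with a 10⁻⁹ epsilon so half-integer mid-rank
  sums are classified stably.
* Geometric summaries refuse non-positive values, naming the offending
  subject.

## Problem sizes used in the shipped checks

The test suite and reproduction script size their simulations to run in
seconds to a few minutes on one CPU: 10,000 Monte-Carlo replicates for
tolerance-limit coverage, 200 simulated studies for WT plausibility,
1,000 simulated comparisons for the test's size and power, 16 replicate
studies (8 subjects each) for the headline summary quantities, and
2,000-point dense grids for the NCA-versus-closed-form oracle checks.

## Known limitations

* The λz window rule is the common automatic convention, not a claim
  about which windows the original analysis used; the `manual` rule
  exists to reproduce any specific fit.
* WT estimates inherit the pooled-regression assumptions (log-linear
  depletion, homoscedastic normal residuals on the ln scale); the
  rising limb of the milk curve is included in the pooled fit exactly as
  the capped time windows dictate, which inflates the residual SD and is
  the main source of conservative (longer) WT estimates at the low dose.
* The exact rank-sum enumeration grows combinatorially; beyond 22 pooled
  observations the normal approximation is used and flagged.
* Dose levels other than 2 and 4 mg/kg have no built-in calibration
  targets; `SimConfig` accepts arbitrary constants for custom studies.
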