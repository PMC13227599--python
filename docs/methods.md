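# Methods

## The model

The package maps combinations of three agents (a propolis extract dosed as a
fold-dilution of a 200 mg/mL raw-equivalent stock, metformin, and
regorafenib) to a phenotypic endpoint — percent cell viability in vitro, or
the per-fish hepatic macrophage infiltration ratio in vivo — with a full
second-order polynomial fitted by ordinary least squares:

    y = b0 + Σ_i b_i x_i + Σ_i b_ii x_i^2 + Σ_{i<j} b_ij x_i x_j + ε

For d = 3 agents this is 10 terms in a frozen order (intercept, 3 linear, 3
squared, 3 pairwise interactions), so coefficient tables are comparable
across endpoints and contexts.  The quadratic form is the simplest family
that captures curvature (diminishing or accelerating returns per agent) and
pairwise drug–drug interaction, while every coefficient stays directly
interpretable.  OLS is retained even when residual diagnostics flag
deviations; in that case nomination leans on the out-of-sample (CV) and
bootstrap evidence rather than on the parametric standard errors.

The fit consumes condition means: technical replicates are first averaged
within each biological replicate, then across biological replicates
(a two-stage mean, not a mixed model — unbalanced technical replication is
averaged as-is and logged).  Per-biological-replicate values are retained on
each aggregated condition so the bootstrap can resample conditions.
A switch (`fit_on="bio_rep"`) fits per-replicate rows as a sensitivity
analysis.

### Numerical conditioning

The agents span ~10 orders of magnitude (fold-dilutions of 1e-4 next to
millimolar concentrations), so raw polynomial columns are catastrophically
ill-conditioned (squares of 1e-4 next to squares of 10).  Internally, doses
are divided by each agent's tested upper bound before the expansion, and
coefficients are back-transformed to original units for reporting; the
back-transform is exact in exact arithmetic, so the original-units contract
is preserved.  The same normalization is applied inside the SLSQP solver
(doses are optimized as fractions of the box), since sequential quadratic
programming's step heuristics fail on wildly unscaled variables.  A z-score
parameterization is available as a sensitivity analysis; it leaves fitted
values and R² unchanged and reports coefficients per SD of dose.

### Degenerate inputs

* Constant response (SST = 0): R² is reported as 1 with a
  `degenerate_fit_` warning flag.
* Rank-deficient designs raise an error naming the collinear terms (QR with
  column pivoting); n < 10 observations raises an under-determined error.
* Prediction outside the tested box raises unless extrapolation is
  explicitly enabled; optimizer iterates may graze the box edge internally.
* Predictions are never clipped during fitting or optimization (clipping
  would destroy smoothness and bias the surface); the report layer clips
  *displayed* predictions at 0 with a flag.

## Adequacy and robustness diagnostics

* **Shapiro–Wilk** on residuals (normality), **Breusch–Pagan**
  (heteroscedasticity; LM statistic n·R² of squared residuals regressed on
  the model design, chi-square with p−1 df), **Durbin–Watson** in run order
  (statistic only, no p-value).  All warn; none aborts nomination.
* **VIF** with flag threshold 3.  VIFs are computed on the mean-centered
  design: doses are rescaled and mean-centered *before* the quadratic
  expansion (the standard polynomial-collinearity remedy), then the expanded
  columns are centered.  On the default grid all VIFs are ≈ 1.0–1.3.
  Centering only the expanded columns of a one-sided dose grid would leave
  linear-vs-squared VIFs of 12–17 — an artifact of parameterization, not of
  the design — which is why the dose-centered convention is used.  Exactly
  collinear terms report VIF = ∞ rather than raising.
* **K-fold CV RMSE** (default K = 5, seeded shuffle; rank-deficient training
  folds are skipped with a warning) pools held-out squared errors over all
  folds.  K is not dictated by the underlying protocol; 5 is the standard
  choice for the small condition counts involved (~27).
* **Nonparametric bootstrap** (default B = 1000 in the library, 200 in the
  example config for speed): case resampling of aggregated *conditions* —
  the unit the model is fit on — with replacement; percentile 95% CIs per
  coefficient; rank-deficient resamples are redrawn and counted, and more
  than B/2 redraws raises a bootstrap-unstable error.  Optionally the
  nomination is re-run per replicate to give per-agent dose CIs.

## Constrained dose nomination

Default ("hard constraint") form: minimize the objective surface (tumor
viability, or macrophage ratio) subject to floor constraints on tolerance
surfaces (predicted hepatocyte viability ≥ θ) and box bounds equal to the
tested dose extremes.  θ is a required analysis choice; the example config
ships θ = 70% purely as a documented demonstration value.  The in vivo
problem uses the macrophage-ratio surface with box bounds only.

Quadratic surfaces on a box can be indefinite, so the solver is a
global–local hybrid: a 31-per-axis vectorized grid pre-scan supplies the
8 best feasible points as SLSQP starts, on top of a seeded 32-point Latin
hypercube, the 8 box corners and the center.  The returned dose is never
worse than the best feasible pre-scan point.  Feasibility tolerance is 1e-6
in endpoint units; objective ties within 1e-6 are broken by lowest total
normalized dose burden Σ(dose/upper), then lexicographically — dose-sparing
and reproducible.  If no feasible point exists the result is flagged
infeasible and carries the constraint-violation minimizer, never a silent
answer.  A weighted-sum scalarization (w₀·objective − Σ w_c·constraint,
floors ignored) is provided as an alternative formulation; hard-constraint
remains the default.  A brute-force tensor-grid oracle (`grid_oracle`)
verifies the optimizer in tests to within one grid cell of objective
variation.

## Endpoint computations

* Infiltration ratio: per-fish area-normalized macrophage density at 15 dpf
  divided by the baseline (9 or 12 dpf) density.  Upstream image analysis
  is out of scope; the contract starts at per-fish densities.  Zero-baseline
  fish are excluded (ratio undefined) with a logged count, never imputed.
  Cohorts mixing 9- and 12-dpf baselines are rejected by default, because
  the baseline timepoint is fixed within one experiment.
* qPCR: efficiency-corrected ΔΔCt with fold change = E^(−ΔΔCt); the default
  per-cycle factor is the calibrated 1.94 (≈94% efficiency), and E = 2
  reduces to the textbook 2^(−ΔΔCt).

## Synthetic data

The generators exist so every stage is testable without any external data;
their defaults are the study conditions the analysis assumes.

* **Viability plates**: value = quadratic truth + per-biological-replicate
  Gaussian offset + per-well Gaussian technical noise; 3 technical × 3
  biological replicates.  Default SDs (technical 5, biological-offset 2
  viability points) are plate-reader-realistic choices; neither is dictated
  by the protocol.  Values are truncated at 0 (viability cannot be
  negative), so noise is mildly right-truncated where the truth approaches
  full kill — unbiasedness checks use surfaces that stay well above 0.
* **Fish cohorts**: baseline density lognormal (log-mean 3.0, log-SD 0.25,
  arbitrary per-area units); endpoint density = baseline × true ratio ×
  per-fish lognormal noise (σ = 0.15) × shared per-batch lognormal factor
  (log-SD 0.05); 2–3 batches of 10–20 fish per group.  Lognormal noise keeps
  densities positive and right-skewed, as count-per-area data are.
* **Dose grid**: per-agent levels {0, ¼, ½, ¾, 1} × upper bound, pruned to a
  deterministic 27-point maximin (space-filling) subset that always contains
  the 8 corners and the center — at least 2× the 10 model terms.  The real
  tested grids are configurable inputs.
* **Context pairs**: the FA (lipid-stress) truth is the FA-free truth plus
  user-specified coefficient deltas; random streams are split per
  (context, replicate/batch) from one root seed, so adding a group never
  perturbs existing draws, and every generator is a pure function of
  (truth, seed).

What passing tests on these generators do **not** show: robustness to plate
edge effects, drift, non-Gaussian outliers, heteroscedastic read noise,
segmentation error in the imaging pipeline, or model misspecification (a
truth outside the quadratic family).  The CV and diagnostic machinery is
what speaks to those risks on real data.

## Problem sizes in tests and the acceptance script

Monte-Carlo components use 100 random nomination problems (51-per-axis
oracle grids), 200 simulation seeds per noise level for coefficient
recovery, 500 null simulations per calibration rate, and fish cohorts of
3 batches × 15 fish over the 27-point grid — sizes chosen so every check
has adequate Monte-Carlo resolution while the whole suite runs in well
under a minute per component.

## Known limitations

* The quadratic family cannot represent plateaus or sigmoidal dose–response
  within the box; it is a local response-surface approximation valid inside
  the tested bounds only, which is why nomination never leaves the box.
* Two-stage means discard within-condition variance information; a mixed
  model would weight unbalanced replication more efficiently.
* Percentile bootstrap CIs are first-order accurate only; with ~27
  conditions, intervals for weakly identified interaction terms are wide.
* The linear dose scale is the default for all agents; a log10 option for
  the dilution axis is a natural extension but changes the design geometry.
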