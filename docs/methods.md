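# Methods

## Setting and estimand

A cohort supplies pairs (Yᵢ, Sᵢ): a binary outcome observed without
intervention (Y = 1, a *case*; Y = 0, a *control*) and a predicted risk
S ∈ (0, 1). A decision policy fixes the risk threshold R at which the
intervention is recommended; R is assumed to encode the harm-benefit
ratio of the intervention, C/B = R/(1−R), and that ratio is held fixed in
every calculation. Clinical utility is the opt-in standardized net
benefit

    sNB = TPR − (R/(1−R)) · ((1−π)/π) · FPR,

estimated by plugging in empirical rates of the rule S > r (strict
inequality throughout; ties at the cutpoint are untreated) and the
empirical prevalence π̂. sNB ≤ 1 with equality only for TPR = 1, FPR = 0.

The recalibration family is f(S) = expit(α₀ + α₁·logit(S)) with α₁ > 0 —
monotone, hence rank-preserving. Scores are clipped to [1e−10, 1−1e−10]
before the logit so all transformed values are finite.

## The sNB-vs-cutpoint curve

For fixed R, the sNB of a recalibrated rule f(S) > R equals the sNB of
the rule S > c at the induced cutpoint c = f⁻¹(R). Sweeping c therefore
enumerates the sNB of every recalibration. The empirical curve is a step
function with jumps only at observed scores, so it is evaluated on the
exact grid of midpoints between consecutive distinct scores plus {0, 1}:
one representative per step, making the recorded maximum exact rather
than grid-resolution-limited. Argmax ties are resolved toward the
cutpoint closest to R (the smallest recalibration shift). Evaluation is
vectorized with binary search over the class-wise sorted scores, so
cohorts of 10⁶ are handled comfortably.

The standard error of the curve maximum is a delta-method expression
evaluated at the argmax r\*, holding π̂ fixed:

    σ̂² = TPR(1−TPR)/n_case + k²·FPR(1−FPR)/n_control,
    k = (R/(1−R))·((1−π̂)/π̂).

Whether prevalence variability should additionally be propagated is a
genuinely open design point; this implementation conditions on π̂ and
pins the consequence with a test requiring agreement with a
1000-replicate bootstrap SE within 25% relative error on calibrated data
at n = 2000. The 1-SE rule flags a model when its sNB is *strictly*
below snb_max − se_max.

## Event-rate smoothing and the weight family

The smoothed observed event rate o(S) is a LOESS fit (local linear, span
0.75, no robustness iterations) of Y on S, evaluated at the subject
scores and clipped to [0, 1]. Above n = 1000 the fit uses the standard
lowess `delta` shortcut (0.5% of the score range) — local fits are
solved at anchor points and interpolated between them, which changes
fitted values negligibly while making n = 10⁵ smooths instant. At least
20 distinct scores are required; constant scores are rejected.

Weights are

    wᵢ = exp(−(o(Sᵢ)−R)²/λ)  if o(Sᵢ) ∈ [Rl, Ru],   wᵢ = δ otherwise,

with two usable forms: `exponential_decay` (interval defaults to [0, 1];
tune λ > 0) and `step` (λ fixed ≥ 10 so in-interval weights are nearly
flat; tune δ). δ is validated against its upper bound, the infimum of
the in-interval weights. Subjects with a non-finite smoothed rate
receive δ — conservative down-weighting of smoothing edge failures. The
effective sample proportion is the mean weight.

## The three estimators

All fits maximize the (weighted) Bernoulli log-likelihood in (α₀, α₁),
scaled by 1/n for conditioning, with analytic gradients, `log(1+eᶻ)`
computed via `logaddexp`, and a hard bound α₁ ≥ 1e−6 enforcing a valid
monotone map. L-BFGS-B with gradient tolerance 1e−8 is the solver; the
objective is concave so the optimum is global. Complete separation
(likelihood unbounded) and optimizer failure are reported through the
`converged` flag rather than an exception. The weighted fit refuses to
run when Σwᵢ < 10 — fewer effective subjects cannot identify two
parameters.

The constrained fit maximizes the unweighted log-likelihood subject to
the plug-in sNB of the recalibrated model being ≥ snb_max − se_max.
Since that plug-in depends on (α₀, α₁) only through the induced cutpoint
c = (logit R − α₀)/α₁, the feasible set is a union of cutpoint
intervals. Runs of feasible grid representatives are merged into closed
intervals of interior points (an inward nudge by construction, which
also resolves the strict-indicator boundary convention). Each interval
is solved by reparametrizing to (c, α₁) with α₀ = logit R − α₁·c, which
turns the two linear constraints into a box on c; box-constrained
L-BFGS-B then finds the interval's unique optimum (the original problem
is concave on a convex wedge and the reparametrization is a
diffeomorphism for α₁ > 0). The best log-likelihood across intervals
wins; exact ties go to the interval whose cutpoint is nearest logit R.
If the standard fit already satisfies the constraint it is returned
exactly (relabeled), so the constrained method departs from standard
recalibration only when there is evidence of lost utility. Direct SLSQP
on the raw linear constraints was tried first and stalled ("positive
directional derivative") on the near-degenerate feasible intervals that
real curves produce; the reparametrization is the robust formulation.

## Cross-validated tuning

One parameter is tuned at a time: λ (exponential form) or δ (step form).
Default grids: λ ∈ logspace(1e−4, 10; 7 points); δ ∈ {0.01, 0.1, 0.25,
0.5, 0.75, bound}. The CV estimand is the held-out sNB at R of the
weighted recalibration: 25 replications of stratified 5-fold CV
(stratified by outcome — rare events destabilize fold-level sNB), with
o(S), the weights, and the fit all computed on the training folds only.
Fold splits failing to contain both classes are redrawn (up to 100
attempts). A candidate whose fit is unidentifiable on some training fold
(too little retained weight) scores −∞ and can never be selected — the
mechanism by which inadequate data push the method back toward standard
recalibration. Selection uses a 1-SE rule oriented the same way: among
candidates within one SE of the best mean, the largest λ (or largest δ)
wins, i.e. the candidate closest to all-ones weights. Everything is
deterministic given the seed.

## Internal validation

Optimism is estimated by the refitting bootstrap: for each of B (default
500) with-replacement resamples, the full procedure (including any CV
tuning it contains) is refit, and the drop in plug-in sNB from the
resample to the original cohort is recorded; the mean drop is subtracted
from the apparent sNB. Confidence intervals are percentile intervals of
the bootstrap apparent sNB. Resamples lacking a class are redrawn; more
than 10% redraws aborts. The multi-method report refits every procedure
on one shared resampling stream so corrected values are paired. TPR/FPR
at R are reported both raw (full-sample fit on the full sample) and as
bootstrap means (resample-fitted models applied to the original sample);
the optimism correction itself applies to sNB only, and neither TPR/FPR
convention is claimed to be canonical.

## The simulator

True risks come from a mixture of three Beta distributions
(low/medium/high-risk subpopulations); the shipped mixture is Beta(2,18),
Beta(6,14), Beta(8,8) with proportions (0.40, 0.35, 0.25), giving
E[Y] = Σ b_m α_m/(α_m+β_m) = 0.27 — a plausible event rate for a
threshold of R = 0.3. Outcomes are Bernoulli(pᵢ). Miscalibration is a
monotone piecewise-cubic (PCHIP) map through increasing control points,
validated numerically on a 10⁴-point grid for monotonicity and range;
the observed score is s = m(p). Since m is strictly increasing, the
population calibration curve of (y, s) is exactly m⁻¹, which the test
suite verifies against a large-sample LOESS curve (sup-norm 0.05 on the
central 90% of scores).

The four archetype maps were chosen once to realize the four qualitative
miscalibration narratives (under near R / over far; under everywhere;
over near R / under far; over everywhere) with visually moderate
distortion; they are conventions, not estimates, and every preset is
overridable through `make_scenario(..., **overrides)` or a YAML scenario
config, so an externally specified parameterization can be dropped in
verbatim.

What the simulator does *not* emulate: covariate-level structure (risks
are drawn directly, not built from risk factors), censoring or event
times (the outcome is a fixed-horizon binary), measurement error in S
beyond the deterministic map, and cohort heterogeneity beyond the
three-component mixture. Passing tests on simulated data therefore
demonstrate correctness of the estimators under the stated generative
model, not robustness to the messiness of real registry data.

## Problem sizes and numerical conventions

Test and validation problem sizes are chosen as the smallest that make
each property sharp: parameter recovery at n = 5×10⁴ (3-SE Wald bands),
the calibrated-score optimality property at n = 10⁵, method-ordering
checks across 20 replicates of n = 5000 fits evaluated on one 10⁶
validation draw per scenario, bootstrap null checks at n = 1000 with
B = 200. Grid oracles for the weighted and constrained optimizers use
step 0.01–0.02 over α₀ ∈ [−3, 3], α₁ ∈ (0, 3], matching the 10⁻²
agreement tolerance. Seeds are explicit everywhere randomness enters;
given a seed, every pipeline stage is bit-for-bit reproducible.

## Known limitations

* The SE of the curve maximum conditions on π̂ and ignores argmax
  selection noise; the bootstrap cross-check bounds, but does not
  eliminate, the discrepancy.
* The plug-in sNB is a step function of the data, so corrected sNB and
  CI endpoints inherit step-function granularity in small cohorts.
* CV tuning optimizes held-out sNB at R only; if calibration over a wide
  interval matters more than utility at R, the step form with a
  hand-chosen δ may be preferable to the tuned exponential form.
* The constrained fit guarantees in-sample sNB near the in-sample
  maximum; out-of-sample superiority is an empirical matter (the
  simulation tests show it holds in the shipped scenarios at n = 5000).
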