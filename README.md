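# snbrecal

Risk-score recalibration that targets clinical utility.

Established risk models — for example a 10-year cardiovascular risk
calculator paired with a treat-above-7.5% guideline — often drift out of
calibration when carried to a new population or a later era. When the
score's sole job is to recommend for or against an intervention at a
mandated risk threshold *R*, what matters is not calibration everywhere
but calibration **at and near R**: miscalibration far from the threshold
never changes a treatment decision. `snbrecal` provides tools for
assessing and repairing exactly that.

## The model

Clinical utility is measured by the standardized net benefit of the
opt-in treatment rule *S > R*,

```
sNB = TPR − (R / (1−R)) · ((1−π) / π) · FPR,
```

where π is the outcome prevalence and the discount factor encodes the
threshold's implied harm-benefit tradeoff C/B = R/(1−R) (R = 7.5% says
the benefit to a case is about 12× the harm to a control). sNB is at most
1, attained only by a perfect rule (TPR = 1, FPR = 0).

Recalibration is restricted to the monotone two-parameter logistic family

```
S′ = expit(α₀ + α₁ · logit(S)),   α₁ > 0,
```

so the score's ranking is preserved. Because any such map moves the
treated set through contiguous blocks of the score ordering, sweeping a
generic cutpoint *r* over [0, 1] (with R fixed in the discount factor)
traces **every sNB attainable by recalibration**. A score is sNB-optimal
among its recalibrations exactly when it is calibrated at R.

On top of that identity the package implements:

* **Graphical assessment** — the sNB-vs-cutpoint curve with a 1-standard-
  error rule: if the original (or standard-recalibrated) score sits more
  than one SE below the curve maximum, recalibration (or a specialized
  method) has something to offer.
* **Standard logistic recalibration** — regress Y on logit(S).
* **Weighted logistic recalibration** — maximize a weighted likelihood
  with weights `w = exp(−(o(S)−R)²/λ)` inside a critical risk interval
  and `δ` outside, where o(S) is a LOESS-smoothed observed event rate;
  λ (or δ) is tuned by 25×5-fold cross-validation with a 1-SE rule that
  falls back toward the standard fit when the data cannot support
  targeted down-weighting. The mean weight (effective sample proportion)
  reports how much information the fit retains.
* **Constrained logistic recalibration** — maximize the ordinary
  likelihood subject to the recalibrated model's plug-in sNB staying
  within one SE of the maximum achievable sNB.
* **Internal validation** — Harrell-style bootstrap optimism correction
  of sNB with percentile confidence intervals, with all methods refit on
  a shared resampling stream for paired comparison.
* **A simulator** — Beta-mixture true risks, Bernoulli outcomes, and
  monotone piecewise-cubic miscalibration maps in four archetypes
  (under/over-estimation near vs. away from the threshold).

## Worked example

```python
import snbrecal as sr

spec = sr.make_scenario("example1")          # under-estimates risk near R
data = sr.CohortData.from_frame(sr.simulate_cohort(spec, n=5000, seed=7))
policy = sr.DecisionPolicy(R=0.3)
report = sr.assess_potential_gain(data, policy)
```

Running `python examples/assess_potential_gain.py` prints:

```
sNB of the original score at R=0.3 : 0.340
sNB after standard recalibration   : 0.337
maximum achievable sNB (any recal) : 0.355
SE of that maximum                 : 0.016
1-SE line                          : 0.339
original flagged below 1-SE line   : False
standard flagged below 1-SE line   : True
```

The curve says the best any recalibration could do on this cohort is an
sNB of 0.355 ± 0.016. The standard recalibration lands below the 1-SE
line, so the targeted methods are worth trying; `fit_constrained` then
returns a fit whose in-sample sNB is guaranteed to be within one SE of
that maximum (see `examples/constrained_recalibration.py`, where the
constrained fit beats the standard one on a large independent validation
draw).

Each script in `examples/` is a narrative of one capability: the
graphical tool, weighted tuning, constrained fitting, bootstrap
validation, and the simulator. A thin CLI wraps the same functions:

```bash
snbrecal simulate --scenario example1 --n 5000 --seed 7 --out cohort.csv
snbrecal assess   --cohort cohort.csv --threshold 0.3 --out assessment/
snbrecal recal    --cohort cohort.csv --method constrained --threshold 0.3 --out model.json
```

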