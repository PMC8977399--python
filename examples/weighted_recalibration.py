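"""Weighted logistic recalibration with cross-validated tuning.

Weights subjects by how close their smoothed observed event rate is to
the policy threshold; lambda (the decay rate) is chosen by 25x5-fold CV
with a 1-SE rule oriented toward standard recalibration.
"""

import snbrecal as sr

spec = sr.make_scenario("example1")
policy = sr.DecisionPolicy(R=0.3, interval=(0.25, 0.35))
data = sr.CohortData.from_frame(sr.simulate_cohort(spec, n=2000, seed=3))

wspec = sr.WeightSpec(form="exponential_decay", lam=1.0)
candidates = [1e-3, 1e-2, 1e-1, 1.0, 10.0]
cv = sr.cv_select(data, wspec, candidates, policy, reps=10, folds=5, seed=3)
for cand, mean, se in zip(cv.candidates, cv.cv_snb_mean, cv.cv_snb_se):
    print(f"lambda={cand:<8g} held-out sNB = {mean:.3f} (SE {se:.3f})")
print(f"selected lambda = {cv.selected:g}")

o = sr.smoothed_event_rate(data)
w = sr.compute_weights(o, wspec.replace(lam=cv.selected), policy)
model = sr.fit_weighted(data, w)
print(f"weighted fit: alpha0={model.alpha0:+.3f} alpha1={model.alpha1:.3f}")
print(f"effective sample proportion = {model.effective_sample_proportion:.2f}")
# The effective sample proportion is the mean weight: how much of the
# cohort's information the targeted fit actually uses.
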