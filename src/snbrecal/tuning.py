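"""Cross-validated selection of the weight-function tuning parameter.

One tuning parameter is selected at a time: lambda for the
exponential-decay weight form, delta for the step form.  The estimand is
the held-out sNB at the policy threshold R of the weighted recalibration,
averaged over repeated stratified K-fold splits (default 25 replications
of 5-fold CV).  Selection follows a 1-standard-error rule oriented toward
standard logistic recalibration: among candidates within one SE of the
best mean, pick the one whose weights are closest to all-ones (largest
lambda, or largest delta).  When the data cannot support targeted
down-weighting, the tuned weighted fit therefore collapses gracefully
toward the standard fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .cohort import CohortData, DecisionPolicy
from .metrics import snb_at_cutpoint
from .recalibrate import fit_weighted
from .weights import WeightSpec, compute_weights, smoothed_event_rate

__all__ = ["CVResult", "cv_select", "default_candidates"]


@dataclass(frozen=True)
class CVResult:
    candidates: np.ndarray
    cv_snb_mean: np.ndarray
    cv_snb_se: np.ndarray
    selected: float
    reps: int
    folds: int

    def to_dict(self) -> dict:
        return {
            "candidates": list(map(float, self.candidates)),
            "cv_snb_mean": list(map(float, self.cv_snb_mean)),
            "cv_snb_se": list(map(float, self.cv_snb_se)),
            "selected": float(self.selected),
            "reps": self.reps,
            "folds": self.folds,
        }


def default_candidates(spec: WeightSpec, policy: DecisionPolicy) -> np.ndarray:
    """Default tuning grids: log-spaced lambdas, or deltas up to their bound."""
    if spec.form == "exponential_decay":
        return np.logspace(-4, 1, 7)
    # delta is capped by the infimum of the in-interval weights; with the
    # step form's large lambda that infimum is close to 1, so cap at the
    # worst case over the interval
    lo, hi = spec.resolve_interval(policy)
    cap = float(np.exp(-max((lo - policy.R) ** 2, (hi - policy.R) ** 2) / spec.lam))
    return np.array([0.01, 0.1, 0.25, 0.5, 0.75, cap])


def _tuning_param(spec: WeightSpec) -> str:
    return "lam" if spec.form == "exponential_decay" else "delta"


def _fold_snb(
    train: CohortData,
    test: CohortData,
    spec: WeightSpec,
    policy: DecisionPolicy,
    o_train: np.ndarray,
) -> float:
    w = compute_weights(o_train, spec, policy)
    try:
        model = fit_weighted(train, w)
    except ValueError:
        # too little weight retained to identify the fit: the data do not
        # support this candidate, so it must never be selected
        return -np.inf
    recal = test.with_scores(model.apply(test.s))
    return snb_at_cutpoint(recal, policy.R, policy)


def _draw_folds(data: CohortData, folds: int, rng: np.random.Generator):
    """Stratified fold splits; re-drawn until every fold sees both classes."""
    for _ in range(100):
        seed = int(rng.integers(0, 2**31 - 1))
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(splitter.split(data.s.reshape(-1, 1), data.y))
        ok = all(
            len(np.unique(data.y[tr])) == 2 and len(np.unique(data.y[te])) == 2
            for tr, te in splits
        )
        if ok:
            return splits
    raise RuntimeError("could not draw stratified folds with both classes present")


def cv_select(
    data: CohortData,
    spec_template: WeightSpec,
    candidates,
    policy: DecisionPolicy,
    reps: int = 25,
    folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Select the weight tuning parameter by repeated stratified K-fold CV.

    For each candidate and each replication: the smoothed event rate and
    the weights are computed on the training folds only, the weighted
    recalibration is fit there, and its sNB at R is evaluated on the
    held-out fold.  Fold means are averaged within a replication; the SE
    per candidate is the standard error of the replication means.
    """
    candidates = np.asarray(list(candidates), dtype=float)
    if candidates.size == 0:
        raise ValueError("no tuning candidates supplied")
    param = _tuning_param(spec_template)
    if candidates.size == 1:
        return CVResult(
            candidates=candidates,
            cv_snb_mean=np.full(1, np.nan),
            cv_snb_se=np.full(1, np.nan),
            selected=float(candidates[0]),
            reps=0,
            folds=folds,
        )

    rng = np.random.default_rng(seed)
    rep_means = np.empty((reps, candidates.size))
    for rep in range(reps):
        splits = _draw_folds(data, folds, rng)
        fold_vals = np.empty((len(splits), candidates.size))
        for k, (tr, te) in enumerate(splits):
            train, test = data.subset(tr), data.subset(te)
            o_train = smoothed_event_rate(train)
            for j, cand in enumerate(candidates):
                spec = spec_template.replace(**{param: float(cand)})
                fold_vals[k, j] = _fold_snb(train, test, spec, policy, o_train)
        rep_means[rep] = fold_vals.mean(axis=0)

    means = rep_means.mean(axis=0)
    supported = np.isfinite(means)
    if not supported.any():
        raise ValueError("no tuning candidate is supported by the data")
    with np.errstate(invalid="ignore"):
        ses = np.where(
            supported,
            rep_means.std(axis=0, ddof=1) / np.sqrt(reps) if reps > 1 else 0.0,
            np.inf,
        )

    best = int(np.argmax(means))
    eligible = means >= means[best] - ses[best]
    # 1-SE rule, oriented toward standard recalibration: the largest
    # eligible lambda (weights -> 1) or the largest eligible delta
    selected = float(candidates[eligible].max())

    return CVResult(
        candidates=candidates,
        cv_snb_mean=means,
        cv_snb_se=ses,
        selected=selected,
        reps=reps,
        folds=folds,
    )
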