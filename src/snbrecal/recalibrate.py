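"""Logistic recalibration: standard, weighted, and sNB-constrained fits.

All three estimators share the two-parameter logistic recalibration family

    f(s) = expit(alpha0 + alpha1 * logit(s)),      alpha1 > 0,

a monotone map of the unit interval onto itself, so every fitted model
preserves the rank order of the scores.

* ``fit_standard`` is the classical logistic recalibration: regress Y on
  Z = logit(S).
* ``fit_weighted`` maximizes the weighted Bernoulli log-likelihood, with
  per-subject weights that prioritize calibration near the policy
  threshold (see :mod:`snbrecal.weights`).
* ``fit_constrained`` maximizes the unweighted log-likelihood subject to
  the recalibrated model's plug-in sNB staying within one standard error
  of the maximum achievable sNB.  The constraint depends on (alpha0,
  alpha1) only through the induced cutpoint c = (logit R - alpha0)/alpha1
  on the logit-score axis, so the feasible set is a union of cutpoint
  intervals; within each, the two linear constraints keep the problem
  concave and the global solution is the best across intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .cohort import EPS, CohortData, DecisionPolicy
from .metrics import SNBCurve, snb_at_cutpoint, snb_curve

__all__ = [
    "RecalModel",
    "apply_recal",
    "fit_standard",
    "fit_weighted",
    "fit_constrained",
    "recalibrated_snb",
]

#: lower bound on the recalibration slope during optimization
ALPHA1_MIN = 1e-6
#: gradient-norm convergence tolerance
GTOL = 1e-8


@dataclass(frozen=True)
class RecalModel:
    """A fitted recalibration map expit(alpha0 + alpha1 * logit(s))."""

    alpha0: float
    alpha1: float
    method: str = "standard"
    effective_sample_proportion: float = 1.0
    converged: bool = True
    constraint_bound: float | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.alpha1 > 0:
            raise ValueError("recalibration slope alpha1 must be positive")

    def apply(self, s: np.ndarray) -> np.ndarray:
        return apply_recal(self, s)

    def induced_cutpoint(self, policy: DecisionPolicy) -> float:
        """Cutpoint c on the logit-score axis equivalent to the rule f(s) > R."""
        return (policy.logit_R - self.alpha0) / self.alpha1

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "alpha0": self.alpha0,
            "alpha1": self.alpha1,
            "method": self.method,
            "effective_sample_proportion": self.effective_sample_proportion,
            "converged": self.converged,
            "constraint_bound": self.constraint_bound,
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2))
        return payload

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "RecalModel":
        if not isinstance(source, dict):
            source = json.loads(Path(source).read_text())
        return cls(**source)


def apply_recal(model: RecalModel, s: np.ndarray) -> np.ndarray:
    """Recalibrated risks expit(alpha0 + alpha1 * logit(s)); rank-preserving."""
    if not model.alpha1 > 0:
        raise ValueError("recalibration slope alpha1 must be positive")
    z = logit(np.clip(np.asarray(s, dtype=float), EPS, 1.0 - EPS))
    return expit(model.alpha0 + model.alpha1 * z)


def _neg_loglik_and_grad(theta, z, y, w):
    # per-subject (1/n) scaling keeps gradients O(1) at any cohort size
    a0, a1 = theta
    n = y.size
    eta = a0 + a1 * z
    # log(1 + e^eta) via logaddexp for stability at extreme logits
    nll = -np.sum(w * (y * eta - np.logaddexp(0.0, eta))) / n
    resid = w * (y - expit(eta))
    grad = -np.array([resid.sum(), (resid * z).sum()]) / n
    return nll, grad


def _maximize_weighted(z, y, w, x0=(0.0, 1.0)) -> tuple[np.ndarray, bool]:
    res = minimize(
        _neg_loglik_and_grad,
        x0=np.asarray(x0, dtype=float),
        args=(z, y, w),
        jac=True,
        method="L-BFGS-B",
        bounds=[(None, None), (ALPHA1_MIN, None)],
        options={"gtol": GTOL, "maxiter": 500},
    )
    return res.x, bool(res.success)


def _check_fit_inputs(data: CohortData) -> np.ndarray:
    data.require_both_classes()
    if np.unique(data.s).size < 2:
        raise ValueError("need at least 2 distinct scores to fit a recalibration")
    return logit(data.s)


def _is_separated(z: np.ndarray, y: np.ndarray) -> bool:
    if not ((y == 1).any() and (y == 0).any()):
        return True  # a single-class likelihood cannot identify both parameters
    return float(z[y == 1].min()) > float(z[y == 0].max())


def fit_standard(data: CohortData) -> RecalModel:
    """Classical logistic recalibration: regress Y on logit(S).

    Complete separation makes the likelihood unbounded; the returned model
    then carries ``converged=False``.
    """
    z = _check_fit_inputs(data)
    theta, ok = _maximize_weighted(z, data.y.astype(float), np.ones(data.n))
    converged = ok and not _is_separated(z, data.y)
    return RecalModel(
        alpha0=float(theta[0]),
        alpha1=float(theta[1]),
        method="standard",
        effective_sample_proportion=1.0,
        converged=converged,
    )


def fit_weighted(data: CohortData, w: np.ndarray) -> RecalModel:
    """Weighted-likelihood logistic recalibration.

    Maximizes sum_i w_i * [y_i * eta_i - log(1 + e^eta_i)] with
    eta_i = alpha0 + alpha1 * logit(s_i).  With all weights 1 this is
    exactly ``fit_standard``.
    """
    z = _check_fit_inputs(data)
    w = np.asarray(w, dtype=float)
    if w.shape != data.y.shape:
        raise ValueError("weights must align with the cohort")
    if (w < 0).any() or (w > 1).any():
        raise ValueError("weights must lie in [0, 1]")
    if w.sum() < 10:
        raise ValueError(
            f"effective subjects sum(w) = {w.sum():.3g} < 10: too few to "
            "identify intercept and slope"
        )
    theta, ok = _maximize_weighted(z, data.y.astype(float), w)
    active = w > 0
    converged = ok and not _is_separated(z[active], data.y[active])
    return RecalModel(
        alpha0=float(theta[0]),
        alpha1=float(theta[1]),
        method="weighted",
        effective_sample_proportion=float(w.mean()),
        converged=converged,
    )


def recalibrated_snb(
    model: RecalModel, data: CohortData, policy: DecisionPolicy
) -> float:
    """Plug-in sNB of the recalibrated score at the policy threshold R.

    Equals the sNB-vs-cutpoint curve of the *original* score evaluated at
    the model's induced cutpoint — the identity that makes the constrained
    problem tractable.
    """
    return snb_at_cutpoint(data.with_scores(model.apply(data.s)), policy.R, policy)


def _feasible_intervals(
    curve: SNBCurve, bound: float
) -> list[tuple[float, float]]:
    """Maximal cutpoint intervals (logit scale) where the curve meets the bound.

    Grid cutpoints are interior representatives of the steps of the sNB
    step function; merging consecutive feasible representatives into closed
    intervals therefore yields intervals that are feasible throughout
    (inward-nudged by construction, resolving boundary ties).
    """
    feasible = curve.snb >= bound - 1e-12
    z_grid = logit(np.clip(curve.cutpoints, EPS, 1.0 - EPS))
    intervals: list[tuple[float, float]] = []
    start = None
    for i, ok in enumerate(feasible):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            intervals.append((float(z_grid[start]), float(z_grid[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(z_grid[start]), float(z_grid[-1])))
    return intervals


def fit_constrained(data: CohortData, policy: DecisionPolicy) -> RecalModel:
    """sNB-constrained logistic recalibration.

    Maximizes the logistic log-likelihood subject to the recalibrated
    model's plug-in sNB being at least snb_max - se(snb_max).  If the
    standard fit already satisfies the constraint, it is returned exactly
    (relabeled), mirroring the design intent: the constrained method only
    departs from standard recalibration when there is evidence the latter
    loses clinical utility.
    """
    z = _check_fit_inputs(data)
    y = data.y.astype(float)
    curve = snb_curve(data, policy)
    bound = curve.snb_max - curve.se_max

    standard = fit_standard(data)
    if recalibrated_snb(standard, data, policy) >= bound - 1e-12:
        return RecalModel(
            alpha0=standard.alpha0,
            alpha1=standard.alpha1,
            method="constrained",
            effective_sample_proportion=1.0,
            converged=standard.converged,
            constraint_bound=float(bound),
        )

    intervals = _feasible_intervals(curve, bound)
    if not intervals:  # cannot occur: the argmax step is always feasible
        raise RuntimeError("empty feasible cutpoint set for the sNB constraint")

    logit_R = policy.logit_R
    w = np.ones(data.n)

    # Within one interval the binding structure is a0 + a1*c = free with
    # c in [c_lo, c_hi]: reparametrize to (c, a1) with a0 = logit R - a1*c.
    # The original problem is concave on a convex wedge, the map is a
    # diffeomorphism for a1 > 0, so box-constrained L-BFGS-B finds the
    # interval's unique optimum.
    def nll_c(theta):
        c, a1 = theta
        a0 = logit_R - a1 * c
        nll, (g0, g1) = _neg_loglik_and_grad((a0, a1), z, y, w)
        return nll, np.array([-a1 * g0, g1 - c * g0])

    best = None  # (nll, |c - logit_R|, theta, success)
    for c_lo, c_hi in intervals:
        c_mid = 0.5 * (c_lo + c_hi)
        a1_0 = max(standard.alpha1, ALPHA1_MIN)
        res = minimize(
            nll_c,
            x0=np.array([c_mid, a1_0]),
            jac=True,
            method="L-BFGS-B",
            bounds=[(c_lo, c_hi), (ALPHA1_MIN, None)],
            options={"gtol": GTOL, "maxiter": 500},
        )
        c_hat, a1_hat = res.x
        theta = np.array([logit_R - a1_hat * c_hat, a1_hat])
        key = (res.fun, abs(c_hat - logit_R))
        if best is None or key < (best[0], best[1]):
            best = (res.fun, abs(c_hat - logit_R), theta, bool(res.success))

    _, _, theta, success = best
    model = RecalModel(
        alpha0=float(theta[0]),
        alpha1=float(max(theta[1], ALPHA1_MIN)),
        method="constrained",
        effective_sample_proportion=1.0,
        converged=success,
        constraint_bound=float(bound),
    )
    return model
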