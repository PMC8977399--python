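"""Standardized net benefit (sNB) and the sNB-versus-cutpoint curve.

For a risk model S, outcome Y, and clinically mandated risk threshold R,

    sNB = TPR - (R / (1-R)) * ((1-pi) / pi) * FPR,

the "opt-in" net benefit (default policy: treat no one) divided by the
prevalence pi.  Its maximum is 1, attained exactly by a perfectly
discriminating, calibrated model (TPR = 1, FPR = 0).

Because any monotone recalibration of S only moves the treated set through
contiguous blocks of the score ordering, sweeping a generic cutpoint r over
[0, 1] while holding R fixed traces every sNB value attainable by
recalibrating S.  The maximum of that curve is the sNB the score would have
if it were calibrated at R; the gap between the curve value at r = R and
the maximum is the utility lost to miscalibration at R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortData, DecisionPolicy

__all__ = [
    "RateEstimates",
    "SNBCurve",
    "classification_rates",
    "snb_at_cutpoint",
    "snb_curve",
    "max_snb_se",
    "harm_benefit_ratio",
]


@dataclass(frozen=True)
class RateEstimates:
    """True- and false-positive rates of the rule s > cutpoint."""

    tpr: float
    fpr: float


@dataclass(frozen=True)
class SNBCurve:
    """sNB evaluated over an exact cutpoint grid, for a fixed policy.

    The grid consists of the midpoints between consecutive sorted distinct
    scores plus the endpoints {0, 1}.  sNB as a function of the cutpoint is
    a step function with jumps only at observed scores, so this grid visits
    every step exactly once and the recorded maximum is exact.
    """

    cutpoints: np.ndarray
    snb: np.ndarray
    r_star: float
    snb_max: float
    se_max: float
    snb_at_R: float
    R: float


def _discount(data: CohortData, policy: DecisionPolicy) -> float:
    """The sNB discount factor k = (R/(1-R)) * ((1-pi)/pi)."""
    pi = data.prevalence_hat
    if pi == 0.0:
        raise ValueError("prevalence is zero: sNB discount factor undefined")
    return (policy.R / (1.0 - policy.R)) * ((1.0 - pi) / pi)


def classification_rates(data: CohortData, cutpoint: float) -> RateEstimates:
    """TPR and FPR of the treatment rule ``s > cutpoint``.

    Ties at the cutpoint are untreated (strict inequality), matching the
    indicator in the plug-in sNB estimator.
    """
    data.require_both_classes()
    treated = data.s > cutpoint
    cases = data.y == 1
    tpr = float(treated[cases].sum()) / data.n_case
    fpr = float(treated[~cases].sum()) / data.n_control
    return RateEstimates(tpr=tpr, fpr=fpr)


def snb_at_cutpoint(data: CohortData, cutpoint: float, policy: DecisionPolicy) -> float:
    """sNB of the rule ``s > cutpoint`` at fixed policy threshold R.

    At ``cutpoint == policy.R`` this is the standardized net benefit of the
    risk model itself.
    """
    rates = classification_rates(data, cutpoint)
    return rates.tpr - _discount(data, policy) * rates.fpr


def _curve_grid(scores: np.ndarray) -> np.ndarray:
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise ValueError("need at least 2 distinct scores to trace an sNB curve")
    mids = 0.5 * (distinct[:-1] + distinct[1:])
    return np.concatenate(([0.0], mids, [1.0]))


def snb_curve(data: CohortData, policy: DecisionPolicy) -> SNBCurve:
    """Trace sNB over every attainable treated set of the score ordering.

    Vectorized: for each grid cutpoint the counts of exceeding cases and
    controls come from binary search on the sorted class-wise scores.
    Argmax ties are broken toward the cutpoint closest to R (the smallest
    recalibration shift).
    """
    data.require_both_classes()
    grid = _curve_grid(data.s)
    case_s = np.sort(data.s[data.y == 1])
    ctrl_s = np.sort(data.s[data.y == 0])
    tpr = (data.n_case - np.searchsorted(case_s, grid, side="right")) / data.n_case
    fpr = (data.n_control - np.searchsorted(ctrl_s, grid, side="right")) / data.n_control
    snb = tpr - _discount(data, policy) * fpr

    snb_max = float(snb.max())
    at_max = np.flatnonzero(snb >= snb_max - 1e-12)
    r_star = float(grid[at_max[np.argmin(np.abs(grid[at_max] - policy.R))]])

    rates = classification_rates(data, r_star)
    k = _discount(data, policy)
    var = rates.tpr * (1.0 - rates.tpr) / data.n_case
    var += k * k * rates.fpr * (1.0 - rates.fpr) / data.n_control

    return SNBCurve(
        cutpoints=grid,
        snb=snb,
        r_star=r_star,
        snb_max=snb_max,
        se_max=float(np.sqrt(var)),
        snb_at_R=snb_at_cutpoint(data, policy.R, policy),
        R=policy.R,
    )


def max_snb_se(data: CohortData, curve: SNBCurve, policy: DecisionPolicy) -> float:
    """Standard error of the curve maximum, via the delta method at r*.

    Treating the empirical prevalence as fixed, the maximum is a linear
    combination of two independent binomial proportions, so

        var = tpr(1-tpr)/n_case + k^2 * fpr(1-fpr)/n_control,

    with k the sNB discount factor.  Perfect separation (tpr = 1, fpr = 0)
    gives SE 0.
    """
    rates = classification_rates(data, curve.r_star)
    k = _discount(data, policy)
    var = rates.tpr * (1.0 - rates.tpr) / data.n_case
    var += k * k * rates.fpr * (1.0 - rates.fpr) / data.n_control
    return float(np.sqrt(var))


def harm_benefit_ratio(policy: DecisionPolicy) -> float:
    """Benefit-to-harm ratio B/C = (1-R)/R implied by the threshold.

    A threshold of 7.5% asserts the benefit of intervening on a case is
    about 12 times the harm of intervening on a control.
    """
    return (1.0 - policy.R) / policy.R
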