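"""Smoothed event rates, calibration curves, and the recalibration weights.

The weighted recalibration strategy down-weights subjects whose smoothed
observed event rate o(S) sits far from the policy threshold R:

    w_i = exp(-(o(S_i) - R)^2 / lambda)   if o(S_i) in [r_lower, r_upper]
    w_i = delta                           otherwise.

Two special forms cover practice: an exponential-decay weight (interval
[0, 1], tune lambda) concentrating on the single threshold R, and a
near-step weight (lambda fixed large, tune delta) prioritizing a critical
risk interval.  All weights live in [0, 1], so the mean weight is the
effective sample proportion — the fraction of the cohort's information the
weighted fit actually uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from statsmodels.nonparametric.smoothers_lowess import lowess

from .cohort import CohortData, DecisionPolicy

__all__ = [
    "WeightSpec",
    "CalibrationCurve",
    "smoothed_event_rate",
    "calibration_curve",
    "compute_weights",
    "effective_sample_proportion",
]

#: LOESS span (fraction of data in each local fit)
LOESS_SPAN = 0.75
#: minimum lambda for the step form, which should flatten in-interval weights
STEP_MIN_LAMBDA = 10.0


@dataclass(frozen=True)
class WeightSpec:
    """Weight-family configuration.

    Parameters
    ----------
    form : {"exponential_decay", "step"}
        ``exponential_decay``: weight decays smoothly with the squared
        distance of the smoothed event rate from R; ``interval`` defaults
        to [0, 1] so ``delta`` is irrelevant.  ``step``: ``lam`` is fixed
        large (>= 10) so in-interval weights are all near 1, and ``delta``
        sets the (smaller) constant weight outside the interval.
    lam : float
        Positive decay parameter lambda.
    delta : float
        Weight for subjects whose event rate falls outside the interval;
        must lie in [0, infimum of the in-interval weights].
    interval : (float, float), optional
        Critical risk interval [r_lower, r_upper]; defaults to the policy's
        interval or, for the exponential form, to [0, 1].
    """

    form: str = "exponential_decay"
    lam: float = 1.0
    delta: float = 0.0
    interval: tuple[float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.form not in ("exponential_decay", "step"):
            raise ValueError(f"unknown weight form {self.form!r}")
        if not self.lam > 0:
            raise ValueError("lambda must be positive")
        if self.form == "step" and self.lam < STEP_MIN_LAMBDA:
            raise ValueError(
                f"step form requires lambda >= {STEP_MIN_LAMBDA} so in-interval "
                "weights are flat"
            )
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError("delta must lie in [0, 1]")

    def resolve_interval(self, policy: DecisionPolicy) -> tuple[float, float]:
        if self.interval is not None:
            return self.interval
        if self.form == "step":
            if policy.interval is None:
                raise ValueError("step weights need a critical risk interval")
            return policy.interval
        return (0.0, 1.0)

    def replace(self, **kwargs) -> "WeightSpec":
        cfg = {
            "form": self.form,
            "lam": self.lam,
            "delta": self.delta,
            "interval": self.interval,
        }
        cfg.update(kwargs)
        return WeightSpec(**cfg)

    # -- key-value config round trip -------------------------------------
    def to_config(self, path: str | Path) -> None:
        cfg = {"form": self.form, "lambda": float(self.lam), "delta": float(self.delta)}
        if self.interval is not None:
            cfg["r_lower"], cfg["r_upper"] = map(float, self.interval)
        Path(path).write_text(yaml.safe_dump(cfg))

    @classmethod
    def from_config(cls, path: str | Path) -> "WeightSpec":
        cfg = yaml.safe_load(Path(path).read_text())
        interval = None
        if "r_lower" in cfg or "r_upper" in cfg:
            interval = (float(cfg["r_lower"]), float(cfg["r_upper"]))
        return cls(
            form=cfg.get("form", "exponential_decay"),
            lam=float(cfg.get("lambda", 1.0)),
            delta=float(cfg.get("delta", 0.0)),
            interval=interval,
        )


@dataclass(frozen=True)
class CalibrationCurve:
    """Smoothed observed event rate over a grid of score values."""

    grid: np.ndarray
    observed: np.ndarray


def _loess_fit(data: CohortData, xvals: np.ndarray) -> np.ndarray:
    # delta > 0 makes lowess interpolate linearly between nearby anchor
    # points instead of solving every local regression; at large n this is
    # the standard speed/accuracy tradeoff and is visually indistinguishable
    span = float(data.s.max() - data.s.min())
    delta = 0.005 * span if data.n > 1000 else 0.0
    fitted = lowess(
        data.y.astype(float),
        data.s,
        frac=LOESS_SPAN,
        it=0,
        delta=delta,
        return_sorted=True,
    )
    # evaluate at the requested points by interpolation along the fit
    return np.interp(xvals, fitted[:, 0], fitted[:, 1])


def smoothed_event_rate(data: CohortData) -> np.ndarray:
    """LOESS-smoothed observed event rate o(S_i) at every subject's score.

    Local linear regression of y on s (span 0.75, no robustness
    iterations), evaluated at each observed score and clipped to [0, 1].
    Requires at least 20 distinct scores.
    """
    distinct = np.unique(data.s)
    if distinct.size < 20:
        raise ValueError(
            f"need >= 20 distinct scores for event-rate smoothing; got {distinct.size}"
        )
    fitted = _loess_fit(data, data.s)
    return np.clip(fitted, 0.0, 1.0)


def calibration_curve(data: CohortData, n_grid: int = 100) -> CalibrationCurve:
    """Calibration curve on an even grid over the observed score range.

    For a calibrated model the curve is the identity line; a curve below
    the identity means risks are overestimated.
    """
    if n_grid < 2:
        raise ValueError("n_grid must be at least 2")
    distinct = np.unique(data.s)
    if distinct.size < 20:
        raise ValueError(
            f"need >= 20 distinct scores for event-rate smoothing; got {distinct.size}"
        )
    grid = np.linspace(data.s.min(), data.s.max(), n_grid)
    fitted = _loess_fit(data, grid)
    return CalibrationCurve(grid=grid, observed=np.clip(fitted, 0.0, 1.0))


def compute_weights(
    o: np.ndarray, spec: WeightSpec, policy: DecisionPolicy
) -> np.ndarray:
    """Per-subject weights from smoothed event rates.

    Subjects with non-finite event rate (smoothing edge failures) receive
    the out-of-interval weight delta, a conservative down-weighting.
    """
    o = np.asarray(o, dtype=float)
    lo, hi = spec.resolve_interval(policy)
    finite = np.isfinite(o)
    inside = finite & (o >= lo) & (o <= hi)
    w = np.full(o.shape, spec.delta, dtype=float)
    w[inside] = np.exp(-((o[inside] - policy.R) ** 2) / spec.lam)
    if inside.any():
        inf_weight = float(w[inside].min())
        if spec.delta > inf_weight + 1e-12:
            raise ValueError(
                f"delta = {spec.delta} exceeds the infimum of the in-interval "
                f"weights ({inf_weight:.6g})"
            )
    return w


def effective_sample_proportion(w: np.ndarray) -> float:
    """Mean weight: the fraction of the sample the weighted fit retains."""
    w = np.asarray(w, dtype=float)
    if w.size == 0:
        raise ValueError("empty weight vector")
    if (w < 0).any() or (w > 1).any():
        raise ValueError("weights must lie in [0, 1]")
    return float(w.mean())
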