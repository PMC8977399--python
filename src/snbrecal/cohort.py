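"""Cohort containers and the decision policy.

A cohort is the universal input for every operation in this package: one
binary outcome ``y`` (1 = case, i.e. the subject experiences the event
without intervention; 0 = control) and one predicted risk ``s`` in (0, 1)
per subject.  The decision policy carries the clinically mandated risk
threshold ``R`` — the cutoff above which the intervention is recommended —
and, optionally, a critical risk interval ``[r_lower, r_upper]`` over which
good calibration matters to clinicians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CohortData", "DecisionPolicy", "read_cohort", "write_cohort"]

#: risks are clipped into [EPS, 1 - EPS] so that logit(s) is always finite
EPS = 1e-10


@dataclass(frozen=True)
class CohortData:
    """Paired outcome / risk-score vectors.

    Parameters
    ----------
    y : array-like of {0, 1}
        Observed binary outcome per subject.
    s : array-like of float
        Predicted risk per subject, in the open interval (0, 1).  Values
        outside ``[EPS, 1 - EPS]`` are clipped on construction so the logit
        transform stays finite.
    """

    y: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        s = np.asarray(self.s, dtype=float)
        if y.ndim != 1 or s.ndim != 1 or y.shape != s.shape:
            raise ValueError("y and s must be one-dimensional and equal length")
        if y.size == 0:
            raise ValueError("empty cohort")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("outcome y must be binary (0/1)")
        if not np.isfinite(s).all():
            raise ValueError("risk scores must be finite")
        if (s < 0).any() or (s > 1).any():
            raise ValueError("risk scores must lie in (0, 1)")
        object.__setattr__(self, "y", y.astype(np.int8))
        object.__setattr__(self, "s", np.clip(s, EPS, 1.0 - EPS))

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def n_case(self) -> int:
        return int(self.y.sum())

    @property
    def n_control(self) -> int:
        return self.n - self.n_case

    @property
    def prevalence_hat(self) -> float:
        """Empirical prevalence π̂ = n_case / n."""
        return self.n_case / self.n

    def require_both_classes(self) -> None:
        """Raise unless the cohort contains at least one case and one control."""
        if self.n_case == 0:
            raise ValueError("cohort contains no cases (y == 1); cannot proceed")
        if self.n_control == 0:
            raise ValueError("cohort contains no controls (y == 0); cannot proceed")

    def subset(self, index: np.ndarray) -> "CohortData":
        return CohortData(self.y[index], self.s[index])

    def with_scores(self, s: np.ndarray) -> "CohortData":
        """Same subjects, new scores (e.g. after recalibration)."""
        return CohortData(self.y, s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"y": self.y.astype(int), "s": self.s})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CohortData":
        for col in ("y", "s"):
            if col not in frame.columns:
                raise ValueError(f"cohort table is missing required column {col!r}")
        return cls(frame["y"].to_numpy(), frame["s"].to_numpy())


@dataclass(frozen=True)
class DecisionPolicy:
    """Risk threshold R and optional critical risk interval [r_lower, r_upper].

    ``R`` encodes the harm-benefit tradeoff of the intervention through
    C/B = R/(1-R) and is fixed a priori; it is never varied when tracing
    the sNB-versus-cutpoint curve.
    """

    R: float
    interval: tuple[float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if not (0.0 < self.R < 1.0):
            raise ValueError(f"risk threshold R must be in (0, 1); got {self.R}")
        if self.interval is not None:
            lo, hi = self.interval
            if not (0.0 <= lo <= self.R <= hi <= 1.0):
                raise ValueError(
                    f"critical risk interval [{lo}, {hi}] must satisfy "
                    f"0 <= r_lower <= R <= r_upper <= 1 (R = {self.R})"
                )
            object.__setattr__(self, "interval", (float(lo), float(hi)))

    @property
    def logit_R(self) -> float:
        return float(np.log(self.R / (1.0 - self.R)))


def read_cohort(path: str | Path, sep: str | None = None) -> CohortData:
    """Read a delimited cohort table with required columns ``y`` and ``s``.

    The delimiter is sniffed (comma/tab) unless given; extra columns are
    ignored.
    """
    frame = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    return CohortData.from_frame(frame)


def write_cohort(frame: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
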