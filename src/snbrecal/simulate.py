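"""Synthetic cohorts: Beta-mixture risks, Bernoulli outcomes, miscalibration.

The generator emulates a recalibration study: true risks p_i are drawn
from a three-component Beta mixture (subpopulations tending to low,
medium, or high risk), outcomes are Bernoulli(p_i), and the observed risk
*score* is a monotone piecewise-polynomial distortion of the true risk,
s_i = m(p_i).  Because m is strictly increasing, the score retains the
rank order of the true risks — it is a miscalibrated but still
recalibratable model — and the population calibration curve of the
simulated data is exactly the inverse map m^{-1}.

Four shipped archetypes cover the canonical miscalibration patterns at a
policy threshold R = 0.3:

* ``example1`` — underestimation near R, overestimation elsewhere;
* ``example2`` — underestimation everywhere;
* ``example3`` — overestimation near R, underestimation far from R;
* ``example4`` — overestimation everywhere.

Every preset parameter (components, mixing, map control points, R) can be
overridden, so externally specified scenario parameters can be dropped in
verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import PchipInterpolator

from .cohort import CohortData

__all__ = [
    "ScenarioSpec",
    "make_scenario",
    "sample_true_risks",
    "sample_outcomes",
    "apply_miscalibration",
    "simulate_cohort",
    "SCENARIO_NAMES",
]

#: grid resolution used to validate map monotonicity and range
_CHECK_GRID = 10_000

# Shared Beta mixture: subpopulations with low / medium / high true risk.
_DEFAULT_COMPONENTS = ((2.0, 18.0), (6.0, 14.0), (8.0, 8.0))
_DEFAULT_MIXING = (0.40, 0.35, 0.25)

# Monotone control points (p, m(p)) for each archetype's miscalibration
# map; the map is the monotone piecewise-cubic (PCHIP) interpolant.
_ARCHETYPE_KNOTS = {
    # under near R = 0.3, over elsewhere
    "example1": ((0.0, 0.0), (0.08, 0.12), (0.30, 0.22), (0.55, 0.62), (0.75, 0.82), (1.0, 1.0)),
    # under everywhere
    "example2": ((0.0, 0.0), (0.20, 0.12), (0.50, 0.38), (0.80, 0.70), (1.0, 1.0)),
    # over near R, under far from R
    "example3": ((0.0, 0.0), (0.08, 0.05), (0.30, 0.38), (0.55, 0.50), (0.80, 0.72), (1.0, 1.0)),
    # over everywhere
    "example4": ((0.0, 0.0), (0.20, 0.30), (0.50, 0.62), (0.80, 0.88), (1.0, 1.0)),
}
SCENARIO_NAMES = tuple(_ARCHETYPE_KNOTS) + ("identity",)

_IDENTITY_KNOTS = ((0.0, 0.0), (0.5, 0.5), (1.0, 1.0))


@dataclass(frozen=True)
class ScenarioSpec:
    """Full parameterization of one simulation scenario.

    ``miscal_knots`` are (x, y) control points of the monotone piecewise
    polynomial miscalibration map (PCHIP through the points); monotonicity
    and range are validated numerically on a dense grid at construction.
    """

    components: tuple[tuple[float, float], ...] = _DEFAULT_COMPONENTS
    mixing: tuple[float, ...] = _DEFAULT_MIXING
    miscal_knots: tuple[tuple[float, float], ...] = _IDENTITY_KNOTS
    name: str = "custom"
    R: float = 0.3

    def __post_init__(self) -> None:
        if len(self.components) != len(self.mixing):
            raise ValueError("one mixing proportion per Beta component required")
        for a, b in self.components:
            if a <= 0 or b <= 0:
                raise ValueError("Beta shape parameters must be positive")
        mix = np.asarray(self.mixing, dtype=float)
        if (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("mixing proportions must be a probability simplex")
        knots = np.asarray(self.miscal_knots, dtype=float)
        if knots.ndim != 2 or knots.shape[0] < 2:
            raise ValueError("miscalibration map needs at least 2 control points")
        grid = np.linspace(0.0, 1.0, _CHECK_GRID)
        vals = PchipInterpolator(knots[:, 0], knots[:, 1])(grid)
        if (np.diff(vals) < -1e-12).any():
            raise ValueError("miscalibration map must be monotone non-decreasing")
        if vals.min() < -1e-9 or vals.max() > 1.0 + 1e-9:
            raise ValueError("miscalibration map must take values in [0, 1]")

    @property
    def miscal_map(self) -> PchipInterpolator:
        knots = np.asarray(self.miscal_knots, dtype=float)
        return PchipInterpolator(knots[:, 0], knots[:, 1])

    @property
    def expected_event_rate(self) -> float:
        """E[Y] = sum_m b_m * alpha_m / (alpha_m + beta_m)."""
        return float(
            sum(b * a / (a + bb) for (a, bb), b in zip(self.components, self.mixing))
        )

    # -- key-value config round trip -------------------------------------
    def to_config(self, path: str | Path) -> None:
        cfg = {
            "name": self.name,
            "R": float(self.R),
            "components": [list(map(float, c)) for c in self.components],
            "mixing": list(map(float, self.mixing)),
            "miscal_knots": [list(map(float, k)) for k in self.miscal_knots],
        }
        Path(path).write_text(yaml.safe_dump(cfg))

    @classmethod
    def from_config(cls, path: str | Path) -> "ScenarioSpec":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(
            components=tuple(tuple(c) for c in cfg["components"]),
            mixing=tuple(cfg["mixing"]),
            miscal_knots=tuple(tuple(k) for k in cfg["miscal_knots"]),
            name=cfg.get("name", "custom"),
            R=float(cfg.get("R", 0.3)),
        )


def make_scenario(name: str, **overrides) -> ScenarioSpec:
    """Build a scenario preset by archetype name, with optional overrides."""
    if name == "identity":
        knots = _IDENTITY_KNOTS
    elif name in _ARCHETYPE_KNOTS:
        knots = _ARCHETYPE_KNOTS[name]
    else:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        )
    params = {"miscal_knots": knots, "name": name}
    params.update(overrides)
    return ScenarioSpec(**params)


def sample_true_risks(
    spec: ScenarioSpec, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw n true risks from the scenario's Beta mixture."""
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty(0)
    comp = rng.choice(len(spec.components), size=n, p=np.asarray(spec.mixing))
    shapes = np.asarray(spec.components, dtype=float)
    return rng.beta(shapes[comp, 0], shapes[comp, 1])


def sample_outcomes(p: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """Independent Bernoulli(p_i) outcomes."""
    rng = np.random.default_rng(seed)
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("true risks must lie in [0, 1]")
    return rng.binomial(1, p).astype(np.int8)


def apply_miscalibration(p: np.ndarray, spec: ScenarioSpec) -> np.ndarray:
    """Observed (miscalibrated) scores s_i = m(p_i); rank order preserved."""
    return np.clip(spec.miscal_map(np.asarray(p, dtype=float)), 0.0, 1.0)


def simulate_cohort(
    spec: ScenarioSpec, n: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """One simulated cohort: columns ``y``, ``s`` and ``p_true``."""
    rng = np.random.default_rng(seed)
    p = sample_true_risks(spec, n, rng)
    y = sample_outcomes(p, rng)
    s = apply_miscalibration(p, spec)
    return pd.DataFrame({"y": y, "s": s, "p_true": p})


def cohort_from_frame(frame: pd.DataFrame) -> CohortData:
    """Convenience: the (y, s) view of a simulated cohort."""
    return CohortData.from_frame(frame)
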