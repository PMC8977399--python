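"""The graphical potential-gain assessment and artifact rendering.

``assess_potential_gain`` implements the look-before-you-recalibrate tool:
plot the sNB attainable at every cutpoint of the original score, mark the
sNB of the original and standard-recalibrated models, and flag either one
that falls more than one standard error below the attainable maximum.  A
flagged original score means recalibration could pay off; a flagged
standard recalibration means specialized (weighted or constrained)
recalibration may be worth pursuing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import CohortData, DecisionPolicy
from .metrics import SNBCurve, snb_curve
from .recalibrate import RecalModel, fit_standard, recalibrated_snb
from .weights import calibration_curve

__all__ = [
    "PotentialGainReport",
    "assess_potential_gain",
    "curve_frame",
    "render_outputs",
    "plot_snb_curve",
    "plot_calibration",
]


@dataclass(frozen=True)
class PotentialGainReport:
    curve: SNBCurve
    snb_original: float
    snb_standard: float
    standard_model: RecalModel
    one_se_line: float
    flag_original_below: bool
    flag_standard_below: bool

    def summary(self) -> dict:
        return {
            "snb_at_R": self.snb_original,
            "snb_standard": self.snb_standard,
            "snb_max": self.curve.snb_max,
            "r_star": self.curve.r_star,
            "se_max": self.curve.se_max,
            "one_se_line": self.one_se_line,
            "flag_original_below": self.flag_original_below,
            "flag_standard_below": self.flag_standard_below,
            "alpha0_standard": self.standard_model.alpha0,
            "alpha1_standard": self.standard_model.alpha1,
            "R": self.curve.R,
        }


def assess_potential_gain(
    data: CohortData, policy: DecisionPolicy
) -> PotentialGainReport:
    """Compute the sNB-vs-cutpoint curve and apply the 1-SE rule.

    Flags use strict inequality: a model is flagged when its sNB is
    strictly below ``snb_max - se_max``.
    """
    curve = snb_curve(data, policy)
    standard = fit_standard(data)
    snb_std = recalibrated_snb(standard, data, policy)
    one_se = curve.snb_max - curve.se_max
    return PotentialGainReport(
        curve=curve,
        snb_original=float(curve.snb_at_R),
        snb_standard=float(snb_std),
        standard_model=standard,
        one_se_line=float(one_se),
        flag_original_below=bool(curve.snb_at_R < one_se),
        flag_standard_below=bool(snb_std < one_se),
    )


def curve_frame(curve: SNBCurve) -> pd.DataFrame:
    return pd.DataFrame({"cutpoint": curve.cutpoints, "snb": curve.snb})


def plot_snb_curve(report: PotentialGainReport, ax=None):
    """sNB-vs-cutpoint plot with the 1-SE line and labeled model points."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    curve = report.curve
    if curve.cutpoints.size == 0:
        raise ValueError("empty sNB curve")
    ax.step(curve.cutpoints, curve.snb, where="post", color="black", lw=1)
    ax.axhline(report.one_se_line, ls=":", color="gray",
               label="1 SE below max sNB")
    ax.plot([curve.R], [report.snb_original], "o", color="tab:red",
            label=f"original (sNB={report.snb_original:.3f})")
    # the standard fit's sNB appears at its equivalent cutpoint on the
    # original-score axis
    c_std = report.standard_model.induced_cutpoint(
        DecisionPolicy(R=curve.R)
    )
    ax.plot([float(expit(c_std))], [report.snb_standard], "s", color="tab:blue",
            label=f"standard recal (sNB={report.snb_standard:.3f})")
    ax.plot([curve.r_star], [curve.snb_max], "^", color="tab:green",
            label=f"max (sNB={curve.snb_max:.3f})")
    ax.set_xlabel("cutpoint r")
    ax.set_ylabel("sNB")
    ax.set_ylim(min(-0.05, curve.snb.min()), 1.05)
    ax.legend(fontsize=8)
    return ax


def plot_calibration(
    data: CohortData,
    models: dict[str, RecalModel] | None = None,
    n_grid: int = 100,
    ax=None,
):
    """Calibration curves (LOESS) with identity reference and score histogram."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    cal = calibration_curve(data, n_grid)
    ax.plot(cal.grid, cal.observed, label="original", color="black")
    if models:
        for name, model in models.items():
            recal = data.with_scores(model.apply(data.s))
            cal_m = calibration_curve(recal, n_grid)
            ax.plot(cal_m.grid, cal_m.observed, label=name)
    ax.plot([0, 1], [0, 1], ls="--", color="gray", lw=1)
    ax2 = ax.twinx()
    ax2.hist(data.s, bins=40, alpha=0.2, color="tab:blue", density=True)
    ax2.set_yticks([])
    ax.set_xlabel("predicted risk")
    ax.set_ylabel("observed event rate")
    ax.legend(fontsize=8)
    return ax


def render_outputs(
    report: PotentialGainReport,
    destination: str | Path,
    data: CohortData | None = None,
) -> dict[str, Path]:
    """Write the plot(s) plus the TSV/JSON data behind every plotted number."""
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    curve_path = dest / "snb_curve.tsv"
    curve_frame(report.curve).to_csv(curve_path, sep="\t", index=False)
    written["curve_tsv"] = curve_path

    summary_path = dest / "report.json"
    summary_path.write_text(json.dumps(report.summary(), indent=2))
    written["report_json"] = summary_path

    fig, ax = plt.subplots(figsize=(6, 4))
    plot_snb_curve(report, ax=ax)
    fig_path = dest / "snb_curve.png"
    fig.savefig(fig_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written["curve_png"] = fig_path

    if data is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        plot_calibration(data, {"standard": report.standard_model}, ax=ax)
        cal_path = dest / "calibration.png"
        fig.savefig(cal_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written["calibration_png"] = cal_path

    return written


def read_report_summary(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
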