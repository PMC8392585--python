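"""Publication-style figures, regenerable from report/model JSON alone.

Every function takes already-computed report data (never recomputes metrics)
and returns a matplotlib Figure, so figures rebuild identically from a saved
:class:`~ntcpkit.validation.ValidationReport`.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .model import Nomogram, NtcpModel

__all__ = [
    "calibration_plot",
    "roc_plot",
    "dose_response_plot",
    "residual_histogram",
    "nomogram_plot",
]


def calibration_plot(report: Mapping, ax=None):
    """Risk-group observed vs predicted with identity and fitted calibration line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    groups = report["risk_groups"] if isinstance(report, Mapping) else report.risk_groups
    x = np.array([g["mean_predicted"] for g in groups])
    y = np.array([g["observed_rate"] for g in groups])
    e = np.array([1.959964 * g["se_observed"] for g in groups])
    ax.errorbar(x, y, yerr=e, fmt="o", color="k", capsize=3, label="risk groups")
    ax.plot([0, 1], [0, 1], "k:", label="identity")
    slope = report["calibration_slope"]
    citl = report["calibration_in_the_large"]
    lp = np.log(np.clip(x, 1e-6, 1 - 1e-6) / (1 - np.clip(x, 1e-6, 1 - 1e-6)))
    fit = 1.0 / (1.0 + np.exp(-(citl + slope * lp)))
    order = np.argsort(x)
    ax.plot(x[order], fit[order], "k-", label=f"calibration (slope {slope:.2f})")
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed event rate")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    ax.set_title(f"calibration-in-the-large {citl:+.2f}")
    return ax.figure


def roc_plot(report: Mapping, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    pts = report["roc_points"] if isinstance(report, Mapping) else report.roc_points
    ax.plot(pts["fpr"], pts["tpr"], "k-")
    ax.plot([0, 1], [0, 1], "k:")
    auc = report["auc"] if isinstance(report, Mapping) else report.auc
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {auc:.2f}")
    return ax.figure


def dose_response_plot(
    model: NtcpModel,
    sweep_term: str = "cpg_d98",
    sweep_range: tuple[float, float] = (5.0, 55.0),
    curve_term: str = "oc_eud",
    curve_values: Sequence[float] = (45.0, 55.0, 65.0),
    fixed: Mapping[str, float] | None = None,
    ax=None,
):
    """NTCP vs one dose metric, one curve per level of a second metric,
    dashed/solid for smoking history no/yes."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 4.0))
    fixed = dict(fixed or {"age_5y": 10.0})
    doses = np.linspace(*sweep_range, 200)
    colors = plt.cm.viridis(np.linspace(0.1, 0.85, len(curve_values)))
    for color, level in zip(colors, curve_values):
        for smoking, style in ((0.0, "--"), (1.0, "-")):
            cov = {**fixed, sweep_term: doses, curve_term: level, "smoking": smoking}
            cov = {t.name: cov[t.name] for t in model.terms}
            ax.plot(doses, model.predict(cov), style, color=color,
                    label=f"{curve_term}={level:g} Gy, smoking={'yes' if smoking else 'no'}")
    ax.set_xlabel(f"{sweep_term} (Gy)")
    ax.set_ylabel("probability of grade >= 2 salivary dysfunction")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7)
    return ax.figure


def residual_histogram(report: Mapping, threshold: float = 0.7, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    flags = report["residual_flags"] if isinstance(report, Mapping) else report.residual_flags
    resid = flags.get("residuals", [])
    ax.hist(resid, bins=np.arange(-1.0, 1.05, 0.1), color="0.6", edgecolor="k")
    for x in (-threshold, threshold):
        ax.axvline(x, color="k", linestyle=":")
    ax.set_xlabel("residual (observed - predicted)")
    ax.set_ylabel("patients")
    return ax.figure


def nomogram_plot(nomogram: Nomogram, ax=None):
    """Stacked per-term point axes plus the total-points-to-probability axis."""
    names = list(nomogram.term_tables)
    n_rows = len(names) + 2
    if ax is not None:
        fig = ax.figure
        fig.clf()
    fig, axes = plt.subplots(n_rows, 1, figsize=(7, 1.0 * n_rows), sharex=False)
    axes[0].set_xlim(0, 100)
    axes[0].set_yticks([])
    axes[0].set_title("points")
    axes[0].xaxis.set_ticks_position("top")
    for axis, name in zip(axes[1:], names):
        vals, pts = nomogram.term_tables[name]
        axis.plot(pts, np.zeros_like(pts), "k-")
        idx = np.linspace(0, len(vals) - 1, 6).astype(int)
        for i in idx:
            axis.annotate(f"{vals[i]:g}", (pts[i], 0), textcoords="offset points",
                          xytext=(0, -12), ha="center", fontsize=7)
        axis.set_xlim(-2, 102)
        axis.set_yticks([])
        axis.set_ylabel(name, rotation=0, ha="right", va="center", fontsize=8)
    total_max = sum(float(np.max(p)) for _, p in nomogram.term_tables.values())
    totals = np.linspace(0, total_max, 200)
    probs = [nomogram.probability(t) for t in totals]
    axes[-1].plot(totals, probs, "k-")
    axes[-1].set_xlabel("total points")
    axes[-1].set_ylabel("NTCP", rotation=0, ha="right", va="center", fontsize=8)
    axes[-1].set_ylim(0, 1)
    fig.tight_layout()
    return fig
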