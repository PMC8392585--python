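"""Equivalent Uniform Dose reduction and dose-metric screening.

The generalized EUD reduces a differential DVH to a single dose,

    EUD(n) = (sum_i v_i * D_i**(1/n)) ** n,

with relative bin volumes ``v_i``, bin doses ``D_i`` and volume-effect
parameter ``n``: n -> 0 weights the hottest bins (serial organ), n = 1 gives
the mean dose (parallel organ).  The association of each candidate metric
with a binary toxicity endpoint is screened with a two-sample t-test; the
best volume-effect parameter is the one minimising the screening p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .dvh import (
    DIFFERENTIAL,
    DoseVolumeHistogram,
    DvhError,
    dose_at_volume,
    summarize,
    to_differential,
)

__all__ = [
    "N_GRID",
    "EudGrid",
    "ScreenResult",
    "MetricSelection",
    "ScreenError",
    "compute_eud",
    "eud_grid",
    "screen_metric",
    "cutpoint_metrics",
    "select_best_metric",
]

#: volume-effect grid scanned for every organ: 0.05 ... 1.00 in steps of 0.05
N_GRID: np.ndarray = np.round(np.arange(1, 21) * 0.05, 2)

_VOL_TOL = 1e-12


class ScreenError(ValueError):
    """A metric screen that does not converge (degenerate groups/variance)."""


@dataclass(frozen=True)
class EudGrid:
    organ_label: str
    n_values: np.ndarray
    eud: np.ndarray  # Gy, one per n

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_values", np.asarray(self.n_values, float))
        object.__setattr__(self, "eud", np.asarray(self.eud, float))
        if self.n_values.size != self.eud.size:
            raise ValueError("n grid and EUD values must align")


@dataclass(frozen=True)
class ScreenResult:
    """Two-sample t-test of one dose metric against the endpoint."""

    metric_name: str
    t_statistic: float
    p_value: float
    mean_event: float
    mean_nonevent: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


@dataclass(frozen=True)
class MetricSelection:
    """Outcome of screening an organ's candidate dose metrics."""

    best: ScreenResult
    family: str  # "eud" or "cutpoint"
    eud_n: float | None  # selected volume-effect parameter, if family == "eud"
    significant: bool  # best p-value <= 0.05
    all_results: tuple[ScreenResult, ...]


def _relative_differential(dvh: DoseVolumeHistogram) -> tuple[np.ndarray, np.ndarray]:
    diff = dvh if dvh.form == DIFFERENTIAL else to_differential(dvh)
    if diff.total_volume <= 0:
        raise DvhError("empty DVH has no EUD")
    return diff.bin_centers, diff.as_relative()


def compute_eud(dvh: DoseVolumeHistogram, n: float) -> float:
    """Generalized EUD of one DVH for volume-effect parameter ``n`` in (0, 1].

    Factors out the maximum bin dose so the power ``1/n`` (20 at n = 0.05)
    never overflows; zero-dose bins contribute exactly zero.
    """
    if not 0.0 < n <= 1.0:
        raise ValueError("volume-effect parameter n must lie in (0, 1]")
    centers, rel = _relative_differential(dvh)
    mask = rel > _VOL_TOL
    if not mask.any():
        raise DvhError("empty DVH has no EUD")
    d, v = centers[mask], rel[mask]
    dmax = d.max()
    if dmax == 0.0:
        return 0.0
    return float(dmax * np.dot(v, (d / dmax) ** (1.0 / n)) ** n)


def eud_grid(dvh: DoseVolumeHistogram, n_values: np.ndarray = N_GRID) -> EudGrid:
    """EUD across the whole volume-effect grid (vectorised over n)."""
    centers, rel = _relative_differential(dvh)
    mask = rel > _VOL_TOL
    d, v = centers[mask], rel[mask]
    dmax = d.max()
    if dmax == 0.0:
        euds = np.zeros(len(n_values))
    else:
        n = np.asarray(n_values, float)[:, None]
        euds = dmax * np.dot((d[None, :] / dmax) ** (1.0 / n), v) ** n[:, 0]
    return EudGrid(dvh.organ_label, np.asarray(n_values, float), euds)


def screen_metric(
    values: Sequence[float],
    endpoint: Sequence[int],
    metric_name: str = "",
    welch: bool = False,
) -> ScreenResult:
    """Two-sample t-test (event vs non-event) of one dose metric.

    Pooled-variance Student test by default; Welch optional.
    """
    x = np.asarray(values, float)
    y = np.asarray(endpoint, int)
    if x.shape != y.shape:
        raise ValueError("values and endpoint must align")
    if not np.all(np.isfinite(x)):
        raise ValueError("metric values must be finite")
    g1, g0 = x[y == 1], x[y == 0]
    if g1.size < 2 or g0.size < 2:
        raise ScreenError(
            f"screen of {metric_name or 'metric'} does not converge: "
            "fewer than 2 patients in an endpoint group"
        )
    if np.ptp(g1) == 0.0 and np.ptp(g0) == 0.0:
        if g1.mean() == g0.mean():
            return ScreenResult(metric_name, 0.0, 1.0, float(g1.mean()), float(g0.mean()))
        raise ScreenError(
            f"screen of {metric_name or 'metric'} does not converge: zero pooled variance"
        )
    t, p = stats.ttest_ind(g1, g0, equal_var=not welch)
    return ScreenResult(metric_name, float(t), float(p), float(g1.mean()), float(g0.mean()))


def cutpoint_metrics(dvh: DoseVolumeHistogram) -> dict[str, float]:
    """The Dx%/VxGy screening family: D98%, D2%, Dmean, Dmax and V30..V70 Gy
    (relative volume receiving at least x Gy, in 5 Gy steps)."""
    summary = summarize(dvh)
    out = {
        "D98%": summary.d98,
        "D2%": dose_at_volume(dvh, 0.02),
        "Dmean": summary.mean_dose,
        "Dmax": summary.max_dose,
    }
    diff = dvh if dvh.form == DIFFERENTIAL else to_differential(dvh)
    rel = diff.as_relative()
    uppers = diff.dose_edges[1:]
    lowers = diff.dose_edges[:-1]
    for x in range(30, 75, 5):
        # fraction of volume at doses >= x, linear within bins
        frac = np.clip((uppers - x) / (uppers - lowers), 0.0, 1.0)
        out[f"V{x}Gy"] = float(np.dot(rel, frac))
    return out


def select_best_metric(
    cohort: Sequence,
    organ_label: str,
    endpoint: Sequence[int],
    welch: bool = False,
) -> MetricSelection:
    """Screen an organ's EUD grid against the endpoint and pick the best metric.

    The EUD family (20 volume-effect values) is screened first and the
    minimum-p metric returned, ties broken toward larger n (the weaker serial
    assumption).  If no EUD screen converges, the Dx%/VxGy cut-point family is
    screened instead.  A best p-value above 0.05 is flagged as
    non-significant rather than suppressed.
    """
    if len(cohort) < 4:
        raise ValueError("need at least 4 patients to screen dose metrics")
    dvhs = [p.organ_dvhs[organ_label] for p in cohort]
    grids = np.stack([eud_grid(d).eud for d in dvhs])  # patients x n
    results: list[ScreenResult] = []
    eud_results: list[tuple[float, ScreenResult]] = []
    for j, n in enumerate(N_GRID):
        name = f"EUD n={n:.2f}"
        try:
            res = screen_metric(grids[:, j], endpoint, name, welch=welch)
        except ScreenError:
            continue
        results.append(res)
        eud_results.append((float(n), res))
    if eud_results:
        # min p; ties toward larger n (scan descending in n, strict improvement)
        best_n, best = eud_results[-1]
        for n, res in reversed(eud_results[:-1]):
            if res.p_value < best.p_value:
                best_n, best = n, res
        return MetricSelection(
            best, "eud", best_n, best.p_value <= 0.05, tuple(results)
        )
    # EUD screening "did not converge": fall back to DVH cut-points
    tables = [cutpoint_metrics(d) for d in dvhs]
    best = None
    for name in tables[0]:
        vals = [t[name] for t in tables]
        try:
            res = screen_metric(vals, endpoint, name, welch=welch)
        except ScreenError:
            continue
        results.append(res)
        if best is None or res.p_value < best.p_value:
            best = res
    if best is None:
        raise ScreenError(
            f"no dose metric of {organ_label} yields a valid screen"
        )
    return MetricSelection(best, "cutpoint", None, best.p_value <= 0.05, tuple(results))
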