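"""Discrimination, calibration and classification metrics with bootstrap
optimism correction and frozen-coefficient external validation.

Internal validation follows Harrell's bootstrap: the whole modelling recipe
is refit on each resample, scored on the resample (apparent) and on the
original cohort (test); the mean apparent-minus-test gap is the optimism
subtracted from the apparent performance.  External validation applies a
frozen :class:`~ntcpkit.model.NtcpModel` to a new cohort without touching
its coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .model import NtcpLogisticRegression, NtcpModel

__all__ = [
    "ValidationReport",
    "OptimismResult",
    "roc_auc",
    "auc_p_value",
    "calibration",
    "hosmer_lemeshow",
    "classification_at_cutoff",
    "residual_analysis",
    "bootstrap_optimism",
    "external_validate",
    "fit_only_recipe",
    "full_recipe",
    "risk_group_table",
]


def _check_binary(observed: np.ndarray) -> None:
    if len(np.unique(observed)) < 2:
        raise ValueError("both outcome classes must be present")


def roc_auc(predicted: Sequence[float], observed: Sequence[int]) -> float:
    """Area under the ROC curve, rank (Mann-Whitney) formulation, ties at 1/2."""
    p = np.asarray(predicted, float)
    y = np.asarray(observed, int)
    _check_binary(y)
    return float(roc_auc_score(y, p))


def auc_p_value(predicted: Sequence[float], observed: Sequence[int]) -> float:
    """Two-sided p for AUC != 0.5 via the normal approximation to Mann-Whitney."""
    p = np.asarray(predicted, float)
    y = np.asarray(observed, int)
    _check_binary(y)
    res = stats.mannwhitneyu(p[y == 1], p[y == 0], alternative="two-sided",
                             method="asymptotic")
    return float(res.pvalue)


def _logit(p: np.ndarray) -> np.ndarray:
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("predicted probabilities must lie strictly in (0, 1)")
    return np.log(p / (1.0 - p))


def calibration(
    predicted: Sequence[float], observed: Sequence[int]
) -> dict[str, float]:
    """Calibration slope and calibration-in-the-large.

    The slope is the MLE slope of a logistic regression of the outcome on the
    model's logit prediction; calibration-in-the-large is the intercept of a
    logistic regression with that logit entered as a fixed offset (logit
    units; 0 means predictions are on average right).  The probability-scale
    difference mean(observed) - mean(predicted) is reported alongside.
    """
    p = np.asarray(predicted, float)
    y = np.asarray(observed, int)
    _check_binary(y)
    lp = _logit(p)
    if np.ptp(lp) == 0.0:
        raise ValueError("constant predictions: calibration slope undefined")
    slope_fit = sm.GLM(
        y, sm.add_constant(lp), family=sm.families.Binomial()
    ).fit()
    citl_fit = sm.GLM(
        y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=lp
    ).fit()
    return {
        "slope": float(slope_fit.params[1]),
        "in_the_large": float(citl_fit.params[0]),
        "mean_observed_minus_predicted": float(y.mean() - p.mean()),
    }


def _hl_group_bounds(order_p: np.ndarray, groups: int) -> list[int]:
    """Right-open boundaries of equal-count risk groups over sorted predictions.

    Remainder patients go to the lowest-risk groups; ties in predicted
    probability never straddle a boundary (the boundary moves down to keep
    equal values together).
    """
    n = len(order_p)
    base, rem = divmod(n, groups)
    sizes = [base + (1 if g < rem else 0) for g in range(groups)]
    bounds, pos = [], 0
    for s in sizes[:-1]:
        b = pos + s
        while 0 < b < n and order_p[b] == order_p[b - 1]:
            b -= 1
        if b <= pos:  # whole group was one tie block; push forward instead
            b = pos + s
            while b < n and order_p[b] == order_p[b - 1]:
                b += 1
        bounds.append(min(b, n))
        pos = bounds[-1]
    bounds.append(n)
    return bounds


def hosmer_lemeshow(
    predicted: Sequence[float], observed: Sequence[int], groups: int = 6
) -> dict[str, float]:
    """Hosmer-Lemeshow goodness-of-fit over equal-count risk groups.

    chi2 = sum over groups and both outcome cells of (O - E)^2 / E, compared
    to a chi-squared distribution with ``groups - 2`` degrees of freedom.
    """
    p = np.asarray(predicted, float)
    y = np.asarray(observed, int)
    _check_binary(y)
    if groups < 3:
        raise ValueError("need at least 3 groups for a chi-squared test")
    order = np.argsort(p, kind="stable")
    ps, ys = p[order], y[order]
    bounds = _hl_group_bounds(ps, groups)
    chi2 = 0.0
    pos = 0
    for b in bounds:
        gp, gy = ps[pos:b], ys[pos:b]
        e1 = gp.sum()
        e0 = (1.0 - gp).sum()
        if e1 <= 0.0 or e0 <= 0.0:
            raise ValueError(
                "expected cell of zero in a risk group; use fewer groups"
            )
        o1 = gy.sum()
        o0 = len(gy) - o1
        chi2 += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
        pos = b
    df = groups - 2
    return {
        "chi2": float(chi2),
        "p": float(stats.chi2.sf(chi2, df)),
        "groups": groups,
        "df": df,
    }


def classification_at_cutoff(
    predicted: Sequence[float], observed: Sequence[int], cutoff: float = 0.65
) -> dict:
    """Predictive values of the positive call ``predicted >= cutoff``.

    PPV = TP/(TP+FP); NPV = TN/(TN+FN); an empty call class leaves the
    corresponding value None (undefined), never 0.
    """
    p = np.asarray(predicted, float)
    y = np.asarray(observed, int)
    _check_binary(y)
    call = p >= cutoff
    tp = int(np.sum(call & (y == 1)))
    fp = int(np.sum(call & (y == 0)))
    tn = int(np.sum(~call & (y == 0)))
    fn = int(np.sum(~call & (y == 1)))
    ppv = tp / (tp + fp) if (tp + fp) else None
    npv = tn / (tn + fn) if (tn + fn) else None
    return {"ppv": ppv, "npv": npv, "tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "cutoff": float(cutoff)}


def residual_analysis(
    predicted: Sequence[float],
    observed: Sequence[int],
    ids: Sequence[str] | None = None,
    threshold: float = 0.7,
) -> dict[str, list]:
    """Flag outlying patients by raw residual observed(0/1) - predicted.

    Residual >= threshold: toxicity despite low prediction (radiosensitive);
    residual <= -threshold: no toxicity despite high prediction
    (radioresistant).
    """
    p = np.asarray(predicted, float)
    y = np.asarray(observed, int)
    if ids is None:
        ids = [str(i) for i in range(len(p))]
    resid = y - p
    return {
        "radiosensitive": [i for i, r in zip(ids, resid) if r >= threshold],
        "radioresistant": [i for i, r in zip(ids, resid) if r <= -threshold],
        "residuals": resid.tolist(),
    }


def risk_group_table(
    predicted: Sequence[float], observed: Sequence[int], groups: int = 6
) -> list[dict]:
    """Per risk group: size, mean predicted risk, observed rate and a normal-
    approximation standard error of the observed proportion (calibration-plot
    points)."""
    p = np.asarray(predicted, float)
    y = np.asarray(observed, int)
    order = np.argsort(p, kind="stable")
    ps, ys = p[order], y[order]
    bounds = _hl_group_bounds(ps, groups)
    rows, pos = [], 0
    for b in bounds:
        gp, gy = ps[pos:b], ys[pos:b]
        rate = float(gy.mean())
        rows.append({
            "n": int(len(gy)),
            "mean_predicted": float(gp.mean()),
            "observed_rate": rate,
            "se_observed": float(np.sqrt(max(rate * (1 - rate), 1e-12) / len(gy))),
        })
        pos = b
    return rows


# ---------------------------------------------------------------------------
# modelling recipes for the bootstrap


def fit_only_recipe(X: pd.DataFrame, y: np.ndarray) -> Callable[[pd.DataFrame], np.ndarray]:
    """Refit the logistic coefficients on all given features (no selection)."""
    est = NtcpLogisticRegression().fit(X, y)
    cols = list(X.columns)
    return lambda Xn: est.predict_proba(Xn[cols])[:, 1]


def full_recipe(
    folds: int = 5, rule: str = "min", seed: int = 0, n_path: int = 100,
    force_in: Sequence[str] = (),
) -> Callable:
    """Recipe repeating LASSO selection + refit inside each bootstrap.

    ``force_in`` lists features always carried into the refit (e.g. the
    dosimetric terms) regardless of the selection.
    """
    from .model import LassoSelector

    def recipe(X: pd.DataFrame, y: np.ndarray):
        sel = LassoSelector(folds=folds, rule=rule, n_path=n_path, random_state=seed)
        sel.fit(X, y)
        chosen = list(dict.fromkeys([*force_in, *sel.selected_features_]))
        if not chosen:  # empty selection: intercept-only model
            p0 = float(np.mean(y))
            return lambda Xn: np.full(len(Xn), p0)
        est = NtcpLogisticRegression().fit(X[chosen], y)
        return lambda Xn: est.predict_proba(Xn[chosen])[:, 1]

    return recipe


@dataclass(frozen=True)
class OptimismResult:
    apparent: dict
    optimism: dict
    corrected: dict
    n_resamples: int
    n_skipped: int
    seed: int


def _clip_probs(p: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    return np.clip(p, eps, 1.0 - eps)


def _perf(p: np.ndarray, y: np.ndarray) -> dict[str, float]:
    cal = calibration(_clip_probs(p), y)
    return {
        "auc": roc_auc(p, y),
        "slope": cal["slope"],
        "in_the_large": cal["in_the_large"],
    }


def bootstrap_optimism(
    X: pd.DataFrame,
    y: Sequence[int],
    recipe: Callable | None = None,
    B: int = 1000,
    seed: int = 0,
    max_skip_fraction: float = 0.1,
) -> OptimismResult:
    """Harrell's optimism correction of AUC, calibration slope and CITL.

    ``recipe(X, y)`` must return a probability predictor; the default refits
    the logistic model on all columns of ``X``.  Resamples with a single
    outcome class are skipped and counted; more than ``max_skip_fraction``
    skips abort the run.
    """
    X = _as_df(X)
    y = np.asarray(y, int)
    _check_binary(y)
    if recipe is None:
        recipe = fit_only_recipe
    rng = np.random.default_rng(seed)
    predictor = recipe(X, y)
    apparent = _perf(predictor(X), y)
    if B == 0:
        zeros = {k: 0.0 for k in apparent}
        return OptimismResult(apparent, zeros, dict(apparent), 0, 0, seed)
    n = len(y)
    sums = {k: 0.0 for k in apparent}
    done = skipped = 0
    while done < B:
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if len(np.unique(yb)) < 2:
            skipped += 1
            if skipped > max_skip_fraction * B:
                raise RuntimeError(
                    "more than 10% of bootstrap resamples had a single outcome class"
                )
            continue
        Xb = X.iloc[idx].reset_index(drop=True)
        try:
            pred_b = recipe(Xb, yb)
            perf_boot = _perf(pred_b(Xb), yb)
            perf_test = _perf(pred_b(X), y)
        except (ValueError, RuntimeError):
            skipped += 1
            if skipped > max_skip_fraction * B:
                raise RuntimeError(
                    "more than 10% of bootstrap resamples failed to refit"
                )
            continue
        for k in sums:
            sums[k] += perf_boot[k] - perf_test[k]
        done += 1
    optimism = {k: v / B for k, v in sums.items()}
    corrected = {k: apparent[k] - optimism[k] for k in apparent}
    return OptimismResult(apparent, optimism, corrected, B, skipped, seed)


def _as_df(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


@dataclass(frozen=True)
class ValidationReport:
    """All discrimination/calibration/classification metrics for one cohort."""

    cohort_label: str
    n: int
    events: int
    auc: float
    auc_p: float
    calibration_slope: float
    calibration_in_the_large: float
    mean_observed_minus_predicted: float
    hl_chi2: float
    hl_p: float
    hl_groups: int
    ppv: float | None
    npv: float | None
    cutoff: float
    confusion: dict
    residual_flags: dict
    risk_groups: list = field(default_factory=list)
    roc_points: dict = field(default_factory=dict)
    optimism: dict | None = None
    refit_odds_ratios: dict | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")
        if self.hl_chi2 < 0:
            raise ValueError("HL chi-squared must be non-negative")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ValidationReport":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        return cls(**json.loads(text))


def evaluate_predictions(
    predicted: Sequence[float],
    observed: Sequence[int],
    cohort_label: str = "",
    ids: Sequence[str] | None = None,
    cutoff: float = 0.65,
    hl_groups: int = 6,
    residual_threshold: float = 0.7,
    optimism: Mapping | None = None,
    refit_odds_ratios: Mapping | None = None,
) -> ValidationReport:
    """Assemble the full metric report for a set of predictions."""
    p = _clip_probs(np.asarray(predicted, float))
    y = np.asarray(observed, int)
    cal = calibration(p, y)
    hl = hosmer_lemeshow(p, y, hl_groups)
    cls = classification_at_cutoff(p, y, cutoff)
    flags = residual_analysis(p, y, ids, residual_threshold)
    fpr, tpr, _ = roc_curve(y, p)
    return ValidationReport(
        cohort_label=cohort_label,
        n=int(len(y)),
        events=int(y.sum()),
        auc=roc_auc(p, y),
        auc_p=auc_p_value(p, y),
        calibration_slope=cal["slope"],
        calibration_in_the_large=cal["in_the_large"],
        mean_observed_minus_predicted=cal["mean_observed_minus_predicted"],
        hl_chi2=hl["chi2"],
        hl_p=hl["p"],
        hl_groups=hl_groups,
        ppv=cls["ppv"],
        npv=cls["npv"],
        cutoff=cutoff,
        confusion={k: cls[k] for k in ("tp", "fp", "tn", "fn")},
        residual_flags={k: flags[k] for k in ("radiosensitive", "radioresistant")},
        risk_groups=risk_group_table(p, y, hl_groups),
        roc_points={"fpr": fpr.tolist(), "tpr": tpr.tolist()},
        optimism=dict(optimism) if optimism is not None else None,
        refit_odds_ratios=dict(refit_odds_ratios) if refit_odds_ratios else None,
    )


def external_validate(
    model: NtcpModel | str | Path,
    covariates: pd.DataFrame,
    observed: Sequence[int],
    cohort_label: str = "external",
    ids: Sequence[str] | None = None,
    cutoff: float = 0.65,
    hl_groups: int = 6,
    refit_effect_sizes: bool = False,
) -> ValidationReport:
    """Validate a frozen model on a new cohort without refitting it.

    Predictions use the stored intercept and coefficients unchanged.  With
    ``refit_effect_sizes`` the cohort's own per-term odds ratios (univariable
    refits of each model term) are reported alongside for effect-size
    comparison; the frozen model itself is never altered.
    """
    if not isinstance(model, NtcpModel):
        model = NtcpModel.from_json(model)
    missing = [t.name for t in model.terms if t.name not in covariates.columns]
    if missing:
        raise KeyError(f"validation cohort missing model covariates: {missing}")
    p = model.predict(covariates)
    refit = None
    if refit_effect_sizes:
        from .model import Z_95, fit_logistic, odds_ratios

        refit = {}
        for t in model.terms:
            try:
                m1 = fit_logistic(covariates[[t.name]], observed)
            except Exception:
                continue
            refit[t.name] = odds_ratios(m1, Z_95)[t.name]
    return evaluate_predictions(
        p, observed, cohort_label=cohort_label, ids=ids, cutoff=cutoff,
        hl_groups=hl_groups, refit_odds_ratios=refit,
    )
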