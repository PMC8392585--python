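"""Logistic NTCP modelling: LASSO-guided selection, maximum-likelihood fit,
frozen-coefficient prediction, odds ratios and the points-based nomogram.

The modelling core is exposed as scikit-learn style estimators so it composes
with sklearn pipelines and model selection:

* :class:`LassoSelector` — L1-penalised logistic feature selection with the
  penalty chosen by 5-fold cross-validated deviance (minimum or 1-SE rule);
* :class:`NtcpLogisticRegression` — unpenalised maximum-likelihood logistic
  refit carrying Wald standard errors and the log-likelihood.

The fitted model freezes into an :class:`NtcpModel`, a plain serialisable
record of intercept, per-term coefficients/SEs and the EUD volume-effect
parameters used for the dosimetric features.  External validation reads this
record and never refits it.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ModelTerm",
    "NtcpModel",
    "Nomogram",
    "SeparationError",
    "LassoSelector",
    "NtcpLogisticRegression",
    "lasso_select",
    "fit_logistic",
    "predict_ntcp",
    "odds_ratios",
    "build_nomogram",
    "reference_model",
]

Z_95 = 1.959964  # two-sided 95% normal quantile used for Wald intervals


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


@dataclass(frozen=True)
class ModelTerm:
    name: str
    coefficient: float  # logit units per unit of the covariate
    standard_error: float
    unit: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.coefficient):
            raise ValueError(f"term {self.name}: non-finite coefficient")
        if not (np.isfinite(self.standard_error) and self.standard_error > 0):
            raise ValueError(f"term {self.name}: standard error must be > 0")


@dataclass(frozen=True)
class NtcpModel:
    """Frozen multivariable logistic NTCP model."""

    intercept: float
    intercept_se: float
    terms: tuple[ModelTerm, ...]
    eud_params: dict = field(default_factory=dict)  # organ -> volume-effect n
    fit_meta: dict = field(default_factory=dict)

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.terms)

    def linear_predictor(self, covariates: Mapping | pd.DataFrame) -> np.ndarray:
        """Intercept + sum of coefficient * covariate, vectorised."""
        missing = [t.name for t in self.terms if t.name not in covariates]
        if missing:
            raise KeyError(f"missing model covariates: {missing}")
        lp = np.asarray(self.intercept, dtype=float)
        for t in self.terms:
            lp = lp + t.coefficient * np.asarray(covariates[t.name], dtype=float)
        return lp

    def predict(self, covariates: Mapping | pd.DataFrame) -> np.ndarray:
        """NTCP = expit(linear predictor)."""
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(covariates)))

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "terms": [asdict(t) for t in self.terms],
            "eud_params": dict(self.eud_params),
            "fit_meta": dict(self.fit_meta),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, data: Mapping) -> "NtcpModel":
        return cls(
            intercept=float(data["intercept"]),
            intercept_se=float(data.get("intercept_se", 1.0)),
            terms=tuple(ModelTerm(**t) for t in data["terms"]),
            eud_params=dict(data.get("eud_params", {})),
            fit_meta=dict(data.get("fit_meta", {})),
        )

    @classmethod
    def from_json(cls, source: str | Path) -> "NtcpModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        return cls.from_dict(json.loads(text))


def reference_model() -> NtcpModel:
    """The development-cohort model for grade >= 2 acute salivary dysfunction.

    Four terms: combined-parotid D98% (Gy), oral-cavity EUD with n = 0.05
    (Gy), age in 5-year units and smoking history (yes = 1).  Used as the
    default generating model for synthetic cohorts and as the frozen model in
    external-validation examples.
    """
    return NtcpModel(
        intercept=-7.233,
        intercept_se=2.620,
        terms=(
            ModelTerm("cpg_d98", 0.038, 0.023, "Gy"),
            ModelTerm("oc_eud", 0.103, 0.043, "Gy"),
            ModelTerm("age_5y", 0.079, 0.074, "5-year interval"),
            ModelTerm("smoking", 0.318, 0.540, "yes=1"),
        ),
        eud_params={"oral_cavity": 0.05},
        fit_meta={"cohort_size": 132, "events": 90},
    )


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


class LassoSelector(SelectorMixin, BaseEstimator):
    """L1-penalised logistic feature selection, penalty by CV deviance.

    Features are standardised internally before penalisation.  The penalty
    path is log-spaced; the chosen penalty minimises the cross-validated
    binomial deviance (``rule="min"``) or is the strongest penalty within one
    standard error of that minimum (``rule="1se"``).  Zero-variance features
    are dropped with a warning before the fit.

    Attributes (after ``fit``): ``support_``, ``selected_features_``,
    ``best_C_``, ``cv_deviance_`` (path x 1 mean), ``cv_deviance_se_``.
    """

    def __init__(
        self,
        folds: int = 5,
        rule: str = "min",
        n_path: int = 100,
        random_state: int = 0,
        max_iter: int = 5000,
    ):
        self.folds = folds
        self.rule = rule
        self.n_path = n_path
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X, y):
        Xf = _as_frame(X)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("outcome must contain both classes")
        if Xf.shape[0] < 2 * self.folds:
            raise ValueError("need at least 2 patients per cross-validation fold")
        variances = Xf.var(axis=0, ddof=0).to_numpy()
        keep = variances > 0
        if not keep.all():
            dropped = list(Xf.columns[~keep])
            warnings.warn(f"dropping zero-variance features: {dropped}")
        self.feature_names_in_ = np.asarray(Xf.columns, dtype=object)
        Xk = Xf.loc[:, Xf.columns[keep]]
        mu, sd = Xk.mean(axis=0).to_numpy(), Xk.std(axis=0, ddof=0).to_numpy()
        Z = (Xk.to_numpy(dtype=float) - mu) / sd
        Cs = np.logspace(-4, 4, self.n_path)
        cv = StratifiedKFold(self.folds, shuffle=True, random_state=self.random_state)
        clf = LogisticRegressionCV(
            Cs=Cs,
            cv=cv,
            penalty="l1",
            solver="liblinear",
            scoring="neg_log_loss",
            refit=False,
            max_iter=self.max_iter,
        )
        with warnings.catch_warnings():
            # sklearn 1.9 emits transition warnings for the penalty= CV API
            warnings.simplefilter("ignore", FutureWarning)
            clf.fit(Z, y)
        scores = clf.scores_[1]  # folds x path, mean neg log-loss per sample
        dev = -2.0 * scores.mean(axis=0)  # mean binomial deviance per sample
        dev_se = 2.0 * scores.std(axis=0, ddof=1) / np.sqrt(self.folds)
        i_min = int(np.argmin(dev))
        if self.rule == "1se":
            within = np.nonzero(dev <= dev[i_min] + dev_se[i_min])[0]
            i_pick = int(within[0])  # smallest C = strongest penalty
        elif self.rule == "min":
            i_pick = i_min
        else:
            raise ValueError("rule must be 'min' or '1se'")
        final = LogisticRegression(
            C=Cs[i_pick],
            l1_ratio=1.0,
            solver="liblinear",
            max_iter=self.max_iter,
        )
        final.fit(Z, y)
        coefs = final.coef_.ravel()
        support_kept = np.abs(coefs) > 1e-10
        support = np.zeros(Xf.shape[1], dtype=bool)
        support[np.nonzero(keep)[0]] = support_kept
        self.support_ = support
        self.best_C_ = float(Cs[i_pick])
        self.c_path_ = Cs
        self.cv_deviance_ = dev
        self.cv_deviance_se_ = dev_se
        self.selected_features_ = list(self.feature_names_in_[support])
        self.n_features_in_ = Xf.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def _more_tags(self):
        return {"requires_y": True}


class NtcpLogisticRegression(ClassifierMixin, BaseEstimator):
    """Unpenalised maximum-likelihood logistic regression with Wald SEs.

    Thin estimator facade over a Newton-type MLE; fitted attributes follow
    sklearn conventions (``coef_``, ``intercept_``) with the inferential
    extras sklearn omits: ``coef_se_``, ``intercept_se_``, ``llf_``.
    Perfect separation raises :class:`SeparationError` naming the runaway
    feature.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-8):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        Xf = _as_frame(X)
        y = np.asarray(y, dtype=float)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("outcome must contain both classes")
        design = sm.add_constant(Xf.to_numpy(dtype=float), has_constant="add")
        names = ["const", *Xf.columns]
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            try:
                res = sm.Logit(y, design).fit(
                    disp=0, maxiter=self.max_iter, tol=self.tol, method="newton"
                )
            except (sm.tools.sm_exceptions.PerfectSeparationError,
                    sm.tools.sm_exceptions.PerfectSeparationWarning,
                    np.linalg.LinAlgError) as exc:
                raise SeparationError(self._separation_message(Xf, y)) from exc
        params = np.asarray(res.params, dtype=float)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError(
                f"logistic fit did not converge within {self.max_iter} iterations"
            )
        if np.any(np.abs(params[1:]) > 30):
            raise SeparationError(self._separation_message(Xf, y, params, names))
        self.classes_ = np.array([0, 1])
        self.intercept_ = np.array([params[0]])
        self.coef_ = params[None, 1:]
        bse = np.asarray(res.bse, dtype=float)
        self.intercept_se_ = float(bse[0])
        self.coef_se_ = bse[1:]
        self.llf_ = float(res.llf)
        self.n_features_in_ = Xf.shape[1]
        self.feature_names_in_ = np.asarray(Xf.columns, dtype=object)
        self.n_obs_ = int(len(y))
        self.n_events_ = int(y.sum())
        return self

    @staticmethod
    def _separation_message(Xf, y, params=None, names=None) -> str:
        if params is not None:
            j = int(np.argmax(np.abs(params[1:])))
            culprit = names[j + 1]
        else:
            # feature whose event/non-event ranges overlap least
            overlaps = []
            for c in Xf.columns:
                x1, x0 = Xf.loc[y == 1, c], Xf.loc[y == 0, c]
                overlaps.append(min(x1.max(), x0.max()) - max(x1.min(), x0.min()))
            culprit = Xf.columns[int(np.argmin(overlaps))]
        return f"perfect separation detected (feature {culprit!r})"

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        Xf = _as_frame(X)
        return self.intercept_[0] + Xf.to_numpy(dtype=float) @ self.coef_.ravel()

    def predict_proba(self, X):
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)

    def to_model(
        self,
        units: Mapping[str, str] | None = None,
        eud_params: Mapping[str, float] | None = None,
    ) -> NtcpModel:
        """Freeze the fit into a serialisable NtcpModel."""
        check_is_fitted(self, "coef_")
        units = units or {}
        terms = tuple(
            ModelTerm(str(n), float(b), float(se), units.get(str(n), ""))
            for n, b, se in zip(
                self.feature_names_in_, self.coef_.ravel(), self.coef_se_
            )
        )
        return NtcpModel(
            intercept=float(self.intercept_[0]),
            intercept_se=self.intercept_se_,
            terms=terms,
            eud_params=dict(eud_params or {}),
            fit_meta={
                "cohort_size": self.n_obs_,
                "events": self.n_events_,
                "log_likelihood": self.llf_,
            },
        )


def lasso_select(
    features: pd.DataFrame,
    outcome: Sequence[int],
    folds: int = 5,
    rule: str = "min",
    seed: int = 0,
    n_path: int = 100,
) -> list[str]:
    """Names of the features with non-zero L1 coefficients at the CV-chosen penalty."""
    sel = LassoSelector(folds=folds, rule=rule, n_path=n_path, random_state=seed)
    sel.fit(features, outcome)
    return sel.selected_features_


def fit_logistic(
    features: pd.DataFrame,
    outcome: Sequence[int],
    units: Mapping[str, str] | None = None,
    eud_params: Mapping[str, float] | None = None,
) -> NtcpModel:
    """Unpenalised maximum-likelihood refit on the selected features."""
    est = NtcpLogisticRegression().fit(features, outcome)
    return est.to_model(units=units, eud_params=eud_params)


_AGE_UNIT_RANGE = (3.6, 20.0)  # plausible age/5 range for adults (18-100 y)


def predict_ntcp(model: NtcpModel, covariates: Mapping | pd.DataFrame) -> np.ndarray:
    """Probability of the endpoint for covariates given in model units.

    Warns when an age term looks like it was passed in years instead of
    5-year units.
    """
    for t in model.terms:
        if "age" in t.name and t.name in covariates:
            vals = np.atleast_1d(np.asarray(covariates[t.name], dtype=float))
            if np.any(vals > _AGE_UNIT_RANGE[1]):
                warnings.warn(
                    f"{t.name} = {vals.max():.1f} exceeds the plausible 5-year-unit "
                    "range; was age passed in years?"
                )
    return model.predict(covariates)


def odds_ratios(model: NtcpModel, z: float = Z_95, decimals: int | None = None):
    """Per-term odds ratio and Wald confidence interval.

    OR = exp(beta); CI = exp(beta -/+ z*SE).  ``decimals`` applies report
    rounding (2 in the printed convention); None returns raw values.
    """
    out = {}
    for t in model.terms:
        o = np.exp(t.coefficient)
        lo = np.exp(t.coefficient - z * t.standard_error)
        hi = np.exp(t.coefficient + z * t.standard_error)
        if decimals is not None:
            o, lo, hi = (round(v, decimals) for v in (o, lo, hi))
        out[t.name] = {"OR": float(o), "CI_low": float(lo), "CI_high": float(hi)}
    return out


@dataclass(frozen=True)
class Nomogram:
    """Points-based calculator equivalent to the logistic linear predictor.

    Each term scores ``100 * beta_i * (x - x_ref,i) / K`` points, where
    ``x_ref,i`` minimises ``beta_i * x`` over the term's range and ``K`` is
    the largest logit span over all terms, so the widest-impact term spans
    exactly 0-100 points.  Total points map back to probability through
    ``LP = lp_offset + K * T / 100``.
    """

    term_tables: dict  # name -> (values array, points array)
    ranges: dict  # name -> (lo, hi)
    scale: float  # K: logit units per 100 points
    lp_offset: float  # intercept + sum of minimal per-term contributions

    def points(self, name: str, value: float) -> float:
        vals, pts = self.term_tables[name]
        lo, hi = self.ranges[name]
        if not lo <= value <= hi:
            raise ValueError(f"{name}={value} outside the nomogram range [{lo}, {hi}]")
        return float(np.interp(value, vals, pts))

    def total_points(self, covariates: Mapping) -> float:
        return float(sum(self.points(n, covariates[n]) for n in self.term_tables))

    def probability(self, total_points: float) -> float:
        lp = self.lp_offset + self.scale * total_points / 100.0
        return float(1.0 / (1.0 + np.exp(-lp)))

    def lookup(self, covariates: Mapping) -> float:
        return self.probability(self.total_points(covariates))


def build_nomogram(
    model: NtcpModel,
    ranges: Mapping[str, tuple[float, float]],
    n_points: int = 101,
) -> Nomogram:
    """Construct the nomogram point tables from a fitted model and term ranges."""
    spans = {}
    for t in model.terms:
        if t.name not in ranges:
            raise KeyError(f"no range given for term {t.name}")
        lo, hi = ranges[t.name]
        if hi <= lo:
            raise ValueError(f"zero-width range for term {t.name}")
        spans[t.name] = abs(t.coefficient) * (hi - lo)
    scale = max(spans.values())
    if scale <= 0:
        raise ValueError("all coefficients are zero; nomogram undefined")
    tables = {}
    lp_offset = model.intercept
    for t in model.terms:
        lo, hi = ranges[t.name]
        vals = np.linspace(lo, hi, n_points)
        ref = lo if t.coefficient >= 0 else hi
        pts = 100.0 * t.coefficient * (vals - ref) / scale
        tables[t.name] = (vals, pts)
        lp_offset += t.coefficient * ref
    return Nomogram(tables, {k: tuple(v) for k, v in ranges.items()}, scale, lp_offset)
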