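"""Synthetic cohorts with the dosimetric, covariate and outcome structure of
a nasopharyngeal-cancer radiotherapy toxicity study.

Per-patient DVHs come from a three-parameter family: the cumulative relative
curve is a plateau followed by a power-law fall-off,

    S(D) = 1                          for D <= a,
    S(D) = ((b - D) / (b - a))**g     for a < D <= b,

whose three parameters (a, b, g) are solved per patient so the curve hits a
jointly drawn (D98%, mean dose, maximum dose) triple; drawing D98% and mean
dose from a correlated bivariate normal induces the target D98%-mean
correlation.  Outcomes are Bernoulli draws from a known logistic model
(default: the development-cohort model), and weekly CTCAE grade trajectories
are assembled so that endpoint derivation reproduces the drawn events with
first-event weeks following the observed actuarial incidence pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .cohort import COMORBIDITIES, PatientRecord, encode_covariates
from .dvh import CUMULATIVE, DoseVolumeHistogram, summarize
from .eud import compute_eud
from .model import NtcpModel, reference_model

__all__ = [
    "OrganTemplate",
    "SyntheticCohortSpec",
    "generate_dvh",
    "generate_cohort",
    "generate_validation_shift",
    "cohort_features",
    "development_spec",
    "npc_validation_spec",
    "hnc_validation_spec",
    "CPG_TEMPLATE",
    "OC_TEMPLATE",
    "WEEKLY_INCIDENCE_TARGETS",
]


@dataclass(frozen=True)
class OrganTemplate:
    """Distributional targets for one organ's DVH summaries (Gy, cc)."""

    label: str
    volume_mean: float
    volume_sd: float
    mean_dose_mean: float
    mean_dose_sd: float
    max_dose_mean: float
    max_dose_sd: float
    d98_mean: float
    d98_sd: float
    d98_mean_corr: float  # Pearson correlation of D98% with mean dose
    grid_width: float = 0.5  # Gy; DVH discretisation

    def __post_init__(self) -> None:
        for name in ("volume_sd", "mean_dose_sd", "max_dose_sd", "d98_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not -1.0 <= self.d98_mean_corr <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")
        if self.d98_mean >= self.max_dose_mean:
            raise ValueError("template implies D98% above the maximum dose")


#: combined parotid glands, moments of the development cohort
CPG_TEMPLATE = OrganTemplate(
    "combined_parotids", 53.3, 19.3, 47.2, 9.5, 74.2, 3.5, 26.8, 9.5, 0.88
)
#: oral cavity; no D98% moment is reported for it, the spread is an assumption
OC_TEMPLATE = OrganTemplate(
    "oral_cavity", 64.8, 20.4, 46.7, 6.4, 71.9, 3.7, 20.0, 7.0, 0.70
)

#: cumulative incidence (%) of the grade >= 2 endpoint by treatment week
WEEKLY_INCIDENCE_TARGETS = {2: 12.0, 3: 26.5, 4: 42.0, 5: 53.0, 6: 60.0, 7: 68.2}

#: covariate prevalences / location-scale parameters, development cohort
DEV_COVARIATES: dict = {
    "male": 0.697,
    "age_median": 49.0, "age_sd": 13.0, "age_lo": 18.0, "age_hi": 81.0,
    "bmi_median": 25.9, "bmi_sd": 4.4, "bmi_lo": 16.6, "bmi_hi": 42.9,
    "smoking": 0.182,
    "hypertension": 0.144, "diabetes": 0.030, "cardiological": 0.045,
    "haematological": 0.053, "oncological": 0.038,
    "histology_scc": 0.098, "histology_other": 0.0,
    "stage_high": 0.849,
    "t_high": 0.40,  # T4 share not tabulated; assumption
    "n_positive": 0.97,
    "treat_icht": 0.773, "treat_rt_alone": 0.0,
    "technique_vmat": 0.470,
    "fraction_ge212": 0.235,
    "ott_lo": 43, "ott_hi": 61,
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Everything needed to regenerate a cohort bit-identically."""

    n_patients: int
    seed: int
    cohort_label: str = "development"
    cpg_template: OrganTemplate = CPG_TEMPLATE
    oc_template: OrganTemplate = OC_TEMPLATE
    covariates: dict = field(default_factory=lambda: dict(DEV_COVARIATES))
    true_model: NtcpModel = field(default_factory=reference_model)
    weekly_incidence_targets: dict = field(
        default_factory=lambda: dict(WEEKLY_INCIDENCE_TARGETS)
    )
    odds_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.odds_multiplier <= 0:
            raise ValueError("odds multiplier must be positive")
        for k, v in self.covariates.items():
            if k in DEV_COVARIATES and k not in (
                "age_median", "age_sd", "age_lo", "age_hi",
                "bmi_median", "bmi_sd", "bmi_lo", "bmi_hi", "ott_lo", "ott_hi",
            ) and not 0.0 <= v <= 1.0:
                raise ValueError(f"prevalence {k}={v} outside [0, 1]")


def _solve_gamma(d98: float, mean: float, dmax: float) -> tuple[float, float]:
    """Solve the fall-off exponent g and plateau end a for a (d98, mean, max)
    triple.  On the physical branch (a >= 0) the predicted D98% increases
    monotonically in g from ~0 to the mean dose, so the root is unique."""
    bm = dmax - mean

    def d98_of(g: float) -> float:
        return dmax - bm * (1.0 + 1.0 / g) * 0.98 ** (1.0 / g)

    g_lo = bm / mean + 1e-6  # a(g) >= 0
    g_hi = 200.0
    lo_val = d98_of(g_lo)
    target = min(max(d98, lo_val + 0.05), mean - 0.5)
    g = brentq(lambda g: d98_of(g) - target, g_lo, g_hi, xtol=1e-10)
    a = mean + (mean - dmax) / g
    return max(a, 0.0), g


def generate_dvh(
    template: OrganTemplate, rng: np.random.Generator
) -> DoseVolumeHistogram:
    """Draw one organ DVH whose summary metrics follow the template moments."""
    t = template
    if t.mean_dose_sd == 0 and t.max_dose_sd == 0 and t.d98_sd == 0:
        m, mx, d98 = t.mean_dose_mean, t.max_dose_mean, t.d98_mean
        vol = t.volume_mean
    else:
        for _ in range(1000):
            z1, z2 = rng.standard_normal(2)
            m = t.mean_dose_mean + t.mean_dose_sd * z1
            rho = t.d98_mean_corr
            d98 = t.d98_mean + t.d98_sd * (rho * z1 + np.sqrt(1 - rho**2) * z2)
            mx = t.max_dose_mean + t.max_dose_sd * rng.standard_normal()
            if d98 >= 1.0 and d98 <= m - 2.0 and m <= mx - 5.0:
                break
        else:  # pragma: no cover - pathological template
            raise ValueError("template admits no valid (D98, mean, max) draw")
        vol = max(t.volume_mean + t.volume_sd * rng.standard_normal(), 5.0)
    a, g = _solve_gamma(d98, m, mx)
    h = t.grid_width
    edges = np.arange(0.0, mx + h, h)
    if edges[-1] < mx:
        edges = np.append(edges, mx)
    s = np.ones_like(edges)
    fall = edges > a
    s[fall] = np.clip((mx - edges[fall]) / (mx - a), 0.0, None) ** g
    s[edges >= mx] = 0.0
    return DoseVolumeHistogram(t.label, CUMULATIVE, edges, vol * s, vol)


def _truncated_normal(
    rng: np.random.Generator, loc: float, scale: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        x = loc + scale * rng.standard_normal()
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(loc, lo, hi))  # pragma: no cover


def _event_week_distribution(targets: Mapping[int, float]) -> tuple[np.ndarray, np.ndarray]:
    weeks = np.array(sorted(targets), dtype=int)
    cum = np.array([targets[w] for w in weeks], dtype=float)
    inc = np.diff(np.concatenate([[0.0], cum]))
    if np.any(inc < 0):
        raise ValueError("weekly incidence targets must be non-decreasing")
    return weeks, inc / inc.sum()


def _weekly_grades(
    event: bool, event_week: int | None, n_weeks: int, rng: np.random.Generator
) -> list[int]:
    grades = np.zeros(n_weeks, dtype=int)
    if event:
        w = min(event_week, n_weeks)
        grades[max(0, w - 3):w - 1] = 1  # prodromal grade-1 weeks
        grades[w - 1:] = 2
        if w < n_weeks and rng.random() < 0.25:
            grades[rng.integers(w, n_weeks):] = 3
    elif rng.random() < 0.6:
        onset = int(rng.integers(3, n_weeks + 1))
        grades[onset - 1:] = 1
    return grades.tolist()


def generate_cohort(spec: SyntheticCohortSpec) -> list[PatientRecord]:
    """Draw a full synthetic cohort: covariates, DVHs, outcomes, weekly grades.

    Events are Bernoulli draws from ``spec.true_model`` evaluated on the
    generated covariates and dose metrics (odds scaled by
    ``spec.odds_multiplier``); first-event weeks follow the cohort's weekly
    incidence pattern.
    """
    rng = np.random.default_rng(spec.seed)
    cv = spec.covariates
    weeks_grid, week_probs = _event_week_distribution(spec.weekly_incidence_targets)
    records: list[PatientRecord] = []
    for i in range(spec.n_patients):
        age = _truncated_normal(rng, cv["age_median"], cv["age_sd"], cv["age_lo"], cv["age_hi"])
        bmi = _truncated_normal(rng, cv["bmi_median"], cv["bmi_sd"], cv["bmi_lo"], cv["bmi_hi"])
        smoking = rng.random() < cv["smoking"]
        u_hist = rng.random()
        histology = (
            "SCC" if u_hist < cv["histology_scc"]
            else "other" if u_hist < cv["histology_scc"] + cv["histology_other"]
            else "undifferentiated"
        )
        u_tr = rng.random()
        treatment = (
            "iCHT+RT-CHT" if u_tr < cv["treat_icht"]
            else "RT alone" if u_tr < cv["treat_icht"] + cv["treat_rt_alone"]
            else "RT-CHT"
        )
        ott = float(rng.integers(int(cv["ott_lo"]), int(cv["ott_hi"]) + 1))
        cpg = generate_dvh(spec.cpg_template, rng)
        oc = generate_dvh(spec.oc_template, rng)
        cpg_sum = summarize(cpg)
        oc_sum = summarize(oc)
        oc_n = float(spec.true_model.eud_params.get("oral_cavity", 0.05))
        metrics = {
            "cpg_d98": cpg_sum.d98,
            "cpg_dmean": cpg_sum.mean_dose,
            "cpg_dmax": cpg_sum.max_dose,
            "oc_eud": compute_eud(oc, oc_n),
            "oc_dmean": oc_sum.mean_dose,
        }
        record = PatientRecord(
            patient_id=f"{spec.cohort_label}-{i + 1:04d}",
            cohort=spec.cohort_label,
            sex="M" if rng.random() < cv["male"] else "F",
            age=age,
            bmi=bmi,
            smoking=smoking,
            comorbidities={k: rng.random() < cv[k] for k in COMORBIDITIES},
            histology=histology,
            stage_group="high" if rng.random() < cv["stage_high"] else "low-intermediate",
            t_high=rng.random() < cv["t_high"],
            n_positive=rng.random() < cv["n_positive"],
            treatment=treatment,
            technique="VMAT" if rng.random() < cv["technique_vmat"] else "IMRT",
            fraction_dose_class=">=2.12" if rng.random() < cv["fraction_ge212"] else "2.00",
            overall_treatment_time=ott,
            organ_dvhs={cpg.organ_label: cpg, oc.organ_label: oc},
            dose_metrics=metrics,
        )
        feats = {**encode_covariates(record), **metrics}
        lp = float(spec.true_model.linear_predictor(feats))
        lp += np.log(spec.odds_multiplier)
        p = 1.0 / (1.0 + np.exp(-lp))
        event = rng.random() < p
        n_weeks = int(np.clip(round(ott / 7.0), 6, 9))
        if event:
            w = int(weeks_grid[rng.choice(len(weeks_grid), p=week_probs)])
            w = min(w, n_weeks)
        else:
            w = None
        record.weekly_grades = _weekly_grades(event, w, n_weeks, rng)
        record.dose_metrics["true_p"] = p
        records.append(record)
    return records


def generate_validation_shift(
    spec: SyntheticCohortSpec, odds_multiplier: float
) -> list[PatientRecord]:
    """Cohort whose event odds are uniformly multiplied relative to the model.

    Frozen-coefficient validation on such a cohort recovers a calibration
    slope of ~1 and a calibration-in-the-large of ~log(odds_multiplier):
    discrimination is unchanged, overall risk is shifted.
    """
    if odds_multiplier <= 0:
        raise ValueError("odds multiplier must be positive")
    return generate_cohort(dc_replace(spec, odds_multiplier=odds_multiplier))


def cohort_features(records: Sequence[PatientRecord]):
    """Design frame: encoded clinical covariates plus stored dose metrics."""
    import pandas as pd

    rows = []
    for r in records:
        row = {**encode_covariates(r), **{
            k: v for k, v in r.dose_metrics.items() if k != "true_p"
        }}
        rows.append(row)
    return pd.DataFrame(rows, index=[r.patient_id for r in records])


def development_spec(n_patients: int = 132, seed: int = 0) -> SyntheticCohortSpec:
    """Development-cohort conditions (covariate prevalences, DVH moments)."""
    return SyntheticCohortSpec(n_patients, seed, "development")


def npc_validation_spec(n_patients: int = 38, seed: int = 1) -> SyntheticCohortSpec:
    """Nasopharyngeal validation cohort: older, more smokers, VMAT-only,
    higher overall toxicity (odds shifted up)."""
    cov = dict(DEV_COVARIATES)
    cov.update(
        male=0.789, age_median=52.0, age_lo=24.0, age_hi=72.0,
        bmi_median=25.8, bmi_lo=18.2, bmi_hi=32.9,
        smoking=0.526, hypertension=0.263, diabetes=0.026,
        cardiological=0.079, haematological=0.0, oncological=0.079,
        histology_scc=0.105, stage_high=0.842, n_positive=0.868,
        treat_icht=0.421, treat_rt_alone=0.079,
        technique_vmat=1.0, fraction_ge212=0.974,
    )
    return SyntheticCohortSpec(
        n_patients, seed, "npc_validation", covariates=cov, odds_multiplier=2.5
    )


def hnc_validation_spec(n_patients: int = 93, seed: int = 2) -> SyntheticCohortSpec:
    """Mixed head-and-neck validation cohort: mostly SCC, highest event rate."""
    cov = dict(DEV_COVARIATES)
    cov.update(
        male=0.731, age_median=62.0, age_lo=23.0, age_hi=83.0,
        bmi_median=24.8, bmi_lo=14.7, bmi_hi=36.4,
        smoking=0.677, hypertension=0.398, diabetes=0.043,
        cardiological=0.215, haematological=0.021, oncological=0.161,
        histology_scc=0.903, histology_other=0.097, stage_high=0.925,
        treat_icht=0.118, treat_rt_alone=0.280,
        technique_vmat=1.0, fraction_ge212=0.656,
    )
    return SyntheticCohortSpec(
        n_patients, seed, "hnc_validation", covariates=cov, odds_multiplier=3.5
    )
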