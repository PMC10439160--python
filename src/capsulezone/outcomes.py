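"""Encapsulation-stratified survival analysis of the metastasis cohort.

Endpoints are overall survival (OS) and hepatic relapse-free survival (hRFS),
in months.  The module provides Kaplan–Meier estimates, log-rank tests, and
Cox proportional-hazards fits in which encapsulation enters either as three
strata (low <33%, medium 33–<100%, high 100%; low is the reference) or as a
continuous covariate coded as pct/10 so the hazard ratio reads "per 0.1
fraction increment" of encapsulation.

Kaplan–Meier, log-rank and Efron-ties Cox fits are computed with lifelines;
Breslow ties use an in-house Newton solver on the Breslow partial likelihood
(the two agree exactly on tie-free data).  Confidence intervals are Wald-type
on the log-hazard scale.  No missing-data imputation is done: records with
missing model covariates are dropped per model, with the count logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from capsulezone.errors import ConvergenceError, ValidationError

logger = logging.getLogger(__name__)

MULTIVARIATE_COVARIATES = [
    "neoadjuvant", "meta_synchronous", "n_metastases", "max_diameter_cm",
]


@dataclass
class PatientRecord:
    """One patient's encapsulation score, outcomes and clinical covariates."""

    patient_id: str
    pct_encapsulated: float
    os_time: float
    os_event: int
    hrfs_time: float
    hrfs_event: int
    neoadjuvant: int = 0
    meta_synchronous: int = 0
    n_metastases: int = 1
    max_diameter_cm: float = float("nan")
    viable_percent: float = float("nan")
    sex: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.pct_encapsulated <= 100:
            raise ValidationError("pct_encapsulated must be in [0, 100]")
        if self.os_time <= 0 or self.hrfs_time <= 0:
            raise ValidationError("survival times must be positive")
        for ev in (self.os_event, self.hrfs_event):
            if ev not in (0, 1):
                raise ValidationError("event flags must be 0/1")

    @property
    def encapsulation_stratum(self) -> str:
        if self.pct_encapsulated >= 100.0 - 1e-12:
            return "high"
        if self.pct_encapsulated >= 33.0:
            return "medium"
        return "low"


@dataclass
class CoxFit:
    """Per-covariate hazard ratios with Wald CIs and p-values."""

    coefficients: pd.Series
    hazard_ratios: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p_values: pd.Series
    ties: str
    n: int
    n_events: int
    n_dropped_missing: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "HR": self.hazard_ratios,
                "ci_lo": self.ci_lower,
                "ci_hi": self.ci_upper,
                "p": self.p_values,
            }
        )


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records])
    df["encapsulation_stratum"] = [r.encapsulation_stratum for r in records]
    return df


# ---------------------------------------------------------------------------
# Kaplan–Meier and log-rank


def km_estimate(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence | None = None,
) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimates, one step function per group.

    Returns, per group, a DataFrame with columns ``time`` and ``survival``
    evaluated at the observed event/censoring times (starting at S(0)=1).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times <= 0):
        raise ValidationError("times must be positive")
    if groups is None:
        groups = np.zeros(len(times), dtype=int)
    groups = np.asarray(groups)
    out: dict[str, pd.DataFrame] = {}
    for g in pd.unique(groups):
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        out[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return out


def logrank_test(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence,
) -> tuple[float, float]:
    """Standard log-rank test across ≥2 groups; returns (chi², p), df = k−1."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2 or np.any(counts < 1):
        raise ValidationError("need at least two non-empty groups")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards


def _breslow_newton(
    T: np.ndarray, E: np.ndarray, X: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Newton–Raphson maximization of the Breslow partial likelihood.

    Returns (beta, inverse information).  Raises on monotone likelihood.
    """
    n, p = X.shape
    order = np.argsort(T)
    T, E, X = T[order], E[order], X[order]
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        eta -= eta.max()  # guard overflow
        w = np.exp(eta)
        # reverse cumulative sums give the risk-set aggregates at each time
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
        s2 = np.cumsum((w[:, None, None] * (X[:, :, None] * X[:, None, :]))[::-1], axis=0)[::-1]
        # risk set of an event at time t includes all with T >= t: map each
        # event row to the first index sharing its time
        first_at_time = np.searchsorted(T, T, side="left")
        ev = np.flatnonzero(E == 1)
        idx = first_at_time[ev]
        xbar = s1[idx] / s0[idx, None]
        grad = (X[ev] - xbar).sum(axis=0)
        info = (s2[idx] / s0[idx, None, None] - xbar[:, :, None] * xbar[:, None, :]).sum(axis=0)
        if not np.all(np.isfinite(info)) or np.linalg.cond(info) > 1e12:
            raise ConvergenceError(
                "monotone partial likelihood (perfect separation?) — Cox fit did not converge"
            )
        step = np.linalg.solve(info, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta, np.linalg.inv(info)
    raise ConvergenceError("Cox Newton iteration did not converge")


def cox_fit(
    records: Sequence[PatientRecord] | pd.DataFrame,
    covariates: Sequence[str],
    endpoint: Literal["os", "hrfs"] = "os",
    ties: Literal["efron", "breslow"] = "efron",
) -> CoxFit:
    """Cox proportional-hazards fit over the given covariate columns.

    Special covariate names:

    * ``encapsulation_per_0.1`` — continuous encapsulation coded as pct/10, so
      the HR is per 0.1-fraction (10 percentage-point) increment;
    * ``encapsulation_stratum`` — expands to indicator columns for medium and
      high encapsulation with low as the reference.

    Rows with missing values in any model covariate are dropped (count
    logged); constant covariates and fits with <2 events raise.
    """
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    if "encapsulation_stratum" not in df.columns and "pct_encapsulated" in df.columns:
        df["encapsulation_stratum"] = pd.cut(
            df["pct_encapsulated"], [-np.inf, 33.0, 100.0 - 1e-12, np.inf],
            right=False, labels=["low", "medium", "high"],
        ).astype(str)
    time_col, event_col = f"{endpoint}_time", f"{endpoint}_event"

    cols: list[str] = []
    for cov in covariates:
        if cov == "encapsulation_per_0.1":
            df[cov] = df["pct_encapsulated"] / 10.0
            cols.append(cov)
        elif cov == "encapsulation_stratum":
            for level in ("medium", "high"):
                name = f"encapsulation_{level}"
                df[name] = (df["encapsulation_stratum"] == level).astype(float)
                cols.append(name)
        else:
            cols.append(cov)

    model = df[[time_col, event_col, *cols]].astype(float)
    n_before = len(model)
    model = model.dropna()
    n_dropped = n_before - len(model)
    if n_dropped:
        logger.info("dropped %d record(s) with missing covariates", n_dropped)
    if int(model[event_col].sum()) < 2:
        raise ValidationError("need at least two events for a Cox fit")
    for c in cols:
        if model[c].nunique() < 2:
            raise ValidationError(f"covariate {c!r} has zero variance")

    if ties == "efron":
        cph = CoxPHFitter()
        try:
            cph.fit(model, duration_col=time_col, event_col=event_col)
        except Exception as exc:  # lifelines raises its own convergence errors
            raise ConvergenceError(f"Cox fit failed: {exc}") from exc
        s = cph.summary
        coef = s["coef"]
        se = s["se(coef)"]
    elif ties == "breslow":
        X = model[cols].to_numpy()
        center = X.mean(axis=0)
        beta, cov_mat = _breslow_newton(
            model[time_col].to_numpy(), model[event_col].to_numpy().astype(int),
            X - center,
        )
        coef = pd.Series(beta, index=cols)
        se = pd.Series(np.sqrt(np.diag(cov_mat)), index=cols)
    else:
        raise ValidationError(f"unknown ties method {ties!r}")

    z = stats.norm.ppf(0.975)
    p_values = pd.Series(
        2.0 * stats.norm.sf(np.abs(coef / se)), index=coef.index
    )
    return CoxFit(
        coefficients=coef,
        hazard_ratios=np.exp(coef),
        ci_lower=np.exp(coef - z * se),
        ci_upper=np.exp(coef + z * se),
        p_values=p_values,
        ties=ties,
        n=len(model),
        n_events=int(model[event_col].sum()),
        n_dropped_missing=n_dropped,
    )


# ---------------------------------------------------------------------------
# full survival report


def build_survival_report(
    records: Sequence[PatientRecord] | pd.DataFrame,
    endpoint: Literal["os", "hrfs"] = "os",
    ties: Literal["efron", "breslow"] = "efron",
) -> dict:
    """Standard survival workup of a scored cohort.

    Produces Kaplan–Meier curves and log-rank tests by encapsulation stratum,
    a univariate Cox fit over the strata (low as reference), a continuous
    per-0.1-fraction Cox fit, a multivariate Cox fit with the clinical
    covariates, and a sex log-rank screen.  A stratum with fewer than two
    events is reported as unestimable rather than raising.
    """
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    time_col, event_col = f"{endpoint}_time", f"{endpoint}_event"
    report: dict = {"endpoint": endpoint, "n": len(df)}

    strata = df["encapsulation_stratum"]
    report["km_by_stratum"] = km_estimate(df[time_col], df[event_col], strata)
    if strata.nunique() >= 2:
        chi2, p = logrank_test(df[time_col], df[event_col], strata)
        report["logrank_stratum"] = {"chi2": chi2, "p": p}
    else:
        report["logrank_stratum"] = None

    def _try_cox(covs: list[str], label: str) -> None:
        try:
            report[label] = cox_fit(df, covs, endpoint=endpoint, ties=ties)
        except (ValidationError, ConvergenceError) as exc:
            logger.warning("%s unestimable: %s", label, exc)
            report[label] = None

    if strata.nunique() >= 2:
        _try_cox(["encapsulation_stratum"], "cox_univariate_strata")
    else:
        report["cox_univariate_strata"] = None
    _try_cox(["encapsulation_per_0.1"], "cox_continuous")
    mv = ["encapsulation_stratum"] + [
        c for c in MULTIVARIATE_COVARIATES if c in df.columns and df[c].nunique() > 1
    ]
    _try_cox(mv, "cox_multivariate")

    if "sex" in df.columns and df["sex"].nunique() >= 2:
        chi2, p = logrank_test(df[time_col], df[event_col], df["sex"])
        report["logrank_sex"] = {"chi2": chi2, "p": p}
    else:
        report["logrank_sex"] = None

    if "predominant" in df.columns and df["predominant"].nunique() >= 2:
        chi2, p = logrank_test(df[time_col], df[event_col], df["predominant"])
        report["logrank_predominant"] = {"chi2": chi2, "p": p}
    else:
        report["logrank_predominant"] = None
    return report
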