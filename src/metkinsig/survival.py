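"""Survival machinery: Kaplan-Meier, log-rank, Cox PH, prognosis labels.

Estimation is delegated to lifelines; this module fixes the package's
conventions (censoring at an event time counts as at-risk for that
time's events; the five-year good-prognosis boundary is inclusive,
>= 60 months) and returns plain containers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .datatypes import PatientCohort

GOOD_PROGNOSIS_FOLLOWUP_MONTHS = 60.0


@dataclass
class SurvivalCurve:
    """Product-limit estimate S(t) with its risk table."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def at(self, t: float) -> float:
        """S(t), right-continuous step function with S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    ``times`` are follow-up durations (>= 0) and ``events`` the 1/0 event
    indicators. Only times with at least one event appear in the curve's
    risk table (censoring-only times do not change S).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative survival times")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("event indicators must be 0/1")
    kmf = KaplanMeierFitter().fit(times, events)
    table = kmf.event_table
    has_event = table["observed"] > 0
    event_times = table.index.to_numpy(dtype=float)[has_event]
    at_risk = table["at_risk"].to_numpy(dtype=float)[has_event]
    d = table["observed"].to_numpy(dtype=float)[has_event]
    survival = np.cumprod(1.0 - d / at_risk)
    return SurvivalCurve(event_times, at_risk, d, survival)


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    note: str = ""


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-group log-rank test (hypergeometric variance, 1-df chi-square)."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a, int), np.asarray(events_b, int)
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        return LogrankResult(np.nan, np.nan, "no events in either group")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a,
                      event_observed_B=events_b)
    return LogrankResult(float(res.test_statistic), float(res.p_value))


def cox_ph(times, events, covariates: pd.DataFrame) -> pd.DataFrame:
    """Cox proportional-hazards fit by partial likelihood.

    Returns a per-covariate table with columns ``coef`` (log hazard
    ratio), ``se``, ``p``, ``ci_lower``, ``ci_upper``. Ties are handled
    by lifelines' Efron approximation (simulated times are continuous,
    so ties are absent almost surely). Non-convergence or separation
    surfaces as an error with lifelines' diagnostics.
    """
    covariates = pd.DataFrame(covariates)
    if len(covariates) <= covariates.shape[1]:
        raise ValueError("need more observations than covariates")
    if (covariates.nunique() <= 1).any():
        bad = list(covariates.columns[covariates.nunique() <= 1])
        raise ValueError(f"constant covariates: {bad}")
    df = covariates.copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = np.asarray(events, dtype=int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")
    s = cph.summary
    return pd.DataFrame({
        "coef": s["coef"],
        "se": s["se(coef)"],
        "p": s["p"],
        "ci_lower": s["coef lower 95%"],
        "ci_upper": s["coef upper 95%"],
    })


def label_prognosis(cohort: PatientCohort) -> pd.Series:
    """Good/bad/excluded prognosis labels.

    bad: the configured event (disease death or metastasis) at any time
    during follow-up. good: event-free with at least five years
    (>= 60 months, inclusive) of follow-up. Everyone else — event-free
    but followed for less than five years, or missing follow-up — is
    excluded.
    """
    clin = cohort.clinical
    fup = clin["followup_time"]
    event = clin["event"]
    labels = pd.Series("excluded", index=clin.index, dtype=object, name="prognosis")
    labels[event == 1] = "bad"
    labels[(event == 0) & (fup >= GOOD_PROGNOSIS_FOLLOWUP_MONTHS)] = "good"
    labels[fup.isna()] = "excluded"
    return labels


@dataclass
class PredictiveValues:
    ppv: float     # P(bad outcome | HighSig)
    npv: float     # P(good outcome | LowSig)
    n_high: int
    n_low: int
    note: str = ""


def ppv_npv(labels: pd.Series, prognosis: pd.Series) -> PredictiveValues:
    """Positive/negative predictive value of the High/Low stratification.

    Computed over patients with a defined (non-excluded) prognosis:
    PPV = P(bad | HighSig), NPV = P(good | LowSig).
    """
    common = labels.index.intersection(prognosis.index)
    lab = labels.loc[common]
    prog = prognosis.loc[common]
    keep = prog != "excluded"
    lab, prog = lab[keep], prog[keep]
    if (lab == "HighSig").sum() == 0 or (lab == "LowSig").sum() == 0:
        return PredictiveValues(np.nan, np.nan, int((lab == "HighSig").sum()),
                                int((lab == "LowSig").sum()),
                                "a stratum has no non-excluded patients")
    high = prog[lab == "HighSig"]
    low = prog[lab == "LowSig"]
    return PredictiveValues(
        ppv=float((high == "bad").mean()),
        npv=float((low == "good").mean()),
        n_high=len(high),
        n_low=len(low),
    )
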