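"""Survival association of the morphometric indices with RP outcomes.

Median dichotomization into higher/lower strata, Kaplan-Meier curves
with log-rank tests, Cox proportional-hazards fits (Efron tie handling,
Wald 95% CIs), Schoenfeld-residual PH checks with the identity time
transform, and Harrell's concordance index. Model fitting is delegated
to lifelines; this module fixes the conventions (reference levels,
ties-at-median rule, risk-score orientation) used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import (
    multivariate_logrank_test,
    proportional_hazard_test,
)
from lifelines.utils import concordance_index

#: reference category per covariate; design columns are indicators of the
#: remaining levels. The index stratum reference is `upper` (higher than
#: median), so the reported HR is for the lower stratum.
REFERENCE_LEVELS = {
    "stratum": "upper",
    "sex": "female",
    "smoking": "never",
    "lung_disease": "none",
    "rt_technique": "IMRT",
    "stage": "I-II",
    "histology": "adenocarcinoma",
}

DEFAULT_TIME_FIELD = "time_months"


@dataclass
class CoxFit:
    coefficients: dict  # term -> (beta, se)
    hazard_ratios: dict  # term -> (hr, ci_low, ci_high, p)
    c_index: float
    log_partial_likelihood: float
    ph_test: dict  # term -> (chi2, p)
    ties: str
    model: CoxPHFitter
    design: pd.DataFrame
    event_field: str
    time_field: str


@dataclass
class KMEstimate:
    strata: dict  # label -> DataFrame(time, survival, at_risk)
    logrank_chi2: float
    logrank_p: float


def dichotomize_at_median(values) -> np.ndarray:
    """Label each value `upper` (>= sample median) or `lower` (< median).

    Ties at the median go to the upper stratum; for odd n with distinct
    values this yields (n+1)/2 in the upper stratum.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to dichotomize")
    med = np.median(values)
    return np.where(values >= med, "upper", "lower")


def kaplan_meier(
    records: pd.DataFrame,
    event_field: str,
    strata,
    time_field: str = DEFAULT_TIME_FIELD,
) -> KMEstimate:
    """Product-limit survival per stratum plus the log-rank comparison."""
    strata = np.asarray(strata)
    t = records[time_field].to_numpy(dtype=float)
    if np.any(t < 0):
        raise ValueError("negative event/censoring times")
    e = records[event_field].to_numpy(dtype=bool)
    curves = {}
    for label in np.unique(strata):
        sel = strata == label
        if not sel.any():
            raise ValueError(f"stratum {label!r} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel])
        tab = kmf.event_table
        curves[str(label)] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": tab["at_risk"].reindex(
                    kmf.survival_function_.index, method="ffill"
                ).to_numpy(),
            }
        )
    chi2, p = logrank_test(records, event_field, strata, time_field=time_field) \
        if len(curves) > 1 else (0.0, 1.0)
    return KMEstimate(strata=curves, logrank_chi2=chi2, logrank_p=p)


def logrank_test(
    records: pd.DataFrame,
    event_field: str,
    strata,
    time_field: str = DEFAULT_TIME_FIELD,
) -> tuple[float, float]:
    """Two-sample log-rank statistic (1 df chi-square) and its p-value."""
    strata = np.asarray(strata)
    if len(np.unique(strata)) != 2:
        raise ValueError("log-rank test requires exactly 2 strata")
    res = multivariate_logrank_test(
        records[time_field].to_numpy(dtype=float),
        strata,
        records[event_field].to_numpy(dtype=bool),
    )
    return float(res.test_statistic), float(res.p_value)


def _build_design(
    records: pd.DataFrame, terms: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Expand categorical terms against their reference levels."""
    cols = {}
    for term in terms:
        if term not in records.columns:
            raise KeyError(f"term {term!r} not in records")
        col = records[term]
        if pd.api.types.is_numeric_dtype(col) and col.dtype != bool:
            cols[term] = col.astype(float).to_numpy()
        else:
            levels = sorted(str(v) for v in pd.unique(col))
            ref = REFERENCE_LEVELS.get(term, levels[0])
            if ref not in levels:
                ref = levels[0]
            for lev in levels:
                if lev == ref:
                    continue
                cols[f"{term}_{lev}"] = (col.astype(str) == lev).to_numpy(float)
    design = pd.DataFrame(cols, index=records.index)
    return design, list(design.columns)


def cox_fit(
    records: pd.DataFrame,
    event_field: str,
    terms: list[str],
    time_field: str = DEFAULT_TIME_FIELD,
    ties: str = "efron",
) -> CoxFit:
    """Cox proportional-hazards fit with Wald inference and diagnostics.

    Categorical terms are expanded as indicators against the reference
    levels in :data:`REFERENCE_LEVELS`. Harrell's C and per-term
    Schoenfeld PH tests (identity time transform) are attached.
    """
    if ties != "efron":
        raise ValueError("only Efron tie handling is supported")
    events = records[event_field].to_numpy(dtype=bool)
    if events.sum() < 1:
        raise ValueError("no events: Cox partial likelihood undefined")
    design, cols = _build_design(records, terms)
    df = design.copy()
    df["_time"] = records[time_field].to_numpy(dtype=float)
    df["_event"] = events.astype(int)

    cph = CoxPHFitter(baseline_estimation_method="breslow")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(
                df, duration_col="_time", event_col="_event",
                fit_options={"precision": 1e-12, "max_steps": 500},
            )
        except Exception as err:  # convergence / separation
            raise RuntimeError(f"Cox fit failed: {err}") from err

    summary = cph.summary
    coefficients = {}
    hazard_ratios = {}
    for term in cols:
        beta = float(summary.loc[term, "coef"])
        se = float(summary.loc[term, "se(coef)"])
        p = float(summary.loc[term, "p"])
        coefficients[term] = (beta, se)
        hazard_ratios[term] = (
            float(np.exp(beta)),
            float(np.exp(beta - 1.96 * se)),
            float(np.exp(beta + 1.96 * se)),
            p,
        )

    ph = {}
    if events.sum() >= 2:
        res = proportional_hazard_test(cph, df, time_transform="identity")
        stats = res.summary
        for term in cols:
            ph[term] = (
                float(stats.loc[term, "test_statistic"].iloc[0])
                if isinstance(stats.loc[term, "test_statistic"], pd.Series)
                else float(stats.loc[term, "test_statistic"]),
                float(stats.loc[term, "p"].iloc[0])
                if isinstance(stats.loc[term, "p"], pd.Series)
                else float(stats.loc[term, "p"]),
            )

    return CoxFit(
        coefficients=coefficients,
        hazard_ratios=hazard_ratios,
        c_index=float(cph.concordance_index_),
        log_partial_likelihood=float(cph.log_likelihood_),
        ph_test=ph,
        ties="efron",
        model=cph,
        design=df,
        event_field=event_field,
        time_field=time_field,
    )


def schoenfeld_test(fit: CoxFit) -> dict:
    """Per-term scaled-Schoenfeld PH test (identity time transform)."""
    if fit.design["_event"].sum() < 2:
        raise ValueError("need >= 2 events for the Schoenfeld test")
    return dict(fit.ph_test)


def harrell_c(time, risk_score, event) -> float:
    """Harrell's concordance index for risk scores.

    Orientation: a higher risk score is concordant with an earlier event.
    Ties in risk score count 1/2; comparability follows the standard
    censoring rules.
    """
    time = np.asarray(time, dtype=float)
    risk = np.asarray(risk_score, dtype=float)
    event = np.asarray(event, dtype=bool)
    return float(concordance_index(time, -risk, event))
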