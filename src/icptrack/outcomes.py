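"""Survival association of the early ctDNA response.

Patients are split by their week-8 ctDNA class (responder: >= 50% decline
of mean MAF) and compared on progression-free survival with Kaplan-Meier
curves, a log-rank test and a univariate Cox proportional-hazards model
(Efron ties). With cohorts of ~10 patients, monotone likelihood (all events
in one arm) is a real possibility; it is flagged rather than hidden and the
CI is reported as unbounded.

An outcome table is a DataFrame with columns ``patient_id``, ``pfs_days``,
``event`` (progression/death observed), ``best_response`` (CR/PR/SD/PD) and
``ctdna_class``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats


@dataclass
class KMResult:
    medians: dict  # group -> median PFS (NaN/inf when undefined)
    statistic: float
    p: float
    curves: dict  # group -> DataFrame (time, survival, at_risk)


def km_logrank(
    outcomes: pd.DataFrame,
    group_col: str = "ctdna_class",
    time_col: str = "pfs_days",
    event_col: str = "event",
) -> KMResult:
    """Product-limit survival per group plus the log-rank test across groups.

    A group with only censored records has an undefined median (reported as
    inf, the lifelines convention).
    """
    groups = outcomes[group_col].unique()
    if len(groups) < 2:
        raise ValueError("need at least two groups for a log-rank test")
    medians, curves = {}, {}
    for g in groups:
        sub = outcomes.loc[outcomes[group_col] == g]
        if sub.empty:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col], label=str(g))
        medians[g] = float(kmf.median_survival_time_)
        tbl = kmf.event_table
        curves[g] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index,
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": tbl["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
            }
        )
    res = multivariate_logrank_test(outcomes[time_col], outcomes[group_col], outcomes[event_col])
    return KMResult(medians=medians, statistic=float(res.test_statistic), p=float(res.p_value), curves=curves)


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    separation: bool  # monotone likelihood: all events in one arm


def cox_hr(
    outcomes: pd.DataFrame,
    group_col: str = "ctdna_class",
    time_col: str = "pfs_days",
    event_col: str = "event",
    reference: str | None = None,
) -> CoxResult:
    """Univariate Cox PH hazard ratio with Wald 95% CI for the non-reference
    group versus *reference* (default: lexicographically first group).

    Efron tie handling. Complete separation (every event in one arm) raises
    the monotone-likelihood flag; the fit is still attempted and the CI is
    reported as unbounded if it fails.
    """
    if int(outcomes[event_col].sum()) < 1:
        raise ValueError("no events in the data")
    levels = sorted(outcomes[group_col].unique())
    if len(levels) != 2:
        raise ValueError("cox_hr expects exactly two groups")
    ref = reference if reference is not None else levels[0]
    other = [g for g in levels if g != ref][0]
    df = pd.DataFrame(
        {
            "T": outcomes[time_col].astype(float),
            "E": outcomes[event_col].astype(int),
            "x": (outcomes[group_col] == other).astype(int),
        }
    )
    events_by_arm = df.groupby("x")["E"].sum()
    separation = bool((events_by_arm == 0).any()) if len(events_by_arm) == 2 else True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(df, duration_col="T", event_col="E")
        hr = float(np.exp(cph.params_["x"]))
        ci = cph.confidence_intervals_
        # under monotone likelihood the Wald bounds explode; inf is intended
        with np.errstate(over="ignore"):
            ci_low = float(np.exp(ci.loc["x"].iloc[0]))
            ci_high = float(np.exp(ci.loc["x"].iloc[1]))
        p = float(cph.summary.loc["x", "p"])
    except Exception:
        hr, ci_low, ci_high, p = float("nan"), 0.0, float("inf"), float("nan")
        separation = True
    if separation:
        ci_low, ci_high = 0.0, float("inf")
    return CoxResult(hr=hr, ci_low=ci_low, ci_high=ci_high, p=p, separation=separation)


RESPONDER_BOR = ("CR", "PR")


@dataclass
class OrderingReport:
    table: pd.DataFrame  # ordered by fold-change ascending; missing last
    odds_ratio: float
    fisher_p: float


def response_ordering_report(patients: pd.DataFrame, fc_col: str = "fold_change") -> OrderingReport:
    """Order patients by ctDNA fold-change (ascending, stable; missing values
    flagged and placed last) and test responder (CR/PR) over-representation
    in the top half with a two-sided Fisher exact test."""
    t = patients.copy()
    t["fc_missing"] = t[fc_col].isna()
    t = t.sort_values([ "fc_missing", fc_col], kind="stable", na_position="last").reset_index(drop=True)
    n = len(t)
    top = t.iloc[: n // 2]
    bottom = t.iloc[n // 2 :]
    is_resp = t["best_response"].isin(RESPONDER_BOR)
    table = [
        [int(is_resp.iloc[: n // 2].sum()), int((~is_resp.iloc[: n // 2]).sum())],
        [int(is_resp.iloc[n // 2 :].sum()), int((~is_resp.iloc[n // 2 :]).sum())],
    ]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return OrderingReport(table=t, odds_ratio=float(odds), fisher_p=float(p))
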