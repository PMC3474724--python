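"""Kaplan-Meier estimation and the log-rank test.

Thin, typed surface over lifelines.  The product-limit curve is the
calibration reference for the model comparison; with a fully observed
(uncensored) cohort it coincides with one minus the empirical CDF.  Tied
events and censorings at the same time follow the standard convention:
events precede censorings, i.e. subjects censored at t remain in the risk
set for deaths at t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import SurvivalCohort

__all__ = ["StepSurvival", "kaplan_meier", "km_by_group", "logrank_test"]


@dataclass(frozen=True)
class StepSurvival:
    """A Kaplan-Meier step curve with risk-set bookkeeping and Greenwood
    log-log confidence band."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def __call__(self, t) -> np.ndarray:
        """Evaluate the right-continuous curve at arbitrary times."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)


def kaplan_meier(times, events) -> StepSurvival:
    """Product-limit estimator over the distinct observed times."""
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    km = KaplanMeierFitter()
    km.fit(times, events)
    table = km.event_table.iloc[1:] if km.event_table.index[0] == 0 else km.event_table
    grid = table.index.to_numpy(dtype=float)
    surv = km.survival_function_at_times(grid).to_numpy()
    ci = km.confidence_interval_
    ci_at = ci.reindex(ci.index.union(grid)).ffill().loc[grid]
    return StepSurvival(
        times=grid,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(),
        events=table["observed"].to_numpy(),
        ci_lower=ci_at.iloc[:, 0].to_numpy(),
        ci_upper=ci_at.iloc[:, 1].to_numpy(),
    )


def km_by_group(cohort: SurvivalCohort, group: str = "pps_group") -> dict[str, StepSurvival]:
    """One Kaplan-Meier curve per stratum of ``group``."""
    out = {}
    for label, g in cohort.data.groupby(group, observed=True):
        out[str(label)] = kaplan_meier(g["time"].to_numpy(), g["event"].to_numpy())
    return out


def logrank_test(cohort: SurvivalCohort, group: str = "pps_group"):
    """Standard (unweighted) k-sample log-rank test.

    Returns ``(chi2, df, p)`` with df = number of groups - 1.
    """
    from lifelines.statistics import multivariate_logrank_test

    labels = cohort.data[group]
    if labels.nunique(dropna=True) < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(cohort.data["time"], labels, cohort.data["event"])
    df = int(labels.nunique(dropna=True) - 1)
    return float(res.test_statistic), df, float(res.p_value)


def export_km_tsv(curves: dict[str, StepSurvival], path) -> None:
    """Write per-group step curves as TSV (group, time, at_risk, events, survival)."""
    rows = []
    for label, c in curves.items():
        for i in range(c.times.size):
            rows.append(
                {
                    "group": label,
                    "time": c.times[i],
                    "at_risk": int(c.at_risk[i]),
                    "events": int(c.events[i]),
                    "survival": c.survival[i],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
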