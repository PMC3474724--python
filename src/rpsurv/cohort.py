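"""Subject-level survival cohort: data model, CSV I/O, preprocessing, summaries.

A cohort is one row per subject: a strictly positive survival time in days
(from hospice admission to death), a binary event indicator (1 = death
observed; the motivating hospice cohort has no censoring, so all 1), the
Palliative Performance Scale (PPS) group at admission, and optional
demographic categoricals.

PPS is an 11-level functional-status scale from 0% (deceased) to 100%
(healthy).  Analysis uses five strata {10, 20, 30, 40, 50-80}: levels 50-80
are pooled because they are sparsely populated in hospice populations, and
10% is the reference level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PPS_STRATA",
    "PPS_REFERENCE",
    "SurvivalCohort",
    "CohortSchemaError",
    "read_cohort",
    "write_cohort",
    "preprocess",
    "summarize",
]

#: The five analysis strata, in increasing functional-status order.
PPS_STRATA: tuple[str, ...] = ("10", "20", "30", "40", "50-80")

#: Reference (baseline) stratum for all regression models.
PPS_REFERENCE: str = "10"

_OPTIONAL_COLS = ("age_group", "gender", "cancer_flag", "diagnosis")


class CohortSchemaError(ValueError):
    """Raised when an input table violates the cohort schema."""


@dataclass(frozen=True)
class SurvivalCohort:
    """Validated subject-level survival data.

    Wraps a DataFrame with columns ``subject_id``, ``time`` (days, > 0),
    ``event`` (0/1), ``pps_group`` (string label or NA) plus any optional
    demographic columns.
    """

    data: pd.DataFrame
    preprocessed: bool = False

    def __post_init__(self) -> None:
        df = self.data
        for col in ("subject_id", "time", "event"):
            if col not in df.columns:
                raise CohortSchemaError(f"required column {col!r} missing")
        if len(df) == 0:
            raise CohortSchemaError("cohort is empty")
        t = df["time"].to_numpy(dtype=float)
        if not np.all(np.isfinite(t)) or np.any(t <= 0):
            bad = df.index[~(np.isfinite(t) & (t > 0))].tolist()
            raise CohortSchemaError(f"non-positive or non-finite time in rows {bad}")
        ev = df["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise CohortSchemaError("event indicator must be 0 or 1")
        if self.preprocessed:
            g = df["pps_group"]
            if g.isna().any():
                raise CohortSchemaError("missing PPS group after preprocessing")
            bad = set(g.unique()) - set(PPS_STRATA)
            if bad:
                raise CohortSchemaError(f"non-analysis PPS labels after preprocessing: {bad}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def pps_group(self) -> pd.Series:
        return self.data["pps_group"]

    def design_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Indicator design for PPS strata with 10% as the reference level.

        Returns ``(X, names)`` where ``X`` has one column per non-reference
        stratum, ordered as in :data:`PPS_STRATA`.
        """
        if not self.preprocessed:
            raise CohortSchemaError("design matrix requires a preprocessed cohort")
        levels = [s for s in PPS_STRATA if s != PPS_REFERENCE]
        g = self.pps_group.to_numpy()
        X = np.column_stack([(g == lev).astype(float) for lev in levels])
        return X, [f"pps_{lev}" for lev in levels]

    def subset(self, index: np.ndarray) -> "SurvivalCohort":
        """Row subset (positional), preserving the preprocessed flag."""
        return SurvivalCohort(self.data.iloc[index].reset_index(drop=True), self.preprocessed)


def _load_mapping(column_map) -> dict:
    if column_map is None:
        return {}
    if isinstance(column_map, Mapping):
        return dict(column_map)
    path = Path(column_map)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text) or {}
    return json.loads(text)


def read_cohort(path, column_map=None) -> SurvivalCohort:
    """Read a cohort from a headered CSV.

    ``column_map`` maps canonical names (``time``, ``event``, ``pps_group``,
    ...) to the file's column names; it may be a dict or a path to a
    YAML/JSON file.  Rows with non-positive time are rejected with a
    row-level report.
    """
    mapping = _load_mapping(column_map)
    df = pd.read_csv(path)
    rename = {v: k for k, v in mapping.items() if v in df.columns}
    df = df.rename(columns=rename)
    for col in ("time", "event"):
        if col not in df.columns:
            raise CohortSchemaError(f"required column {col!r} not found in {path}")
    if "subject_id" not in df.columns:
        df.insert(0, "subject_id", np.arange(1, len(df) + 1))
    time = pd.to_numeric(df["time"], errors="coerce")
    if time.isna().any():
        rows = df.index[time.isna()].tolist()
        raise CohortSchemaError(f"non-numeric time values in rows {rows}")
    df["time"] = time
    bad = df.index[df["time"] <= 0].tolist()
    if bad:
        raise CohortSchemaError(f"non-positive survival time in rows {bad}")
    if "pps_group" in df.columns:
        df["pps_group"] = df["pps_group"].astype("string")
    else:
        df["pps_group"] = pd.Series(pd.NA, index=df.index, dtype="string")
    keep = ["subject_id", "time", "event", "pps_group"] + [
        c for c in _OPTIONAL_COLS if c in df.columns
    ]
    return SurvivalCohort(df[keep].reset_index(drop=True))


def write_cohort(cohort: SurvivalCohort, path) -> None:
    """Write a cohort to CSV (UTF-8, header, comma-separated)."""
    cohort.data.to_csv(path, index=False)


def preprocess(cohort: SurvivalCohort) -> SurvivalCohort:
    """Apply the analysis preprocessing rules.

    PPS levels 50, 60, 70, 80 are pooled into the ``"50-80"`` stratum;
    subjects with missing PPS are dropped (complete-case); the 10% level is
    the recorded reference.  Idempotent.
    """
    df = cohort.data.copy()
    g = df["pps_group"].astype("string")
    pooled = {"50": "50-80", "60": "50-80", "70": "50-80", "80": "50-80"}
    g = g.map(lambda v: pooled.get(v, v), na_action="ignore")
    df["pps_group"] = g
    keep = g.notna()
    if not keep.any():
        raise CohortSchemaError("all subjects have missing PPS; nothing to analyse")
    df = df[keep].reset_index(drop=True)
    unknown = set(df["pps_group"].unique()) - set(PPS_STRATA)
    if unknown:
        raise CohortSchemaError(f"unrecognized PPS levels: {sorted(unknown)}")
    return SurvivalCohort(df, preprocessed=True)


def _median_ci(times: np.ndarray, events: np.ndarray) -> tuple[float, float]:
    """95% CI for the median via the Kaplan-Meier band (Brookmeyer-Crowley style)."""
    from lifelines import KaplanMeierFitter
    from lifelines.utils import median_survival_times

    km = KaplanMeierFitter()
    km.fit(times, events)
    ci = median_survival_times(km.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return lo, hi


def summarize(cohort: SurvivalCohort, by: str | None = None) -> pd.DataFrame:
    """Descriptive survival-time summary, overall or per stratum.

    One row per stratum of ``by`` (or a single ``overall`` row), with n,
    mean (95% normal-theory CI), median (95% CI from the Kaplan-Meier band),
    and range of survival time in days.
    """
    from scipy import stats

    df = cohort.data
    if by is None:
        groups = [("overall", df)]
    else:
        if by not in df.columns:
            raise KeyError(f"unknown stratification variable {by!r}")
        groups = [(str(k), g) for k, g in df.groupby(by, observed=True, dropna=True)]
    rows = []
    for label, g in groups:
        t = g["time"].to_numpy(dtype=float)
        e = g["event"].to_numpy(dtype=int)
        n = t.size
        mean = float(np.mean(t))
        if n > 1:
            half = stats.t.ppf(0.975, n - 1) * np.std(t, ddof=1) / np.sqrt(n)
            mean_lo, mean_hi = mean - half, mean + half
        else:
            mean_lo = mean_hi = mean
        med_lo, med_hi = _median_ci(t, e) if n > 1 else (float(t[0]), float(t[0]))
        rows.append(
            {
                "stratum": label,
                "n": n,
                "mean": mean,
                "mean_lo": mean_lo,
                "mean_hi": mean_hi,
                "median": float(np.median(t)),
                "median_lo": med_lo,
                "median_hi": med_hi,
                "min": float(np.min(t)),
                "max": float(np.max(t)),
            }
        )
    return pd.DataFrame(rows)
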