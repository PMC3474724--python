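"""Prognostic performance: Brier score, scaled Brier, Yates slope, R²_D.

Conventions fixed throughout: at a horizon ``t`` the outcome is
``Y_i = 1`` if subject ``i`` is still alive (``T_i > t``) and ``p_i`` is the
model's predicted probability of surviving beyond ``t``.

* Brier score ``BS = mean((Y_i - p_i)^2)``: 0 is perfect, 0.25 is the
  coin-flip value (every ``p_i = 0.5``).
* Scaled Brier ``= 100 (1 - BS / Brier_max)`` with
  ``Brier_max = mean(p)(1 - mean(p))``: 0-100%, higher better; the best
  *constant* predictor (the event rate) scores 0.
* Discrimination (Yates) slope: ``|mean(p | alive) - mean(p | dead)|``.
* Explained variation ``R²_D`` (Royston-Sauerbrei): rank the prognostic
  index, map ranks to expected-normal-order-statistic scores (Blom), divide
  by ``kappa = sqrt(8/pi)``, refit the survival model with that single
  regressor; its coefficient is the separation statistic ``D`` and
  ``R² = (D²/kappa²) / (sigma² + D²/kappa²)`` with the link-family variance
  ``sigma²`` (pi²/6 for PH and Cox, pi²/3 for proportional odds, 1 for
  probit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "KAPPA",
    "brier",
    "scaled_brier",
    "discrimination_slope",
    "alive_at",
    "performance_curves",
    "rankits",
    "d_statistic",
    "r2_explained_variation",
    "PerformancePanel",
]

#: Rankit scaling constant sqrt(8/pi) of the D-statistic methodology.
KAPPA: float = float(np.sqrt(8.0 / np.pi))

_FAMILY_VARIANCE = {
    "cox": np.pi**2 / 6.0,
    "PH": np.pi**2 / 6.0,
    "PO": np.pi**2 / 3.0,
    "probit": 1.0,
}


def brier(predicted_survival, alive_at_t) -> float:
    """Mean squared difference between survival status and prediction."""
    p = np.asarray(predicted_survival, dtype=float)
    y = np.asarray(alive_at_t, dtype=float)
    if p.shape != y.shape:
        raise ValueError("prediction and outcome vectors must have equal length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    return float(np.mean((y - p) ** 2))


def scaled_brier(predicted_survival, alive_at_t) -> float:
    """100 (1 - BS / Brier_max) with Brier_max = mean(p)(1 - mean(p)), in %."""
    p = np.asarray(predicted_survival, dtype=float)
    pbar = float(np.mean(p))
    bmax = pbar * (1.0 - pbar)
    if bmax <= 0.0:
        raise ValueError("scaled Brier undefined for degenerate mean prediction")
    return float(100.0 * (1.0 - brier(p, alive_at_t) / bmax))


def discrimination_slope(predicted_survival, alive_at_t) -> float:
    """|mean prediction among the alive - mean prediction among the dead|.

    Returns NaN when either outcome group is empty at the horizon.
    """
    p = np.asarray(predicted_survival, dtype=float)
    y = np.asarray(alive_at_t, dtype=bool)
    if p.shape != y.shape:
        raise ValueError("prediction and outcome vectors must have equal length")
    if y.all() or not y.any():
        return float("nan")
    return float(abs(p[y].mean() - p[~y].mean()))


def alive_at(times, events, horizon) -> tuple[np.ndarray, np.ndarray]:
    """Vital status at a horizon: ``(mask, Y)``.

    ``Y_i = 1`` iff ``T_i > horizon``; subjects censored at or before the
    horizon have unknown status and are masked out (the motivating cohort
    has no censoring, so the mask is normally all-True).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    known = (t > horizon) | (e == 1)
    return known, (t > horizon).astype(float)


def performance_curves(pred, times, events, horizons) -> pd.DataFrame:
    """Brier / scaled-Brier / slope curves over a horizon grid.

    ``pred`` is an ``(n_subjects, n_horizons)`` matrix of predicted survival
    probabilities aligned with ``horizons``.  Horizons where a metric is
    undefined (degenerate mean prediction, an empty outcome group) yield
    NaN cells.
    """
    pred = np.asarray(pred, dtype=float)
    horizons = np.asarray(horizons)
    rows = []
    for j, h in enumerate(horizons):
        known, y = alive_at(times, events, h)
        p = pred[known, j]
        yk = y[known]
        bs = brier(p, yk)
        pbar = p.mean()
        sb = 100.0 * (1.0 - bs / (pbar * (1 - pbar))) if 0 < pbar < 1 else np.nan
        rows.append(
            {
                "horizon": h,
                "brier": bs,
                "scaled_brier": sb,
                "slope": discrimination_slope(p, yk),
            }
        )
    return pd.DataFrame(rows)


def rankits(values) -> np.ndarray:
    """Blom normal scores of the ranks, divided by kappa = sqrt(8/pi)."""
    v = np.asarray(values, dtype=float)
    r = stats.rankdata(v)
    z = special.ndtri((r - 0.375) / (v.size + 0.25))
    return z / KAPPA


def d_statistic(prognostic_index, times, events, family: str, m: int = 0) -> float:
    """Separation statistic D: coefficient of the scaled rankits of the
    prognostic index in a refitted survival model of the given family
    ("cox", "PH", "PO" or "probit"; ``m`` sets the spline knots for the
    flexible-parametric families)."""
    pi = np.asarray(prognostic_index, dtype=float)
    if np.ptp(pi) == 0.0:
        return 0.0
    z = rankits(pi)
    frame = pd.DataFrame(
        {
            "subject_id": np.arange(1, pi.size + 1),
            "time": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=int),
            "pps_group": pd.array(["10"] * pi.size, dtype="string"),
            "z": z,
        }
    )
    from .cohort import SurvivalCohort

    cohort = SurvivalCohort(frame, preprocessed=True)
    if family == "cox":
        from .cox import fit_cox

        fit = fit_cox(cohort, design=["z"])
        return float(fit.beta[0])
    from .rp import RPSpec, fit

    rp_fit = fit(cohort, RPSpec(family=family, m=m, covariates=("z",)))
    return float(rp_fit.beta[0])


def r2_from_d(D: float, family: str) -> float:
    sigma2 = _FAMILY_VARIANCE[family]
    dk2 = (D / KAPPA) ** 2
    return dk2 / (sigma2 + dk2)


def r2_explained_variation(
    prognostic_index,
    times,
    events,
    family: str,
    m: int = 0,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float, tuple[float, float]]:
    """Explained variation with a nonparametric bootstrap percentile CI.

    Returns ``(r2, D, (lo, hi))``.  A constant prognostic index gives
    ``D = 0`` and ``r2 = 0`` (not an error).  ``n_boot = 0`` skips the CI
    (NaN bounds).
    """
    if family not in _FAMILY_VARIANCE:
        raise ValueError(f"family must be one of {sorted(_FAMILY_VARIANCE)}")
    pi = np.asarray(prognostic_index, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    D = d_statistic(pi, t, e, family, m=m)
    r2 = r2_from_d(D, family)
    if n_boot <= 0 or np.ptp(pi) == 0.0:
        return r2, D, (float("nan"), float("nan"))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    boots = np.empty(n_boot)
    n = pi.size
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            Db = d_statistic(pi[idx], t[idx], e[idx], family, m=m)
            boots[b] = r2_from_d(Db, family)
        except Exception:
            boots[b] = np.nan
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return r2, D, (float(lo), float(hi))


@dataclass(frozen=True)
class PerformancePanel:
    """Horizon curves plus explained variation for one model on one dataset."""

    curves: pd.DataFrame       # horizon, brier, scaled_brier, slope
    r2: float
    D: float
    r2_ci: tuple[float, float]

    def to_tsv(self, path) -> None:
        self.curves.to_csv(path, sep="\t", index=False)
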