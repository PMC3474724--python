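"""Synthetic hospice-like survival cohorts.

The motivating patient records are not public, so every downstream stage is
exercised on generated cohorts that carry the same statistical structure:
five PPS strata with fixed membership weights, right-skewed integer-day
survival times with short stratum medians (3/5/7/14/18 days, overall about
6), no censoring, and *unequal* log-scale spread across strata so that the
proportional-hazards assumption fails — the regime the comparison between
flexible parametric and Cox models is about.

Within a stratum, survival days are log-normal: ``ln T ~ N(mu_s, sigma_s^2)``
rounded up to whole days.  A log-normal stratum is exactly a probit-link
flexible parametric model with no interior knots, which gives downstream
fits a closed-form oracle.  ``mu_s = ln(median)`` pins each stratum median;
``sigma_s`` values are calibration choices producing maxima from tens to
hundreds of days.

:func:`generate_ph` is a separate oracle generator with exact proportional
hazards (Weibull baseline, inverse-transform sampling) for hazard-ratio
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import PPS_STRATA, SurvivalCohort

__all__ = ["GeneratorConfig", "default_config", "generate", "generate_ph"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the cohort generator.

    ``stratum_weights`` are membership probabilities over the five PPS
    strata; ``stratum_log_mu`` / ``stratum_log_sigma`` the per-stratum
    location/scale of log survival days; ``censor_rate`` the probability of
    administrative censoring (0 by default: the emulated cohort has none),
    drawn uniformly over ``(0, censor_window]`` days when positive.
    ``weibull_shape``/``weibull_scale`` parameterize the proportional-hazards
    oracle baseline of :func:`generate_ph`.
    """

    n: int = 576
    stratum_weights: tuple[float, ...] = (188 / 576, 125 / 576, 123 / 576, 96 / 576, 44 / 576)
    stratum_log_mu: tuple[float, ...] = tuple(np.log((3.0, 5.0, 7.0, 14.0, 18.0)))
    stratum_log_sigma: tuple[float, ...] = (0.8, 1.6, 1.1, 0.9, 0.6)
    censor_rate: float = 0.0
    censor_window: float = 100.0
    discretize: bool = True
    weibull_shape: float = 1.0
    weibull_scale: float = 10.0

    def __post_init__(self) -> None:
        w = np.asarray(self.stratum_weights, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("stratum weights must be non-negative and sum to 1")
        if len(self.stratum_log_mu) != len(w) or len(self.stratum_log_sigma) != len(w):
            raise ValueError("stratum parameter vectors must have equal length")
        if np.any(np.asarray(self.stratum_log_sigma) <= 0):
            raise ValueError("stratum_log_sigma must all be > 0")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must be in [0, 1]")


def default_config(n: int = 576) -> GeneratorConfig:
    """Default hospice-like configuration (five strata, no censoring)."""
    return GeneratorConfig(n=n)


def _cohort_frame(time, event, stratum_labels) -> SurvivalCohort:
    df = pd.DataFrame(
        {
            "subject_id": np.arange(1, len(time) + 1),
            "time": time,
            "event": event,
            "pps_group": pd.array(stratum_labels, dtype="string"),
        }
    )
    return SurvivalCohort(df, preprocessed=True)


def generate(config: GeneratorConfig, seed: int) -> SurvivalCohort:
    """Draw a cohort: stratum categorically, days log-normal, ceiling-rounded.

    Reproducible given ``seed``.  Events are all 1 unless ``censor_rate > 0``,
    in which case an independent uniform administrative censoring time over
    ``(0, censor_window]`` is applied to the selected fraction of subjects.
    """
    if config.n <= 0:
        raise ValueError(f"cohort size must be positive, got {config.n}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    k = len(config.stratum_weights)
    strata = rng.choice(k, size=config.n, p=np.asarray(config.stratum_weights))
    mu = np.asarray(config.stratum_log_mu)[strata]
    sigma = np.asarray(config.stratum_log_sigma)[strata]
    t = np.exp(rng.normal(mu, sigma))
    event = np.ones(config.n, dtype=int)
    if config.censor_rate > 0:
        censored = rng.random(config.n) < config.censor_rate
        c = rng.uniform(0.0, config.censor_window, size=config.n)
        c = np.maximum(c, np.finfo(float).tiny)
        event = np.where(censored & (c < t), 0, 1)
        t = np.where(censored, np.minimum(t, c), t)
    if config.discretize:
        t = np.maximum(np.ceil(t), 1.0)
    labels = np.asarray(PPS_STRATA, dtype=object)[strata]
    return _cohort_frame(t, event, labels)


def generate_ph(config: GeneratorConfig, beta, seed: int, discretize: bool = False) -> SurvivalCohort:
    """Draw a cohort with *exact* proportional hazards.

    Covariates are independent Bernoulli(1/2) indicators, one per element of
    ``beta`` (log hazard ratios).  Times come by inverse transform from a
    Weibull baseline hazard multiplied by ``exp(x . beta)``:

        T = scale * (-ln U / exp(x . beta))^(1/shape)

    Continuous times by default so tie-handling does not blur hazard-ratio
    recovery; ``discretize=True`` applies ceiling rounding.  The first
    covariate doubles as the reported stratum label ("10" vs "20") so the
    cohort passes through PPS-based code paths.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    if config.n <= 0:
        raise ValueError(f"cohort size must be positive, got {config.n}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    X = (rng.random((config.n, beta.size)) < 0.5).astype(float)
    eta = X @ beta
    u = rng.random(config.n)
    t = config.weibull_scale * (-np.log(u) / np.exp(eta)) ** (1.0 / config.weibull_shape)
    if discretize:
        t = np.maximum(np.ceil(t), 1.0)
    labels = np.where(X[:, 0] > 0, "20", "10")
    cohort = _cohort_frame(t, np.ones(config.n, dtype=int), labels)
    df = cohort.data.copy()
    for j in range(X.shape[1]):
        df[f"x{j}"] = X[:, j]
    return SurvivalCohort(df, preprocessed=True)
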