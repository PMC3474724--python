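"""Restricted cubic spline basis on log-time.

The baseline log-time function of a flexible parametric survival model is a
restricted (natural) cubic spline: piecewise cubic between knots, twice
continuously differentiable everywhere, and constrained to be *linear* beyond
the boundary knots.  Interior knots are placed at equally spaced centiles of
the observed log event times (for one interior knot, the 50th centile; for
two, the 33.3rd and 66.7th; and so on), with boundary knots at the minimum
and maximum log event time.

With knots ``k_min < k_1 < ... < k_m < k_max`` the non-constant basis
functions are

    v_1(x) = x
    v_{j+1}(x) = (x - k_j)^3_+ - lam_j (x - k_min)^3_+ - (1 - lam_j)(x - k_max)^3_+

for ``j = 1..m``, where ``lam_j = (k_max - k_j) / (k_max - k_min)`` and
``(u)^3_+ = max(u, 0)^3``.  The full spline is
``s(x) = gamma_0 + sum_j gamma_j v_j(x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KnotSet", "KnotPlacementError", "place_knots", "basis", "basis_derivative"]


class KnotPlacementError(ValueError):
    """Raised when a valid knot set cannot be derived from the data."""


@dataclass(frozen=True)
class KnotSet:
    """Interior and boundary knots on the log-time scale."""

    interior: np.ndarray
    boundary_min: float
    boundary_max: float

    def __post_init__(self) -> None:
        interior = np.atleast_1d(np.asarray(self.interior, dtype=float))
        object.__setattr__(self, "interior", interior)
        if interior.size:
            if np.any(np.diff(interior) <= 0):
                raise KnotPlacementError("interior knots must be strictly increasing")
            if interior[0] <= self.boundary_min or interior[-1] >= self.boundary_max:
                raise KnotPlacementError(
                    "interior knots must lie strictly between the boundary knots"
                )
        if self.boundary_min >= self.boundary_max:
            raise KnotPlacementError("boundary knots must satisfy min < max")

    @property
    def m(self) -> int:
        """Number of interior knots."""
        return int(self.interior.size)

    @property
    def all_knots(self) -> np.ndarray:
        return np.concatenate(([self.boundary_min], self.interior, [self.boundary_max]))


def place_knots(log_times: np.ndarray, m: int) -> KnotSet:
    """Place ``m`` interior knots at equally spaced centiles of log event times.

    Interior knot ``j`` sits at the ``100*j/(m+1)`` centile (empirical
    quantile, linear interpolation) of ``log_times``; boundary knots at the
    minimum and maximum.  Only uncensored (event) log-times should be passed.

    Raises
    ------
    KnotPlacementError
        If ``m < 0``, there are fewer than ``m + 2`` distinct values, or a
        computed interior knot collides with a boundary knot (the fit for
        that ``m`` is infeasible rather than silently perturbed).
    """
    if m < 0:
        raise KnotPlacementError(f"m must be >= 0, got {m}")
    x = np.asarray(log_times, dtype=float)
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise KnotPlacementError("log_times must be non-empty and finite")
    n_distinct = np.unique(x).size
    if n_distinct < m + 2:
        raise KnotPlacementError(
            f"need at least {m + 2} distinct log-times for m={m}, have {n_distinct}"
        )
    lo, hi = float(np.min(x)), float(np.max(x))
    if m == 0:
        return KnotSet(np.empty(0), lo, hi)
    centiles = np.arange(1, m + 1) / (m + 1)
    interior = np.quantile(x, centiles)
    if interior[0] <= lo or interior[-1] >= hi or np.any(np.diff(interior) <= 0):
        raise KnotPlacementError(
            f"centile-based interior knots collide for m={m} on these data "
            f"(heavy ties); this knot count is infeasible"
        )
    return KnotSet(interior, lo, hi)


def basis(x: np.ndarray, knots: KnotSet) -> np.ndarray:
    """Evaluate the non-constant basis functions at ``x``.

    Returns an array of shape ``(len(x), m + 1)``: column 0 is ``x`` itself,
    columns ``1..m`` the restricted cubic terms.  Beyond the boundary knots
    the cubic terms are linear in ``x`` by construction.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.empty((x.size, knots.m + 1))
    out[:, 0] = x
    kmin, kmax = knots.boundary_min, knots.boundary_max
    span = kmax - kmin
    cube = lambda u: np.maximum(u, 0.0) ** 3
    for j, kj in enumerate(knots.interior, start=1):
        lam = (kmax - kj) / span
        out[:, j] = cube(x - kj) - lam * cube(x - kmin) - (1.0 - lam) * cube(x - kmax)
    return out


def basis_derivative(x: np.ndarray, knots: KnotSet) -> np.ndarray:
    """Analytic first derivative of :func:`basis` with respect to ``x``."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.empty((x.size, knots.m + 1))
    out[:, 0] = 1.0
    kmin, kmax = knots.boundary_min, knots.boundary_max
    span = kmax - kmin
    dcube = lambda u: 3.0 * np.maximum(u, 0.0) ** 2
    for j, kj in enumerate(knots.interior, start=1):
        lam = (kmax - kj) / span
        out[:, j] = dcube(x - kj) - lam * dcube(x - kmin) - (1.0 - lam) * dcube(x - kmax)
    return out
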