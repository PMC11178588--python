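"""Mono-exponential time-activity modelling.

Total VOI activities at the imaging time points are fitted with

    A(t) = A(t0) · exp(−ln2 / T_eff · t),

where the effective half-life combines physical decay and biological
clearance, 1/T_eff = 1/T_phys + 1/T_bio.  With exactly two time points
(the clinical situation here: scans at 24 and 48 h only) the fit is exact
interpolation in closed form; with more points an unweighted (optionally
1/σ²-weighted) nonlinear least squares is used.

Time-integrated activity Ã = A(t0)·T_eff/ln2 integrates the fitted
exponential over t ∈ [0, ∞); the uptake phase before the first scan is
thereby approximated as instantaneous (documented limitation).  Integration
from the first scan time is available via ``from_time``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .chain import LN2, Nuclide
from .errors import InvalidInputError, NonDecayingTACError, NonPhysicalKineticsError

__all__ = [
    "TimeActivityPoint",
    "MonoExpFit",
    "HalfLifeDecomposition",
    "fit_monoexp",
    "biological_half_life",
    "time_integrated_activity",
]


@dataclass(frozen=True)
class TimeActivityPoint:
    """One total-VOI activity measurement."""

    time: float  # hours post-injection
    activity: float  # Bq
    sigma: float | None = None  # optional 1-sigma weight, Bq

    def __post_init__(self):
        if self.time < 0:
            raise InvalidInputError("time must be non-negative")
        if self.activity < 0:
            raise InvalidInputError("activity must be non-negative")


@dataclass(frozen=True)
class MonoExpFit:
    """Fitted mono-exponential parameters for one VOI and photopeak."""

    a_t0: float  # Bq, amplitude extrapolated to t = 0
    t_eff: float  # hours
    n_points: int
    residual_norm: float  # Bq; 0 for the exact two-point interpolation

    def __post_init__(self):
        if self.a_t0 <= 0 or self.t_eff <= 0:
            raise InvalidInputError("fit parameters must be positive")

    def activity(self, t):
        """Model prediction A(t) in Bq."""
        return self.a_t0 * np.exp(-LN2 / self.t_eff * np.asarray(t, dtype=float))


@dataclass(frozen=True)
class HalfLifeDecomposition:
    """Effective half-life split into physical and biological components."""

    t_eff: float
    t_phys: float
    t_bio: float
    lambda_bio: float  # h⁻¹
    lambda_phys: float  # h⁻¹


def fit_monoexp(points: list[TimeActivityPoint], weighted: bool = False) -> MonoExpFit:
    """Fit the mono-exponential model to a time-activity curve.

    Two points: closed-form interpolation
    T_eff = (t₂−t₁)·ln2 / ln(A₁/A₂), A(t0) = A₁·2^(t₁/T_eff).
    More points: nonlinear least squares started from the endpoint
    closed form; residuals optionally weighted by 1/σ.

    Raises :class:`NonDecayingTACError` for a two-point curve that does not
    decrease (the effective half-life would be negative) and
    :class:`InvalidInputError` for duplicate times or < 2 usable points.
    """
    pts = sorted(points, key=lambda p: p.time)
    if len(pts) < 2:
        raise InvalidInputError("need at least 2 time-activity points")
    times = np.array([p.time for p in pts])
    acts = np.array([p.activity for p in pts])
    if len(np.unique(times)) != len(times):
        raise InvalidInputError("duplicate measurement times")
    if np.any(acts <= 0):
        raise InvalidInputError("activities must be positive for a log-kinetic fit")

    def _closed_form(t1, a1, t2, a2):
        if a1 <= a2:
            raise NonDecayingTACError(
                f"activity does not decrease ({a1:g} Bq at {t1:g} h vs {a2:g} Bq at {t2:g} h)"
            )
        t_eff = (t2 - t1) * LN2 / math.log(a1 / a2)
        a_t0 = a1 * 2.0 ** (t1 / t_eff)
        return a_t0, t_eff

    if len(pts) == 2:
        a_t0, t_eff = _closed_form(times[0], acts[0], times[1], acts[1])
        return MonoExpFit(a_t0=a_t0, t_eff=t_eff, n_points=2, residual_norm=0.0)

    # log-linear regression supplies the starting point for > 2 points
    slope, intercept = np.polyfit(times, np.log(acts), 1)
    if slope >= 0:
        raise NonDecayingTACError("time-activity curve does not decrease overall")
    a0_init, teff_init = math.exp(intercept), -LN2 / slope
    sigmas = np.array([p.sigma if p.sigma else 1.0 for p in pts]) if weighted else np.ones_like(acts)

    def residuals(theta):
        a_t0, t_eff = theta
        return (a_t0 * np.exp(-LN2 / t_eff * times) - acts) / sigmas

    sol = least_squares(
        residuals,
        x0=[a0_init, teff_init],
        bounds=([1e-300, 1e-300], [np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    a_t0, t_eff = sol.x
    return MonoExpFit(
        a_t0=float(a_t0),
        t_eff=float(t_eff),
        n_points=len(pts),
        residual_norm=float(np.linalg.norm(residuals(sol.x) * sigmas)),
    )


def biological_half_life(t_eff: float, parent: Nuclide) -> HalfLifeDecomposition:
    """Decompose an effective half-life into physical and biological parts.

    λ_bio = λ_eff − λ_phys; requires 0 < T_eff < T_phys, otherwise the
    implied biological clearance is non-positive.
    """
    t_phys = parent.half_life
    if not (0.0 < t_eff < t_phys):
        raise NonPhysicalKineticsError(
            f"T_eff = {t_eff:g} h must lie in (0, T_phys = {t_phys:g} h) for {parent.name}"
        )
    lam_phys = LN2 / t_phys
    lam_bio = LN2 / t_eff - lam_phys
    return HalfLifeDecomposition(
        t_eff=t_eff,
        t_phys=t_phys,
        t_bio=LN2 / lam_bio,
        lambda_bio=lam_bio,
        lambda_phys=lam_phys,
    )


def time_integrated_activity(fit: MonoExpFit, from_time: float = 0.0) -> float:
    """Ã in Bq·h: the fitted exponential integrated from ``from_time`` to ∞.

    Default lower bound 0 extrapolates back to injection (standard MIRD
    self-dose practice when no earlier imaging exists).
    """
    if from_time < 0:
        raise InvalidInputError("integration lower bound must be non-negative")
    return float(fit.activity(from_time)) * fit.t_eff / LN2
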