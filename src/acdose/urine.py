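"""Bateman fitting of urine gamma-counter series.

A 1-ml urine aliquot is counted in the ²¹³Bi window for ≥ 6 h, until the
²¹³Bi already present at collection has decayed and secular equilibrium with
the ²²⁵Ac in the sample is reached.  The measured ²¹³Bi activity is modelled
as the two-member Bateman solution (``chain.bateman_bi_activity``): an
ingrowth term proportional to the ²²⁵Ac activity at collection, A_Ac(0), and
a decay term for the ²¹³Bi activity present at collection, A_Bi(0).  A
bound-constrained nonlinear least squares recovers both amplitudes; their
ratio A_Bi(0)/A_Ac(0) is identifiable even when the counter efficiency is
unknown, because a global scale factors out of the two-amplitude model.

Cohort summaries report the per-epoch mean and population standard deviation
(divide-by-n) of the per-patient ratios, and the mean per-patient ratio
change in percentage points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .chain import DecayChain, bateman_bi_activity, default_chain
from .errors import (
    InsufficientDataError,
    InvalidInputError,
    PairingError,
    UndefinedRatioError,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CountingSeries:
    """Gamma-counter measurements of one urine sample.

    ``times`` are hours since sample collection; ``measured`` is either raw
    counts per bin (``kind='counts'``, Poisson-weighted fit, bin width
    ``bin_width_h``) or pre-calibrated activities in Bq (``kind='activity'``,
    unweighted fit).  ``efficiency`` is counts detected per decay in the
    window; when absent the fit runs on an arbitrary scale and only the
    amplitude ratio is trustworthy.
    """

    sample_id: str
    collection_time: float  # hours post-injection
    times: np.ndarray  # hours since collection, bin start times for counts
    measured: np.ndarray
    kind: str = "activity"  # or "counts"
    bin_width_h: float | None = None
    efficiency: float | None = None
    window_kev: float = 440.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.measured, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "measured", m)
        if t.shape != m.shape:
            raise InvalidInputError("times and measurements must have equal length")
        if np.any(t < 0):
            raise InvalidInputError("times since collection must be non-negative")
        if np.any(np.diff(t) < 0):
            raise InvalidInputError("times must be sorted")
        if self.kind not in ("activity", "counts"):
            raise InvalidInputError(f"unknown measurement kind {self.kind!r}")
        if self.kind == "counts" and not self.bin_width_h:
            raise InvalidInputError("counts series needs a bin width")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class UrineFit:
    """Recovered collection-time activities and diagnostics."""

    a_ac0: float  # Bq (or arbitrary scale when efficiency unknown)
    a_bi0: float
    covariance: np.ndarray  # 2x2, Gauss-Newton approximation
    residual_norm: float
    bi_ac_ratio: float
    absolute_scale_known: bool = True
    at_bound: bool = False


@dataclass(frozen=True)
class RatioSummary:
    """Cohort ²¹³Bi/²²⁵Ac ratio statistics at two collection epochs."""

    patients: tuple[str, ...]
    ratios_epoch1: np.ndarray
    ratios_epoch2: np.ndarray
    mean_epoch1: float
    sd_epoch1: float  # population convention (divide by n)
    mean_epoch2: float
    sd_epoch2: float
    mean_change_points: float  # mean per-patient ratio difference × 100
    sd_change_points: float
    mean_relative_change_percent: float  # alternative convention, also emitted


def _bateman_model(series: CountingSeries, chain: DecayChain):
    """Return f(a_ac0, a_bi0) -> model prediction in the series' units."""
    lam_bi = chain["Bi-213"].decay_constant
    lam_ac = chain["Ac-225"].decay_constant
    eff = series.efficiency if series.efficiency is not None else 1.0

    if series.kind == "counts":
        # expected counts per bin = eff × ∫ A_Bi dt over the bin (Bq·h → decays/3600)
        t0 = series.times
        t1 = series.times + series.bin_width_h

        def integral(lam):
            return (np.exp(-lam * t0) - np.exp(-lam * t1)) / lam

        pref = lam_bi / (lam_bi - lam_ac)

        def predict(a_ac0, a_bi0):
            ingrowth = a_ac0 * pref * (integral(lam_ac) - integral(lam_bi))
            decay = a_bi0 * integral(lam_bi)
            return eff * 3600.0 * (ingrowth + decay)

        return predict

    def predict(a_ac0, a_bi0):
        return eff * bateman_bi_activity(series.times, a_ac0, a_bi0, chain)

    return predict


def fit_urine_series(series: CountingSeries, chain: DecayChain | None = None) -> UrineFit:
    """Bound-constrained least-squares fit of the two-member Bateman model.

    Requires ≥ 5 points spanning ≥ 3 ²¹³Bi half-lives.  Counts are weighted
    by Poisson σ = √counts (floored at 1); activities are unweighted.  A fit
    ending on the non-negativity bound is flagged, not failed.
    """
    chain = chain or default_chain()
    t_half_bi = chain["Bi-213"].half_life
    if len(series.times) < 5:
        raise InsufficientDataError(f"need ≥ 5 points, got {len(series.times)}")
    if series.duration < 3 * t_half_bi:
        raise InsufficientDataError(
            f"series spans {series.duration:.2f} h < 3 Bi-213 half-lives "
            f"({3 * t_half_bi:.2f} h)"
        )
    predict = _bateman_model(series, chain)
    y = series.measured
    sigma = np.sqrt(np.maximum(y, 1.0)) if series.kind == "counts" else np.ones_like(y)

    def residuals(theta):
        return (predict(*theta) - y) / sigma

    # scale-free starting point: late points ≈ equilibrium (∝ A_Ac0), early ≈ A_Bi0
    scale = max(float(np.mean(y)), 1e-12)
    unit = float(np.mean(predict(1.0, 1.0)))
    x0 = np.array([scale / unit, scale / unit])
    sol = least_squares(residuals, x0=x0, bounds=([0.0, 0.0], [np.inf, np.inf]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    a_ac0, a_bi0 = sol.x
    at_bound = bool(np.any(sol.x <= 0.0))
    if at_bound:
        log.warning("%s: fit ended on the non-negativity bound", series.sample_id)

    # Gauss-Newton covariance: (JᵀJ)⁻¹ scaled by residual variance for
    # unweighted fits; for Poisson weights the scaling is already in σ.
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    dof = max(len(y) - 2, 1)
    if series.kind == "activity":
        cov = cov * (2 * sol.cost / dof)

    ratio = a_bi0 / a_ac0 if a_ac0 > 0 else np.inf
    return UrineFit(
        a_ac0=float(a_ac0),
        a_bi0=float(a_bi0),
        covariance=cov,
        residual_norm=float(np.sqrt(2 * sol.cost)),
        bi_ac_ratio=float(ratio),
        absolute_scale_known=series.efficiency is not None or series.kind == "activity",
        at_bound=at_bound,
    )


def bi_ac_ratio_at(fit: UrineFit) -> float:
    """A_Bi(0) / A_Ac(0) at sample collection."""
    if fit.a_ac0 <= 0:
        raise UndefinedRatioError("A_Ac(0) is zero; ratio undefined")
    return fit.a_bi0 / fit.a_ac0


def cohort_ratio_summary(
    fits: dict[str, tuple[UrineFit, UrineFit]]
) -> RatioSummary:
    """Summarize per-patient ratio pairs (epoch 1, epoch 2).

    ``fits`` maps patient id to its (≈24 h, ≈48 h) urine fits.  Standard
    deviations use the population convention (divide by n).  The headline
    change statistic is the mean per-patient ratio difference expressed in
    percentage points; the mean relative change is also emitted.
    """
    if not fits:
        raise PairingError("no patients supplied")
    for patient, pair in fits.items():
        if len(pair) != 2:
            raise PairingError(f"patient {patient!r} does not have exactly two epochs")
    patients = tuple(fits)
    r1 = np.array([bi_ac_ratio_at(fits[p][0]) for p in patients])
    r2 = np.array([bi_ac_ratio_at(fits[p][1]) for p in patients])
    diff = r2 - r1
    return RatioSummary(
        patients=patients,
        ratios_epoch1=r1,
        ratios_epoch2=r2,
        mean_epoch1=float(r1.mean()),
        sd_epoch1=float(r1.std(ddof=0)),
        mean_epoch2=float(r2.mean()),
        sd_epoch2=float(r2.std(ddof=0)),
        mean_change_points=float(diff.mean() * 100.0),
        sd_change_points=float(diff.std(ddof=0) * 100.0),
        mean_relative_change_percent=float((diff / r1).mean() * 100.0),
    )
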