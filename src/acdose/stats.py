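"""Cohort statistics: Pearson correlation and the exact Wilcoxon signed-rank test.

Both statistics are implemented here rather than delegated, because the
small-sample exactness of the signed-rank p-value matters at cohort sizes of
eight kidneys: with eight paired differences all of one sign the exact
two-sided p is 2/2⁸ = 0.0078125, a value a normal approximation does not
reproduce.  Exactness is obtained by enumerating the distribution of the
positive-rank sum over all 2ⁿ sign assignments (via a dynamic-programming
convolution, equivalent to full enumeration); above n = 25 a normal
approximation with continuity correction is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata
from scipy.stats import t as t_dist

from .errors import InvalidInputError

log = logging.getLogger(__name__)

EXACT_N_MAX = 25


@dataclass(frozen=True)
class PairedSample:
    """Two equal-length measurement lists (SUVs, half-lives or doses)."""

    values_a: np.ndarray
    values_b: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)
        if a.shape != b.shape or a.ndim != 1:
            raise InvalidInputError("paired sample needs two equal-length 1D lists")
        if len(a) < 2:
            raise InvalidInputError("need at least 2 pairs")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise InvalidInputError("values must be finite")


def pearson(sample: PairedSample) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p-value.

    p is obtained from the t-transform t = r·√((n−2)/(1−r²)) against the
    t distribution with n−2 degrees of freedom.
    """
    a, b = sample.values_a, sample.values_b
    n = len(a)
    if n < 3:
        raise InvalidInputError("Pearson p-value needs n ≥ 3")
    da, db = a - a.mean(), b - b.mean()
    ssa, ssb = float(da @ da), float(db @ db)
    if ssa == 0.0 or ssb == 0.0:
        raise InvalidInputError("zero variance in one variable")
    r = float(da @ db) / np.sqrt(ssa * ssb)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * t_dist.sf(abs(t), df=n - 2)
    return r, float(min(p, 1.0))


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Exact distribution of the positive-rank sum over all sign assignments.

    ``ranks2`` holds the (mid-)ranks doubled so ties give integers.  Returns
    counts c[w] of assignments with doubled rank-sum w; sum(c) = 2ⁿ.  The
    convolution enumerates the same 2ⁿ outcomes as brute force.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(sample: PairedSample) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (count logged); ties receive mid-ranks.
    For n ≤ 25 the p-value enumerates all 2ⁿ sign assignments exactly:
    p = 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)), capped at 1.  Larger n uses the normal
    approximation with continuity and tie corrections.  Returns (W⁺, p).
    """
    diff = sample.values_a - sample.values_b
    nonzero = diff[diff != 0]
    dropped = len(diff) - len(nonzero)
    if dropped:
        log.info("dropped %d zero difference(s)", dropped)
    if len(nonzero) == 0:
        raise InvalidInputError("all differences are zero")
    ranks = rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    n = len(nonzero)

    if n <= EXACT_N_MAX:
        ranks2 = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_distribution(ranks2)
        total = counts.sum()  # 2^n
        w2 = int(round(2 * w_plus))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return w_plus, float(p)

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction: subtract Σ(t³−t)/48 over tie groups
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= ((tie_counts**3 - tie_counts).sum()) / 48.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return w_plus, float(min(p, 1.0))


def cross_pairs(kidney_values: dict[str, list[float]], lesion_values: dict[str, list[float]]):
    """Every kidney × every lesion within each patient, in sorted-key order.

    Reproduces the "each kidney compared with each lesion" pairing used for
    the kidney-vs-lesion dose comparison (13 pairs for the study cohort
    shape).  Returns (labels, kidney list, lesion list).
    """
    labels, ks, ls = [], [], []
    for patient in sorted(set(kidney_values) & set(lesion_values)):
        for i, k in enumerate(kidney_values[patient]):
            for j, v in enumerate(lesion_values[patient]):
                labels.append(f"{patient}:kidney{i}-lesion{j}")
                ks.append(k)
                ls.append(v)
    return labels, ks, ls
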