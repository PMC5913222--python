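"""Nonparametric two-group inference: Wilcoxon rank-sum and Hodges-Lehmann.

Implements the exact (enumeration) and normal-approximation paths of the
two-sample Wilcoxon rank-sum (Mann-Whitney) test, the Hodges-Lehmann
location-shift estimator with its rank-based confidence interval, and the
median/interquartile summaries used to report group comparisons in the form

    median (IQR) vs median (IQR), location shift (95%CI): s (l to u), p = ...

The statistic reported is the Mann-Whitney U of the second sample
(treatment) against the first (control): the number of (x_i, y_j) pairs
with y_j > x_i, ties counted one half.  The exact null distribution is
built by the standard counting recursion, so exact p-values are available
whenever the pooled data is tie-free and the group sizes are within the
enumeration cap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats

from .io import InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)

# Exact enumeration is used when min(n) <= EXACT_MIN_CAP and max(n) <= EXACT_MAX_CAP
# and the pooled sample is tie-free.
EXACT_MIN_CAP = 10
EXACT_MAX_CAP = 20


# ---------------------------------------------------------------------------
# Exact null distribution of U
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def _u_counts(m: int, n: int) -> tuple[int, ...]:
    """Counts of arrangements with U = 0..m*n for group sizes (m, n).

    Standard recursion on the last pooled rank:
    c(m, n, u) = c(m-1, n, u-n) + c(m, n-1, u); exact integer arithmetic.
    """
    if m == 0 or n == 0:
        return (1,)
    left = _u_counts(m - 1, n)    # length (m-1)*n + 1
    right = _u_counts(m, n - 1)   # length m*(n-1) + 1
    out = []
    for u in range(m * n + 1):
        total = 0
        if 0 <= u - n < len(left):
            total += left[u - n]
        if u < len(right):
            total += right[u]
        out.append(total)
    return tuple(out)


def exact_u_cdf(m: int, n: int) -> np.ndarray:
    """P(U <= u) for u = 0..m*n under the tie-free null."""
    counts = np.array(_u_counts(m, n), dtype=float)
    return np.cumsum(counts) / counts.sum()


# ---------------------------------------------------------------------------
# Rank-sum test
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of y against x (pairs with y > x; ties count 1/2)."""
    greater = (y[:, None] > x[None, :]).sum()
    ties = (y[:, None] == x[None, :]).sum()
    return float(greater) + 0.5 * float(ties)


def _tie_corrected_sigma(pooled: np.ndarray, m: int, n: int) -> float:
    big_n = m + n
    _, t = np.unique(pooled, return_counts=True)
    tie_term = float((t**3 - t).sum())
    var = m * n / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    return math.sqrt(max(var, 0.0))


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    *,
    exact_min_cap: int = EXACT_MIN_CAP,
    exact_max_cap: int = EXACT_MAX_CAP,
) -> tuple[float, float, str]:
    """Two-sample Wilcoxon rank-sum test; returns (U, p, method).

    The exact path enumerates the full null distribution of U (tie-free
    pooled data, group sizes within the caps); otherwise the normal
    approximation with tie-corrected variance and a 0.5 continuity
    correction is used.  Two-sided p doubles the smaller tail, capped at 1.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise InsufficientDataError("rank_sum_test requires non-empty samples")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    m, n = xa.size, ya.size
    u = _u_statistic(xa, ya)
    pooled = np.concatenate([xa, ya])
    if np.unique(pooled).size == 1:
        return u, 1.0, "degenerate"
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (not has_ties) and min(m, n) <= exact_min_cap and max(m, n) <= exact_max_cap
    if has_ties and min(m, n) <= exact_min_cap and max(m, n) <= exact_max_cap:
        logger.info("rank_sum_test: ties present; falling back to normal approximation")
    if use_exact:
        cdf = exact_u_cdf(m, n)
        ui = int(round(u))
        p_le = float(cdf[ui])
        p_ge = float(1.0 - (cdf[ui - 1] if ui > 0 else 0.0))
        method = "exact"
    else:
        mu = m * n / 2.0
        sigma = _tie_corrected_sigma(pooled, m, n)
        if sigma == 0:
            return u, 1.0, "degenerate"
        p_le = float(stats.norm.cdf((u - mu + 0.5) / sigma))
        p_ge = float(stats.norm.sf((u - mu - 0.5) / sigma))
        method = "normal-approximation"
    if alternative == "greater":      # y shifted above x
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_le, p_ge))
    return u, p, method


# ---------------------------------------------------------------------------
# Hodges-Lehmann shift and CI
# ---------------------------------------------------------------------------

def _ci_rank_offset(
    m: int, n: int, alpha: float, exact: bool
) -> int:
    """Largest k with P(U <= k) <= alpha/2 under the null (k may be -1)."""
    if exact:
        cdf = exact_u_cdf(m, n)
        k = int(np.searchsorted(cdf, alpha / 2.0, side="right")) - 1
    else:
        mu = m * n / 2.0
        sigma = math.sqrt(m * n * (m + n + 1) / 12.0)
        # invert Phi((k + 0.5 - mu)/sigma) <= alpha/2
        k = int(math.floor(mu + stats.norm.ppf(alpha / 2.0) * sigma - 0.5))
    return max(-1, min(k, m * n // 2 - 1))


def hodges_lehmann_shift(
    x: Sequence[float],
    y: Sequence[float],
    confidence: float = 0.95,
    *,
    exact_min_cap: int = EXACT_MIN_CAP,
    exact_max_cap: int = EXACT_MAX_CAP,
) -> tuple[float, float, float]:
    """Hodges-Lehmann estimate of the y - x location shift with its CI.

    The estimate is the median of all n_x * n_y pairwise differences
    y_j - x_i; the CI endpoints are order statistics of those differences at
    ranks obtained by inverting the rank-sum null distribution (exact where
    available, else the normal approximation).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size < 2 or ya.size < 2:
        raise InsufficientDataError("hodges_lehmann_shift requires >=2 values per group")
    if not (0.0 < confidence < 1.0):
        raise ValidationError("confidence must be in (0, 1)")
    diffs = np.sort((ya[:, None] - xa[None, :]).ravel())
    estimate = float(np.median(diffs))
    m, n = xa.size, ya.size
    pooled = np.concatenate([xa, ya])
    tie_free = np.unique(pooled).size == pooled.size
    exact = tie_free and min(m, n) <= exact_min_cap and max(m, n) <= exact_max_cap
    k = _ci_rank_offset(m, n, 1.0 - confidence, exact)
    total = diffs.size
    if k < 0:
        lo, hi = float(diffs[0]), float(diffs[-1])
        logger.info("hodges_lehmann_shift: requested confidence unattainable at "
                    "n=(%d, %d); returning the full difference range", m, n)
    else:
        lo = float(diffs[k])           # d_(k+1) in 1-based order statistics
        hi = float(diffs[total - 1 - k])
    return estimate, lo, hi


def group_summary(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, q1, q3) with linear interpolation between order statistics."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise InsufficientDataError("group_summary requires at least one value")
    return (
        float(np.median(vals)),
        float(np.quantile(vals, 0.25)),
        float(np.quantile(vals, 0.75)),
    )


# ---------------------------------------------------------------------------
# Assembled comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    group_a_label: str   # control
    group_b_label: str   # treatment
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    iqr_a: tuple[float, float]
    iqr_b: tuple[float, float]
    hl_shift: float      # treatment - control orientation
    ci_low: float
    ci_high: float
    p_value: float
    method: str

    def format(self) -> str:
        """Render the comparison in the conventional reporting sentence."""
        return (
            f"{self.group_a_label} vs. {self.group_b_label}, median (interquartile): "
            f"{self.median_a:.2f} ({self.iqr_a[0]:.2f}, {self.iqr_a[1]:.2f}) vs. "
            f"{self.median_b:.2f} ({self.iqr_b[0]:.2f}, {self.iqr_b[1]:.2f}), "
            f"location shift (95%CI): {self.hl_shift:.2f} "
            f"({self.ci_low:.2f} to {self.ci_high:.2f}), p = {self.p_value:.3g}"
        )


def compare_groups(
    norm,
    control_label: str | None = None,
    confidence: float = 0.95,
) -> GroupComparison:
    """Assemble a two-group comparison from normalized expression values.

    ``norm`` is a sequence of objects with ``ratio`` and ``group_label``
    attributes (e.g. :class:`refnorm.quantify.NormalizedExpression`), or a
    ``(values, labels)`` pair.  Orientation is treatment minus control.
    """
    if isinstance(norm, tuple) and len(norm) == 2:
        values = np.asarray(norm[0], dtype=float)
        labels = list(norm[1])
    else:
        values = np.array([v.ratio for v in norm], dtype=float)
        labels = [v.group_label for v in norm]
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValidationError(f"expected exactly two groups, found {groups}")
    if control_label is None:
        control_label = groups[0]
        logger.info("compare_groups: control label not given; using %r", control_label)
    if control_label not in groups:
        raise ValidationError(f"control label {control_label!r} not among {groups}")
    treatment_label = next(g for g in groups if g != control_label)
    x = values[[i for i, g in enumerate(labels) if g == control_label]]
    y = values[[i for i, g in enumerate(labels) if g == treatment_label]]
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("each group needs at least 2 values")
    med_a, q1_a, q3_a = group_summary(x)
    med_b, q1_b, q3_b = group_summary(y)
    _, p, method = rank_sum_test(x, y)
    shift, lo, hi = hodges_lehmann_shift(x, y, confidence)
    return GroupComparison(
        group_a_label=control_label,
        group_b_label=treatment_label,
        n_a=int(x.size),
        n_b=int(y.size),
        median_a=med_a,
        median_b=med_b,
        iqr_a=(q1_a, q3_a),
        iqr_b=(q1_b, q3_b),
        hl_shift=shift,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        method=method,
    )
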