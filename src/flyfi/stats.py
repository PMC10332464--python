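"""Inferential toolkit used across the package.

Implements the group-comparison procedures applied to every readout:
standard error of the mean, the two-tailed unpaired (pooled-variance)
Student t-test, one-way ANOVA, and the Newman-Keuls step-down
studentized-range multiple-comparison procedure.

Conventions
-----------
* The t-test is the equal-variance (Student) test by default; Welch's
  correction is available behind ``welch=True``.
* Studentized-range tail probabilities come from
  :data:`scipy.stats.studentized_range` (numerical integration); no
  critical-value tables are embedded.
* ``alpha`` defaults to 0.05 everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ComparisonResult",
    "PairwiseComparison",
    "sem",
    "unpaired_t_test",
    "one_way_anova",
    "newman_keuls",
]


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    df: float | tuple[float, float]
    p_value: float
    significant: bool
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class PairwiseComparison:
    """One row of a Newman-Keuls pairwise table."""

    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    span: int
    q: float
    q_critical: float
    p_value: float
    significant: bool


def sem(values) -> float:
    """Standard error of the mean: sample SD (n-1 denominator) / sqrt(n)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    n = x.size
    if n < 2:
        raise ValueError("SEM undefined for fewer than 2 values")
    return float(np.std(x, ddof=1) / math.sqrt(n))


def unpaired_t_test(a, b, alpha: float = 0.05, welch: bool = False) -> ComparisonResult:
    """Two-tailed unpaired t-test.

    Pooled-variance Student's t by default (``df = n_a + n_b - 2``);
    ``welch=True`` switches to the Welch-Satterthwaite correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs n >= 2")
    diff = float(np.mean(a) - np.mean(b))
    va, vb = float(np.var(a, ddof=1)), float(np.var(b, ddof=1))
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0.0:
            t, df, p = _degenerate_t(diff)
        else:
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            t = diff / math.sqrt(se2)
            p = 2.0 * float(_sps.t.sf(abs(t), df))
    else:
        df = na + nb - 2
        pooled = ((na - 1) * va + (nb - 1) * vb) / df
        se2 = pooled * (1.0 / na + 1.0 / nb)
        if se2 == 0.0:
            t, _, p = _degenerate_t(diff)
        else:
            t = diff / math.sqrt(se2)
            p = 2.0 * float(_sps.t.sf(abs(t), df))
    return ComparisonResult(t, df, p, p < alpha, alpha)


def _degenerate_t(diff: float) -> tuple[float, float, float]:
    # Zero within-group variance: identical groups -> (0, p=1); any mean
    # difference is then infinitely many SEs away.
    if diff == 0.0:
        return 0.0, 0.0, 1.0
    return math.copysign(math.inf, diff), 0.0, 0.0


def one_way_anova(groups, alpha: float = 0.05) -> ComparisonResult:
    """One-way fixed-effects ANOVA.

    Returns F = MS_between / MS_within with df ``(k - 1, N - k)``.  With
    zero between-group variability F = 0 and p = 1 by convention, even
    when the within-group variance is also zero.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    k = len(gs)
    if k < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("each group needs n >= 2")
    n_total = sum(g.size for g in gs)
    grand = sum(float(g.sum()) for g in gs) / n_total
    ss_between = sum(g.size * (float(g.mean()) - grand) ** 2 for g in gs)
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in gs)
    df_b, df_w = k - 1, n_total - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_b == 0.0:
        f, p = 0.0, 1.0
    elif ms_w == 0.0:
        f, p = math.inf, 0.0
    else:
        f = ms_b / ms_w
        p = float(_sps.f.sf(f, df_b, df_w))
    return ComparisonResult(f, (df_b, df_w), p, p < alpha, alpha)


def newman_keuls(groups, alpha: float = 0.05, labels=None) -> list[PairwiseComparison]:
    """Newman-Keuls step-down multiple comparisons after one-way ANOVA.

    Group means are ordered; each pair is tested with the studentized
    range statistic

        q = |mean_i - mean_j| / sqrt(MS_within / 2 * (1/n_i + 1/n_j))

    against the critical value for the stretch of means it spans, at the
    within-group df.  Step-down coherence: a pair enclosed by a stretch
    already found non-significant is declared non-significant without
    being allowed to reach significance on its own.

    Parameters
    ----------
    groups : sequence of 1-D arrays, ``k >= 3`` groups of ``n >= 2``.
    labels : optional group names (defaults ``g1..gk``).

    Returns
    -------
    list of :class:`PairwiseComparison`, one per unordered pair, widest
    stretches first.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    k = len(gs)
    if k < 3:
        raise ValueError("Newman-Keuls needs >= 3 groups; use a t-test for 2")
    if any(g.size < 2 for g in gs):
        raise ValueError("each group needs n >= 2")
    if labels is None:
        labels = [f"g{i + 1}" for i in range(k)]
    labels = list(labels)
    if len(labels) != k:
        raise ValueError("labels length must match number of groups")

    n = np.array([g.size for g in gs])
    means = np.array([g.mean() for g in gs])
    df_w = int(n.sum()) - k
    ms_w = sum(float(((g - g.mean()) ** 2).sum()) for g in gs) / df_w

    order = np.argsort(means, kind="stable")  # ascending means
    blocked: list[tuple[int, int]] = []  # non-significant stretches (sorted idx)
    rows: list[PairwiseComparison] = []
    for span in range(k, 1, -1):
        for lo in range(0, k - span + 1):
            hi = lo + span - 1
            i, j = order[lo], order[hi]
            diff = abs(means[j] - means[i])
            se = math.sqrt(ms_w / 2.0 * (1.0 / n[i] + 1.0 / n[j]))
            if se == 0.0:
                q = 0.0 if diff == 0.0 else math.inf
                p = 1.0 if diff == 0.0 else 0.0
            else:
                q = diff / se
                p = float(_sps.studentized_range.sf(q, span, df_w))
            q_crit = float(_sps.studentized_range.ppf(1.0 - alpha, span, df_w))
            enclosed = any(b_lo <= lo and hi <= b_hi for b_lo, b_hi in blocked)
            sig = (not enclosed) and bool(q > q_crit)
            if not sig:
                blocked.append((lo, hi))
                if enclosed:  # report the protected verdict, not the raw p
                    p = max(p, alpha)
            rows.append(
                PairwiseComparison(
                    group_a=labels[i],
                    group_b=labels[j],
                    mean_a=float(means[i]),
                    mean_b=float(means[j]),
                    span=span,
                    q=float(q),
                    q_critical=q_crit,
                    p_value=min(p, 1.0),
                    significant=sig,
                )
            )
    return rows
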