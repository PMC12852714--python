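"""Rank-based statistical primitives, implemented from first principles.

These are the statistics the whole analysis stands on: midrank assignment,
Spearman correlation with an exact small-sample permutation p-value,
the Mann-Whitney U test (exact by enumeration for small samples, normal
approximation with tie and continuity corrections otherwise), the
Kaplan-Meier product-limit estimator, and the two-group log-rank
(Mantel-Cox) test. Only tail probabilities of reference distributions
(t, normal, chi-square) are delegated to scipy.

Conventions
-----------
* Spearman p two-sided: exact enumeration of all n! rank permutations when
  n <= 9 and both vectors are tie-free; otherwise the t approximation
  t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom. |rho| = 1
  under the t approximation reports the smallest positive float.
* Mann-Whitney U counts pairs with x > y plus half the ties; exact p by
  enumeration of all C(n1+n2, n1) group assignments when n1+n2 <= 12 and
  the pooled sample is tie-free.
* Kaplan-Meier median: smallest event time t with S(t) <= 0.5; subjects
  censored at an event time remain in the risk set at that time.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from typing import Sequence

import numpy as np
from scipy import stats as _dist

from .datatypes import CorrelationResult, KMCurve, SurvivalRecord, TestResult
from .errors import ComputationError, ValidationError

__all__ = [
    "midranks",
    "spearman",
    "mann_whitney_u",
    "km_estimate",
    "logrank_test",
]

EXACT_SPEARMAN_MAX_N = 9
EXACT_MWU_MAX_N = 12


def midranks(x: Sequence[float] | np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties replaced by the average of the tied positions."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValidationError("midranks requires a non-empty 1-D vector")
    if not np.all(np.isfinite(x)):
        raise ValidationError("midranks requires finite values")
    n = x.size
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(n, dtype=float)
    sx = x[order]
    i = 0
    while i < n:
        j = i
        while j < n and sx[j] == sx[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j + 1)  # average of positions i+1..j
        i = j
    return ranks


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0.0:
        raise ComputationError("correlation undefined: zero variance")
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided p by enumerating all n! equally likely rank pairings."""
    n = rx.size
    # rho for a permutation pi of tie-free ranks depends only on sum(rx * ry[pi])
    mean = (n + 1) / 2.0
    ss = float(np.sum((rx - mean) ** 2))
    count = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        rho = float(np.sum((rx - mean) * (ry[list(perm)] - mean))) / ss
        if abs(rho) >= target:
            count += 1
        total += 1
    return count / total


def spearman(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    gene_a: str = "X",
    gene_b: str = "Y",
) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of midranks. The tier field is left
    unset; classification is a separate concern.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 4:
        raise ValidationError(f"spearman requires n >= 4, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("spearman requires finite values")
    rx = midranks(x)
    ry = midranks(y)
    rho = _pearson(rx, ry)
    tie_free = np.unique(x).size == n and np.unique(y).size == n
    if n <= EXACT_SPEARMAN_MAX_N and tie_free:
        p = _exact_spearman_p(rx, ry, rho)
        method = "exact"
    else:
        if abs(rho) >= 1.0:
            p = float(np.finfo(float).tiny)
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(min(1.0, 2.0 * _dist.t.sf(abs(t), df=n - 2)))
        method = "t_approx"
    return CorrelationResult(
        gene_a=gene_a, gene_b=gene_b, rho=rho, p_two_sided=p, n=n, tier=None, method=method
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(ties)


def mann_whitney_u(
    x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray
) -> TestResult:
    """Mann-Whitney U test, two-sided.

    U counts pairs (x_i, y_j) with x_i > y_j, ties contributing 1/2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("mann_whitney_u requires non-empty samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("mann_whitney_u requires finite values")
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    mu = n1 * n2 / 2.0
    if n1 + n2 <= EXACT_MWU_MAX_N and tie_free:
        # enumerate group assignments over pooled ranks; U = R1 - n1(n1+1)/2
        ranks = midranks(pooled)
        dev = abs(u - mu) - 1e-12
        count = 0
        total = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u_perm = float(sum(ranks[i] for i in combo)) - n1 * (n1 + 1) / 2.0
            if abs(u_perm - mu) >= dev:
                count += 1
            total += 1
        return TestResult(
            statistic=u, p_two_sided=count / total, n1=n1, n2=n2, method="exact"
        )
    # normal approximation with tie and continuity corrections
    n = n1 + n2
    tie_counts = np.array(list(Counter(pooled.tolist()).values()), dtype=float)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return TestResult(statistic=u, p_two_sided=1.0, n1=n1, n2=n2, method="normal_approx")
    diff = u - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(sigma2) if diff != 0 else 0.0
    p = float(min(1.0, 2.0 * _dist.norm.sf(abs(z))))
    return TestResult(statistic=u, p_two_sided=p, n1=n1, n2=n2, method="normal_approx")


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimate for a single group of records."""
    if not records:
        raise ValidationError("km_estimate requires at least one record")
    times = np.array([r.time_days for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    event_times = np.unique(times[events])
    s = 1.0
    surv, at_risk, median = [], [], None
    for t in event_times:
        n_risk = int(np.sum(times >= t))
        d = int(np.sum(events & (times == t)))
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
        if median is None and s <= 0.5 + 1e-12:
            median = float(t)
    return KMCurve(
        times=tuple(float(t) for t in event_times),
        survival=tuple(surv),
        at_risk=tuple(at_risk),
        median=median,
    )


def logrank_test(records: Sequence[SurvivalRecord]) -> TestResult:
    """Two-group log-rank (Mantel-Cox) chi-square test on 1 df.

    Statistic = (sum(O1 - E1))^2 / sum(V) over distinct event times, with
    the hypergeometric variance at each time; p from the chi-square upper
    tail.
    """
    groups = sorted({r.group for r in records})
    if len(groups) != 2:
        raise ValidationError(f"logrank_test requires exactly two groups, got {groups}")
    g1, g2 = groups
    times = np.array([r.time_days for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    in_g1 = np.array([r.group == g1 for r in records], dtype=bool)
    if not events.any():
        raise ValidationError("logrank_test requires at least one event")
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in_g1).sum())
        dead = events & (times == t)
        d = int(dead.sum())
        d1 = int((dead & in_g1).sum())
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0.0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = o_minus_e**2 / var
        p = float(_dist.chi2.sf(chi2, df=1))
    n1_tot = int(in_g1.sum())
    return TestResult(
        statistic=float(chi2),
        p_two_sided=p,
        n1=n1_tot,
        n2=len(records) - n1_tot,
        method="chi_square",
    )
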