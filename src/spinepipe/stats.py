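"""Distribution and group-comparison statistics.

Implements the reporting conventions used throughout the pipeline: empirical
CDFs, the two-sample Kolmogorov–Smirnov test reported as the triple
(D, ks, p) where ``ks = D * sqrt(n1*n2/(n1+n2))`` is the sample-size-scaled
statistic, a compartment-stratified variant of the KS test for spine-shape
distributions split at a ratio threshold, the pooled-variance unpaired
Student's t-test, and the coefficient of variation.

Reported KS p-values are floored at ``P_FLOOR`` (1e-6); the raw value is kept
on the result object for programmatic use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _sps

P_FLOOR = 1e-6

#: largest n1*n2 for which exact permutation enumeration is permitted
EXACT_LIMIT = 10_000


@dataclass(frozen=True)
class EcdfCurve:
    """Right-continuous empirical CDF: step up at each sorted value."""

    values: np.ndarray      # sorted, ascending
    fractions: np.ndarray   # cumulative fractions, ends at 1.0

    def __call__(self, x: float) -> float:
        """Evaluate F(x); 0 below the smallest value."""
        idx = np.searchsorted(self.values, x, side="right")
        return 0.0 if idx == 0 else float(self.fractions[idx - 1])


@dataclass(frozen=True)
class KsResult:
    """Two-sample KS result in the (D, ks, p) reporting convention."""

    D: float
    ks_scaled: float
    p: float            # reported p, floored at P_FLOOR
    p_raw: float        # unfloored p
    n1: int
    n2: int
    method: Literal["exact", "asymptotic"]


@dataclass(frozen=True)
class TTestResult:
    mean1: float
    mean2: float
    t: float
    df: int
    p: float


def ecdf(values: Sequence[float]) -> EcdfCurve:
    """Empirical CDF of a nonempty sample."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("ecdf requires a nonempty sample")
    srt = np.sort(arr)
    frac = np.arange(1, srt.size + 1) / srt.size
    # collapse ties so the curve steps once per distinct value
    uniq, last_idx = np.unique(srt, return_index=True)
    # index of last occurrence of each distinct value
    last = np.r_[last_idx[1:] - 1, srt.size - 1]
    return EcdfCurve(values=uniq, fractions=frac[last])


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Max absolute ECDF deviation over the pooled sample points."""
    a = np.sort(a)
    b = np.sort(b)
    pooled = np.concatenate([a, b])
    fa = np.searchsorted(a, pooled, side="right") / a.size
    fb = np.searchsorted(b, pooled, side="right") / b.size
    return float(np.max(np.abs(fa - fb)))


def scale_ks(D: float, n1: int, n2: int) -> float:
    """Effective-sample-size scaling: D * sqrt(n1*n2/(n1+n2))."""
    return D * math.sqrt(n1 * n2 / (n1 + n2))


def kolmogorov_sf(lam: float, tol: float = 1e-12) -> float:
    """Asymptotic Kolmogorov survival function Q(λ) = 2 Σ (−1)^{k−1} e^{−2k²λ²}.

    The alternating series is truncated once a term drops below ``tol``.
    """
    if lam <= 0:
        return 1.0
    total = 0.0
    for k in range(1, 101):
        term = math.exp(-2.0 * k * k * lam * lam)
        total += (-term if k % 2 == 0 else term)
        if term < tol:
            break
    return float(min(1.0, max(0.0, 2.0 * total)))


def _exact_ks_pvalue(a: np.ndarray, b: np.ndarray, observed_d: float) -> float:
    """Exact permutation p: tail probability of D over all label assignments.

    Counts the C(n1+n2, n1) equally likely splits of the pooled sample whose
    D reaches the observed one. Rather than enumerating splits, monotone
    lattice paths (i, j) = (#a used, #b used) through the pooled sorted
    values are counted by dynamic programming; the ECDF deviation
    |i/n1 - j/n2| is evaluated only at the ends of blocks of tied values,
    which reproduces plain enumeration exactly (ties included). Complexity
    O(n1 * n_blocks) instead of the binomial blow-up.
    """
    n1, n2 = a.size, b.size
    pooled = np.sort(np.concatenate([a, b]))
    # blocks of tied values: the deviation is only observable at block ends
    _, block_starts = np.unique(pooled, return_index=True)
    block_sizes = np.diff(np.r_[block_starts, pooled.size])
    eps = 1e-12
    limit = observed_d - eps

    # paths[i] = number of ways to reach i a-values used after the current
    # block, restricted to paths whose deviation stayed below the observed D
    paths = np.zeros(n1 + 1)
    paths[0] = 1.0
    used = 0
    from math import comb

    for m in block_sizes:
        m = int(m)
        new = np.zeros(n1 + 1)
        weights = [comb(m, k) for k in range(m + 1)]
        for i in np.nonzero(paths)[0]:
            for k in range(m + 1):
                ni = i + k
                if ni > n1:
                    break
                new[ni] += paths[i] * weights[k]
        used += m
        # prune states whose deviation at this block end reaches D
        for ni in range(n1 + 1):
            nj = used - ni
            if nj < 0 or nj > n2:
                new[ni] = 0.0
            elif abs(ni / n1 - nj / n2) >= limit:
                new[ni] = 0.0
        paths = new
    total = comb(n1 + n2, n1)
    surviving = paths[n1]
    return float(max(0.0, min(1.0, 1.0 - surviving / total)))


def ks_two_sample(
    a: Sequence[float],
    b: Sequence[float],
    method: Literal["exact", "asymptotic"] = "asymptotic",
) -> KsResult:
    """Two-sample KS test reported as (D, ks, p).

    ``method="exact"`` enumerates the full permutation distribution of D and
    is permitted only for n1*n2 <= EXACT_LIMIT; ``"asymptotic"`` evaluates
    the Kolmogorov distribution at the scaled statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_two_sample requires two nonempty samples")
    d = _ks_statistic(a, b)
    lam = scale_ks(d, a.size, b.size)
    if method == "exact":
        if a.size * b.size > EXACT_LIMIT:
            raise ValueError(
                f"exact method limited to n1*n2 <= {EXACT_LIMIT}; "
                f"got {a.size * b.size}"
            )
        p_raw = _exact_ks_pvalue(a, b, d)
    elif method == "asymptotic":
        p_raw = kolmogorov_sf(lam)
    else:
        raise ValueError(f"unknown method {method!r}")
    return KsResult(
        D=d,
        ks_scaled=lam,
        p=max(p_raw, P_FLOOR),
        p_raw=p_raw,
        n1=int(a.size),
        n2=int(b.size),
        method=method,
    )


def stratified_ks(
    a: Sequence[float],
    b: Sequence[float],
    threshold: float = 2.0,
    side: Literal["below", "above"] = "below",
    method: Literal["exact", "asymptotic"] = "asymptotic",
    boundary_to: Literal["below", "above"] = "below",
) -> KsResult:
    """KS test restricted to one compartment of both samples.

    ``side="below"`` compares the subsets with value < threshold,
    ``side="above"`` the subsets with value > threshold. Values exactly equal
    to the threshold join the ``boundary_to`` stratum (default below).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if side not in ("below", "above"):
        raise ValueError(f"unknown side {side!r}")
    if side == "below":
        keep_eq = boundary_to == "below"
        sub_a = a[(a < threshold) | (keep_eq & (a == threshold))]
        sub_b = b[(b < threshold) | (keep_eq & (b == threshold))]
    else:
        keep_eq = boundary_to == "above"
        sub_a = a[(a > threshold) | (keep_eq & (a == threshold))]
        sub_b = b[(b > threshold) | (keep_eq & (b == threshold))]
    for name, sub in (("a", sub_a), ("b", sub_b)):
        if sub.size == 0:
            raise ValueError(
                f"stratum '{side} {threshold}' of sample {name} is empty"
            )
    return ks_two_sample(sub_a, sub_b, method=method)


def t_test_two_sample(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Unpaired Student's t-test (pooled variance, two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test requires at least 2 observations per group")
    pooled_var = ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled_var == 0:
        raise ZeroDivisionError("zero pooled variance: t statistic undefined")
    res = _sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(
        mean1=float(a.mean()),
        mean2=float(b.mean()),
        t=float(res.statistic),
        df=int(a.size + b.size - 2),
        p=float(res.pvalue),
    )


def coefficient_of_variation(values: Sequence[float]) -> float:
    """CV in percent: 100 * sample sd / mean (n−1 denominator)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV requires at least 2 observations")
    mean = arr.mean()
    if mean == 0:
        raise ZeroDivisionError("CV undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)
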