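"""Statistical kernel for the sleep-stage comparisons.

Implements the test battery used throughout the ROI-based and channel-wise
analyses: two-sample t tests (Welch or pooled, from raw samples or printed
summary statistics), one-sample and paired location tests, pooled Cohen's d
with stratified percentile-bootstrap confidence intervals, label-permutation
and sign-flip resampling p values, Benjamini-Hochberg FDR adjustment, and the
1.5*IQR outlier rule applied within each sleep-stage group.

Parametric machinery is delegated to scipy/statsmodels; the resampling
procedures and their exhaustive small-sample fallbacks are implemented here
because their exact conventions (identity permutation included, two-sided on
the absolute statistic, stratified resampling) define the reported numbers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("nirsleep")

__all__ = [
    "StatsParams",
    "SummaryStats",
    "TestResult",
    "ZeroVarianceError",
    "two_sample_t",
    "cohens_d_pooled",
    "location_test",
    "bh_fdr",
    "iqr_filter",
    "permutation_test",
    "sign_flip_test",
    "bootstrap_d_ci",
    "compare_groups",
    "assumption_checks",
]


class ZeroVarianceError(ValueError):
    """Raised when a test statistic is undefined because all spread is zero."""


class SummaryStats(NamedTuple):
    """Printed summary of one group: mean, standard deviation, group size."""

    mean: float
    sd: float
    n: int


@dataclass
class StatsParams:
    """Configuration of the resampling and filtering procedures.

    alpha            significance level for adjusted p values
    n_permutations   label permutations (exhaustive enumeration is used
                     instead whenever the total number of distinct
                     relabelings does not exceed this budget)
    n_bootstrap      bootstrap resamples for effect-size CIs
    ci_level         bootstrap confidence level (fraction)
    iqr_multiplier   fence multiplier of the IQR outlier rule
    rng_seed         seed for Monte-Carlo permutations and bootstrap
    """

    alpha: float = 0.05
    n_permutations: int = 5000
    n_bootstrap: int = 5000
    ci_level: float = 0.95
    iqr_multiplier: float = 1.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 1 or self.n_bootstrap < 1:
            raise ValueError("resample counts must be >= 1")


@dataclass
class TestResult:
    """One comparison: statistic, p values, effect size and bootstrap CI."""

    statistic: float
    df: float
    p_parametric: float
    variant: Literal["welch", "pooled", "one_sample", "paired"]
    n_per_group: tuple[int, ...]
    p_permutation: float | None = None
    effect_size_d: float | None = None
    d_ci: tuple[float, float] | None = None
    extra: dict = field(default_factory=dict)


def _as_summary(x) -> SummaryStats:
    if isinstance(x, SummaryStats):
        return x
    a = np.asarray(x, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise ValueError("need at least two observations per group")
    return SummaryStats(float(a.mean()), float(a.std(ddof=1)), int(a.size))


def two_sample_t(group_a, group_b, variant: str = "welch") -> TestResult:
    """Independent two-sample t test from samples or (mean, sd, n) summaries.

    ``welch`` uses unpooled standard errors with Welch-Satterthwaite degrees
    of freedom; ``pooled`` uses the classical pooled-variance statistic with
    df = n1 + n2 - 2. Two-tailed p value in both cases.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown variant {variant!r}")
    sa, sb = _as_summary(group_a), _as_summary(group_b)
    if sa.sd == 0 and sb.sd == 0:
        if sa.mean == sb.mean:
            raise ZeroVarianceError("both groups constant and equal")
        # constant groups with different means: infinitely strong evidence
        t = math.inf if sa.mean > sb.mean else -math.inf
        return TestResult(t, float(sa.n + sb.n - 2), 0.0, variant, (sa.n, sb.n))
    t, p = sps.ttest_ind_from_stats(
        sa.mean, sa.sd, sa.n, sb.mean, sb.sd, sb.n,
        equal_var=(variant == "pooled"),
    )
    if variant == "pooled":
        df = float(sa.n + sb.n - 2)
    else:
        va, vb = sa.sd**2 / sa.n, sb.sd**2 / sb.n
        df = (va + vb) ** 2 / (va**2 / (sa.n - 1) + vb**2 / (sb.n - 1))
    return TestResult(float(t), float(df), float(p), variant, (sa.n, sb.n))


def cohens_d_pooled(group_a, group_b) -> float:
    """Cohen's d with the (n-1)-weighted pooled standard deviation."""
    sa, sb = _as_summary(group_a), _as_summary(group_b)
    pooled_var = ((sa.n - 1) * sa.sd**2 + (sb.n - 1) * sb.sd**2) / (sa.n + sb.n - 2)
    if pooled_var == 0:
        raise ZeroVarianceError("pooled standard deviation is zero")
    return (sa.mean - sb.mean) / math.sqrt(pooled_var)


def location_test(x, y=None, mode: str = "one_sample") -> TestResult:
    """One-sample (mean vs 0) or paired t test, two-tailed."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two observations")
    if mode == "one_sample":
        if x.std(ddof=1) == 0:
            raise ZeroVarianceError("one-sample test undefined for constant data")
        t, p = sps.ttest_1samp(x, 0.0)
        n = (x.size,)
    elif mode == "paired":
        y = np.asarray(y, dtype=float)
        if y.shape != x.shape:
            raise ValueError("paired samples must have equal length")
        d = x - y
        if d.std(ddof=1) == 0:
            raise ZeroVarianceError("paired differences have zero variance")
        t, p = sps.ttest_rel(x, y)
        n = (x.size,)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(float(t), float(x.size - 1), float(p), mode, n)


def bh_fdr(p_values: Sequence[float], alpha: float = 0.05):
    """Benjamini-Hochberg step-up adjustment across one test family.

    Returns (adjusted p values, boolean significance array) where a test is
    significant iff its adjusted p is strictly below ``alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, p_adj < alpha


def iqr_filter(x, k: float = 1.5):
    """Drop values outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation between order statistics (the numpy
    default), which sets the fences and is therefore part of the contract.
    Returns (retained values, boolean keep mask).
    """
    x = np.asarray(x, dtype=float)
    q1, q3 = np.quantile(x, [0.25, 0.75])
    iqr = q3 - q1
    keep = (x >= q1 - k * iqr) & (x <= q3 + k * iqr)
    return x[keep], keep


def _stat_mean_diff(a: np.ndarray, b: np.ndarray, axis=-1):
    return a.mean(axis=axis) - b.mean(axis=axis)


def _stat_welch_t(a: np.ndarray, b: np.ndarray, axis=-1):
    na, nb = a.shape[axis], b.shape[axis]
    se = np.sqrt(a.var(axis=axis, ddof=1) / na + b.var(axis=axis, ddof=1) / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (a.mean(axis=axis) - b.mean(axis=axis)) / se


_PERM_STATS = {"mean_diff": _stat_mean_diff, "t": _stat_welch_t}


def permutation_test(
    group_a, group_b, stat: str = "mean_diff", params: StatsParams | None = None
) -> float:
    """Two-sided label-permutation p value for a two-group comparison.

    Counts the proportion of relabelings (identity included) whose absolute
    statistic reaches the observed one. All C(n, n_a) distinct assignments
    are enumerated when that count fits within the permutation budget;
    otherwise a seeded Monte-Carlo sample is drawn and the observed labeling
    is included in the numerator and denominator.
    """
    params = params or StatsParams()
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    fn = _PERM_STATS[stat]
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    observed = abs(fn(a, b))
    tol = 1e-12 * (1.0 + observed)
    n_exact = math.comb(n, na)
    if n_exact <= params.n_permutations:
        count = 0
        idx_all = frozenset(range(n))
        for idx in combinations(range(n), na):
            sel = np.array(idx)
            rest = np.array(sorted(idx_all - set(idx)), dtype=int)
            if abs(fn(pooled[sel], pooled[rest])) >= observed - tol:
                count += 1
        return count / n_exact
    rng = np.random.default_rng(params.rng_seed)
    B = params.n_permutations
    perm = np.tile(pooled, (B, 1))
    perm = rng.permuted(perm, axis=1)
    stat_b = np.abs(fn(perm[:, :na], perm[:, na:], axis=1))
    return (1 + int(np.sum(stat_b >= observed - tol))) / (1 + B)


def sign_flip_test(x, params: StatsParams | None = None) -> float:
    """One-sample analogue of the permutation test via sign flipping.

    Two-sided p = proportion of sign patterns whose |mean| reaches the
    observed |mean|; exhaustive over the 2^n patterns when affordable.
    """
    params = params or StatsParams()
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("sample must be nonempty")
    observed = abs(x.mean())
    tol = 1e-12 * (1.0 + observed)
    n = x.size
    if 2**n <= params.n_permutations:
        # all sign patterns via the bits of 0 .. 2^n - 1
        bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        signs = 2 * bits - 1
        means = np.abs((signs * x).mean(axis=1))
        return float(np.mean(means >= observed - tol))
    rng = np.random.default_rng(params.rng_seed)
    signs = rng.choice([-1.0, 1.0], size=(params.n_permutations, n))
    means = np.abs((signs * x).mean(axis=1))
    return (1 + int(np.sum(means >= observed - tol))) / (1 + params.n_permutations)


def bootstrap_d_ci(group_a, group_b, params: StatsParams | None = None):
    """Percentile bootstrap CI for pooled Cohen's d, stratified by group.

    Resamples within each group independently; resamples whose pooled SD is
    zero are redrawn (and logged) so d stays defined. Deterministic for a
    given ``params.rng_seed``.
    """
    params = params or StatsParams()
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need n >= 2 per group")
    rng = np.random.default_rng(params.rng_seed)
    B = params.n_bootstrap

    def draw(n_draws):
        ra = a[rng.integers(0, na, size=(n_draws, na))]
        rb = b[rng.integers(0, nb, size=(n_draws, nb))]
        va = ra.var(axis=1, ddof=1)
        vb = rb.var(axis=1, ddof=1)
        pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        return ra.mean(axis=1), rb.mean(axis=1), pooled

    ma, mb, pooled = draw(B)
    bad = pooled == 0
    tries = 0
    while bad.any() and tries < 100:
        logger.debug("redrawing %d degenerate bootstrap resamples", int(bad.sum()))
        ma2, mb2, p2 = draw(int(bad.sum()))
        ma[bad], mb[bad], pooled[bad] = ma2, mb2, p2
        bad = pooled == 0
        tries += 1
    d = (ma - mb) / np.sqrt(pooled)
    lo = (1 - params.ci_level) / 2
    low, high = np.quantile(d, [lo, 1 - lo])
    return float(low), float(high)


def compare_groups(
    group_a,
    group_b,
    params: StatsParams | None = None,
    variant: str = "welch",
    perm_stat: str = "mean_diff",
) -> TestResult:
    """Full two-group comparison: t, p, permutation p, d and bootstrap CI."""
    params = params or StatsParams()
    res = two_sample_t(group_a, group_b, variant=variant)
    res.effect_size_d = cohens_d_pooled(group_a, group_b)
    res.p_permutation = permutation_test(group_a, group_b, stat=perm_stat, params=params)
    res.d_ci = bootstrap_d_ci(group_a, group_b, params=params)
    return res


def assumption_checks(group_a, group_b=None) -> dict:
    """Shapiro-Wilk normality (per group) and Levene variance screening.

    The results are logged for reporting only; they never gate the parametric
    tests automatically.
    """
    out: dict = {}
    a = np.asarray(group_a, dtype=float)
    out["shapiro_a"] = tuple(map(float, sps.shapiro(a))) if a.size >= 3 else None
    if group_b is not None:
        b = np.asarray(group_b, dtype=float)
        out["shapiro_b"] = tuple(map(float, sps.shapiro(b))) if b.size >= 3 else None
        out["levene"] = tuple(map(float, sps.levene(a, b)))
    logger.info("assumption checks: %s", out)
    return out
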