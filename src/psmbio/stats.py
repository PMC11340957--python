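"""Normality-driven two-group comparison, correlation CIs, categorical
tests and ROC analysis.

Test selection mirrors common clinical-imaging practice: Shapiro-Wilk
normality screening at alpha = 0.05 per group, Welch's t when both groups
pass, Mann-Whitney U (asymptotic, tie-corrected) otherwise; Pearson
chi-squared for categorical tables with adequate expected counts, Fisher's
exact test for sparse 2x2 tables. Pearson correlations carry Fisher-z 95%
confidence intervals. All tests are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "CorrelationResult",
    "compare_groups",
    "pearson_ci",
    "categorical_test",
    "roc_auc",
]

NORMALITY_ALPHA = 0.05


@dataclass
class ComparisonResult:
    """One two-group comparison cell: means, the test chosen, and p."""

    variable: str
    group_labels: tuple[str, str]
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    test_used: str  # "welch_t" | "mann_whitney"
    statistic: float
    p: float
    normality_p: tuple[float, float]
    n_dropped: int = 0
    #: sensitivity: p from the test NOT selected, and whether the
    #: significance call at 0.05 flips between the two
    p_other: Optional[float] = None
    decision_flips: Optional[bool] = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class CorrelationResult:
    """One Pearson correlation cell with Fisher-z 95% CI."""

    pair: tuple[str, str]
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    level: float = 0.95
    warnings: list[str] = field(default_factory=list)


def _clean(values) -> tuple[np.ndarray, int]:
    arr = np.asarray(values, dtype=np.float64).ravel()
    finite = np.isfinite(arr)
    return arr[finite], int((~finite).sum())


def compare_groups(
    values_a,
    values_b,
    variable: str = "",
    group_labels: tuple[str, str] = ("A", "B"),
    normality_alpha: float = NORMALITY_ALPHA,
    sensitivity: bool = True,
    test: str = "auto",
) -> ComparisonResult:
    """Two-group comparison with Shapiro-Wilk-driven test selection.

    With ``test="auto"`` (default): both groups normal at
    ``normality_alpha`` -> Welch's t; otherwise Mann-Whitney U (exact for
    small tie-free samples, tie-corrected normal approximation elsewhere).
    ``test="welch_t"`` / ``"mann_whitney"`` force one branch; the normality
    screen is still reported. Means +/- SD (ddof=1) are always reported
    regardless of the test used. Missing values are dropped per group and
    counted in ``n_dropped``.
    """
    if test not in ("auto", "welch_t", "mann_whitney"):
        raise ValueError(f"unknown test {test!r}")
    a, dropped_a = _clean(values_a)
    b, dropped_b = _clean(values_b)
    if a.size < 3 or b.size < 3:
        raise ValueError(
            f"each group needs >= 3 finite values (got {a.size} and {b.size})"
        )
    warns: list[str] = []

    constant_a = np.ptp(a) == 0
    constant_b = np.ptp(b) == 0
    if constant_a or constant_b:
        # Shapiro is undefined on a constant sample; a constant group can
        # never look normal, so fall through to the rank test.
        sw_a = sw_b = 0.0
        warns.append(
            "constant group: Mann-Whitney used; asymptotic p is inexact here"
        )
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw_a = float(sps.shapiro(a).pvalue)
            sw_b = float(sps.shapiro(b).pvalue)

    both_normal = sw_a > normality_alpha and sw_b > normality_alpha

    def _welch() -> tuple[float, float]:
        with warnings.catch_warnings():
            # constant groups trip scipy's precision-loss warning in the
            # sensitivity branch; the chosen test is the rank test there
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sps.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)

    def _mwu() -> tuple[float, float]:
        # small samples: exact enumeration of the permutation distribution
        # (valid with ties, unlike the classical exact U tables); otherwise
        # the tie-corrected normal approximation
        from math import comb

        if comb(a.size + b.size, a.size) <= 100_000:
            method = sps.PermutationMethod(n_resamples=100_000, rng=0)
        else:
            method = "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)

    if test != "auto":
        both_normal = test == "welch_t"
    if both_normal:
        test_used = "welch_t"
        statistic, p = _welch()
        p_other = _mwu()[1] if sensitivity else None
    else:
        test_used = "mann_whitney"
        statistic, p = _mwu()
        p_other = _welch()[1] if sensitivity else None

    flips = None
    if p_other is not None:
        flips = (p < 0.05) != (p_other < 0.05)

    return ComparisonResult(
        variable=variable,
        group_labels=group_labels,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=int(b.size),
        test_used=test_used,
        statistic=statistic,
        p=p,
        normality_p=(sw_a, sw_b),
        n_dropped=dropped_a + dropped_b,
        p_other=p_other,
        decision_flips=flips,
        warnings=warns,
    )


def pearson_ci(
    x,
    y,
    level: float = 0.95,
    pair: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Sample Pearson r with Fisher-z confidence interval.

    CI: ``tanh(atanh(r) +/- z_{1-alpha/2} / sqrt(n - 3))``; p-value from
    ``t = r sqrt((n - 2) / (1 - r^2))`` on n - 2 degrees of freedom.
    Complete cases only; |r| = 1 is clamped inside atanh with a warning.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 4:
        raise ValueError(f"need >= 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")

    r = float(sps.pearsonr(x, y).statistic)
    warns: list[str] = []
    r_for_z = r
    if abs(r) >= 1.0 - 1e-15:
        warns.append("|r| = 1: Fisher z clamped, CI degenerate")
        r_for_z = float(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    zcrit = float(sps.norm.ppf(0.5 + level / 2.0))
    z = np.arctanh(r_for_z)
    half = zcrit / np.sqrt(n - 3)
    ci_low = float(np.tanh(z - half))
    ci_high = float(np.tanh(z + half))
    return CorrelationResult(
        pair=pair, r=r, ci_low=ci_low, ci_high=ci_high, p=p, n=n,
        level=level, warnings=warns,
    )


def categorical_test(table) -> dict:
    """Chi-squared or Fisher exact test on a 2 x k contingency table.

    Pearson chi-squared (no Yates correction) when every expected count is
    >= 5. Otherwise: a 2x2 table gets Fisher's exact test; a 2xk table has
    its smallest-total column merged into the next-smallest repeatedly
    until expected counts are adequate or only two columns remain (the
    collapse is reported in the result).
    """
    tab = np.asarray(table, dtype=np.float64)
    if tab.ndim != 2 or tab.shape[0] != 2 or tab.shape[1] < 2:
        raise ValueError("expected a 2 x k table with k >= 2")
    if (tab < 0).any() or not np.allclose(tab, np.round(tab)):
        raise ValueError("counts must be non-negative integers")
    if (tab.sum(axis=1) == 0).any() or (tab.sum(axis=0) == 0).any():
        raise ValueError("table has an all-zero row or column")

    collapsed = 0
    work = tab.copy()
    while True:
        expected = sps.contingency.expected_freq(work)
        if (expected >= 5).all():
            stat, p, _, _ = sps.chi2_contingency(work, correction=False)
            return {
                "statistic": float(stat),
                "p": float(p),
                "test_used": "chi_squared",
                "columns_collapsed": collapsed,
            }
        if work.shape[1] == 2:
            stat, p = sps.fisher_exact(np.round(work).astype(np.int64))
            return {
                "statistic": float(stat),
                "p": float(p),
                "test_used": "fisher_exact",
                "columns_collapsed": collapsed,
            }
        # merge the column with the smallest total into the next smallest
        totals = work.sum(axis=0)
        order = np.argsort(totals, kind="stable")
        i, j = int(order[0]), int(order[1])
        work[:, j] += work[:, i]
        work = np.delete(work, i, axis=1)
        collapsed += 1


def roc_auc(
    scores,
    labels,
    positive_direction: str = "high",
) -> dict:
    """ROC AUC via the rank (Mann-Whitney) estimator with tie midranks.

    ``positive_direction="high"`` means larger scores indicate the positive
    class; ``"low"`` negates the scores first (e.g. lower muscle enhancement
    predicting the high-MELD group) and records that orientation.
    Also returns the full ROC curve as (fpr, tpr) point arrays.
    """
    s = np.asarray(scores, dtype=np.float64).ravel()
    y = np.asarray(labels).ravel().astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    keep = np.isfinite(s)
    s, y = s[keep], y[keep]
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if positive_direction not in ("high", "low"):
        raise ValueError("positive_direction must be 'high' or 'low'")
    if positive_direction == "low":
        s = -s

    ranks = sps.rankdata(s)  # midranks for ties
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    # ROC points: thresholds descending over the (possibly negated) scores
    order = np.argsort(-s, kind="stable")
    sorted_y = y[order]
    sorted_s = s[order]
    distinct = np.r_[np.where(np.diff(sorted_s))[0], sorted_y.size - 1]
    tps = np.cumsum(sorted_y)[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return {
        "auc": float(auc),
        "fpr": fpr,
        "tpr": tpr,
        "n_pos": n_pos,
        "n_neg": n_neg,
        "orientation": positive_direction,
    }
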