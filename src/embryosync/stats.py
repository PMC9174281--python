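"""Outcome statistics: test-selection policy, proportion test, correlation,
count-curve comparison, ROC cutoff analysis, and the cohort report.

The two-group policy mirrors a common R workflow: Kolmogorov–Smirnov
normality (estimated-parameter/Lilliefors variant) on both groups, an F-test
for equal variances if both pass, then Student's t, Welch's t, or the
Wilcoxon rank-sum test accordingly — all two-sided.  The proportion test is
the chi-square two-proportion test with Yates continuity correction
(R ``prop.test`` defaults).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.diagnostic import lilliefors

from .lineage import CountCurve, SynchronyProfile


@dataclass
class GroupTestResult:
    test_name: str
    statistic: float
    p_value: float
    normality_p: tuple = (np.nan, np.nan)
    variance_ratio_p: float = np.nan
    n: tuple = (0, 0)
    degenerate: bool = False


def _f_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided F-test for equality of variances (R var.test)."""
    f = np.var(x, ddof=1) / np.var(y, ddof=1)
    d1, d2 = len(x) - 1, len(y) - 1
    p = 2 * min(sps.f.cdf(f, d1, d2), sps.f.sf(f, d1, d2))
    return float(f), float(min(p, 1.0))


def compare_groups(x, y, policy: str = "auto", alpha: float = 0.05) -> GroupTestResult:
    """Two-group comparison under the stated test-selection policy.

    ``policy="auto"``: both groups normal (Lilliefors KS, alpha) → F-test;
    equal variances → Student's t, unequal → Welch's t; any non-normal group
    → Wilcoxon rank-sum.  ``policy="wilcoxon"`` forces the rank-sum test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs n >= 3")
    n = (len(x), len(y))

    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        return GroupTestResult("degenerate", 0.0, 1.0, n=n, degenerate=True)

    if policy == "wilcoxon":
        stat, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return GroupTestResult("wilcoxon_rank_sum", float(stat), float(p), n=n)
    if policy != "auto":
        raise ValueError(f"unknown policy {policy!r}")

    def _norm_p(v: np.ndarray) -> float:
        if np.ptp(v) == 0 or len(v) < 4:
            return 0.0  # constant or tiny group: treat as non-normal
        return float(lilliefors(v, dist="norm")[1])

    px, py = _norm_p(x), _norm_p(y)
    if px > alpha and py > alpha:
        fstat, pvar = _f_test(x, y)
        if pvar > alpha:
            stat, p = sps.ttest_ind(x, y, equal_var=True)
            name = "student_t"
        else:
            stat, p = sps.ttest_ind(x, y, equal_var=False)
            name = "welch_t"
        return GroupTestResult(
            name, float(stat), float(p), normality_p=(px, py), variance_ratio_p=pvar, n=n
        )
    stat, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return GroupTestResult(
        "wilcoxon_rank_sum", float(stat), float(p), normality_p=(px, py), n=n
    )


def two_proportion_test(k1: int, n1: int, k2: int, n2: int, correction: bool = True) -> float:
    """Two-sided chi-square two-proportion test (Yates-corrected by default).

    Equivalent to R's ``prop.test(c(k1, k2), c(n1, n2))``.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("group sizes must be positive")
        if not 0 <= k <= n:
            raise ValueError("successes must satisfy 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table.sum(axis=0) == 0):
        return 1.0  # all successes or all failures: proportions equal
    _, p, _, _ = sps.chi2_contingency(table, correction=correction)
    return float(p)


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-rank ties), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length inputs with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: ranks undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def interpolate_count(curve: CountCurve, t: float) -> float | None:
    """Previous-value interpolation of the cleaned count at relative time t."""
    idx = np.searchsorted(curve.times, t, side="right") - 1
    if idx < 0 or t > curve.times[-1]:
        return None
    return float(curve.cleaned_counts[idx])


def compare_count_curves(
    group_a: list[CountCurve], group_b: list[CountCurve], times, alpha: float = 0.05
) -> list[dict]:
    """Per-time-point Wilcoxon rank-sum comparison of aligned count curves.

    Embryos whose recording does not cover a requested time are excluded
    from that time point (with a warning).  No multiple-testing correction
    by default: each time's raw p is flagged against ``alpha``.
    """
    out = []
    for t in times:
        a = [interpolate_count(c, t) for c in group_a]
        b = [interpolate_count(c, t) for c in group_b]
        n_drop = a.count(None) + b.count(None)
        if n_drop:
            warnings.warn(f"t={t}: {n_drop} embryos excluded (time beyond recording)")
        a = [v for v in a if v is not None]
        b = [v for v in b if v is not None]
        if len(a) < 3 or len(b) < 3:
            out.append({"time": t, "result": None, "significant": False})
            continue
        res = compare_groups(a, b, policy="wilcoxon")
        out.append({"time": t, "result": res, "significant": res.p_value < alpha})
    return out


# ---------------------------------------------------------------------------
# ROC cutoff analysis

POSITIVE_CLASS = "abort"


@dataclass
class RocSummary:
    """Cutoff sweep for a 'high score = positive (abort)' classifier."""

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    accuracy: np.ndarray
    selected_cutoff: float
    selection_criterion: str
    auc: float

    def at_cutoff(self, cutoff: float) -> dict:
        """Metrics at the sweep point nearest the requested cutoff."""
        i = int(np.argmin(np.abs(self.cutoffs - cutoff)))
        return {
            "cutoff": float(self.cutoffs[i]),
            "sensitivity": float(self.sensitivity[i]),
            "specificity": float(self.specificity[i]),
            "accuracy": float(self.accuracy[i]),
        }


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "UO":
        return (y == POSITIVE_CLASS).astype(int)
    return y.astype(int)


def roc_analysis(scores, labels, criterion: str = "accuracy") -> RocSummary:
    """Sweep cutoffs over the scores; prediction is positive iff
    score >= cutoff; positive class is 'abort'.

    Cutoffs are all observed scores plus the midpoints between sorted unique
    scores.  The selected cutoff maximizes the criterion ("accuracy" or
    "youden"), ties broken toward higher specificity, then lower cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    uniq = np.unique(s)
    cutoffs = np.sort(np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2]))
    pred = s[None, :] >= cutoffs[:, None]
    tp = (pred & (y == 1)).sum(axis=1)
    fp = (pred & (y == 0)).sum(axis=1)
    sens = tp / n_pos
    spec = 1 - fp / n_neg
    acc = (tp + (n_neg - fp)) / len(y)

    if criterion == "accuracy":
        objective = acc
    elif criterion == "youden":
        objective = sens + spec - 1
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    order = np.lexsort((cutoffs, -spec, -objective))
    best = order[0]

    from sklearn.metrics import roc_auc_score

    return RocSummary(
        cutoffs=cutoffs,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        selected_cutoff=float(cutoffs[best]),
        selection_criterion=criterion,
        auc=float(roc_auc_score(y, s)),
    )


class SynchronyCutoffClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style classifier: threshold a synchrony score at the cutoff
    selected by ROC analysis on the training cohort.

    ``fit`` sweeps cutoffs on (score, outcome) pairs and stores the one
    maximizing the criterion; ``predict`` labels scores >= cutoff as the
    positive class ('abort').
    """

    def __init__(self, criterion: str = "accuracy"):
        self.criterion = criterion

    def fit(self, X, y):
        s = np.asarray(X, dtype=float).reshape(-1)
        roc = roc_analysis(s, y, criterion=self.criterion)
        self.cutoff_ = roc.selected_cutoff
        self.roc_ = roc
        self.classes_ = np.array(["born", "abort"])
        return self

    def predict(self, X):
        check_is_fitted(self, "cutoff_")
        s = np.asarray(X, dtype=float).reshape(-1)
        return np.where(s >= self.cutoff_, "abort", "born")

    def score(self, X, y):
        check_is_fitted(self, "cutoff_")
        pred = _as_binary(self.predict(X))
        return float((pred == _as_binary(y)).mean())


# ---------------------------------------------------------------------------
# Cohort report


def cohort_report(
    profiles: list[SynchronyProfile], outcomes: dict, cutoff: float = 0.15
) -> dict:
    """Cohort-level synchrony/outcome summary.

    Reports the high-CV fraction among aborted embryos and among all
    embryos, the born rate within the high and low classes, and the
    two-proportion test p-value of the born rates.
    """
    ids = {p.embryo_id for p in profiles}
    orphans = ids.symmetric_difference(outcomes.keys())
    if orphans:
        raise ValueError(f"profile/outcome id mismatch: {sorted(orphans)}")

    high = {p.embryo_id for p in profiles if p.third_cv >= cutoff}
    aborts = {e for e, o in outcomes.items() if o == "abort"}
    borns = ids - aborts

    n = len(ids)
    report = {
        "cutoff": cutoff,
        "n_embryos": n,
        "n_abort": len(aborts),
        "n_born": len(borns),
        "n_high": len(high),
        "high_fraction_of_aborts": (len(high & aborts) / len(aborts)) if aborts else np.nan,
        "high_fraction_of_all": len(high) / n if n else np.nan,
        "born_rate_high": (len(high & borns) / len(high)) if high else np.nan,
        "born_rate_low": (len(borns - high) / (n - len(high))) if n > len(high) else np.nan,
    }
    if high and len(high) < n:
        report["born_rate_p"] = two_proportion_test(
            len(high & borns), len(high), len(borns - high), n - len(high)
        )
    else:
        warnings.warn("one synchrony class empty: proportion test skipped")
        report["born_rate_p"] = np.nan
    return report
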