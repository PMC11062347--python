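"""Outcome-separability statistics.

Three pieces of machinery, mirroring how the clinical analysis is run:

* Pearson correlation with a Fisher-z 95% confidence interval, used to
  compare ultrasound metrics against the CT reference measure.
* A gated two-group location test: Student's t (pooled variance) when both
  groups pass an Anderson–Darling normality check *and* Levene's test
  finds equal variances; the Mann–Whitney U test otherwise (exact
  enumeration for tiny samples, tie/continuity-corrected normal
  approximation at realistic sizes).
* ROC AUC by pairwise comparison (the Mann–Whitney statistic scaled to
  [0, 1]) with the Hanley–McNeil closed-form standard error.

The positive class is the *good* outcome throughout, so a muscle metric
that predicts good outcomes yields AUC > 0.5.  α = 0.05 everywhere; no
multiple-testing correction is applied across metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import EXCLUDED, GOOD, POOR, CohortTable, normalize_by_height, stratify_overflow
from .errors import AnalysisSkipped, DegenerateSampleError, EchomorphError

ALPHA = 0.05

#: critical value for the adjusted Anderson–Darling statistic at α = 0.05
#: (normality with estimated mean and SD)
AD_CRITICAL_05 = 0.752

#: largest pooled sample size for which Mann–Whitney p is enumerated exactly
MW_EXACT_MAX_N = 12


@dataclass
class CorrelationResult:
    r: float
    n: int
    ci_low: float
    ci_high: float
    p: float

    @property
    def r_squared(self) -> float:
        return self.r**2


@dataclass
class SeparabilityResult:
    metric_name: str
    n_good: int
    n_poor: int
    mean_good: float
    mean_poor: float
    test_used: str  # "student_t" | "mann_whitney"
    p: float
    auc: float
    auc_se: float


# ---------------------------------------------------------------- correlation

def fisher_interval(r: float, n: int, alpha: float = ALPHA) -> tuple:
    """Fisher-z confidence interval for a correlation coefficient.

    CI = tanh(atanh r ± z_{1−α/2} / √(n−3)).
    """
    if n < 4:
        raise EchomorphError("Fisher interval needs n >= 4")
    if not -1 < r < 1:
        raise EchomorphError("r must lie strictly inside (-1, 1)")
    z = math.atanh(r)
    half = sps.norm.ppf(1 - alpha / 2) / math.sqrt(n - 3)
    return math.tanh(z - half), math.tanh(z + half)


def pearson_fisher_ci(x, y, alpha: float = ALPHA) -> CorrelationResult:
    """Pearson r with Fisher-z CI and the t-based two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise EchomorphError("need paired samples with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise EchomorphError("samples must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateSampleError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    lo, hi = fisher_interval(res.statistic, len(x), alpha)
    return CorrelationResult(
        r=float(res.statistic), n=len(x), ci_low=lo, ci_high=hi, p=float(res.pvalue)
    )


# ------------------------------------------------------------ normality gates

def anderson_darling_normal(sample, alpha: float = ALPHA) -> tuple:
    """Anderson–Darling normality test with estimated mean and SD.

    Returns ``(A2_star, is_normal)`` where A2* is the small-sample-adjusted
    statistic A²(1 + 0.75/n + 2.25/n²) and normality is accepted when
    A2* < 0.752 (the α = 0.05 critical value for the estimated-parameter
    case).
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n < 8:
        raise EchomorphError("Anderson-Darling gate needs n >= 8")
    s = x.std(ddof=1)
    if s == 0:
        raise DegenerateSampleError("constant sample")
    z = (x - x.mean()) / s
    # clip the CDF away from 0/1 so the logs stay finite for extreme points
    cdf = np.clip(sps.norm.cdf(z), 1e-300, 1 - 1e-16)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(cdf) + np.log1p(-cdf[::-1])))
    a2_star = a2 * (1 + 0.75 / n + 2.25 / n**2)
    return float(a2_star), bool(a2_star < AD_CRITICAL_05)


def levene_equal_variance(g1, g2, alpha: float = ALPHA) -> tuple:
    """Classic mean-centered Levene test; returns ``(W, p, equal_var)``."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise EchomorphError("Levene needs n >= 2 per group")
    if g1.std() == 0 and g2.std() == 0:
        raise DegenerateSampleError("both groups constant")
    w, p = sps.levene(g1, g2, center="mean")
    return float(w), float(p), bool(p > alpha)


# ------------------------------------------------------------- location tests

def _u_statistics(g1, g2) -> tuple:
    """Mann–Whitney U for each group, midranks for ties."""
    pooled = np.concatenate([g1, g2])
    ranks = sps.rankdata(pooled)
    n1 = len(g1)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    u2 = len(g1) * len(g2) - u1
    return u1, u2


def mann_whitney_exact(g1, g2) -> tuple:
    """Exact two-sided Mann–Whitney p by full enumeration of labelings.

    Every C(n1+n2, n1) assignment of the pooled midranks to group 1 is
    enumerated; the two-sided p is the null probability that
    min(U1, U2) is at most the observed minimum.  Valid with ties (it is
    then the exact permutation test on midranks).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    n1, n2 = len(g1), len(g2)
    if n1 + n2 > MW_EXACT_MAX_N:
        raise EchomorphError(f"exact enumeration limited to n1+n2 <= {MW_EXACT_MAX_N}")
    u1_obs, u2_obs = _u_statistics(g1, g2)
    crit = min(u1_obs, u2_obs) + 1e-9
    ranks = sps.rankdata(np.concatenate([g1, g2]))
    offset = n1 * (n1 + 1) / 2
    total = hits = 0
    for idx in combinations(range(n1 + n2), n1):
        u1 = ranks[list(idx)].sum() - offset
        if min(u1, n1 * n2 - u1) <= crit:
            hits += 1
        total += 1
    return float(min(u1_obs, u2_obs)), hits / total


def separability_test(g1, g2, alpha: float = ALPHA) -> tuple:
    """Normality/variance-gated two-group test; returns ``(test_used, p)``.

    Student's t with pooled variance when both groups are accepted as
    normal by Anderson–Darling *and* Levene accepts equal variances;
    otherwise the two-sided Mann–Whitney U test (exact for pooled n ≤ 12,
    tie- and continuity-corrected normal approximation above that).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    use_t = False
    if len(g1) >= 8 and len(g2) >= 8:
        try:
            normal = anderson_darling_normal(g1, alpha)[1] and anderson_darling_normal(g2, alpha)[1]
            use_t = normal and levene_equal_variance(g1, g2, alpha)[2]
        except DegenerateSampleError:
            use_t = False
    if use_t:
        return "student_t", float(sps.ttest_ind(g1, g2, equal_var=True).pvalue)
    if len(g1) + len(g2) <= MW_EXACT_MAX_N:
        return "mann_whitney", mann_whitney_exact(g1, g2)[1]
    res = sps.mannwhitneyu(g1, g2, alternative="two-sided", method="asymptotic")
    return "mann_whitney", float(res.pvalue)


# ----------------------------------------------------------------------- ROC

def roc_auc(scores, labels, positive: str = GOOD) -> float:
    """AUC = P(score_pos > score_neg) + ½·P(tie), via the rank formula."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise EchomorphError("both classes must be present")
    u_pos, _ = _u_statistics(pos, neg)
    return float(u_pos / (len(pos) * len(neg)))


def roc_points(scores, labels, positive: str = GOOD) -> pd.DataFrame:
    """ROC curve points (threshold, fpr, tpr) at every distinct score."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], y[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tps = np.cumsum(y)[distinct]
    fps = distinct + 1 - tps
    return pd.DataFrame(
        {
            "threshold": np.r_[np.inf, s[distinct]],
            "fpr": np.r_[0.0, fps / max(fps[-1], 1)],
            "tpr": np.r_[0.0, tps / max(tps[-1], 1)],
        }
    )


def hanley_mcneil_se(auc: float, n1: int, n2: int) -> float:
    """Hanley–McNeil standard error of an ROC AUC.

    SE² = [A(1−A) + (n1−1)(Q1−A²) + (n2−1)(Q2−A²)] / (n1·n2),
    with Q1 = A/(2−A) and Q2 = 2A²/(1+A); n1, n2 are the class sizes.
    """
    if not 0 <= auc <= 1:
        raise EchomorphError("AUC must lie in [0, 1]")
    if n1 < 1 or n2 < 1:
        raise EchomorphError("class sizes must be positive")
    a = auc
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n2 - 1) * (q2 - a * a)) / (n1 * n2)
    return math.sqrt(max(var, 0.0))


# ------------------------------------------------------------ cohort analysis

def evaluate_metric(
    cohort: CohortTable,
    metric_name: str,
    normalized: bool = False,
    overflow_policy: str = "all",
    alpha: float = ALPHA,
    min_per_class: int = 8,
) -> SeparabilityResult:
    """Full separability analysis of one metric on a labelled cohort.

    Applies the overflow policy (``all`` or ``exclude_overflow``), optional
    height² normalization, outcome labelling, complete-case filtering, then
    the gated location test, ROC AUC (positive class = good outcome) and
    its Hanley–McNeil SE.
    """
    if overflow_policy not in ("all", "exclude_overflow"):
        raise EchomorphError(f"unknown overflow policy {overflow_policy!r}")
    if overflow_policy == "exclude_overflow":
        cohort = stratify_overflow(cohort)[1]
    df = cohort.with_outcomes().df
    cols = [metric_name, "outcome"] + (["height_m"] if normalized else [])
    df = df.dropna(subset=[c for c in cols if c != "outcome"])
    values = df[metric_name].to_numpy(dtype=float)
    if normalized:
        values = normalize_by_height(values, df["height_m"].to_numpy(dtype=float))
    outcome = df["outcome"].to_numpy()
    good = values[outcome == GOOD]
    poor = values[outcome == POOR]
    if len(good) < min_per_class or len(poor) < min_per_class:
        raise AnalysisSkipped(
            f"{metric_name}: class sizes {len(good)}/{len(poor)} below {min_per_class}"
        )
    test_used, p = separability_test(good, poor, alpha)
    keep = outcome != EXCLUDED
    auc = roc_auc(values[keep], outcome[keep])
    return SeparabilityResult(
        metric_name=metric_name + ("_per_m2" if normalized else ""),
        n_good=len(good),
        n_poor=len(poor),
        mean_good=float(good.mean()),
        mean_poor=float(poor.mean()),
        test_used=test_used,
        p=float(p),
        auc=auc,
        auc_se=hanley_mcneil_se(auc, len(good), len(poor)),
    )


def evaluate_all(
    cohort: CohortTable,
    metric_names: Sequence[str],
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Separability grid: metric × {raw, height-normalized} × {all, no-overflow}.

    Mirrors the clinical results layout; combinations with too few
    subjects per class are skipped (row omitted) rather than failing.
    """
    rows = []
    for policy in ("all", "exclude_overflow"):
        for normalized in (False, True):
            for name in metric_names:
                try:
                    res = evaluate_metric(cohort, name, normalized, policy, alpha)
                except AnalysisSkipped:
                    continue
                rows.append(
                    {
                        "metric": res.metric_name,
                        "overflow_policy": policy,
                        "normalized": normalized,
                        "n_good": res.n_good,
                        "n_poor": res.n_poor,
                        "mean_good": res.mean_good,
                        "mean_poor": res.mean_poor,
                        "test": res.test_used,
                        "p": res.p,
                        "auc": res.auc,
                        "auc_se": res.auc_se,
                    }
                )
    return pd.DataFrame(rows)


def correlate_with_reference(
    cohort: CohortTable,
    metric_names: Sequence[str],
    reference: str = "ct_sma_cm2",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Pearson-with-CI table of each metric against a reference column."""
    rows = []
    for name in metric_names:
        sub = cohort.df.dropna(subset=[name, reference])
        res = pearson_fisher_ci(sub[reference], sub[name], alpha)
        rows.append(
            {
                "reference": reference,
                "metric": name,
                "n": res.n,
                "r": res.r,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)
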