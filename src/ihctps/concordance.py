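"""Agreement statistics for comparing scoring methods.

Implements the evaluation toolkit for continuous and categorical PD-L1
scores: Lin's concordance correlation coefficient (population moments, Fisher
z confidence interval), Cohen's kappa with a large-sample Wald interval and
the interpretation bands used in the clinical literature (0.40-0.69 weak,
0.70-0.79 moderate, 0.80-0.89 strong, >=0.90 near perfect), dichotomized
agreement/sensitivity/specificity against a gold standard, Wilcoxon /
Mann-Whitney rank tests, Pearson chi-squared for category distributions,
Bland-Altman limits of agreement, and the two-group normal-approximation
power arithmetic for differences between kappas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DegenerateInputError",
    "JoinError",
    "CCCResult",
    "KappaResult",
    "AgreementReport",
    "BlandAltman",
    "RankTestResult",
    "lin_ccc",
    "cohens_kappa",
    "interpret_kappa",
    "agreement_vs_gold",
    "paired_difference_tests",
    "category_distribution_test",
    "bland_altman",
    "kappa_detectable_difference",
    "kappa_power",
]


class DegenerateInputError(ValueError):
    """The requested statistic is undefined for this input."""


class JoinError(ValueError):
    """Method and gold-standard scores could not be aligned by id."""


@dataclass(frozen=True)
class CCCResult:
    estimate: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class KappaResult:
    estimate: float
    ci_low: float
    ci_high: float
    se: float
    interpretation: str


@dataclass(frozen=True)
class AgreementReport:
    percent_concordance: float
    kappa: KappaResult
    sensitivity: float  # percent
    specificity: float  # percent
    table: np.ndarray  # rows: gold (neg, pos); cols: method (neg, pos)
    n: int


@dataclass(frozen=True)
class BlandAltman:
    mean_difference: float
    sd_difference: float
    lower_limit: float
    upper_limit: float


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_value: float
    degenerate: bool = False


def lin_ccc(x, y, alpha: float = 0.05) -> CCCResult:
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    ccc = 2*cov(x,y) / (var(x) + var(y) + (mean(x)-mean(y))^2) with
    population (1/n) moments, penalizing both dispersion and location
    differences from the identity line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    n = len(x)
    mx, my = x.mean(), y.mean()
    vx = float(((x - mx) ** 2).mean())
    vy = float(((y - my) ** 2).mean())
    sxy = float(((x - mx) * (y - my)).mean())
    denom = vx + vy + (mx - my) ** 2
    if vx == 0 and vy == 0:
        raise DegenerateInputError("both series have zero variance; CCC undefined")
    ccc = 2.0 * sxy / denom

    # Lin's large-sample variance on the Fisher-z scale.
    if vx == 0 or vy == 0 or abs(ccc) >= 1.0:
        return CCCResult(float(ccc), float(ccc), float(ccc), n)
    r = sxy / np.sqrt(vx * vy)
    z = np.arctanh(ccc)
    u2 = (mx - my) ** 2 / np.sqrt(vx * vy)
    if abs(r) < 1e-12:
        return CCCResult(float(ccc), -1.0, 1.0, n)
    var_z = (
        (1 - r**2) * ccc**2 * (1 - ccc**2) / r**2
        + 2 * ccc**3 * (1 - ccc) * u2 / r
        - ccc**4 * u2**2 / (2 * r**2)
    ) / ((n - 2) * (1 - ccc**2) ** 2)
    var_z = max(var_z, 0.0)
    zq = stats.norm.ppf(1 - alpha / 2)
    lo, hi = np.tanh(z - zq * np.sqrt(var_z)), np.tanh(z + zq * np.sqrt(var_z))
    return CCCResult(float(ccc), float(lo), float(hi), n)


def interpret_kappa(kappa: float) -> str:
    """Interpretation band for a kappa estimate."""
    if kappa >= 0.90:
        return "near perfect"
    if kappa >= 0.80:
        return "strong"
    if kappa >= 0.70:
        return "moderate"
    if kappa >= 0.40:
        return "weak"
    return "minimal or none"


def cohens_kappa(table, alpha: float = 0.05) -> KappaResult:
    """Cohen's kappa for a k x k confusion table, with a Wald 95% CI.

    kappa = (p_o - p_e) / (1 - p_e), p_e from marginal products. The standard
    large-sample SE sqrt(p_o(1-p_o) / (n (1-p_e)^2)) gives Wald bounds
    truncated to [-1, 1].
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("confusion table must be square")
    if np.any(t < 0):
        raise ValueError("confusion table counts must be non-negative")
    n = t.sum()
    if n <= 0:
        raise ValueError("confusion table is empty")
    po = np.trace(t) / n
    pe = float((t.sum(axis=1) * t.sum(axis=0)).sum()) / n**2
    if pe >= 1.0 - 1e-15:
        raise DegenerateInputError("degenerate marginals (p_e = 1); kappa undefined")
    kappa = (po - pe) / (1 - pe)
    se = float(np.sqrt(po * (1 - po) / (n * (1 - pe) ** 2)))
    zq = stats.norm.ppf(1 - alpha / 2)
    lo = max(kappa - zq * se, -1.0)
    hi = min(kappa + zq * se, 1.0)
    return KappaResult(float(kappa), lo, hi, se, interpret_kappa(float(kappa)))


def agreement_vs_gold(
    method_scores: pd.Series,
    gold_scores: pd.Series,
    threshold: float,
) -> AgreementReport:
    """Dichotomized agreement of a method with the gold standard.

    Both series are indexed by patch/case id; positive means score >=
    threshold (consistent with the 1-49% and >=50% category bounds). The
    gold standard defines truth for sensitivity TP/(TP+FN) and specificity
    TN/(TN+FP).
    """
    m = pd.Series(method_scores).astype(float)
    g = pd.Series(gold_scores).astype(float)
    only_m = m.index.difference(g.index)
    only_g = g.index.difference(m.index)
    if len(only_m) or len(only_g):
        raise JoinError(
            f"ids only in method: {list(only_m)}; only in gold: {list(only_g)}"
        )
    g = g.loc[m.index]
    mp = (m >= threshold).to_numpy()
    gp = (g >= threshold).to_numpy()
    tp = int(np.sum(mp & gp))
    tn = int(np.sum(~mp & ~gp))
    fp = int(np.sum(mp & ~gp))
    fn = int(np.sum(~mp & gp))
    table = np.array([[tn, fp], [fn, tp]], dtype=float)
    n = len(m)
    concord = 100.0 * (tp + tn) / n
    try:
        kappa = cohens_kappa(table)
    except DegenerateInputError:
        # one-sided marginals (e.g. every score below threshold): kappa has
        # no information; report NaN rather than abort a whole evaluation
        nan = float("nan")
        kappa = KappaResult(nan, nan, nan, nan, "undefined")
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    return AgreementReport(concord, kappa, sens, spec, table, n)


def paired_difference_tests(x, y, paired: bool = True) -> RankTestResult:
    """Two-sided rank test: Wilcoxon signed rank (paired) or Mann-Whitney U.

    Tie-corrected; all-zero paired differences are degenerate (signalled,
    p = 1: there is no evidence of a shift).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        diffs = x - y
        if np.all(diffs == 0):
            return RankTestResult(0.0, 1.0, degenerate=True)
        res = stats.wilcoxon(x, y, zero_method="zsplit", alternative="two-sided")
        return RankTestResult(float(res.statistic), float(res.pvalue))
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return RankTestResult(float(res.statistic), float(res.pvalue))


def category_distribution_test(counts) -> tuple[float, float]:
    """Pearson chi-squared on a methods x categories contingency table.

    Zero-margin rows/columns are dropped with a warning. Returns (statistic,
    p-value); identical distributions give statistic 0, p = 1.
    """
    t = np.asarray(counts, dtype=float)
    if t.ndim != 2:
        raise ValueError("counts must be a 2-D contingency table")
    row_ok = t.sum(axis=1) > 0
    col_ok = t.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping zero-margin rows/columns from contingency table")
        t = t[row_ok][:, col_ok]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise DegenerateInputError("contingency table too small after dropping margins")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def bland_altman(x, y) -> BlandAltman:
    """Bland-Altman summary of paired differences x - y.

    Limits of agreement are mean difference +/- 2 * sd (n-1 denominator).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("need paired samples with n >= 2")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(mean, sd, mean - 2 * sd, mean + 2 * sd)


def kappa_detectable_difference(
    n: int, sd: float = 0.4, alpha: float = 0.05, power: float = 0.80
) -> float:
    """Minimum detectable difference between two kappas (normal approximation).

    d = (z_{1-alpha/2} + z_power) * sd * sqrt(2/n), the two-independent-group
    formula; exact inverse of :func:`kappa_power`.
    """
    if n <= 0 or not (0 < alpha < 1) or not (0 < power < 1) or sd <= 0:
        raise ValueError("require n > 0, sd > 0, 0 < alpha < 1, 0 < power < 1")
    za = stats.norm.ppf(1 - alpha / 2)
    zb = stats.norm.ppf(power)
    return float((za + zb) * sd * np.sqrt(2.0 / n))


def kappa_power(n: int, sd: float = 0.4, alpha: float = 0.05, d: float = 0.1) -> float:
    """Power to detect a difference ``d`` between two kappas at sample size n."""
    if n <= 0 or not (0 < alpha < 1) or sd <= 0 or d < 0:
        raise ValueError("require n > 0, sd > 0, 0 < alpha < 1, d >= 0")
    za = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(d / (sd * np.sqrt(2.0 / n)) - za))
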