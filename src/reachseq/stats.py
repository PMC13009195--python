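"""Significance machinery for coarticulation analyses.

One-sample zero-mean tests gated by Shapiro-Wilk normality, Pearson
correlation summaries with Fisher-z confidence intervals, a label-permutation
bootstrap for fusion-index group differences, and a thin Welch two-sample
wrapper.  Significance is evaluated at alpha = 0.01 throughout, with no
multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "SignificanceResult",
    "CorrelationResult",
    "coarticulation_test",
    "correlation_summary",
    "fusion_bootstrap",
    "welch_test",
]

#: Shapiro-Wilk p-value below which the Wilcoxon branch is taken
NORMALITY_GATE = 0.05
#: default significance level
DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class SignificanceResult:
    mean: float
    n: int
    normality_p: float
    test: str  # "t" | "wilcoxon" | "degenerate"
    statistic: float
    p_value: float
    significant: bool
    alpha: float
    sem: float

    def as_row(self) -> dict:
        """Flat record for results tables."""
        return {
            "mean": self.mean,
            "se": self.sem,
            "n": self.n,
            "test": self.test,
            "statistic": self.statistic,
            "p": self.p_value,
            "significant": self.significant,
        }


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    df: int
    n: int


def coarticulation_test(
    samples: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> SignificanceResult:
    """Test whether signed coarticulation values have zero mean.

    Shapiro-Wilk gates the choice of test: a one-sample t-test when the
    sample looks normal (p >= 0.05), the Wilcoxon signed-rank test otherwise.
    All-identical samples are flagged degenerate (p = 1 unless the common
    value is nonzero and exactly testable -- no distributional test applies).
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D sample of size >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    mean = float(np.mean(x))
    n = int(x.size)
    sem = float(sps.sem(x)) if np.ptp(x) > 0 else 0.0
    if np.ptp(x) == 0:
        return SignificanceResult(
            mean=mean, n=n, normality_p=np.nan, test="degenerate",
            statistic=np.nan, p_value=np.nan, significant=False,
            alpha=alpha, sem=sem,
        )
    norm_p = float(sps.shapiro(x).pvalue)
    if norm_p >= NORMALITY_GATE:
        res = sps.ttest_1samp(x, 0.0)
        test = "t"
    else:
        res = sps.wilcoxon(x)
        test = "wilcoxon"
    p = float(res.pvalue)
    return SignificanceResult(
        mean=mean, n=n, normality_p=norm_p, test=test,
        statistic=float(res.statistic), p_value=p,
        significant=bool(p < alpha), alpha=alpha, sem=sem,
    )


def correlation_summary(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson correlation with Fisher-z 95% CI, two-sided p, df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if x.size < 4:
        raise ValueError("need at least 4 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    n = int(x.size)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = sps.norm.ppf(0.975) / np.sqrt(n - 3)
    return CorrelationResult(
        r=r,
        ci_low=float(np.tanh(z - half)),
        ci_high=float(np.tanh(z + half)),
        p_value=float(res.pvalue),
        df=n - 2,
        n=n,
    )


def fusion_bootstrap(
    values: np.ndarray,
    labels: np.ndarray,
    n_resamples: int = 100_000,
    seed: int | None = None,
) -> float:
    """One-sided label-permutation p for a between-group fusion difference.

    Labels are randomly reassigned with group sizes preserved; p is the
    fraction of resamples whose absolute mean difference is greater than or
    equal to the observed absolute difference (ties count as exceedances, so
    an observed difference of zero gives p = 1).
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if v.shape != lab.shape or v.ndim != 1:
        raise ValueError("values and labels must be 1-D and equal length")
    if n_resamples < 1000:
        raise ValueError("n_resamples must be >= 1000")
    groups = np.unique(lab)
    if groups.size != 2:
        raise ValueError("labels must contain exactly two groups")
    mask = lab == groups[0]
    n0 = int(mask.sum())
    if n0 == 0 or n0 == v.size:
        raise ValueError("degenerate group sizes")
    if seed is None:
        raise ValueError("a seed is required for the bootstrap")
    observed = abs(float(np.mean(v[mask]) - np.mean(v[~mask])))
    rng = np.random.default_rng(seed)
    total = float(np.sum(v))
    n1 = v.size - n0
    count = 0
    # vectorized permutations in blocks to bound memory
    block = max(1, min(n_resamples, 20_000_000 // max(v.size, 1)))
    done = 0
    while done < n_resamples:
        b = min(block, n_resamples - done)
        idx = np.argsort(rng.random((b, v.size)), axis=1)[:, :n0]
        sums0 = np.sum(v[idx], axis=1)
        diffs = np.abs(sums0 / n0 - (total - sums0) / n1)
        count += int(np.sum(diffs >= observed - 1e-12))
        done += b
    return count / n_resamples


def welch_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t-test (statistic, p); for contrasts such as
    single-target versus sequential halfway crosses."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs at least 3 values")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
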