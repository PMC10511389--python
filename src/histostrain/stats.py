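"""Strain distribution indices and the study's hypothesis tests.

Four scalar indices condense a distribution of local first-principal strain
values: the arithmetic mean, the maximum local strain, the coefficient of
variation (SD/mean, the "heterogeneity index") and the adjusted
Fisher-Pearson sample skewness (positive = right-skewed: a long tail of few
large strains).  Group-level comparisons screen for normality first and use a
Student's t-test when both groups look normal, a rank-sum test otherwise.
Per-region strain distributions are compared pairwise with Mann-Whitney U
tests under Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class SDISummary:
    """Strain distribution indices of one sample of strain values."""

    mean: float
    maximum: float
    coefficient_of_variation: float
    skewness: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean,
            "maximum": self.maximum,
            "coefficient_of_variation": self.coefficient_of_variation,
            "skewness": self.skewness,
        }


SDI_NAMES = ("mean", "maximum", "coefficient_of_variation", "skewness")


def compute_sdi(samples: np.ndarray) -> SDISummary:
    """Mean, maximum, CV and adjusted Fisher-Pearson skewness of a sample.

    CV is the sample standard deviation (ddof=1) over the mean and is NaN for
    a zero-mean sample; zero-variance samples get skewness 0 by convention.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if len(x) < 3:
        raise ValueError("SDIs require at least 3 samples")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    cv = float("nan") if mean == 0.0 else sd / mean
    skew = 0.0 if sd == 0.0 else float(sps.skew(x, bias=False))
    return SDISummary(mean=mean, maximum=float(x.max()), coefficient_of_variation=cv, skewness=skew, n=len(x))


@dataclass
class GroupComparison:
    branch: str  # "t" or "ranksum"
    statistic: float
    p_value: float
    normality_p: tuple[float, float]


def compare_groups_sdi(
    group_a: np.ndarray, group_b: np.ndarray, normality_alpha: float = 0.05
) -> GroupComparison:
    """Location test between two groups of per-specimen SDI values.

    Both groups are screened with Shapiro-Wilk at ``normality_alpha``; if both
    pass (or are too small to screen, n < 3), a two-sample Student's t-test is
    used, otherwise a Mann-Whitney rank-sum test.  The branch taken is
    reported alongside the statistic and p-value.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 specimens")
    if (a.std() == 0 and b.std() == 0) and a.mean() == b.mean():
        # identical constant groups: no evidence against equal location
        return GroupComparison("t", 0.0, 1.0, (1.0, 1.0))
    # constant groups trivially violate normality; the rank test still applies
    pa = 0.0 if a.std() == 0 else (sps.shapiro(a).pvalue if len(a) >= 3 else 1.0)
    pb = 0.0 if b.std() == 0 else (sps.shapiro(b).pvalue if len(b) >= 3 else 1.0)
    if pa > normality_alpha and pb > normality_alpha:
        res = sps.ttest_ind(a, b)
        return GroupComparison("t", float(res.statistic), float(res.pvalue), (pa, pb))
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison("ranksum", float(res.statistic), float(res.pvalue), (pa, pb))


# The six region comparisons of the study: elastin with vs without thrombus
# attachment, intact vs fragmented elastin, thrombus with vs without RBCs,
# thrombus with RBCs vs intact elastin, and the two 'similar strain' checks.
DEFAULT_REGION_PAIRS = (
    ("A1", "A2"),
    ("A1", "A3"),
    ("A4", "A5"),
    ("A1", "A4"),
    ("A2", "A5"),
    ("A3", "A5"),
)


@dataclass
class PairTestResult:
    pair: tuple[str, str]
    n: tuple[int, int]
    statistic: float
    p_value: float
    corrected_alpha: float
    significant: bool
    skipped: bool = False


def pairwise_region_tests(
    region_strains,
    pairs=DEFAULT_REGION_PAIRS,
    alpha: float = 0.05,
) -> list[PairTestResult]:
    """Mann-Whitney U per region pair, Bonferroni-corrected over tested pairs.

    Pairs whose regions are missing or empty are skipped with a flag (not all
    areas are present in all section planes); the Bonferroni divisor is the
    number of pairs actually tested.
    """
    samples = region_strains.samples if hasattr(region_strains, "samples") else region_strains
    testable = [
        p for p in pairs if len(samples.get(p[0], ())) > 0 and len(samples.get(p[1], ())) > 0
    ]
    m = len(testable)
    out = []
    for pair in pairs:
        if pair not in testable:
            out.append(PairTestResult(pair, (len(samples.get(pair[0], ())), len(samples.get(pair[1], ()))), float("nan"), float("nan"), float("nan"), False, skipped=True))
            continue
        a, b = np.asarray(samples[pair[0]]), np.asarray(samples[pair[1]])
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        corrected = alpha / m
        out.append(
            PairTestResult(
                pair,
                (len(a), len(b)),
                float(res.statistic),
                float(res.pvalue),
                corrected,
                bool(res.pvalue < corrected),
            )
        )
    return out


@dataclass
class FitResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def fit_mean_strain_vs_proportion(x: np.ndarray, y: np.ndarray) -> FitResult:
    """OLS fit of mean strain against a tissue proportion, with R^2 and slope p.

    Used for the relation between cross-sectional mean strain and the
    proportion of thrombus without red blood cells.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: slope undefined")
    res = sps.linregress(x, y)
    return FitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
    )
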