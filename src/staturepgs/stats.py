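"""Comparison statistics: Wilcoxon signed-rank tests, Tukey HSD, paired d.

Wilcoxon tests drop zero differences before ranking and use the exact
signed-rank distribution for small tie-free samples (n <= 25 by default),
falling back to the tie-corrected normal approximation with continuity
correction otherwise.  Tukey's HSD uses the studentized-range distribution
with the Tukey-Kramer adjustment for unequal group sizes.  The paired
effect size is Cohen's d on paired differences: mean(diff) / SD(diff).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError

EXACT_MAX_N = 25


@dataclass(frozen=True)
class TestResult:
    comparison: str
    statistic: float
    p_value: float
    estimate: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    method: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p value {self.p_value} outside [0, 1]")


def results_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    """Tidy table (comparison, estimate, ci_low, ci_high, p, method)."""
    return pd.DataFrame(
        {
            "comparison": [r.comparison for r in results],
            "estimate": [r.estimate for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "statistic": [r.statistic for r in results],
            "p": [r.p_value for r in results],
            "method": [r.method for r in results],
        }
    )


def wilcoxon_one_sample(
    values, mu0: float = 0.0, exact_max_n: int = EXACT_MAX_N, comparison: str = "median vs mu0"
) -> TestResult:
    """Two-sided one-sample Wilcoxon signed-rank test of median == mu0."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("empty sample")
    d = x - mu0
    d = d[d != 0.0]
    estimate = float(np.median(x)) - mu0
    if d.size == 0:
        return TestResult(comparison, 0.0, 1.0, estimate, method="wilcoxon (degenerate: all values at mu0)")
    has_ties = len(np.unique(np.abs(d))) < d.size
    if d.size <= exact_max_n and not has_ties:
        res = scipy.stats.wilcoxon(d, alternative="two-sided", method="exact", zero_method="wilcox")
        method = "wilcoxon exact"
    else:
        res = scipy.stats.wilcoxon(
            d, alternative="two-sided", method="approx", correction=True, zero_method="wilcox"
        )
        method = "wilcoxon normal approx"
    return TestResult(comparison, float(res.statistic), float(res.pvalue), estimate, method=method)


def wilcoxon_paired(a, b, exact_max_n: int = EXACT_MAX_N, comparison: str = "a vs b") -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test; identical to the one-sample
    test applied to the differences a - b.  Estimate is median(a - b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"paired samples have different lengths: {a.shape} vs {b.shape}")
    diff = a - b
    res = wilcoxon_one_sample(diff, 0.0, exact_max_n=exact_max_n, comparison=comparison)
    return TestResult(
        comparison, res.statistic, res.p_value, float(np.median(diff)), method="paired " + res.method
    )


def tukey_hsd(groups: Mapping[str, Sequence[float]], confidence_level: float = 0.95) -> list[TestResult]:
    """All pairwise mean differences with studentized-range adjusted p values
    and simultaneous CIs (Tukey-Kramer for unequal n)."""
    names = list(groups)
    if len(names) < 2:
        raise ValidationError("Tukey HSD needs at least 2 groups")
    samples = []
    for name in names:
        arr = np.asarray(groups[name], dtype=float)
        if arr.size < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 observations")
        samples.append(arr)
    res = scipy.stats.tukey_hsd(*samples)
    ci = res.confidence_interval(confidence_level=confidence_level)
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            out.append(
                TestResult(
                    comparison=f"{names[i]} - {names[j]}",
                    statistic=float(res.statistic[i, j]),
                    p_value=float(min(1.0, res.pvalue[i, j])),
                    estimate=float(samples[i].mean() - samples[j].mean()),
                    ci_low=float(ci.low[i, j]),
                    ci_high=float(ci.high[i, j]),
                    method="tukey_hsd",
                )
            )
    return out


def paired_effect_size(a, b) -> float:
    """Paired Cohen's d: mean(a - b) / SD(a - b) with ddof=1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired samples have different lengths")
    d = a - b
    if d.size < 2:
        raise ValidationError("need at least 2 pairs")
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise ValidationError("zero SD of paired differences: effect size undefined")
    return float(d.mean()) / sd
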