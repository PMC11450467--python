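"""Two-sample t-tests and distribution summaries for cluster-size samples.

The size comparison reported for the filament data ("Ca clusters are not
significantly larger than K clusters at the 95% confidence level") is a
Student's t-test on per-cluster areas; the violin-plot summaries are
quartiles plus 1.5×IQR fences.  Both the classical pooled-variance variant
and Welch's unequal-variance variant are computed — the pooled form is the
default, the phrasing of the hypothesis makes the one-sided p relevant, so
two- and one-sided p-values are always emitted together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class SizeSample:
    """Cluster sizes (areas in µm² or diameters in µm) of one element."""

    element: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise ValueError("sample must contain at least one value")
        if (self.values <= 0).any():
            raise ValueError("sizes must be positive")


@dataclass
class TTestResult:
    t: float
    df: float
    p_two: float
    p_one: float
    variant: str  # pooled | welch
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def students_t(a: SizeSample, b: SizeSample, variant: str = "pooled") -> TTestResult:
    """Two-sample t-test of mean sizes; pooled (Student) or Welch variant.

    The one-sided p is for the alternative mean(a) > mean(b): p_one =
    p_two/2 when t is positive, 1 − p_two/2 otherwise.  Zero pooled
    variance (all values identical across both samples) is an error.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    x, y = a.values, b.values
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need n >= 2")
    if np.ptp(np.concatenate([x, y])) == 0:
        raise ValueError("zero variance: t statistic undefined")
    res = stats.ttest_ind(x, y, equal_var=(variant == "pooled"))
    t = float(res.statistic)
    p_two = float(res.pvalue)
    df = float(res.df)
    p_one = p_two / 2.0 if t >= 0 else 1.0 - p_two / 2.0
    return TTestResult(
        t=t,
        df=df,
        p_two=p_two,
        p_one=p_one,
        variant=variant,
        mean_a=float(x.mean()),
        mean_b=float(y.mean()),
        n_a=int(x.size),
        n_b=int(y.size),
    )


@dataclass
class DistributionSummary:
    """Violin-plot summary: quartiles, mean, and 1.5×IQR fences."""

    element: str
    n: int
    mean: float
    q1: float
    median: float
    q3: float
    iqr: float
    fence_low: float
    fence_high: float


def distribution_summary(s: SizeSample) -> DistributionSummary:
    """25/50/75th percentiles (linear interpolation), mean, IQR fences."""
    q1, med, q3 = np.percentile(s.values, [25, 50, 75])
    iqr = q3 - q1
    return DistributionSummary(
        element=s.element,
        n=int(s.values.size),
        mean=float(s.values.mean()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        iqr=float(iqr),
        fence_low=float(q1 - 1.5 * iqr),
        fence_high=float(q3 + 1.5 * iqr),
    )
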