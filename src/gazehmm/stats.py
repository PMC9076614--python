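"""Group-comparison statistics and fixation heatmaps.

Thin, uniformly-shaped wrappers around the standard tests used to compare
eye-movement measures between groups: two-sample t (pooled or Welch),
one-sample t against a reference value (e.g. gaze preference vs the 50%
no-preference point), one-way ANOVA across age groups, and Pearson
correlation with a Fisher-z confidence interval. Every result carries the
statistic, degrees of freedom, two-tailed p, mean difference with its
standard error, and a 95% CI. No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .types import InputError

__all__ = ["ComparisonResult", "two_sample_t", "one_sample_t",
           "one_way_anova", "pearson_r", "fixation_heatmap"]


@dataclass
class ComparisonResult:
    """One statistical comparison in a common shape."""

    name: str                      # "t", "F" or "r"
    value: float
    df: float | tuple[float, float]
    p_value: float
    mean_diff: float | None = None
    sem: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    def as_dict(self) -> dict:
        return {
            "statistic": self.name, "value": self.value,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p_value": self.p_value, "mean_diff": self.mean_diff,
            "sem": self.sem, "ci_low": self.ci_low, "ci_high": self.ci_high,
        }


def two_sample_t(group_a, group_b, variant: str = "welch") -> ComparisonResult:
    """Two-tailed two-sample t-test on the difference of group means.

    ``variant="pooled"`` assumes equal variances (df = nA + nB - 2);
    ``"welch"`` uses the Welch-Satterthwaite approximation with fractional df.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 observations")
    if variant not in ("pooled", "welch"):
        raise InputError(f"unknown t-test variant {variant!r}")
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    mean_diff = float(a.mean() - b.mean())
    if variant == "pooled":
        sp2 = (((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
               / (a.size + b.size - 2))
        sem = float(np.sqrt(sp2 * (1 / a.size + 1 / b.size)))
    else:
        sem = float(np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size))
    ci = res.confidence_interval(0.95)
    return ComparisonResult(name="t", value=float(res.statistic),
                            df=float(res.df), p_value=float(res.pvalue),
                            mean_diff=mean_diff, sem=sem,
                            ci_low=float(ci.low), ci_high=float(ci.high))


def one_sample_t(values, mu0: float = 0.5) -> ComparisonResult:
    """Two-tailed one-sample t-test of the mean against ``mu0`` (df = n - 1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InputError("need at least 2 observations")
    if x.var(ddof=1) == 0.0 and x.mean() == mu0:
        # all observations exactly at the null value: t = 0/0, define as 0
        return ComparisonResult(name="t", value=0.0, df=float(x.size - 1),
                                p_value=1.0, mean_diff=0.0, sem=0.0,
                                ci_low=0.0, ci_high=0.0)
    res = sps.ttest_1samp(x, popmean=mu0)
    ci = res.confidence_interval(0.95)
    return ComparisonResult(name="t", value=float(res.statistic),
                            df=float(x.size - 1), p_value=float(res.pvalue),
                            mean_diff=float(x.mean() - mu0),
                            sem=float(sps.sem(x)),
                            ci_low=float(ci.low - mu0), ci_high=float(ci.high - mu0))


def one_way_anova(groups) -> ComparisonResult:
    """One-way ANOVA across k groups; df = (k - 1, N - k)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise InputError("need >= 2 groups with >= 2 observations each")
    res = sps.f_oneway(*gs)
    n_total = sum(g.size for g in gs)
    return ComparisonResult(name="F", value=float(res.statistic),
                            df=(float(len(gs) - 1), float(n_total - len(gs))),
                            p_value=float(res.pvalue))


def pearson_r(x, y) -> ComparisonResult:
    """Pearson correlation with a Fisher-z 95% confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InputError("need paired samples of size >= 3")
    res = sps.pearsonr(x, y)
    ci = res.confidence_interval(0.95)
    return ComparisonResult(name="r", value=float(res.statistic),
                            df=float(x.size - 2), p_value=float(res.pvalue),
                            ci_low=float(ci.low), ci_high=float(ci.high))


def fixation_heatmap(sequences, layout, bandwidth_px: float = 50.0,
                     grid_shape: tuple[int, int] = (108, 192)):
    """Gaussian kernel density of fixation positions over the stimulus grid.

    Returns ``(density, x_centers, y_centers)`` with density of shape
    ``grid_shape`` (rows = y, columns = x) normalized to sum to 1 over the
    grid, so cell values are probability mass per cell.
    """
    pts = np.vstack([seq.xy for seq in sequences])
    ny, nx = grid_shape
    x_centers = (np.arange(nx) + 0.5) * layout.screen_w_px / nx
    y_centers = (np.arange(ny) + 0.5) * layout.screen_h_px / ny
    gx, gy = np.meshgrid(x_centers, y_centers)
    density = np.zeros((ny, nx))
    inv2b2 = 1.0 / (2.0 * bandwidth_px ** 2)
    for px, py in pts:
        density += np.exp(-((gx - px) ** 2 + (gy - py) ** 2) * inv2b2)
    total = density.sum()
    if total > 0:
        density /= total
    return density, x_centers, y_centers
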