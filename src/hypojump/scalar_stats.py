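"""Gated paired comparisons and the averaged-SD Hedges effect size.

Each scalar metric is compared between a baseline jump and a probe jump
(Early Adaptation, Late Adaptation, POST, Washout) with a two-tailed paired
t-test, unless Shapiro-Wilk (on the paired differences) or Levene
(median-centered, on the two condition vectors) rejects its assumption at
.05, in which case a Wilcoxon signed-rank test substitutes. Effect sizes
use Hedges g_av: the mean paired difference standardized by the average of
the two condition standard deviations, with the small-sample correction
J = 1 - 3 / (4(n-1) - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

GATE_ALPHA = 0.05


@dataclass
class PairedComparison:
    metric: str
    timepoint: str
    n: int
    test_used: str  # "t" | "wilcoxon"
    statistic: float  # t statistic (t path) or W (wilcoxon path)
    z: float | None  # normal-approximation z for the wilcoxon path
    df: int | None
    p: float
    g_av: float
    shapiro_p: float | None = None
    levene_p: float | None = None
    degenerate: bool = False


def hedges_g_av(x: np.ndarray, y: np.ndarray, signed: bool = False) -> float:
    """Hedges g_av for paired samples.

    d_av = mean(x - y) / ((sd(x) + sd(y)) / 2), corrected by
    J = 1 - 3/(4(n-1) - 1). Reported as a magnitude by default (the signed
    value is available with ``signed=True``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or n != y.size:
        raise ValueError("need paired vectors of length >= 3")
    sd_sum = x.std(ddof=1) + y.std(ddof=1)
    if sd_sum == 0:
        warnings.warn("zero pooled SD: effect size undefined", stacklevel=2)
        return float("nan")
    d_av = float(np.mean(x - y) / (sd_sum / 2.0))
    j = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
    g = d_av * j
    return g if signed else abs(g)


def _wilcoxon_z(d: np.ndarray) -> tuple[float, float]:
    """Signed-rank statistic W+ and its continuity-corrected normal z."""
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    # tie correction
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    if sigma == 0:
        return w_plus, 0.0
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sigma
    return w_plus, float(z)


def paired_compare(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    metric: str = "",
    timepoint: str = "",
    shapiro_on: str = "diff",
) -> PairedComparison:
    """Compare paired vectors with the normality/variance-gated test battery."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3 or n != y.size:
        raise ValueError("need pairwise-complete vectors of length >= 3")
    d = x - y

    if np.all(d == 0):
        return PairedComparison(
            metric, timepoint, n, "t", 0.0, None, n - 1, 1.0,
            hedges_g_av(x, y) if (x.std(ddof=1) + y.std(ddof=1)) > 0 else float("nan"),
            degenerate=True,
        )
    if d.std(ddof=1) == 0:
        # constant nonzero shift: the paired test is exact in the limit
        return PairedComparison(
            metric, timepoint, n, "t", float("inf") * np.sign(d.mean()), None, n - 1, 0.0,
            hedges_g_av(x, y), degenerate=True,
        )

    sw_p = float(stats.shapiro(d if shapiro_on == "diff" else np.concatenate([x, y])).pvalue)
    lev_p = float(stats.levene(x, y, center="median").pvalue)

    if sw_p > GATE_ALPHA and lev_p > GATE_ALPHA:
        res = stats.ttest_rel(x, y)
        return PairedComparison(
            metric, timepoint, n, "t", float(res.statistic), None, n - 1,
            float(res.pvalue), hedges_g_av(x, y), shapiro_p=sw_p, levene_p=lev_p,
        )

    nz = int(np.count_nonzero(d))
    method = "exact" if nz <= 25 else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = stats.wilcoxon(x, y, zero_method="wilcox", method=method)
        except ValueError:
            res = stats.wilcoxon(x, y, zero_method="wilcox", method="approx")
    w_plus, z = _wilcoxon_z(d)
    return PairedComparison(
        metric, timepoint, n, "wilcoxon", w_plus, z, None, float(res.pvalue),
        hedges_g_av(x, y), shapiro_p=sw_p, levene_p=lev_p,
    )
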