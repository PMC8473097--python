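"""Device-comparison statistics and a-priori sample-size computation.

Given paired gait-parameter measurements from two devices (e.g. a LiDAR
system against a pressure-sensitive walkway), this module provides:

* paired two-sided t-tests with Bonferroni adjustment, mean difference with
  confidence interval, and RMSE;
* agreement metrics: Pearson r, regression-based R² (B regressed on A, so
  it is not forced to equal r²), and the intraclass correlation from the
  two-way ANOVA mean squares — both the consistency form
  ICC(3,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E) and the single-measure
  agreement form, reported side by side;
* Bland–Altman bias and limits of agreement (bias ± 1.96·sd of differences);
* the minimum number of study participants from a two-sided paired-t power
  analysis (noncentral-t iteration, with the normal-approximation closed
  form ((z_{1−α/2} + z_{1−β}) / d)² available as a cross-check).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PairedSeries:
    """Paired values of one gait parameter from two devices."""

    name: str
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if len(self.a) != len(self.b):
            raise ValueError("paired series must have equal lengths")

    def __len__(self) -> int:
        return len(self.a)


@dataclass(frozen=True)
class PowerSpec:
    """Design of the a-priori sample-size computation."""

    effect_size: float = 0.3
    alpha: float = 0.01
    power: float = 0.99
    walks_per_participant: int = 7
    legs: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.power < 1 and self.effect_size > 0):
            raise ValueError("invalid power specification")

    @property
    def obs_per_participant(self) -> int:
        return self.walks_per_participant * self.legs


def paired_comparison(series: PairedSeries, m_comparisons: int = 1,
                      alpha: float = 0.01) -> dict:
    """Two-sided paired t-test with Bonferroni-adjusted p, CI of the mean
    difference, and RMSE.  Zero-variance differences are reported as exact
    equality (p_adj = 1 by convention, flagged)."""
    if len(series) < 3:
        raise ValueError("need at least 3 pairs")
    d = series.a - series.b
    n = len(d)
    mean_diff = float(d.mean())
    rmse = float(np.sqrt((d**2).mean()))
    sd = d.std(ddof=1)
    if sd == 0:
        return {"parameter": series.name, "n": n, "mean_diff": mean_diff,
                "ci": (mean_diff, mean_diff), "p_adj": 1.0, "rmse": rmse,
                "exact_equality": mean_diff == 0.0}
    t_res = stats.ttest_rel(series.a, series.b)
    p_adj = min(1.0, m_comparisons * t_res.pvalue)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    half = tcrit * sd / math.sqrt(n)
    return {"parameter": series.name, "n": n, "mean_diff": mean_diff,
            "ci": (mean_diff - half, mean_diff + half),
            "p_adj": float(p_adj), "rmse": rmse, "exact_equality": False}


def icc_two_way(ratings: np.ndarray) -> dict[str, float]:
    """Single-measure ICC from the two-way ANOVA mean squares.

    ``ratings`` is (n targets, k raters).  Returns the consistency form
    ICC(3,1) and the agreement form (which additionally penalizes rater
    mean offsets)."""
    x = np.asarray(ratings, dtype=float)
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 targets and 2 raters")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    consistency = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    agreement = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e))
    return {"icc3_consistency": float(consistency), "icc3_agreement": float(agreement)}


def agreement_metrics(series: PairedSeries) -> dict:
    """Pearson r, regression R² (b on a), and two-rater ICC forms."""
    if len(series) < 3:
        raise ValueError("need at least 3 pairs")
    a, b = series.a, series.b
    if a.std() == 0 or b.std() == 0:
        return {"parameter": series.name, "r": None, "r2": None,
                "icc3_consistency": None, "icc3_agreement": None,
                "reason": "zero variance"}
    r = float(stats.pearsonr(a, b).statistic)
    slope, intercept = np.polyfit(a, b, 1)
    resid = b - (slope * a + intercept)
    r2 = float(1.0 - (resid**2).sum() / ((b - b.mean()) ** 2).sum())
    icc = icc_two_way(np.column_stack([a, b]))
    return {"parameter": series.name, "r": r, "r2": r2, **icc}


def bland_altman(series: PairedSeries) -> dict:
    """Bias and limits of agreement; the per-pair means/differences are
    returned as plotting payload (rendering is up to the caller)."""
    if len(series) < 3:
        raise ValueError("need at least 3 pairs")
    d = series.a - series.b
    m = (series.a + series.b) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {"parameter": series.name, "bias": bias,
            "loa_low": bias - 1.96 * sd, "loa_high": bias + 1.96 * sd,
            "means": m, "differences": d}


# -- sample size -------------------------------------------------------------


def _paired_t_power(n: int, d: float, alpha: float) -> float:
    """Power of the two-sided one-sample/paired t-test at n observations."""
    df = n - 1
    tcrit = stats.t.isf(alpha / 2.0, df)
    nc = d * math.sqrt(n)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def required_observations(d: float, alpha: float, power: float,
                          method: str = "nct") -> int:
    """Smallest total number of paired observations achieving the target
    power for a two-sided paired t-test at effect size ``d``."""
    if method not in ("nct", "normal"):
        raise ValueError("method must be 'nct' or 'normal'")
    z = stats.norm.isf(alpha / 2.0) + stats.norm.isf(1.0 - power)
    n_normal = int(math.ceil((z / d) ** 2))
    if method == "normal":
        return n_normal
    n = max(3, n_normal - 10)
    while _paired_t_power(n, d, alpha) < power:
        n += 1
        if n > 10 * n_normal + 1000:
            raise ValueError("target power unreachable")
    # walk back in case the start already exceeded the requirement
    while n > 3 and _paired_t_power(n - 1, d, alpha) >= power:
        n -= 1
    return n


def required_participants(spec: PowerSpec = PowerSpec(), method: str = "nct") -> int:
    """Minimum participants: ceil of required observations over the
    observations contributed per participant (legs × walks)."""
    n_obs = required_observations(spec.effect_size, spec.alpha, spec.power, method)
    return int(math.ceil(n_obs / spec.obs_per_participant))


def compare_devices(a: pd.DataFrame, b: pd.DataFrame, on: str = "parameter",
                    value: str = "value", alpha: float = 0.01) -> pd.DataFrame:
    """Full comparison report for two long-format parameter tables.

    Rows are matched on ``on`` + event order; one output row per parameter
    with t-test, agreement and Bland–Altman summaries; Bonferroni m is the
    number of parameters compared."""
    params = sorted(set(a[on]) & set(b[on]))
    m = len(params)
    rows = []
    for p in params:
        va = a.loc[a[on] == p, value].to_numpy()
        vb = b.loc[b[on] == p, value].to_numpy()
        k = min(len(va), len(vb))
        if k < 3:
            continue
        s = PairedSeries(p, va[:k], vb[:k])
        row = paired_comparison(s, m_comparisons=m, alpha=alpha)
        row.update({k2: v for k2, v in agreement_metrics(s).items() if k2 != "parameter"})
        ba = bland_altman(s)
        row.update({"bias": ba["bias"], "loa_low": ba["loa_low"], "loa_high": ba["loa_high"]})
        rows.append(row)
    return pd.DataFrame(rows)
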