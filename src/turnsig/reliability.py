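"""Robustness and test-retest reliability statistics for turn metrics.

Two analyses accompany the signature extraction:

* a paced-condition comparison — per-participant metric means at normal vs
  fast pace, tested with a two-sided Wilcoxon signed-rank test; and
* test-retest reliability over the repeated trials — a two-way random-
  effects, absolute-agreement, average-measures intraclass correlation,
  ICC(2,k), with its F-based 95% confidence interval and the standard error
  of measurement SEM = SD * sqrt(1 - ICC).

ICC interpretation bands: poor < 0.50, moderate [0.50, 0.75), good
[0.75, 0.90), excellent [0.90, 1.00]; negative estimates are labelled poor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReliabilityResult",
    "paired_wilcoxon",
    "icc_2k",
    "interpret_icc",
    "velocity_effect_report",
    "reliability_report",
]

_SIGNATURE_METRICS = [
    "H2Tmax", "D1", "D2", "t01", "t02", "tbar1", "tbar2", "s1", "s2",
]
_TRADITIONAL_METRICS = ["NbSteps", "turnvel_mean", "turnvel_max"]


@dataclass
class ReliabilityResult:
    icc: float
    ci95: tuple[float, float]
    sem: float
    category: str
    n: int
    k: int
    degenerate: bool = False


def paired_wilcoxon(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-participant means.

    Zero differences are discarded (classic Wilcoxon convention).  The exact
    null distribution is used for n <= 25 tie-free pairs; otherwise the
    normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0.0]
    if len(d) == 0:
        warnings.warn("all paired differences are zero", stacklevel=2)
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    has_ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        d,
        zero_method="wilcox",
        alternative="two-sided",
        correction=(method == "approx"),
        method=method,
    )
    del ranks
    return float(res.statistic), float(res.pvalue)


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way (participants x trials) ANOVA mean squares (MSR, MSC, MSE)."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_2k(matrix, alpha: float = 0.05) -> ReliabilityResult:
    """ICC(2,k): two-way random effects, absolute agreement, average measures.

    ``matrix`` is participants x trials (rows x columns); rows containing
    missing values are dropped listwise.  The 95% CI follows the F-based
    interval for absolute-agreement average measures (Satterthwaite degrees
    of freedom); SEM is the pooled SD of all retained cells times
    sqrt(1 - ICC).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D (participants x trials)")
    keep = ~np.isnan(x).any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"listwise deletion dropped {dropped} participant(s)",
                      stacklevel=2)
    x = x[keep]
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 participants and 2 trials")

    if np.allclose(x, x.flat[0]):
        return ReliabilityResult(np.nan, (np.nan, np.nan), 0.0,
                                 "degenerate", n, k, degenerate=True)

    msr, msc, mse = _anova_mean_squares(x)
    denom = msr + (msc - mse) / n
    if denom == 0:
        return ReliabilityResult(np.nan, (np.nan, np.nan), np.nan,
                                 "degenerate", n, k, degenerate=True)
    icc_k = (msr - mse) / denom

    # single-measures point estimate feeds the CI transformation
    icc_1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if 1.0 - icc_1 < 1e-12:  # perfect agreement: interval collapses
        sd = float(np.std(x, ddof=1))
        return ReliabilityResult(
            float(icc_k), (float(icc_k), float(icc_k)),
            sd * np.sqrt(max(0.0, 1.0 - icc_k)),
            interpret_icc(icc_k), n, k,
        )
    a = (k * icc_1) / (n * (1.0 - icc_1))
    b = 1.0 + (k * icc_1 * (n - 1.0)) / (n * (1.0 - icc_1))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    )
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lo1 = (n * (msr - f_l * mse)) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    up1 = (n * (f_u * msr - mse)) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    lo_k = lo1 * k / (1.0 + (k - 1.0) * lo1)
    up_k = up1 * k / (1.0 + (k - 1.0) * up1)

    sd = float(np.std(x, ddof=1))
    sem = sd * np.sqrt(max(0.0, 1.0 - icc_k))
    return ReliabilityResult(
        float(icc_k), (float(lo_k), float(up_k)), float(sem),
        interpret_icc(icc_k), n, k,
    )


def interpret_icc(icc: float) -> str:
    """Reliability band for an ICC estimate.

    Half-open bands: poor [−inf, 0.50), moderate [0.50, 0.75),
    good [0.75, 0.90), excellent [0.90, 1.00]; negative values are poor.
    """
    if not np.isfinite(icc):
        raise ValueError("non-finite ICC")
    if icc < 0.50:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.90:
        return "good"
    return "excellent"


def _per_participant_pace_means(df: pd.DataFrame, metrics: list[str]) -> pd.DataFrame:
    return (
        df.groupby(["participant_id", "pace"])[metrics].mean().reset_index()
    )


def velocity_effect_report(
    metrics_df: pd.DataFrame,
    metrics: list[str] | None = None,
    qc_filter: bool = True,
) -> pd.DataFrame:
    """Pace-robustness table: per-pace mean +/- SD across participants and the
    Wilcoxon signed-rank p-value (normal vs fast), one row per metric.
    """
    if metrics is None:
        metrics = [
            m for m in _SIGNATURE_METRICS + _TRADITIONAL_METRICS
            if m in metrics_df.columns
        ]
    df = metrics_df
    if qc_filter and "qc_pass" in df.columns:
        df = df[df["qc_pass"].astype(bool)]
    means = _per_participant_pace_means(df, metrics)
    wide = means.pivot(index="participant_id", columns="pace", values=metrics)
    rows = []
    for m in metrics:
        sub = wide[m].dropna()
        normal, fast = sub["normal"].to_numpy(), sub["fast"].to_numpy()
        stat, p = paired_wilcoxon(normal, fast)
        rows.append(
            {
                "metric": m,
                "normal_mean": normal.mean(),
                "normal_sd": normal.std(ddof=1),
                "fast_mean": fast.mean(),
                "fast_sd": fast.std(ddof=1),
                "wilcoxon_stat": stat,
                "p_value": p,
                "significant": p < 0.05,
                "n": len(sub),
            }
        )
    return pd.DataFrame(rows)


def reliability_report(
    metrics_df: pd.DataFrame,
    metrics: list[str] | None = None,
    qc_filter: bool = True,
) -> pd.DataFrame:
    """ICC(2,k) reliability table over the repeated trials of each metric."""
    if metrics is None:
        metrics = [
            m for m in _SIGNATURE_METRICS + _TRADITIONAL_METRICS
            if m in metrics_df.columns
        ]
    df = metrics_df
    if qc_filter and "qc_pass" in df.columns:
        df = df[df["qc_pass"].astype(bool)]
    rows = []
    for m in metrics:
        mat = df.pivot_table(
            index="participant_id", columns="trial_id", values=m
        )
        res = icc_2k(mat.to_numpy())
        rows.append(
            {
                "metric": m,
                "ICC": res.icc,
                "ci95_lo": res.ci95[0],
                "ci95_hi": res.ci95[1],
                "SEM": res.sem,
                "category": res.category,
                "n": res.n,
                "k": res.k,
            }
        )
    return pd.DataFrame(rows)
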