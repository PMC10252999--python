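"""Statistical comparison layer: ANOVA + Tukey HSD, Kruskal-Wallis on Likert
ratings, median (IQR) summaries, and two-way random-effects ICC.

Group comparisons of the continuous metrics (attenuation, noise, CNR,
sharpness) use one-way ANOVA with Tukey HSD post hoc tests; ordinal Likert
ratings are compared with tie-corrected Kruskal-Wallis tests and summarised
as median (IQR). Inter-reader agreement is the single-measure,
absolute-agreement intraclass correlation ICC(2,1), interpreted with the
conventional bins: <0.2 poor, 0.2-0.4 fair, 0.4-0.6 moderate, 0.6-0.8
substantial, >0.8 excellent (boundary values fall into the lower bin).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    """Outcome of a group-comparison test.

    ``degenerate`` marks inputs on which the statistic is undefined (e.g.
    zero variance within and across groups); the p-value is then reported
    as 1.0 — no evidence of a difference — rather than propagating NaN.
    """

    method: str
    statistic: float
    p_value: float
    df: tuple[int, ...] = ()
    group_sizes: tuple[int, ...] = ()
    posthoc: pd.DataFrame | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class ICCResult:
    """Intraclass correlation with its qualitative agreement label."""

    icc: float
    model: str
    interpretation: str


_ICC_BINS = (
    (0.2, "poor"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
)


def interpret_icc(icc: float) -> str:
    """Agreement label for an ICC value; boundaries go to the lower bin."""
    for upper, label in _ICC_BINS:
        if icc <= upper:
            return label
    return "excellent"


def _as_groups(groups) -> tuple[list[str], list[np.ndarray]]:
    if isinstance(groups, Mapping):
        labels = [str(k) for k in groups]
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        labels = [str(i) for i in range(len(groups))]
        arrays = [np.asarray(v, dtype=float) for v in groups]
    return labels, arrays


def anova_oneway_posthoc(groups, posthoc: bool = True) -> TestResult:
    """One-way ANOVA across groups, with Tukey HSD pairwise post hoc tests.

    ``groups`` is a mapping label -> values or a sequence of value arrays;
    every group needs at least two observations. When all observations are
    identical the F ratio is 0/0; the result is flagged degenerate instead.
    """
    labels, arrays = _as_groups(groups)
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for lab, arr in zip(labels, arrays):
        if arr.size < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 observations")
    allv = np.concatenate(arrays)
    n, k = allv.size, len(arrays)
    if np.ptp(allv) == 0:
        return TestResult(
            method="one-way ANOVA (degenerate: zero variance)",
            statistic=0.0, p_value=1.0, df=(k - 1, n - k),
            group_sizes=tuple(a.size for a in arrays), degenerate=True,
        )
    f, p = sps.f_oneway(*arrays)
    ph = None
    if posthoc:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        codes = np.concatenate(
            [np.full(a.size, lab, dtype=object) for lab, a in zip(labels, arrays)]
        )
        res = pairwise_tukeyhsd(allv, codes)
        ph = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    return TestResult(
        method="one-way ANOVA + Tukey HSD",
        statistic=float(f), p_value=float(p), df=(k - 1, n - k),
        group_sizes=tuple(a.size for a in arrays), posthoc=ph,
    )


def kruskal_wallis(groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test with chi-square asymptotic p.

    Heavily tied ordinal data (Likert scores) are the intended input; when
    every observation is identical the test reports H = 0, p = 1.
    """
    labels, arrays = _as_groups(groups)
    if len(arrays) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    for lab, arr in zip(labels, arrays):
        if arr.size < 1:
            raise ValueError(f"group {lab!r} is empty")
    allv = np.concatenate(arrays)
    sizes = tuple(a.size for a in arrays)
    if np.ptp(allv) == 0:
        return TestResult(
            method="Kruskal-Wallis (all values identical)",
            statistic=0.0, p_value=1.0, df=(len(arrays) - 1,),
            group_sizes=sizes,
        )
    h, p = sps.kruskal(*arrays)
    return TestResult(
        method="Kruskal-Wallis", statistic=float(h), p_value=float(p),
        df=(len(arrays) - 1,), group_sizes=sizes,
    )


def icc_absolute_agreement(ratings) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an (n_targets, k_raters) array-like (k >= 2) or a wide
    DataFrame with one column per rater. Computed from the two-way
    mean-squares decomposition:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    A table with no variability anywhere (all raters identical on all
    targets, zero spread) is perfect agreement and reports ICC = 1.
    """
    x = np.asarray(ratings, dtype=float)
    if isinstance(ratings, pd.DataFrame):
        x = ratings.to_numpy(dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("ratings must be a 2D (targets x raters>=2) table")
    n, k = x.shape
    if n < 2:
        raise ValueError("ICC needs at least 2 rated targets")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        icc = 1.0 if abs(msr - mse) == 0 else np.nan
    else:
        icc = float((msr - mse) / denom)
    return ICCResult(
        icc=icc,
        model="ICC(2,1) two-way random, absolute agreement, single measure",
        interpretation=interpret_icc(icc),
    )


def _fmt_num(v: float) -> str:
    return f"{v:g}"


def likert_summary(
    scores: pd.DataFrame,
    by: Sequence[str] = ("family",),
    value_col: str = "score",
) -> pd.DataFrame:
    """Median (IQR) summary of Likert scores per group.

    Quantiles use linear interpolation (the common type-7 rule), and the
    formatted column renders e.g. ``"5 (4-5)"``. Groups listed in the data
    but empty after NaN removal are reported as ``"missing"``.
    """
    rows = []
    for key, g in scores.groupby(list(by), sort=False):
        key = key if isinstance(key, tuple) else (key,)
        vals = g[value_col].dropna().to_numpy(dtype=float)
        row = dict(zip(by, key))
        if vals.size == 0:
            row.update(median=np.nan, q1=np.nan, q3=np.nan, formatted="missing")
        else:
            med = float(np.percentile(vals, 50))
            q1 = float(np.percentile(vals, 25))
            q3 = float(np.percentile(vals, 75))
            row.update(
                median=med, q1=q1, q3=q3,
                formatted=f"{_fmt_num(med)} ({_fmt_num(q1)}–{_fmt_num(q3)})",
            )
        rows.append(row)
    return pd.DataFrame(rows)
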