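"""Method-comparison statistics: Bland-Altman, ICC(A,1), repeated-measures
ANOVA and Holm-Sidak-corrected post-hoc tests against a control condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ParameterError, UndefinedICCError

#: qualitative reliability bands for a single-measurement ICC; closed lower
#: bounds (0.50 <= ICC < 0.75 is "moderate", etc.)
ICC_BANDS = ((0.50, "poor"), (0.75, "moderate"), (0.90, "good"),
             (np.inf, "excellent"))


@dataclass
class AgreementResult:
    """Bland-Altman bias and 95% limits of agreement."""

    n: int
    bias: float  # mean of (reference - degraded)
    sd: float  # sample SD of the differences (n - 1)
    loa_low: float
    loa_high: float
    multiplier: float = 1.96
    means: np.ndarray | None = None  # (ref + deg) / 2, for plotting/export
    differences: np.ndarray | None = None
    per_subject: pd.DataFrame | None = None

    @property
    def loa_width(self) -> float:
        return self.loa_high - self.loa_low


@dataclass
class ICCResult:
    """Single-measurement absolute-agreement intraclass correlation."""

    icc: float
    msr: float  # rows (strides) mean square
    msc: float  # columns (systems) mean square
    mse: float  # error mean square
    n: int  # rows
    k: int  # columns
    band: str = ""

    def __post_init__(self) -> None:
        if not self.band:
            for bound, name in ICC_BANDS:
                if self.icc < bound:
                    self.band = name
                    break


@dataclass
class AnovaResult:
    """One-way repeated-measures ANOVA with optional post-hoc table."""

    f_statistic: float
    df_condition: int
    df_error: int
    p_value: float
    posthoc: pd.DataFrame | None = None  # condition, p_raw, p_adj, significant
    alpha: float = 0.05
    notices: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def bland_altman(
    reference,
    degraded,
    subjects=None,
    multiplier: float = 1.96,
    keep_arrays: bool = True,
) -> AgreementResult:
    """Bland-Altman agreement of paired measurements.

    Differences are reference minus degraded; the limits of agreement are
    ``bias +/- multiplier * SD`` with the sample (n-1) standard deviation.
    With ``subjects`` given, per-subject mean differences are tabulated to
    expose participant-specific bias clustering.
    """
    reference = np.asarray(reference, dtype=float)
    degraded = np.asarray(degraded, dtype=float)
    if reference.shape != degraded.shape:
        raise ParameterError("paired arrays must have equal shape")
    if reference.size < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 pairs")
    diffs = reference - degraded
    means = 0.5 * (reference + degraded)
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    per_subject = None
    if subjects is not None:
        per_subject = (
            pd.DataFrame({"subject": np.asarray(subjects), "diff": diffs})
            .groupby("subject")["diff"].agg(["mean", "std", "count"])
            .reset_index()
            .rename(columns={"mean": "bias", "std": "sd", "count": "n"}))
    return AgreementResult(
        n=int(reference.size), bias=bias, sd=sd,
        loa_low=bias - multiplier * sd, loa_high=bias + multiplier * sd,
        multiplier=multiplier,
        means=means if keep_arrays else None,
        differences=diffs if keep_arrays else None,
        per_subject=per_subject)


def icc_a1(matrix) -> ICCResult:
    """ICC(A,1): two-way, absolute agreement, single measurement.

    ``matrix`` is (n rows x k columns) with rows the subjects of measurement
    (here individual strides) and columns the raters (here the two systems)::

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))

    computed from the two-way ANOVA mean squares.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ParameterError("ICC needs an (n, k>=2) matrix")
    n, k = x.shape
    if n < 3:
        raise InsufficientDataError("ICC needs at least 3 rows")
    if not np.all(np.isfinite(x)):
        raise ParameterError("ICC matrix contains missing values")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(np.sum((x - grand) ** 2))
    if ss_total <= 0:
        raise UndefinedICCError("zero total variance; ICC undefined")
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    return ICCResult(icc=float(icc), msr=msr, msc=msc, mse=mse, n=n, k=k)


def rm_anova(table) -> AnovaResult:
    """One-way repeated-measures ANOVA on a complete subjects x conditions table.

    ``F = MS_condition / MS_(subject x condition)`` with
    ``(c-1, (c-1)(s-1))`` degrees of freedom.  Missing cells raise (no
    imputation).
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ParameterError("table must be 2-D (subjects x conditions)")
    s, c = x.shape
    if s < 2 or c < 2:
        raise InsufficientDataError(
            "repeated-measures ANOVA needs >= 2 subjects and >= 2 conditions")
    if not np.all(np.isfinite(x)):
        raise ParameterError("table contains missing cells")
    grand = x.mean()
    ss_cond = s * float(np.sum((x.mean(axis=0) - grand) ** 2))
    ss_subj = c * float(np.sum((x.mean(axis=1) - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_err = max(ss_total - ss_cond - ss_subj, 0.0)
    df1 = c - 1
    df2 = (c - 1) * (s - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err == 0.0:
        f = 0.0 if ms_cond == 0.0 else np.inf
        p = 1.0 if ms_cond == 0.0 else 0.0
    else:
        f = ms_cond / ms_err
        p = float(stats.f.sf(f, df1, df2))
    return AnovaResult(f_statistic=float(f), df_condition=df1, df_error=df2,
                       p_value=p)


def holm_sidak(p_values) -> np.ndarray:
    """Holm-Sidak step-down adjustment of raw p-values.

    Sorted ascending, ``p_(i)`` becomes ``1 - (1 - p_(i))^(k - i + 1)``; a
    running maximum enforces monotonicity; values are returned in the
    original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    k = p.size
    adj_sorted = 1.0 - (1.0 - p[order]) ** (k - np.arange(k))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty_like(p)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def posthoc_vs_control(
    table: pd.DataFrame, control: str = "normal", alpha: float = 0.05
) -> pd.DataFrame:
    """Paired t-tests of each condition against the control, Holm-Sidak adjusted.

    ``table`` has subjects as rows and condition labels as columns (subject
    level means).  Returns a frame with raw and adjusted p per non-control
    condition and significance flags at ``alpha``.
    """
    if control not in table.columns:
        raise ParameterError(f"control condition '{control}' not in table")
    others = [c for c in table.columns if c != control]
    raw = []
    for cond in others:
        res = stats.ttest_rel(table[cond].to_numpy(),
                              table[control].to_numpy())
        raw.append(float(res.pvalue))
    adj = holm_sidak(raw)
    return pd.DataFrame({
        "condition": others,
        "p_raw": raw,
        "p_adj": adj,
        "significant": adj < alpha,
    })


def rm_anova_with_posthoc(
    table: pd.DataFrame, control: str = "normal", alpha: float = 0.05
) -> AnovaResult:
    """Omnibus repeated-measures ANOVA plus control-referenced post-hoc tests."""
    res = rm_anova(table.to_numpy())
    res.alpha = alpha
    res.posthoc = posthoc_vs_control(table, control=control, alpha=alpha)
    return res
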