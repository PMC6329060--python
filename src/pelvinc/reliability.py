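"""Reliability statistics: ANOVA-based ICCs and cohort comparisons.

Interobserver agreement is the two-way random-effects, absolute-agreement,
single-measurement ICC(2,1); intraobserver consistency is the two-way
mixed-effects, consistency, single-measurement ICC(3,1) over one rater's
sessions (Shrout-Fleiss conventions). Confidence intervals follow McGraw &
Wong (F-based).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RatingsTable:
    """Complete crossed design: subjects x raters x sessions (degrees)."""

    values: np.ndarray  # (n_subjects, n_raters, n_sessions)
    subjects: list | None = None
    raters: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        if self.values.ndim != 3:
            raise ValueError("ratings must be subjects x raters x sessions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ratings contain missing or non-finite cells")
        n, k, s = self.values.shape
        if self.subjects is None:
            self.subjects = list(range(n))
        if self.raters is None:
            self.raters = list(range(k))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]

    @property
    def n_sessions(self) -> int:
        return self.values.shape[2]

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "RatingsTable":
        """Build from long format with columns subject, rater, session, pi_deg."""
        required = {"subject", "rater", "session", "pi_deg"}
        if not required.issubset(df.columns):
            raise ValueError(f"long table needs columns {sorted(required)}")
        wide = df.pivot_table(
            index="subject", columns=["rater", "session"], values="pi_deg"
        )
        if wide.isna().any().any():
            raise ValueError("incomplete crossed design: missing cells")
        subjects = list(wide.index)
        raters = sorted(df["rater"].unique())
        sessions = sorted(df["session"].unique())
        arr = np.empty((len(subjects), len(raters), len(sessions)))
        for j, r in enumerate(raters):
            for s, ses in enumerate(sessions):
                arr[:, j, s] = wide[(r, ses)].to_numpy()
        return cls(values=arr, subjects=subjects, raters=raters)

    @classmethod
    def from_csv(cls, path: str) -> "RatingsTable":
        return cls.from_long(pd.read_csv(path))


@dataclass
class ICCResult:
    estimate: float
    ci95: tuple[float, float]
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    n_raters: int
    degenerate: bool = False


def _mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """Two-way crossed ANOVA mean squares: rows (subjects), cols, residual."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    resid = data - row_means[:, None] - col_means[None, :] + grand
    ss_err = float((resid**2).sum())
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def icc_interobserver(table: RatingsTable, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    Sessions, if present, are averaged per rater first. All raters giving
    identical values on varying subjects is treated as perfect agreement
    (ICC = 1) rather than an ANOVA degeneracy.
    """
    if table.n_raters < 2:
        raise ValueError("interobserver ICC needs at least 2 raters")
    if table.n_subjects < 5:
        raise ValueError("interobserver ICC needs at least 5 subjects")
    data = table.values.mean(axis=2)
    n, k = data.shape
    msr, msc, mse = _mean_squares(data)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or np.ptp(data) == 0:
        return ICCResult(1.0, (1.0, 1.0), msr, msc, mse, n, k, degenerate=True)
    icc = (msr - mse) / denom
    if mse == 0 and msc == 0:
        return ICCResult(1.0, (1.0, 1.0), msr, msc, mse, n, k, degenerate=True)

    # McGraw & Wong F-based interval for ICC(A,1)
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and mse > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        fj = msr / mse
        lower = n * (fj - f1) / (f1 * (k * msc / mse + (k * n - k - n)) + n * fj)
        upper = n * (f2 * fj - 1) / (k * msc / mse + (k * n - k - n) + n * f2 * fj)
        ci = (float(np.clip(lower, -1, 1)), float(np.clip(upper, -1, 1)))
    else:
        ci = (1.0, 1.0)
    return ICCResult(float(icc), ci, msr, msc, mse, n, k)


def icc_intraobserver(table: RatingsTable, rater, alpha: float = 0.05) -> ICCResult:
    """ICC(3,1): two-way mixed effects, consistency, single measurement,
    over one rater's repeated sessions."""
    if rater not in table.raters:
        raise ValueError(f"unknown rater {rater!r}; available: {table.raters}")
    j = table.raters.index(rater)
    data = table.values[:, j, :]
    if data.shape[1] < 2:
        raise ValueError("intraobserver ICC needs at least 2 sessions")
    n, k = data.shape
    msr, msc, mse = _mean_squares(data)
    denom = msr + (k - 1) * mse
    if denom <= 0 or mse == 0:
        return ICCResult(1.0, (1.0, 1.0), msr, msc, mse, n, k, degenerate=True)
    icc = (msr - mse) / denom
    f = msr / mse
    fl = f / stats.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
    fu = f * stats.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
    ci = (
        float(np.clip((fl - 1) / (fl + k - 1), -1, 1)),
        float(np.clip((fu - 1) / (fu + k - 1), -1, 1)),
    )
    return ICCResult(float(icc), ci, msr, msc, mse, n, k)


def intraobserver_summary(table: RatingsTable, alpha: float = 0.05) -> dict:
    """Per-rater ICC(3,1) plus their mean as a single pooled figure."""
    per_rater = {r: icc_intraobserver(table, r, alpha) for r in table.raters}
    estimates = [res.estimate for res in per_rater.values()]
    return {
        "per_rater": per_rater,
        "mean": float(np.mean(estimates)),
        "range": (float(np.min(estimates)), float(np.max(estimates))),
    }


def cohort_compare(values_a, values_b, covariate=None, alpha: float = 0.05) -> dict:
    """Two-group comparison: normality, variance homogeneity, then the t test.

    The Levene test chooses between the pooled-variance and separate-variance
    (Welch) t test; normality is a Kolmogorov-Smirnov check against a normal
    with the sample moments. Optionally reports the Pearson correlation of
    the pooled values against ``covariate``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")

    def ks_normal(x):
        sd = x.std(ddof=1)
        if sd == 0:
            return 0.0, 0.0
        res = stats.kstest(x, "norm", args=(x.mean(), sd))
        return float(res.statistic), float(res.pvalue)

    ks_a, ks_b = ks_normal(a), ks_normal(b)
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        levene_p = 1.0
        t_stat, t_p, pooled = 0.0, 1.0, True
    else:
        lev = stats.levene(a, b, center="mean")
        levene_p = float(lev.pvalue)
        pooled = levene_p > alpha
        tt = stats.ttest_ind(a, b, equal_var=pooled)
        t_stat, t_p = float(tt.statistic), float(tt.pvalue)
        if np.isnan(t_stat):  # identical constant groups
            t_stat, t_p = 0.0, 1.0

    report = {
        "n_a": len(a),
        "n_b": len(b),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "sd_a": float(a.std(ddof=1)),
        "sd_b": float(b.std(ddof=1)),
        "ks_normality_a": {"statistic": ks_a[0], "p": ks_a[1]},
        "ks_normality_b": {"statistic": ks_b[0], "p": ks_b[1]},
        "levene_p": levene_p,
        "t_test": {"pooled_variance": pooled, "t": t_stat, "p": t_p},
    }
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        pooled_vals = np.concatenate([a, b])
        if len(cov) != len(pooled_vals):
            raise ValueError("covariate length must equal the pooled sample size")
        r, p = stats.pearsonr(pooled_vals, cov)
        report["pearson"] = {"r": float(r), "p": float(p)}
    return report
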