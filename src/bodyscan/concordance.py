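"""Agreement and reliability statistics for method validation.

Implements the statistics used to validate one measurement method against a
reference: Bland–Altman limits of agreement with confidence intervals,
two-way ANOVA intraclass correlation coefficients (absolute-agreement
ICC(2,1) and consistency ICC(3,1)), the coefficient of variation, and
exhaustive best-subsets linear regression ranked by R-squared / adjusted
R-squared with Mallows' Cp.

All sample standard deviations use the n-1 denominator; the limits of
agreement use the conventional fixed 1.96 multiplier (not adjusted for n).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, InputError, UndefinedStatisticError

__all__ = [
    "AgreementReport",
    "ICCResult",
    "SubsetModel",
    "bland_altman",
    "loa_from_summary",
    "icc",
    "coefficient_of_variation",
    "best_subsets",
    "bland_altman_plot",
]

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementReport:
    """Bland–Altman summary for paired differences ``a - b``."""

    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_mean: tuple
    ci_loa_low: tuple
    ci_loa_high: tuple
    inside_loa_frac: float
    multiplier: float = LOA_MULTIPLIER


@dataclass(frozen=True)
class ICCResult:
    icc_value: float
    ci: tuple
    form: str
    n_subjects: int
    k_raters: int


@dataclass(frozen=True)
class SubsetModel:
    """One candidate regression: a predictor subset and its fit summary."""

    predictor_names: tuple
    coefficients: tuple  # intercept first
    r2: float
    adjusted_r2: float
    mallows_cp: float
    n: int
    p: int  # number of predictors (intercept not counted)


def loa_from_summary(mean_diff: float, sd_diff: float) -> tuple[float, float]:
    """Limits of agreement from a printed mean/SD of differences."""
    if sd_diff < 0:
        raise DomainError("sd_diff must be >= 0")
    half = LOA_MULTIPLIER * sd_diff
    return (mean_diff - half, mean_diff + half)


def bland_altman(a, b) -> AgreementReport:
    """Bland–Altman agreement between two paired measurement series.

    Differences are ``a - b``.  The CI of the mean difference is t-based;
    the CI of each limit of agreement uses the standard large-sample
    standard error ``SD * sqrt(1/n + multiplier^2 / (2 (n-1)))`` with the
    t(n-1) quantile.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("inputs must be equal-length 1-D arrays")
    n = len(a)
    if n < 3:
        raise InputError("need at least 3 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = loa_from_summary(mean, sd)
    tq = float(stats.t.ppf(0.975, n - 1))
    se_mean = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(1.0 / n + LOA_MULTIPLIER**2 / (2.0 * (n - 1)))
    inside = float(np.mean((d >= lo) & (d <= hi)))
    return AgreementReport(
        n=n,
        mean_diff=mean,
        sd_diff=sd,
        loa_low=lo,
        loa_high=hi,
        ci_mean=(mean - tq * se_mean, mean + tq * se_mean),
        ci_loa_low=(lo - tq * se_loa, lo + tq * se_loa),
        ci_loa_high=(hi - tq * se_loa, hi + tq * se_loa),
        inside_loa_frac=inside,
    )


def _anova_mean_squares(x: np.ndarray):
    """Two-way (subjects x raters) ANOVA mean squares without replication."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return ms_rows, ms_cols, ms_err


def icc(ratings, form: str = "ICC(2,1)", alpha: float = 0.05) -> ICCResult:
    """Intraclass correlation of an ``n_subjects x k_raters`` rating grid.

    ``ICC(2,1)``: two-way random effects, absolute agreement, single rating.
    ``ICC(3,1)``: two-way mixed effects, consistency, single rating.
    Confidence intervals follow the F-distribution constructions of the
    standard single-rating forms.  A grid with no variance at all is
    undefined; a grid whose subjects do not vary yields a non-positive ICC
    with a warning.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise InputError("ratings must be a 2-D grid")
    if np.isnan(x).any():
        raise InputError("missing cells are not supported")
    n, k = x.shape
    if n < 3 or k < 2:
        raise InputError("need at least 3 subjects and 2 raters")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("zero total variance; ICC undefined")
    msr, msc, mse = _anova_mean_squares(x)

    if form == "ICC(2,1)":
        value = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        ci = _icc2_ci(msr, msc, mse, n, k, value, alpha)
    elif form == "ICC(3,1)":
        value = (msr - mse) / (msr + (k - 1) * mse)
        f = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
        ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    else:
        raise InputError(f"unknown ICC form '{form}'")
    if value <= 0:
        warnings.warn(
            f"{form} is non-positive ({value:.3f}): subject variance does not "
            "exceed error variance",
            stacklevel=2,
        )
    ci = (min(ci[0], value), max(ci[1], value))
    return ICCResult(float(value), (float(ci[0]), float(ci[1])), form, n, k)


def _icc2_ci(msr, msc, mse, n, k, r, alpha):
    """Satterthwaite-approximate CI for the two-way random, absolute-agreement,
    single-rating ICC (the classic Fleiss–Shrout construction)."""
    a = k * r / (n * (1 - r)) if r < 1 else np.inf
    b = 1 + k * r * (n - 1) / (n * (1 - r)) if r < 1 else np.inf
    if not np.isfinite(a) or not np.isfinite(b):
        return (1.0, 1.0)
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den
    f_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_lo * mse) / (
        f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr
    )
    return (lower, upper)


def coefficient_of_variation(values) -> float:
    """Sample SD (n-1) over mean; dimensionless."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise InputError("need a 1-D sample of at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise UndefinedStatisticError("zero mean; CV undefined")
    return float(x.std(ddof=1) / mean)


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS with intercept; returns (coef, rss, rank)."""
    A = np.column_stack([np.ones(len(y)), X])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return coef, float(resid @ resid), rank


def best_subsets(
    predictors: dict,
    response,
    criterion: str = "adjusted_r2",
    max_size: int | None = None,
) -> list[SubsetModel]:
    """Exhaustive best-subsets OLS over all non-empty predictor subsets.

    *predictors* maps names to 1-D columns.  Each subset is fitted with an
    intercept; rank-deficient subsets are skipped with a warning.  Models are
    ranked by *criterion*: ``"r2"`` (max R-squared per subset size, sizes in
    ascending order of remaining unexplained variance), ``"adjusted_r2"``
    (global ranking), or ``"cp"`` (Mallows' Cp closest to p+1 from below,
    i.e. smallest).  The full model's Cp equals p+1 identically.
    """
    names = list(predictors)
    y = np.asarray(response, dtype=float)
    cols = {m: np.asarray(predictors[m], dtype=float) for m in names}
    for m, c in cols.items():
        if c.shape != y.shape:
            raise InputError(f"predictor '{m}' length differs from response")
    n = len(y)
    p_max = max_size if max_size is not None else len(names)
    if n <= p_max + 1:
        raise InputError("need n > p_max + 1 observations")

    X_full = np.column_stack([cols[m] for m in names])
    _, rss_full, rank_full = _ols(X_full, y)
    if rank_full < len(names) + 1:
        raise InputError("full predictor matrix is rank-deficient")
    mse_full = rss_full / (n - len(names) - 1)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise UndefinedStatisticError("response has zero variance")

    models = []
    for size in range(1, p_max + 1):
        for subset in itertools.combinations(names, size):
            X = np.column_stack([cols[m] for m in subset])
            coef, rss, rank = _ols(X, y)
            if rank < size + 1:
                warnings.warn(f"subset {subset} is rank-deficient; skipped", stacklevel=2)
                continue
            p = size
            r2 = 1.0 - rss / tss
            adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
            cp = rss / mse_full - n + 2 * (p + 1)
            models.append(
                SubsetModel(subset, tuple(coef), r2, adj, cp, n, p)
            )
    if not models:
        raise InputError("every subset was rank-deficient")

    if criterion == "r2":
        models.sort(key=lambda m: (-m.r2, m.p, m.predictor_names))
    elif criterion == "adjusted_r2":
        models.sort(key=lambda m: (-m.adjusted_r2, m.p, m.predictor_names))
    elif criterion == "cp":
        models.sort(key=lambda m: (m.mallows_cp, m.p, m.predictor_names))
    else:
        raise InputError(f"unknown criterion '{criterion}'")
    return models


def bland_altman_plot(report: AgreementReport, a, b, path, title: str | None = None):
    """Scatter of pair means vs differences with bias and LoA lines.

    Rendering is deterministic for fixed inputs.  Returns the written path.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise InputError("need equal-length non-empty pair arrays")
    means = (a + b) / 2.0
    diffs = a - b
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(means, diffs, s=18, color="#32507d", zorder=3)
    for yv, style, lbl in (
        (report.mean_diff, "-", f"bias {report.mean_diff:.3f}"),
        (report.loa_low, "--", f"-{report.multiplier} SD {report.loa_low:.3f}"),
        (report.loa_high, "--", f"+{report.multiplier} SD {report.loa_high:.3f}"),
    ):
        ax.axhline(yv, linestyle=style, color="#9b3333", linewidth=1)
        ax.annotate(lbl, xy=(1.0, yv), xycoords=("axes fraction", "data"),
                    fontsize=8, ha="right", va="bottom")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference between methods")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
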