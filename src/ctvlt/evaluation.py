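"""Agreement statistics between reader VLTs and predicted VLTs.

Implements the validation battery: mean absolute difference with a
t-based confidence interval, intraclass correlation ICC(2,1) (two-way
random effects, absolute agreement, single rater; McGraw & Wong
convention A,1) with an F-based CI, Bland-Altman bias and limits of
agreement, one-way repeated-measures ANOVA across methods with
Bonferroni-corrected paired t post-hocs, and the t-based sample-size
computation for a mean confidence interval of prescribed half-width.

The ICC and repeated-measures F are computed directly from the classical
mean-squares decomposition of the subjects x raters table; this keeps the
simulation-heavy tests fast and is cross-checked against pingouin in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "mean_abs_diff_ci",
    "icc_2_1",
    "bland_altman",
    "rm_anova_posthoc",
    "sample_size_for_mean_ci",
    "preliminary_split_sd",
    "agreement_report",
]


@dataclass(frozen=True)
class AgreementReport:
    """Agreement between one prediction method and the reader reference."""

    method: str
    mean_abs_diff: float
    mad_ci: tuple[float, float]
    icc: float
    icc_ci: tuple[float, float]
    bias: float
    loa_low: float
    loa_high: float
    n: int

    def __post_init__(self) -> None:
        if not self.loa_low <= self.bias <= self.loa_high:
            raise ValueError("limits of agreement must bracket the bias")


def _paired(a, b):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    if a.size < 2:
        raise ValueError("need at least two paired observations")
    return a, b


def mean_abs_diff_ci(a, b, confidence: float = 0.95):
    """Mean of |a - b| with a two-sided t confidence interval."""
    a, b = _paired(a, b)
    d = np.abs(a - b)
    n = d.size
    m = float(d.mean())
    sd = float(d.std(ddof=1))
    half = stats.t.ppf(0.5 + confidence / 2.0, n - 1) * sd / np.sqrt(n)
    return m, (m - half, m + half)


def icc_2_1(ratings: np.ndarray, confidence: float = 0.95):
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is a complete subjects x raters matrix. Returns
    ``(icc, (lo, hi))`` with the F-based confidence interval.
    """
    Y = np.asarray(ratings, dtype=np.float64)
    if Y.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters matrix")
    if np.any(~np.isfinite(Y)):
        raise ValueError("ratings must have no missing cells")
    n, k = Y.shape
    if n < 5 or k < 2:
        raise ValueError("need >= 5 subjects and >= 2 raters")

    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)          # between-subjects
    msc = ss_cols / (k - 1)          # between-raters
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = 1.0 if denom == 0 else float((msr - mse) / denom)

    # McGraw & Wong F-based interval for ICC(A,1)
    alpha = 1.0 - confidence
    if mse == 0 and msc == 0:
        return icc, (1.0, 1.0)
    r = max(min(icc, 1 - 1e-12), -1 + 1e-12)
    a = k * r / (n * (1.0 - r))
    b = 1.0 + k * r * (n - 1) / (n * (1.0 - r))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f1 * mse) / (
        f1 * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2 * msr
    )
    return icc, (float(lower), float(upper))


def bland_altman(a, b):
    """Bias and 95% limits of agreement: bias +/- 1.96 SD of (a - b)."""
    a, b = _paired(a, b)
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


def rm_anova_posthoc(diffs: np.ndarray, alpha: float = 0.05):
    """One-way repeated-measures ANOVA across methods plus post-hocs.

    ``diffs`` is an images x methods matrix (each column one method's
    per-image error). Returns a dict with the F statistic, its p-value,
    and Bonferroni-corrected paired-t p-values per method pair.
    Zero-variance input yields the sentinel (F=0, p=1).
    """
    Y = np.asarray(diffs, dtype=np.float64)
    if Y.ndim != 2 or Y.shape[0] < 3 or Y.shape[1] < 2:
        raise ValueError("need a matrix with >= 3 images and >= 2 methods")
    n, m = Y.shape
    grand = Y.mean()
    ss_subj = m * np.sum((Y.mean(axis=1) - grand) ** 2)
    ss_meth = n * np.sum((Y.mean(axis=0) - grand) ** 2)
    ss_err = np.sum((Y - grand) ** 2) - ss_subj - ss_meth
    df_meth = m - 1
    df_err = (m - 1) * (n - 1)
    ms_meth = ss_meth / df_meth
    ms_err = ss_err / df_err
    if ms_err <= 0:
        f_stat, p = (0.0, 1.0) if ms_meth <= 0 else (np.inf, 0.0)
    else:
        f_stat = float(ms_meth / ms_err)
        p = float(stats.f.sf(f_stat, df_meth, df_err))

    pairs = {}
    n_pairs = m * (m - 1) // 2
    for i in range(m):
        for j in range(i + 1, m):
            d = Y[:, i] - Y[:, j]
            if np.allclose(d.std(ddof=1), 0):
                p_ij = 1.0 if np.allclose(d.mean(), 0) else 0.0
            else:
                p_ij = float(stats.ttest_rel(Y[:, i], Y[:, j]).pvalue)
            pairs[(i, j)] = min(1.0, p_ij * n_pairs)
    return {"F": f_stat, "p": p, "df": (df_meth, df_err), "posthoc": pairs}


def sample_size_for_mean_ci(
    sd: float, half_width: float, confidence: float = 0.95, n_max: int = 10**7
) -> int:
    """Smallest n >= 2 with t_{1-a/2, n-1} * sd / sqrt(n) <= half_width."""
    if not (sd > 0 and half_width > 0):
        raise ValueError("sd and half_width must be > 0")
    q = 0.5 + confidence / 2.0
    for n in range(2, n_max):
        if stats.t.ppf(q, n - 1) * sd / np.sqrt(n) <= half_width:
            return n
    raise ValueError("required sample size exceeds n_max")


def preliminary_split_sd(
    rows, y, n_splits: int = 200, seed: int = 0, fit_fn=None
) -> float:
    """Mean SD of test-set |y - prediction| over repeated 50/50 splits.

    Reproduces the preliminary sample-size workflow: the data are split
    in half ``n_splits`` times (seeded), a regression is fit on each
    training half, and the SD of the absolute prediction error on the
    held-out half is averaged over splits.
    """
    from .vlt_model import fit_ols, predict_vlt

    y = np.asarray(y, dtype=np.float64)
    n = len(rows)
    rng = np.random.default_rng(seed)
    sds = []
    for _ in range(n_splits):
        idx = rng.permutation(n)
        tr, te = idx[: n // 2], idx[n // 2 :]
        model = (fit_fn or fit_ols)([rows[i] for i in tr], y[tr])
        preds = np.array([predict_vlt(model, rows[i])[0] for i in te])
        sds.append(np.std(np.abs(y[te] - preds), ddof=1))
    return float(np.mean(sds))


def agreement_report(method: str, reference, predicted) -> AgreementReport:
    """Bundle the per-method agreement statistics into one report."""
    ref, pred = _paired(reference, predicted)
    mad, mad_ci = mean_abs_diff_ci(ref, pred)
    icc, icc_ci = icc_2_1(np.column_stack([ref, pred]))
    bias, (lo, hi) = bland_altman(ref, pred)
    return AgreementReport(
        method=method,
        mean_abs_diff=mad,
        mad_ci=mad_ci,
        icc=icc,
        icc_ci=icc_ci,
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        n=ref.size,
    )
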