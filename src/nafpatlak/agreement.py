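"""Method-agreement statistics for paired K_i measurements.

The battery used to compare shortened-scan against routine-scan clearance
estimates on the same scans: Spearman rank correlation, intraclass
correlation (two-way, absolute agreement, single measurement -- ICC(A,1))
with an F-distribution 95% CI, Bland-Altman bias and 95% limits of
agreement, and the two-sided Wilcoxon signed-rank test.  All tests are
two-sided; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "BlandAltman",
    "spearman",
    "icc_agreement",
    "bland_altman",
    "wilcoxon_signed_rank",
    "agreement_report",
]


def _check_pair(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    return x, y


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rho with t-approximation p (n-2 df)."""
    x, y = _check_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _two_way_mean_squares(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the two-way targets-by-raters ANOVA, k = 2 raters."""
    scores = np.column_stack([x, y])
    n, k = scores.shape
    grand = scores.mean()
    row_means = scores.mean(axis=1)
    col_means = scores.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((scores - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_agreement(
    x, y, form: str = "absolute", confidence: float = 0.95
) -> tuple[float, float, float]:
    """Single-measurement two-way ICC between two fixed methods.

    ``form='absolute'`` (default) is the absolute-agreement coefficient
    ICC(A,1), which penalizes a systematic offset between the methods;
    ``form='consistency'`` is ICC(C,1).  Returns (icc, ci_low, ci_high)
    with an F-distribution confidence interval (McGraw-Wong construction).
    """
    x, y = _check_pair(x, y)
    if np.ptp(np.concatenate([x, y])) == 0:
        raise ValueError("ICC undefined: zero total variance")
    if form not in ("absolute", "consistency"):
        raise ValueError(f"unknown ICC form {form!r}")
    n, k = x.size, 2
    msr, msc, mse = _two_way_mean_squares(x, y)
    a = 1.0 - (1.0 - confidence) / 2.0
    if form == "consistency":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        f_obs = msr / mse if mse > 0 else np.inf
        fl = f_obs / stats.f.ppf(a, n - 1, (n - 1) * (k - 1))
        fu = f_obs * stats.f.ppf(a, (n - 1) * (k - 1), n - 1)
        lo = (fl - 1.0) / (fl + k - 1.0)
        hi = (fu - 1.0) / (fu + k - 1.0)
        return float(icc), float(lo), float(hi)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ValueError("ICC undefined: zero total variance")
    icc = (msr - mse) / denom
    if mse == 0 and msc == 0:
        # identical raters: perfect agreement, degenerate CI
        return 1.0, 1.0, 1.0
    # Satterthwaite df for the ICC(A,1) interval
    ai = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
    bi = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if np.isfinite(ai):
        v = (ai * msc + bi * mse) ** 2 / (
            (ai * msc) ** 2 / (k - 1) + (bi * mse) ** 2 / ((n - 1) * (k - 1))
        )
        fu_q = stats.f.ppf(a, v, n - 1)
        fl_q = stats.f.ppf(a, n - 1, v)
        lo = n * (msr - fl_q * mse) / (
            fl_q * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (fu_q * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * fu_q * msr
        )
    else:
        lo = hi = 1.0
    return float(icc), float(lo), float(hi)


@dataclass(frozen=True)
class BlandAltman:
    """Bias and 95% limits of agreement for differences d = x - y."""

    bias: float
    loa_low: float
    loa_high: float
    bias_ci: tuple[float, float]
    loa_low_ci: tuple[float, float]
    loa_high_ci: tuple[float, float]
    sd_diff: float
    n: int


def bland_altman(x, y) -> BlandAltman:
    """Bland-Altman summary: bias = mean(x - y), LoA = bias +/- 1.96 sd.

    The bias CI uses the t distribution; the LoA CIs use the standard
    large-sample variance ``sd^2 (1/n + 1.96^2 / (2(n-1)))`` with a t
    quantile.
    """
    x, y = _check_pair(x, y)
    d = x - y
    n = d.size
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    tq = float(stats.t.ppf(0.975, n - 1))
    half_bias = tq * sd / np.sqrt(n)
    half_loa = tq * sd * np.sqrt(1.0 / n + 1.96**2 / (2.0 * (n - 1)))
    return BlandAltman(
        bias=bias,
        loa_low=loa_low,
        loa_high=loa_high,
        bias_ci=(bias - half_bias, bias + half_bias),
        loa_low_ci=(loa_low - half_loa, loa_low + half_loa),
        loa_high_ci=(loa_high - half_loa, loa_high + half_loa),
        sd_diff=sd,
        n=n,
    )


def wilcoxon_signed_rank(x, y) -> float:
    """Two-sided Wilcoxon signed-rank p for paired samples.

    Zero differences are dropped (Wilcoxon convention); if every pair is
    tied the test is uninformative and p = 1 by convention.  The exact
    null distribution is used for n <= 25, the normal approximation with
    continuity correction above.
    """
    x, y = _check_pair(x, y)
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    method = "exact" if n <= 25 else "approx"
    res = stats.wilcoxon(
        d, correction=True, alternative="two-sided", method=method, zero_method="wilcox"
    )
    return float(res.pvalue)


@dataclass(frozen=True)
class AgreementReport:
    """Full agreement battery between two paired K_i vectors."""

    rs: float
    rs_p: float
    icc: float
    icc_ci: tuple[float, float]
    ba: BlandAltman
    wilcoxon_p: float
    n: int

    def as_row(self) -> dict:
        return {
            "n": self.n,
            "rs": self.rs,
            "rs_p": self.rs_p,
            "icc": self.icc,
            "icc_low": self.icc_ci[0],
            "icc_high": self.icc_ci[1],
            "ba_bias": self.ba.bias,
            "ba_loa_low": self.ba.loa_low,
            "ba_loa_high": self.ba.loa_high,
            "wilcoxon_p": self.wilcoxon_p,
        }


def agreement_report(x, y, icc_form: str = "absolute") -> AgreementReport:
    """Compute the full battery for x (e.g. shortened) vs y (routine)."""
    x, y = _check_pair(x, y)
    icc, lo, hi = icc_agreement(x, y, form=icc_form)
    if np.array_equal(x, y):
        # identical vectors: rank correlation is 1 by definition even
        # though the generic path would hit the degenerate-variance guard
        rs, rs_p = 1.0, 0.0
    else:
        rs, rs_p = spearman(x, y)
    return AgreementReport(
        rs=rs,
        rs_p=rs_p,
        icc=icc,
        icc_ci=(lo, hi),
        ba=bland_altman(x, y),
        wilcoxon_p=wilcoxon_signed_rank(x, y),
        n=int(np.asarray(x).size),
    )
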