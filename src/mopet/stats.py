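"""Method-agreement statistics: volume ratios, Spearman correlation,
intra-class correlation, Bland-Altman analysis.

Conventions fixed here:

* ratio = MTV / GTV, summarized as mean and sample SD (ddof=1);
* Spearman rho uses mid-ranks for ties; p-values are two-sided, computed by
  the t approximation for n >= 10 and by exact permutation below that;
* ICC is ICC(A,1) — two-way random effects, absolute agreement, single
  measures — with a 95% CI from the McGraw & Wong F-distribution method;
* Bland-Altman differences are MTV - GTV; "bias +/- sd" reports the sample
  SD of the differences, with 95% limits of agreement bias +/- 1.96 sd.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AgreementReport",
    "ratio_stats",
    "spearman",
    "icc_agreement",
    "bland_altman",
    "compare_methods",
]


_PERM_CACHE: dict[int, np.ndarray] = {}


def _pair(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    return x, y


def ratio_stats(mtv, gtv) -> tuple[float, float]:
    """Mean and sample SD (ddof=1) of the per-case MTV/GTV ratio."""
    mtv, gtv = _pair(mtv, gtv, min_n=2)
    if np.any(gtv <= 0):
        raise ValueError("GTV must be positive elementwise")
    r = mtv / gtv
    return float(r.mean()), float(r.std(ddof=1))


def _rank_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)  # mid-ranks for ties
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    return float(rx @ ry) / denom


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    p is computed from the t approximation for n >= 10 and by exhaustive
    permutation of one rank vector for n < 10 (exact under exchangeability).
    """
    x, y = _pair(x, y, min_n=3)
    rho = _rank_rho(x, y)
    n = x.size
    if n >= 10:
        if abs(rho) == 1.0:
            return rho, 0.0
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    else:
        # exact permutation null; ranks of a permuted vector are the
        # permuted ranks, so all n! correlations reduce to one matmul
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        rx = rx - rx.mean()
        ry = ry - ry.mean()
        denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
        if n not in _PERM_CACHE:
            _PERM_CACHE[n] = np.array(
                list(itertools.permutations(range(n))), dtype=np.intp
            )
        rhos = (ry[_PERM_CACHE[n]] @ rx) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return rho, float(min(p, 1.0))


def _icc_mean_squares(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, int, int]:
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_agreement(x, y, confidence: float = 0.95) -> tuple[float, tuple[float, float]]:
    """ICC(A,1): two-way random effects, absolute agreement, single measures.

    Returns the point estimate and the F-method confidence interval
    (McGraw & Wong).  Raises on zero total variance, where agreement is
    undefined.
    """
    x, y = _pair(x, y, min_n=4)
    msr, msc, mse, n, k = _icc_mean_squares(x, y)
    if msr + msc + mse <= 0 or np.allclose([x.var(), y.var()], 0):
        raise ValueError("zero total variance: ICC undefined")
    icc = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))

    alpha = 1.0 - confidence
    if mse == 0:
        return float(icc), (float(icc), float(icc))
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd if vd > 0 else 1.0
    f_l = sps.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = sps.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    lower, upper = float(min(lower, icc)), float(max(upper, icc))
    return float(icc), (lower, upper)


def bland_altman(mtv, gtv) -> tuple[float, float, tuple[float, float]]:
    """Bias (mean of MTV-GTV), sample SD of differences, and 95% LoA."""
    mtv, gtv = _pair(mtv, gtv, min_n=2)
    d = mtv - gtv
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, sd, (bias - 1.96 * sd, bias + 1.96 * sd)


@dataclass(frozen=True)
class AgreementReport:
    """One method's agreement-with-reference summary (one table row)."""

    method: str
    n: int
    ratio_mean: float
    ratio_sd: float
    spearman_rho: float
    p_value: float
    icc: float
    icc_ci95_low: float
    icc_ci95_high: float
    ba_bias_cm3: float
    ba_sd_cm3: float
    ba_loa95_low_cm3: float
    ba_loa95_high_cm3: float
    icc_variant: str = "ICC(A,1) two-way random, absolute agreement, single measures"

    def to_dict(self) -> dict:
        return asdict(self)


def compare_methods(
    volumes_by_method: dict[str, "np.ndarray | list[float]"],
    reference: "np.ndarray | list[float]",
) -> pd.DataFrame:
    """Agreement table: one row per method vs. the reference volumes (cm^3)."""
    rows = []
    ref = np.asarray(reference, dtype=float)
    for method, vols in volumes_by_method.items():
        v = np.asarray(vols, dtype=float)
        rmean, rsd = ratio_stats(v, ref)
        rho, p = spearman(v, ref)
        icc, (lo, hi) = icc_agreement(v, ref)
        bias, sd, (loa_lo, loa_hi) = bland_altman(v, ref)
        rows.append(
            AgreementReport(
                method=method,
                n=int(v.size),
                ratio_mean=rmean,
                ratio_sd=rsd,
                spearman_rho=rho,
                p_value=p,
                icc=icc,
                icc_ci95_low=lo,
                icc_ci95_high=hi,
                ba_bias_cm3=bias,
                ba_sd_cm3=sd,
                ba_loa95_low_cm3=loa_lo,
                ba_loa95_high_cm3=loa_hi,
            ).to_dict()
        )
    return pd.DataFrame(rows)
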