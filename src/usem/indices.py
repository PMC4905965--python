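"""Chi-square-based fit indices for covariance-structure models.

RMSEA with its 90% confidence interval from the noncentral chi-square
distribution, the Browne-Cudeck criterion (BCC), the comparative fit
index (CFI) against an independence baseline, and AIC/BIC for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from scipy import optimize, stats

__all__ = ["rmsea", "rmsea_ci", "bcc", "cfi", "aic", "bic", "FitIndexBundle", "bundle"]


def rmsea(chi_square: float, df: int, n: int) -> float:
    """Root mean square error of approximation,
    sqrt(max(chi^2 - df, 0) / (n * df))."""
    if df <= 0:
        raise ValueError("df must be positive")
    if n <= 1:
        raise ValueError("n must exceed 1")
    return (max(chi_square - df, 0.0) / (n * df)) ** 0.5


def _noncentrality(chi_square: float, df: int, tail: float) -> float:
    """Solve Phi(chi^2 | delta, df) = tail for the noncentrality delta.

    The noncentral chi-square CDF is strictly decreasing in delta, so the
    root is unique; delta is clamped at 0 when no root exists.
    """
    if stats.chi2.cdf(chi_square, df) < tail:
        return 0.0
    f = lambda d: stats.ncx2.cdf(chi_square, df, d) - tail
    hi = max(2.0 * chi_square, 10.0)
    while f(hi) > 0:
        hi *= 2.0
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-10))


def rmsea_ci(chi_square: float, df: int, n: int) -> tuple[float, float]:
    """90% confidence bounds: delta_U solves Phi(chi^2|delta,df)=0.05 and
    delta_L solves Phi(chi^2|delta,df)=0.95; bounds are
    sqrt(delta / (n*df))."""
    if df <= 0:
        raise ValueError("df must be positive")
    if n <= 1:
        raise ValueError("n must exceed 1")
    delta_u = _noncentrality(chi_square, df, 0.05)
    delta_l = _noncentrality(chi_square, df, 0.95)
    return (delta_l / (n * df)) ** 0.5, (delta_u / (n * df)) ** 0.5


def bcc(
    chi_square: float,
    q: int,
    group_sizes: list[int],
    p_per_group: list[int],
    printed_denominator: bool = False,
) -> float:
    """Browne-Cudeck criterion.

    BCC = chi^2 + 2q * [sum_g b_g p_g (p_g+3) / (N_g - p_g - 2)]
                     / [sum_g p_g (p_g+3)]
    with b_g = N_g.  The alternative denominator sum_g b_g (p_g+3)
    (``printed_denominator=True``) makes the penalty vanish for large
    samples and is retained only for comparison.
    """
    if q < 0:
        raise ValueError("q must be non-negative")
    num = 0.0
    den = 0.0
    for N, p in zip(group_sizes, p_per_group, strict=True):
        if N <= p + 2:
            raise ValueError(f"group size {N} must exceed p + 2 = {p + 2}")
        b = N
        num += b * p * (p + 3) / (N - p - 2)
        den += b * (p + 3) if printed_denominator else p * (p + 3)
    return chi_square + 2.0 * q * num / den


def cfi(chi_square: float, df: int, null_chi_square: float, null_df: int) -> float:
    """Comparative fit index vs the independence (null) model,
    1 - max(chi^2-df, 0) / max(chi^2_null - df_null, chi^2 - df, 0)."""
    d_model = max(chi_square - df, 0.0)
    d_null = max(null_chi_square - null_df, d_model, 0.0)
    if null_chi_square - null_df < chi_square - df:
        warnings.warn(
            "baseline model fits no worse than target; CFI clamped", stacklevel=2
        )
    if d_null == 0.0:
        return 1.0
    return min(max(1.0 - d_model / d_null, 0.0), 1.0)


def aic(chi_square: float, q: int) -> float:
    return chi_square + 2.0 * q


def bic(chi_square: float, q: int, n: int) -> float:
    import math

    return chi_square + q * math.log(n)


@dataclass
class FitIndexBundle:
    """Fit-index summary for one fitted model (pooled + per group)."""

    chi_square: float
    df: int
    n_total: int
    q: int
    rmsea: float
    rmsea_lo90: float
    rmsea_hi90: float
    bcc: float
    cfi: float
    aic: float
    bic: float
    groups: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "chi_square": self.chi_square,
            "df": self.df,
            "n_total": self.n_total,
            "q": self.q,
            "rmsea": self.rmsea,
            "rmsea_lo90": self.rmsea_lo90,
            "rmsea_hi90": self.rmsea_hi90,
            "bcc": self.bcc,
            "cfi": self.cfi,
            "aic": self.aic,
            "bic": self.bic,
            "groups": self.groups,
        }


def bundle(
    chi_square: float,
    df: int,
    n_total: int,
    q: int,
    group_sizes: list[int],
    p_per_group: list[int],
    null_chi_square: float,
    null_df: int,
    groups: dict[str, tuple[float, int, int]] | None = None,
) -> FitIndexBundle:
    """Assemble all indices; ``groups`` maps a cohort label to its
    (chi^2_g, df_g, N_g) for per-cohort RMSEA sub-bundles (each cohort
    treated as fit alone, so the divisor is the group's own n).

    A saturated or over-parameterized model (df <= 0) reproduces any
    covariance exactly; its RMSEA is reported as 0 with a degenerate
    interval and CFI as 1."""
    if df <= 0:
        point, lo, hi, cfi_val = 0.0, 0.0, 0.0, 1.0
    else:
        point = rmsea(chi_square, df, n_total)
        lo, hi = rmsea_ci(chi_square, df, n_total)
        cfi_val = cfi(chi_square, df, null_chi_square, null_df)
    out = FitIndexBundle(
        chi_square=chi_square,
        df=df,
        n_total=n_total,
        q=q,
        rmsea=point,
        rmsea_lo90=lo,
        rmsea_hi90=hi,
        bcc=bcc(chi_square, q, group_sizes, p_per_group),
        cfi=cfi_val,
        aic=aic(chi_square, q),
        bic=bic(chi_square, q, n_total),
    )
    if groups:
        for label, (c2, dfg, ng) in groups.items():
            if dfg <= 0:
                gpoint, glo, ghi = 0.0, 0.0, 0.0
            else:
                gpoint = rmsea(c2, dfg, ng)
                glo, ghi = rmsea_ci(c2, dfg, ng)
            out.groups[label] = {
                "chi_square": c2,
                "df": dfg,
                "n": ng,
                "rmsea": gpoint,
                "rmsea_lo90": glo,
                "rmsea_hi90": ghi,
            }
    return out
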