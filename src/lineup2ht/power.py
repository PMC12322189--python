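"""Chi-square power and sensitivity calculations.

For a chi-square test with ``df`` degrees of freedom on ``n_total``
observations and Cohen's effect size ``w``, the test statistic is
asymptotically noncentral chi-square with noncentrality
``lambda_nc = w**2 * n_total``.  Power is the probability that this
noncentral variate exceeds the central chi-square critical value at level
``alpha``; the sensitivity analysis inverts this relation for the smallest
detectable ``w`` at a requested power.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import optimize, stats

from .model import ValidationError

__all__ = ["PowerSpec", "chi2_power", "minimal_detectable_w"]


@dataclass
class PowerSpec:
    """A chi-square sensitivity-analysis configuration and its solution."""

    df: int
    alpha: float
    power: float
    n_total: int
    w: float | None = None

    @property
    def noncentrality(self) -> float | None:
        return None if self.w is None else self.w**2 * self.n_total

    def to_dict(self) -> dict:
        return {
            "df": int(self.df),
            "alpha": float(self.alpha),
            "power": float(self.power),
            "n_total": int(self.n_total),
            "w": None if self.w is None else float(self.w),
            "noncentrality": self.noncentrality,
        }


def chi2_power(w: float, n_total: float, df: int, alpha: float) -> float:
    """Power of a chi-square test at effect size ``w``.

    ``P(X > q)`` with ``X ~ noncentral chi2(df, w**2 * n_total)`` and ``q``
    the central chi-square ``1 - alpha`` quantile.  At ``w = 0`` the power
    equals ``alpha``.
    """
    if df < 1 or n_total <= 0 or not (0.0 < alpha < 1.0) or w < 0:
        raise ValidationError("require df >= 1, n_total > 0, 0 < alpha < 1, w >= 0")
    q = stats.chi2.ppf(1.0 - alpha, df)
    if w == 0.0:
        return float(alpha)
    return float(stats.ncx2.sf(q, df, w * w * n_total))


def minimal_detectable_w(
    n_total: float, df: int, alpha: float, power: float, tol: float = 1e-8
) -> float:
    """Smallest effect size ``w`` detectable at the requested power.

    Solves ``chi2_power(w, n_total, df, alpha) = power`` by monotone
    root bracketing; power is strictly increasing in ``w``.
    """
    if not (alpha < power < 1.0):
        raise ValidationError("power must lie in (alpha, 1)")
    hi = 0.1
    while chi2_power(hi, n_total, df, alpha) < power:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - unreachable for sane inputs
            raise RuntimeError("failed to bracket the effect size")
    return float(
        optimize.brentq(
            lambda w: chi2_power(w, n_total, df, alpha) - power,
            0.0,
            hi,
            xtol=tol,
        )
    )
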