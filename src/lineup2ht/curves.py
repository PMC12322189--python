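"""Forgetting-curve fits to the delay-dependent detection estimates.

Retention of the culprit's face is summarised by the culprit-presence
detection probability ``dP`` estimated per delay condition.  Three standard
descriptions of its decline with delay ``t`` (in days) are supported, each
defined at ``t = 0``:

* modified power:        ``dP = lambda * (1 + t) ** (-psi)``
* modified logarithmic:  ``dP = lambda * ln(1 + t) + psi``
* simplified Wickelgren power-exponential: ``m = lambda * (1 + beta*t) ** (-psi)``
  with ``lambda`` fixed a priori to the no-delay estimate (the boundary
  condition ``m(0) = lambda``), so only the scaling parameter ``beta`` and
  the forgetting rate ``psi`` are fitted.

The logarithmic family is exact OLS; the power family is, by default and by
long-standing convention for power-law retention data, estimated as OLS on
the double-log scale (direct nonlinear least squares is available via
``objective="raw"``); the Wickelgren family is unweighted multi-start
nonlinear least squares.  ``R^2 = 1 - SS_res / SS_tot`` is always computed
from raw-scale residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .model import ValidationError

__all__ = [
    "CurveFit",
    "fit_power_curve",
    "fit_log_curve",
    "fit_wickelgren_curve",
    "predict_curve",
    "fit_forgetting_curves",
]

FAMILIES = ("modified_power", "modified_log", "wickelgren_simplified")


@dataclass
class CurveFit:
    """A fitted forgetting function."""

    family: str
    coefficients: dict[str, float]
    r_squared: float
    ss_res: float
    delays: tuple[float, ...]
    values: tuple[float, ...]
    fixed: dict[str, float] = field(default_factory=dict)
    method: str = ""

    def predict(self, delay) -> np.ndarray | float:
        return predict_curve(self, delay)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "fixed": {k: float(v) for k, v in self.fixed.items()},
            "r_squared": float(self.r_squared),
            "ss_res": float(self.ss_res),
            "delays": list(self.delays),
            "values": list(self.values),
            "method": self.method,
        }


def _check_points(delays, values, minimum: int) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(delays, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValidationError("delays and values must be 1-d and of equal length")
    if t.size < minimum:
        raise ValidationError(f"need at least {minimum} points, got {t.size}")
    if np.any(t < 0):
        raise ValidationError("delays must be non-negative")
    if len(np.unique(t)) != t.size:
        raise ValidationError("delays must be distinct")
    return t, y


def _r_squared(y: np.ndarray, residuals: np.ndarray) -> tuple[float, float]:
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0, ss_res
    return 1.0 - ss_res / ss_tot, ss_res


def _multistart_ls(residual, starts, bounds) -> optimize.OptimizeResult:
    best = None
    for x0 in starts:
        res = optimize.least_squares(
            residual, x0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14
        )
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    return best


def fit_power_curve(
    delays: Sequence[float], values: Sequence[float], objective: str = "log"
) -> CurveFit:
    """Fit the modified power function ``lambda*(1+t)**(-psi)``.

    With ``objective="log"`` (the default, and the conventional way power-law
    retention curves are estimated) the fit is exact ordinary least squares of
    ``ln(y)`` on ``ln(1+t)``, which requires strictly positive values; with
    ``objective="raw"`` it is multi-start nonlinear least squares on the
    original scale with ``lambda >= 0`` and ``psi`` unconstrained.  ``R^2``
    and ``ss_res`` are always reported on the original scale.
    """
    t, y = _check_points(delays, values, 3)

    def residual(p):
        lam, psi = p
        return lam * (1.0 + t) ** (-psi) - y

    if objective == "log":
        if np.any(y <= 0):
            raise ValidationError(
                "log-scale power fit requires strictly positive values"
            )
        design = np.column_stack([np.log1p(t), np.ones_like(t)])
        slope, intercept = np.linalg.lstsq(design, np.log(y), rcond=None)[0]
        lam, psi = float(np.exp(intercept)), float(-slope)
    elif objective == "raw":
        starts = [(lam, psi) for lam in np.linspace(0.05, 1.0, 10)
                  for psi in np.linspace(0.0, 3.0, 5)]
        res = _multistart_ls(residual, starts, ([0.0, -np.inf], [np.inf, np.inf]))
        lam, psi = (float(v) for v in res.x)
    else:
        raise ValidationError(f"unknown objective {objective!r}")
    r2, ss_res = _r_squared(y, residual((lam, psi)))
    return CurveFit(
        "modified_power", {"lambda": lam, "psi": psi},
        r2, ss_res, tuple(t.tolist()), tuple(y.tolist()),
        method={"log": "log-scale OLS", "raw": "raw-scale NLS"}[objective],
    )


def fit_log_curve(delays: Sequence[float], values: Sequence[float]) -> CurveFit:
    """Exact ordinary least squares of ``lambda*ln(1+t) + psi`` (linear in both)."""
    t, y = _check_points(delays, values, 2)
    x = np.log1p(t)
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    lam, psi = coef
    r2, ss_res = _r_squared(y, design @ coef - y)
    return CurveFit(
        "modified_log", {"lambda": float(lam), "psi": float(psi)},
        r2, ss_res, tuple(t.tolist()), tuple(y.tolist()),
        method="OLS",
    )


def fit_wickelgren_curve(
    delays: Sequence[float], values: Sequence[float], lambda_fixed: float
) -> CurveFit:
    """Fit ``lambda*(1 + beta*t)**(-psi)`` with ``lambda`` fixed.

    ``lambda`` is the memory state at ``t = 0`` and is supplied, not fitted
    (typically the no-delay detection estimate, honouring the boundary
    condition of the power-exponential retention theory).  ``beta >= 0``
    scales the time axis; ``psi`` is the forgetting rate.
    """
    t, y = _check_points(delays, values, 3)
    if not (0.0 < lambda_fixed <= 1.0):
        raise ValidationError(
            f"lambda_fixed must lie in (0, 1], got {lambda_fixed}"
        )

    def residual(p):
        beta, psi = p
        return lambda_fixed * (1.0 + beta * t) ** (-psi) - y

    starts = [(beta, psi) for beta in np.linspace(0.0, 20.0, 10)
              for psi in np.linspace(0.0, 3.0, 5)]
    res = _multistart_ls(residual, starts, ([0.0, -np.inf], [np.inf, np.inf]))
    beta, psi = res.x
    r2, ss_res = _r_squared(y, residual(res.x))
    return CurveFit(
        "wickelgren_simplified", {"beta": float(beta), "psi": float(psi)},
        r2, ss_res, tuple(t.tolist()), tuple(y.tolist()),
        fixed={"lambda": float(lambda_fixed)},
        method="raw-scale NLS",
    )


def predict_curve(fit: CurveFit, delay):
    """Evaluate a fitted forgetting function at one or more delays."""
    t = np.asarray(delay, dtype=float)
    if np.any(t < 0):
        raise ValidationError("delay must be non-negative")
    c = fit.coefficients
    if fit.family == "modified_power":
        out = c["lambda"] * (1.0 + t) ** (-c["psi"])
    elif fit.family == "modified_log":
        out = c["lambda"] * np.log1p(t) + c["psi"]
    elif fit.family == "wickelgren_simplified":
        out = fit.fixed["lambda"] * (1.0 + c["beta"] * t) ** (-c["psi"])
    else:
        raise ValidationError(f"unknown curve family {fit.family!r}")
    return float(out) if np.isscalar(delay) else out


def fit_forgetting_curves(
    delays: Sequence[float],
    values: Sequence[float],
    lambda_fixed: float | None = None,
    families: Sequence[str] = FAMILIES,
) -> dict[str, CurveFit]:
    """Fit the requested curve families to one set of (delay, dP) points.

    ``lambda_fixed`` (required for the Wickelgren family) is typically the
    no-delay detection estimate rounded to four decimals.
    """
    fits: dict[str, CurveFit] = {}
    for family in families:
        if family == "modified_power":
            fits[family] = fit_power_curve(delays, values)
        elif family == "modified_log":
            fits[family] = fit_log_curve(delays, values)
        elif family == "wickelgren_simplified":
            if lambda_fixed is None:
                raise ValidationError(
                    "wickelgren_simplified requires lambda_fixed"
                )
            fits[family] = fit_wickelgren_curve(delays, values, lambda_fixed)
        else:
            raise ValidationError(f"unknown curve family {family!r}")
    return fits


def plot_forgetting(fits, ax=None):
    """Plot dP estimates against delay with the fitted curves overlaid.

    Requires matplotlib (optional dependency).  Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    first = next(iter(fits.values()))
    ax.scatter(first.delays, first.values, color="black", zorder=3,
               label="dP estimates")
    grid = np.linspace(0.0, max(first.delays), 200)
    for name, fit in fits.items():
        ax.plot(grid, predict_curve(fit, grid),
                label=f"{name} (R^2={fit.r_squared:.2f})")
    ax.set_xlabel("delay (days)")
    ax.set_ylabel("culprit-presence detection dP")
    ax.legend()
    return ax
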