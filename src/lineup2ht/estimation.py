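"""Maximum-likelihood estimation of the multi-condition 2-HT model.

Fits the free parameters of a :class:`~lineup2ht.model.ModelSpec` to observed
lineup response frequencies by maximising the multinomial log-likelihood
kernel ``sum_i O_i * ln(p_i)`` over the unit box, using box-constrained
quasi-Newton optimisation (L-BFGS-B with analytic gradients) from multiple
starting points.  Goodness of fit is reported as the likelihood-ratio
statistic ``G^2 = 2 * sum_i O_i * ln(O_i / E_i)`` with an asymptotic
chi-square p-value, and Wald confidence intervals are derived from the
observed information matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess1

from .model import (
    CATEGORIES,
    PARAM_FAMILIES,
    ConditionParams,
    LineupCounts,
    ModelSpec,
    ParameterMap,
    ValidationError,
    counts_matrix,
    tree_probabilities,
    tree_probability_gradient,
    validate_dataset,
)

__all__ = [
    "FitResult",
    "log_likelihood",
    "g_squared",
    "degrees_of_freedom",
    "fit_model",
    "wald_intervals",
]

_PROB_FLOOR = 1e-300  # floor inside logs; keeps -inf out of the optimiser
_BOUNDARY_TOL = 1e-6


@dataclass
class FitResult:
    """Result of a maximum-likelihood 2-HT model fit."""

    spec: ModelSpec
    estimates: dict[str, float]
    log_likelihood: float
    g_squared: float
    df: int
    p_value: float
    n_starts: int
    converged: bool
    theta: np.ndarray  # (n_conditions, 4) full parameter array
    expected: dict[str, dict[str, float]]  # condition -> category -> E
    observed: dict[str, dict[str, float]]
    standard_errors: dict[str, float] = field(default_factory=dict)
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    boundary: dict[str, bool] = field(default_factory=dict)

    @property
    def free_names(self) -> list[str]:
        return list(self.estimates)

    def params_for(self, condition: str) -> ConditionParams:
        """The full parameter set (free + restricted + fixed) of one condition."""
        j = self.spec.conditions.index(condition)
        return ConditionParams(*self.theta[j])

    def params_by_condition(self) -> dict[str, ConditionParams]:
        return {cond: self.params_for(cond) for cond in self.spec.conditions}

    def to_dict(self) -> dict:
        """JSON-ready summary of the fit."""
        return {
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "standard_errors": {
                k: (None if np.isnan(v) else float(v))
                for k, v in self.standard_errors.items()
            },
            "ci95": {k: [float(lo), float(hi)] for k, (lo, hi) in self.ci95.items()},
            "boundary": dict(self.boundary),
            "log_likelihood": float(self.log_likelihood),
            "g_squared": float(self.g_squared),
            "df": int(self.df),
            "p_value": float(self.p_value),
            "n_starts": int(self.n_starts),
            "converged": bool(self.converged),
            "conditions": {
                cond: {
                    "params": {
                        fam: float(v)
                        for fam, v in zip(PARAM_FAMILIES, self.theta[j])
                    },
                    "expected": self.expected[cond],
                    "observed": self.observed[cond],
                }
                for j, cond in enumerate(self.spec.conditions)
            },
        }


def log_likelihood(
    dataset: Sequence[LineupCounts],
    params_by_condition: Mapping[str, ConditionParams],
    spec: ModelSpec | None = None,
    sampling_constant: float | None = None,
) -> float:
    """Multinomial log-likelihood kernel ``sum O * ln(p)``.

    Categories with a zero count contribute nothing; a zero probability paired
    with a positive count yields ``-inf`` (a legal return value).
    """
    if sampling_constant is None:
        sampling_constant = (
            spec.sampling_constant if spec is not None else 0.16667
        )
    total = 0.0
    for cond in dataset:
        params = params_by_condition[cond.condition_id]
        probs = tree_probabilities(params.as_array(), sampling_constant)
        counts = cond.as_array()
        for o, p in zip(counts, probs):
            if o > 0:
                if p <= 0.0:
                    return float("-inf")
                total += o * np.log(p)
    return float(total)


def g_squared(observed: np.ndarray, expected: np.ndarray) -> float:
    """Likelihood-ratio goodness-of-fit statistic ``2 * sum O * ln(O/E)``.

    Cells with an observed count of zero contribute zero.  An expected value
    of zero against a positive observed count yields ``+inf`` with a warning.
    """
    observed = np.asarray(observed, dtype=float).ravel()
    expected = np.asarray(expected, dtype=float).ravel()
    if observed.shape != expected.shape:
        raise ValidationError("observed and expected must have the same shape")
    mask = observed > 0
    if np.any(expected[mask] <= 0.0):
        warnings.warn(
            "expected frequency of zero with a positive observed count; G^2 is infinite",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return float(2.0 * np.sum(observed[mask] * np.log(observed[mask] / expected[mask])))


def degrees_of_freedom(spec: ModelSpec) -> int:
    """Data degrees of freedom minus free parameters.

    Each condition supplies two trinomial trees, i.e. four independent
    category probabilities.
    """
    pmap = spec.parameter_map()
    df = 4 * len(spec.conditions) - pmap.n_free
    if df < 0:
        raise ValidationError(
            f"model is over-parameterised: {pmap.n_free} free parameters for "
            f"{4 * len(spec.conditions)} independent data categories"
        )
    return df


def _neg_loglik_and_grad(
    x: np.ndarray, pmap: ParameterMap, counts: np.ndarray, c: float
) -> tuple[float, np.ndarray]:
    theta = pmap.expand(x)
    probs = tree_probabilities(theta, c)
    safe = np.clip(probs, _PROB_FLOOR, None)
    ll = float(np.sum(counts * np.log(safe)))
    # d ll / d theta: sum over cells of (O/p) * dp/dtheta
    jac = tree_probability_gradient(theta, c)  # (n_cond, 6, 4)
    ratio = np.where(counts > 0, counts / np.clip(probs, 1e-12, None), 0.0)
    grad_theta = np.einsum("ij,ijk->ik", ratio, jac)
    return -ll, -pmap.contract_gradient(grad_theta)


def _chi2_upper_tail(g2: float, df: int) -> float:
    if df == 0:
        return 1.0 if g2 <= 1e-8 else 0.0
    return float(stats.chi2.sf(g2, df))


def fit_model(
    dataset: Sequence[LineupCounts],
    spec: ModelSpec,
    n_starts: int = 20,
    seed: int = 1,
    warm_starts: Sequence[np.ndarray] = (),
    compute_ci: bool = True,
) -> FitResult:
    """Fit the 2-HT model to a dataset by maximum likelihood.

    Parameters
    ----------
    dataset
        One :class:`~lineup2ht.model.LineupCounts` per condition; conditions
        must match ``spec.conditions`` (any order).
    spec
        Model specification (conditions, restrictions, sampling constant).
    n_starts
        Number of optimisation starts: a central start at 0.25, the remainder
        drawn uniformly from [0.02, 0.98] with a seeded generator.  The best
        converged solution wins; ties are broken by first occurrence.
    warm_starts
        Extra free-parameter vectors prepended to the start list (used by the
        bootstrap to warm-start replicate fits).
    compute_ci
        Attach Wald standard errors and 95% intervals (see
        :func:`wald_intervals`).

    Returns
    -------
    FitResult
        With ``G^2`` evaluated against the fitted expected counts and an
        asymptotic chi-square p-value on :func:`degrees_of_freedom` degrees
        of freedom.
    """
    dataset = validate_dataset(dataset)
    by_id = {cond.condition_id: cond for cond in dataset}
    if set(by_id) != set(spec.conditions):
        raise ValidationError(
            f"dataset conditions {sorted(by_id)} do not match "
            f"spec conditions {sorted(spec.conditions)}"
        )
    ordered = [by_id[cond] for cond in spec.conditions]
    counts = counts_matrix(ordered)
    pmap = spec.parameter_map()
    c = spec.sampling_constant
    df = degrees_of_freedom(spec)

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = [np.asarray(w, dtype=float) for w in warm_starts]
    starts.append(np.full(pmap.n_free, 0.25))
    while len(starts) < n_starts + len(warm_starts):
        starts.append(rng.uniform(0.02, 0.98, size=pmap.n_free))

    if pmap.n_free == 0:
        best_x = np.empty(0)
        best_fun = _neg_loglik_and_grad(best_x, pmap, counts, c)[0]
        converged = True
    else:
        best_x, best_fun, converged = None, np.inf, False
        bounds = [(0.0, 1.0)] * pmap.n_free
        for x0 in starts:
            res = optimize.minimize(
                _neg_loglik_and_grad,
                np.clip(x0, 0.0, 1.0),
                args=(pmap, counts, c),
                method="L-BFGS-B",
                jac=True,
                bounds=bounds,
                options={"ftol": 1e-13, "gtol": 1e-8, "maxiter": 1000},
            )
            if res.fun < best_fun - 1e-12:
                best_x, best_fun = res.x, float(res.fun)
                converged = bool(res.success)
        if best_x is None:
            raise RuntimeError(
                f"all {len(starts)} optimisation starts failed for spec "
                f"with {pmap.n_free} free parameters"
            )

    theta = pmap.expand(best_x)
    probs = tree_probabilities(theta, c)
    totals = np.stack(
        [[cond.cp_total] * 3 + [cond.ca_total] * 3 for cond in ordered]
    ).astype(float)
    expected = totals * probs
    g2 = g_squared(counts, expected)
    estimates = pmap.estimates_dict(best_x)
    boundary = {
        name: bool(v <= _BOUNDARY_TOL or v >= 1.0 - _BOUNDARY_TOL)
        for name, v in estimates.items()
    }

    fit = FitResult(
        spec=spec,
        estimates=estimates,
        log_likelihood=-best_fun,
        g_squared=g2,
        df=df,
        p_value=_chi2_upper_tail(g2, df),
        n_starts=len(starts),
        converged=converged,
        theta=theta,
        expected={
            cond.condition_id: dict(zip(CATEGORIES, expected[j].tolist()))
            for j, cond in enumerate(ordered)
        },
        observed={
            cond.condition_id: dict(zip(CATEGORIES, counts[j].tolist()))
            for j, cond in enumerate(ordered)
        },
        boundary=boundary,
    )
    if compute_ci and pmap.n_free > 0:
        wald_intervals(fit, ordered)
    return fit


def wald_intervals(
    fit: FitResult, dataset: Sequence[LineupCounts] | None = None
) -> FitResult:
    """Attach Wald standard errors and 95% confidence intervals to a fit.

    Standard errors come from the inverse of the observed information matrix
    (negative Hessian of the log-likelihood at the MLE, evaluated by central
    finite differences).  Intervals are ``estimate +/- 1.96 * SE`` clipped to
    [0, 1]; parameters flagged as boundary solutions get one-sided clipped
    intervals.  A singular information matrix produces NaN standard errors
    with a warning rather than an error.
    """
    spec = fit.spec
    if dataset is None:
        # rebuild counts from the stored observed table
        counts = np.array(
            [
                [fit.observed[cond][cat] for cat in CATEGORIES]
                for cond in spec.conditions
            ]
        )
    else:
        by_id = {cond.condition_id: cond for cond in dataset}
        counts = counts_matrix([by_id[cond] for cond in spec.conditions])
    pmap = spec.parameter_map()
    x = np.array([fit.estimates[name] for name in pmap.free_names])

    def nll(v: np.ndarray) -> float:
        return _neg_loglik_and_grad(v, pmap, counts, spec.sampling_constant)[0]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hess = approx_hess1(x, nll, epsilon=1e-5)
    try:
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        if np.any(~np.isfinite(diag)):
            raise np.linalg.LinAlgError("non-finite covariance diagonal")
        se = np.sqrt(np.clip(diag, 0.0, None))
        if np.any(diag < -1e-8):
            warnings.warn(
                "observed information is not positive definite; some standard "
                "errors are unreliable",
                RuntimeWarning,
                stacklevel=2,
            )
            se = np.where(diag < -1e-8, np.nan, se)
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular observed information matrix; standard errors undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        se = np.full(pmap.n_free, np.nan)

    fit.standard_errors = dict(zip(pmap.free_names, se.tolist()))
    ci: dict[str, tuple[float, float]] = {}
    for name, est, s in zip(pmap.free_names, x, se):
        if np.isnan(s):
            ci[name] = (float("nan"), float("nan"))
            continue
        lo = max(0.0, est - 1.96 * s)
        hi = min(1.0, est + 1.96 * s)
        if fit.boundary.get(name):
            # one-sided: pin the interval to the boundary the estimate sits on
            if est <= 0.5:
                lo = 0.0
            else:
                hi = 1.0
        ci[name] = (float(lo), float(hi))
    fit.ci95 = ci
    return fit
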