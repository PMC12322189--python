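"""Nested-model hypothesis tests: Delta-G^2 with asymptotic and bootstrap p-values.

An equality or fixed-value restriction added to a model produces a nested
null model.  The drop in fit, ``Delta G^2 = G^2(restricted) - G^2(base)``,
is asymptotically chi-square on the difference in free parameters; when
estimates sit near the boundary of the parameter space the asymptotics are
unreliable and a parametric bootstrap is used instead: replicate datasets are
drawn from the fitted null model at the observed tree totals, both models are
refitted to each replicate, and the p-value is the proportion of replicate
``Delta G^2`` values at least as large as the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .estimation import FitResult, degrees_of_freedom, fit_model
from .model import (
    LineupCounts,
    ModelSpec,
    ValidationError,
    tree_probabilities,
    validate_dataset,
)

__all__ = ["ComparisonResult", "is_nested", "compare_nested", "bootstrap_p"]


@dataclass
class ComparisonResult:
    """Outcome of a nested-model likelihood-ratio comparison."""

    delta_g_squared: float
    delta_df: int
    p_asymptotic: float
    p_bootstrap: float | None = None
    bootstrap_reps: int | None = None
    seed: int | None = None
    n_retried: int = 0

    def to_dict(self) -> dict:
        out = {
            "delta_g_squared": float(self.delta_g_squared),
            "delta_df": int(self.delta_df),
            "p_asymptotic": float(self.p_asymptotic),
        }
        if self.p_bootstrap is not None:
            out["p_bootstrap"] = float(self.p_bootstrap)
            out["bootstrap_reps"] = int(self.bootstrap_reps)
            out["seed"] = self.seed
            out["n_retried"] = int(self.n_retried)
        return out


def _slot_classes(spec: ModelSpec) -> dict[tuple[str, str], object]:
    """Map each (family, condition) slot to its symbol (free name or fixed value)."""
    return spec.parameter_map().slot_symbol


def is_nested(base: ModelSpec, restricted: ModelSpec) -> bool:
    """Structural check that ``restricted`` nests within ``base``.

    Requires identical conditions and sampling constant; every pair of slots
    equated in the base must remain equated in the restricted model, and every
    slot fixed in the base must carry the same fixed value in the restricted
    model.
    """
    if base.conditions != restricted.conditions:
        return False
    if base.sampling_constant != restricted.sampling_constant:
        return False
    base_sym = _slot_classes(base)
    restr_sym = _slot_classes(restricted)
    slots = list(base_sym)
    for i, s1 in enumerate(slots):
        v1 = base_sym[s1]
        if isinstance(v1, float):
            if restr_sym[s1] != v1:
                return False
            continue
        for s2 in slots[i + 1 :]:
            if base_sym[s2] == v1 and restr_sym[s1] != restr_sym[s2]:
                return False
    return True


def compare_nested(base_fit: FitResult, restricted_fit: FitResult) -> ComparisonResult:
    """Delta-G^2 test between a base fit and a nested restricted fit."""
    if not is_nested(base_fit.spec, restricted_fit.spec):
        raise ValidationError(
            "restricted model is not nested within the base model"
        )
    delta_df = restricted_fit.df - base_fit.df
    delta_g2 = restricted_fit.g_squared - base_fit.g_squared
    if delta_g2 < -1e-6:
        raise RuntimeError(
            f"restricted fit beats the base fit (Delta G^2 = {delta_g2:.3g}); "
            "the base optimisation has not converged - increase n_starts"
        )
    delta_g2 = max(delta_g2, 0.0)
    if delta_df == 0:
        p = 1.0 if delta_g2 <= 1e-8 else 0.0
    else:
        p = float(stats.chi2.sf(delta_g2, delta_df))
    return ComparisonResult(delta_g2, delta_df, p)


def _simulate_from_fit(
    fit: FitResult, dataset: Sequence[LineupCounts], rng: np.random.Generator
) -> list[LineupCounts]:
    """Draw one parametric-bootstrap dataset from a fitted model."""
    reps = []
    for cond in dataset:
        theta = fit.params_for(cond.condition_id).as_array()
        probs = tree_probabilities(theta, fit.spec.sampling_constant)
        cp = rng.multinomial(cond.cp_total, probs[:3] / probs[:3].sum())
        ca = rng.multinomial(cond.ca_total, probs[3:] / probs[3:].sum())
        reps.append(
            LineupCounts(
                cond.condition_id,
                cond.nominal_delay,
                cond.actual_delay_days,
                int(cp[0]),
                int(cp[1]),
                int(cp[2]),
                int(ca[0]),
                int(ca[1]),
                int(ca[2]),
            )
        )
    return reps


def bootstrap_p(
    dataset: Sequence[LineupCounts],
    base_spec: ModelSpec,
    restricted_spec: ModelSpec,
    reps: int = 2000,
    seed: int = 1,
    n_starts: int = 20,
    replicate_starts: int = 5,
    max_failure_rate: float = 0.01,
) -> ComparisonResult:
    """Parametric-bootstrap p-value for a nested-model comparison.

    Replicate datasets are multinomial draws from the restricted-model fitted
    probabilities at the observed per-tree totals.  Both models are refitted
    to every replicate (``replicate_starts`` optimisation starts each, warm
    started at the observed-data solutions) and the p-value is the simple
    proportion of replicates with ``Delta G^2* >= Delta G^2(observed)``.

    All randomness derives from ``seed`` through one independent substream
    per replicate, so results do not depend on execution order.  Replicate
    fits that fail are retried with fresh starts; more than
    ``max_failure_rate`` unrecovered failures is an error.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    if not is_nested(base_spec, restricted_spec):
        raise ValidationError("restricted model is not nested within the base model")
    dataset = validate_dataset(dataset)
    base_fit = fit_model(dataset, base_spec, n_starts=n_starts, seed=seed,
                         compute_ci=False)
    restricted_fit = fit_model(dataset, restricted_spec, n_starts=n_starts,
                               seed=seed, compute_ci=False)
    observed = compare_nested(base_fit, restricted_fit)
    delta_df = observed.delta_df

    base_pmap = base_spec.parameter_map()
    restr_pmap = restricted_spec.parameter_map()
    base_warm = np.array([base_fit.estimates[n] for n in base_pmap.free_names])
    restr_warm = np.array(
        [restricted_fit.estimates[n] for n in restr_pmap.free_names]
    )

    children = np.random.SeedSequence(seed).spawn(reps)
    exceed = 0
    failures = 0
    retried = 0
    for child in children:
        rng = np.random.default_rng(child)
        rep_data = _simulate_from_fit(restricted_fit, dataset, rng)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        dg2 = None
        for attempt in range(3):
            try:
                rb = fit_model(
                    rep_data, base_spec, n_starts=replicate_starts,
                    seed=rep_seed + attempt, warm_starts=[base_warm],
                    compute_ci=False,
                )
                rr = fit_model(
                    rep_data, restricted_spec, n_starts=replicate_starts,
                    seed=rep_seed + attempt, warm_starts=[restr_warm],
                    compute_ci=False,
                )
                dg2 = compare_nested(rb, rr).delta_g_squared
                break
            except RuntimeError:
                retried += 1
        if dg2 is None:
            failures += 1
            continue
        if dg2 >= observed.delta_g_squared:
            exceed += 1
    if failures > max_failure_rate * reps:
        raise RuntimeError(
            f"{failures}/{reps} bootstrap replicates failed to fit"
        )
    p_boot = exceed / (reps - failures)
    return ComparisonResult(
        delta_g_squared=observed.delta_g_squared,
        delta_df=delta_df,
        p_asymptotic=observed.p_asymptotic,
        p_bootstrap=p_boot,
        bootstrap_reps=reps,
        seed=seed,
        n_retried=retried,
    )
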