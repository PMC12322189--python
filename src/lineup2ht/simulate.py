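"""Synthetic lineup data and the packaged four-delay study dataset.

Simulation collapses participant-level responding to tree-level multinomials:
each participant answers two culprit-present and two culprit-absent lineups,
and under the model those responses are independent draws from the
category probabilities, so a condition with ``k`` participants is two
multinomial samples of size ``2k``.  This matches the aggregated likelihood
used for fitting.

The packaged dataset contains the observed response frequencies of a large
online eyewitness identification study (2,108 participants) with four
crime-to-lineup delays: none, one day, one week (average actual delay eight
days) and one month (average actual delay 33 days).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .curves import CurveFit, predict_curve
from .model import (
    ConditionParams,
    LineupCounts,
    ValidationError,
    DEFAULT_SAMPLING_CONSTANT,
    tree_probabilities,
    validate_dataset,
)

__all__ = [
    "SimDesign",
    "load_delay_study",
    "simulate_condition",
    "simulate_study",
    "study_design",
]

# Observed response frequencies of the packaged four-delay study:
# (condition, nominal delay, average actual delay in days,
#  CP: culprit/filler/reject, CA: suspect/filler/reject)
_DELAY_STUDY = (
    ("no_delay", "none", 0.0, 401, 276, 423, 133, 383, 584),
    ("one_day", "1 day", 1.0, 265, 355, 444, 137, 397, 530),
    ("one_week", "1 week", 8.0, 188, 359, 493, 117, 396, 527),
    ("one_month", "1 month", 33.0, 134, 347, 531, 109, 370, 533),
)


def load_delay_study() -> list[LineupCounts]:
    """The packaged four-delay eyewitness identification dataset.

    Four conditions at average actual delays of 0, 1, 8 and 33 days; each
    condition's tree totals equal twice its participant count
    (550, 532, 520 and 506 participants respectively).
    """
    return validate_dataset(LineupCounts(*row) for row in _DELAY_STUDY)


@dataclass
class SimDesign:
    """Design of a simulated multi-condition lineup study.

    ``dp`` is either an explicit per-condition sequence or a
    :class:`~lineup2ht.curves.CurveFit` evaluated at the delays.  ``b``,
    ``g`` and ``dA`` may be scalars (shared) or per-condition sequences.
    Defaults emulate the packaged study: delays 0/1/8/33 days, its
    per-condition participant counts, and generating values derived from the
    fitted model (b = 0.04, g = 0.45, dA = 0.02, dP from the fitted
    modified power curve).
    """

    delays: tuple[float, ...] = (0.0, 1.0, 8.0, 33.0)
    participants: tuple[int, ...] = (550, 532, 520, 506)
    dp: object = field(
        default_factory=lambda: CurveFit(
            "modified_power", {"lambda": 0.2744, "psi": 0.726},
            r_squared=float("nan"), ss_res=float("nan"),
            delays=(), values=(),
        )
    )
    b: object = 0.04
    g: object = 0.45
    dA: object = 0.02
    sampling_constant: float = DEFAULT_SAMPLING_CONSTANT
    seed: int = 1
    condition_ids: tuple[str, ...] | None = None

    def _per_condition(self, value, name: str) -> np.ndarray:
        n = len(self.delays)
        arr = (
            np.full(n, float(value))
            if np.isscalar(value)
            else np.asarray(value, dtype=float)
        )
        if arr.shape != (n,):
            raise ValidationError(f"{name} must be scalar or length {n}")
        return arr

    def generating_params(self) -> list[ConditionParams]:
        """Evaluate the design's per-condition 2-HT parameters."""
        if isinstance(self.dp, CurveFit):
            dp = np.asarray(predict_curve(self.dp, np.asarray(self.delays)))
        else:
            dp = self._per_condition(self.dp, "dp")
        if np.any((dp < 0) | (dp > 1)):
            raise ValidationError(
                "generating dP leaves [0, 1] at the requested delays"
            )
        b = self._per_condition(self.b, "b")
        g = self._per_condition(self.g, "g")
        dA = self._per_condition(self.dA, "dA")
        return [
            ConditionParams(dp[j], b[j], g[j], dA[j])
            for j in range(len(self.delays))
        ]

    def labels(self) -> tuple[str, ...]:
        if self.condition_ids is not None:
            return self.condition_ids
        return tuple(f"delay_{d:g}d" for d in self.delays)


def simulate_condition(
    params: ConditionParams,
    participants: int,
    sampling_constant: float = DEFAULT_SAMPLING_CONSTANT,
    seed: int | np.random.SeedSequence = 1,
    condition_id: str = "sim",
    nominal_delay: str = "",
    actual_delay_days: float = 0.0,
) -> LineupCounts:
    """Simulate one condition: two multinomials of size ``2 * participants``."""
    if participants < 1:
        raise ValidationError("participants must be >= 1")
    rng = np.random.default_rng(seed)
    probs = tree_probabilities(params.as_array(), sampling_constant)
    n = 2 * participants
    cp = rng.multinomial(n, probs[:3] / probs[:3].sum())
    ca = rng.multinomial(n, probs[3:] / probs[3:].sum())
    return LineupCounts(
        condition_id, nominal_delay or f"{actual_delay_days:g} days",
        actual_delay_days,
        int(cp[0]), int(cp[1]), int(cp[2]),
        int(ca[0]), int(ca[1]), int(ca[2]),
    )


def simulate_study(design: SimDesign) -> list[LineupCounts]:
    """Simulate a full multi-condition study from a :class:`SimDesign`.

    Each condition uses an independent substream spawned deterministically
    from the design's master seed, so the dataset is reproducible and
    per-condition draws are independent.
    """
    params = design.generating_params()
    labels = design.labels()
    if len(design.participants) != len(design.delays):
        raise ValidationError("participants must match the number of delays")
    children = np.random.SeedSequence(design.seed).spawn(len(design.delays))
    dataset = [
        simulate_condition(
            params[j],
            design.participants[j],
            design.sampling_constant,
            seed=children[j],
            condition_id=labels[j],
            actual_delay_days=design.delays[j],
        )
        for j in range(len(design.delays))
    ]
    return validate_dataset(dataset)


def study_design(**overrides) -> SimDesign:
    """A :class:`SimDesign` emulating the packaged study's conditions."""
    design = SimDesign(**overrides)
    if design.condition_ids is None and tuple(design.delays) == (0.0, 1.0, 8.0, 33.0):
        design.condition_ids = tuple(row[0] for row in _DELAY_STUDY)
    return design
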