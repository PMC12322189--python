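"""Core structure of the two-high-threshold (2-HT) eyewitness identification model.

The 2-HT model is a multinomial processing tree (MPT) model for simultaneous
lineup data.  Each delay condition contributes two multinomial trees with
three observable response categories each:

* culprit-present lineups: culprit identification, filler identification,
  lineup rejection;
* culprit-absent lineups: innocent-suspect identification, filler
  identification, lineup rejection.

Four latent process probabilities generate these responses:

``dP``
    culprit-presence detection (leads directly to a culprit identification),
``b``
    biased suspect selection in the absence of detection (the lineup-fairness
    parameter; ``b > 0`` means the suspect stands out),
``g``
    guessing-based selection (no preference for the suspect: the suspect is
    sampled with the constant probability ``1/n`` for an ``n``-person lineup),
``dA``
    culprit-absence detection (leads directly to a correct rejection).

This module holds the domain types (counts, parameters, restrictions, model
specifications), the mapping from parameters to category probabilities (with
analytic gradients, used by the fitting routines), dataset validation, and
export of the model to the plain-text EQN format understood by standard MPT
software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PARAM_FAMILIES",
    "DEFAULT_SAMPLING_CONSTANT",
    "CATEGORIES",
    "LineupCounts",
    "ConditionParams",
    "CategoryProbabilities",
    "RestrictionSet",
    "ModelSpec",
    "ParameterMap",
    "category_probabilities",
    "expected_counts",
    "validate_dataset",
    "export_eqn",
]

#: Parameter families, in canonical order (also the column order of the
#: internal ``theta`` arrays of shape ``(n_conditions, 4)``).
PARAM_FAMILIES = ("dP", "b", "g", "dA")

#: Suspect-sampling constant ``1/n`` for a six-person lineup, written with the
#: five-digit rounding conventionally used in MPT model files.
DEFAULT_SAMPLING_CONSTANT = 0.16667

CP_CATEGORIES = ("cp_culprit", "cp_filler", "cp_reject")
CA_CATEGORIES = ("ca_suspect", "ca_filler", "ca_reject")
CATEGORIES = CP_CATEGORIES + CA_CATEGORIES


class ValidationError(ValueError):
    """Raised when counts, parameters or model specifications are inconsistent."""


def _check_prob(name: str, value: float) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise ValidationError(f"parameter {name!r} must lie in [0, 1], got {value}")
    return value


@dataclass(frozen=True)
class LineupCounts:
    """Observed response frequencies for one delay condition.

    One culprit-present tree (``cp_*``) and one culprit-absent tree (``ca_*``),
    three categories each, in the fixed order
    (culprit/suspect, filler, rejection).
    """

    condition_id: str
    nominal_delay: str
    actual_delay_days: float
    cp_culprit: int
    cp_filler: int
    cp_reject: int
    ca_suspect: int
    ca_filler: int
    ca_reject: int

    def __post_init__(self) -> None:
        if self.actual_delay_days < 0:
            raise ValidationError(
                f"condition {self.condition_id!r}: actual_delay_days must be >= 0"
            )
        for name in CATEGORIES:
            value = getattr(self, name)
            if int(value) != value or value < 0:
                raise ValidationError(
                    f"condition {self.condition_id!r}: count {name} must be a "
                    f"non-negative integer, got {value!r}"
                )

    @property
    def cp_total(self) -> int:
        return self.cp_culprit + self.cp_filler + self.cp_reject

    @property
    def ca_total(self) -> int:
        return self.ca_suspect + self.ca_filler + self.ca_reject

    def as_array(self) -> np.ndarray:
        """The six counts as a float array in canonical category order."""
        return np.array([getattr(self, name) for name in CATEGORIES], dtype=float)


@dataclass(frozen=True)
class ConditionParams:
    """The four 2-HT process probabilities for a single condition."""

    dP: float
    b: float
    g: float
    dA: float

    def __post_init__(self) -> None:
        for name in PARAM_FAMILIES:
            object.__setattr__(self, name, _check_prob(name, getattr(self, name)))

    def as_array(self) -> np.ndarray:
        return np.array([self.dP, self.b, self.g, self.dA], dtype=float)


@dataclass(frozen=True)
class CategoryProbabilities:
    """Probabilities of the six observable response categories.

    Each tree's three probabilities sum to one by construction.
    """

    p_cp_culprit: float
    p_cp_filler: float
    p_cp_reject: float
    p_ca_suspect: float
    p_ca_filler: float
    p_ca_reject: float

    def cp(self) -> np.ndarray:
        return np.array([self.p_cp_culprit, self.p_cp_filler, self.p_cp_reject])

    def ca(self) -> np.ndarray:
        return np.array([self.p_ca_suspect, self.p_ca_filler, self.p_ca_reject])

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.cp(), self.ca()])


# ---------------------------------------------------------------------------
# Category probabilities and their gradient
# ---------------------------------------------------------------------------

def tree_probabilities(theta: np.ndarray, sampling_constant: float) -> np.ndarray:
    """Vectorised 2-HT category probabilities.

    Parameters
    ----------
    theta
        Array of shape ``(..., 4)`` with columns ``(dP, b, g, dA)``.
    sampling_constant
        The constant ``1/n`` for the lineup size ``n``.

    Returns
    -------
    Array of shape ``(..., 6)`` in canonical category order; each tree's
    probabilities sum to one exactly (up to floating point).
    """
    theta = np.asarray(theta, dtype=float)
    c = float(sampling_constant)
    dP, b, g, dA = (theta[..., i] for i in range(4))
    # probability of landing on the suspect through bias or guessing,
    # conditional on no detection
    suspect_pick = b + (1.0 - b) * g * c
    filler_pick = (1.0 - b) * g * (1.0 - c)
    reject = (1.0 - b) * (1.0 - g)
    out = np.empty(theta.shape[:-1] + (6,), dtype=float)
    out[..., 0] = dP + (1.0 - dP) * suspect_pick
    out[..., 1] = (1.0 - dP) * filler_pick
    out[..., 2] = (1.0 - dP) * reject
    out[..., 3] = (1.0 - dA) * suspect_pick
    out[..., 4] = (1.0 - dA) * filler_pick
    out[..., 5] = dA + (1.0 - dA) * reject
    return out


def tree_probability_gradient(theta: np.ndarray, sampling_constant: float) -> np.ndarray:
    """Jacobian of :func:`tree_probabilities`.

    Returns an array of shape ``(..., 6, 4)``: derivative of each category
    probability with respect to ``(dP, b, g, dA)``.
    """
    theta = np.asarray(theta, dtype=float)
    c = float(sampling_constant)
    dP, b, g, dA = (theta[..., i] for i in range(4))
    suspect_pick = b + (1.0 - b) * g * c
    filler_pick = (1.0 - b) * g * (1.0 - c)
    reject = (1.0 - b) * (1.0 - g)
    d_suspect_db = 1.0 - g * c
    d_filler_db = -g * (1.0 - c)
    d_reject_db = -(1.0 - g)
    d_suspect_dg = (1.0 - b) * c
    d_filler_dg = (1.0 - b) * (1.0 - c)
    d_reject_dg = -(1.0 - b)

    jac = np.zeros(theta.shape[:-1] + (6, 4), dtype=float)
    # culprit-present tree
    jac[..., 0, 0] = 1.0 - suspect_pick
    jac[..., 0, 1] = (1.0 - dP) * d_suspect_db
    jac[..., 0, 2] = (1.0 - dP) * d_suspect_dg
    jac[..., 1, 0] = -filler_pick
    jac[..., 1, 1] = (1.0 - dP) * d_filler_db
    jac[..., 1, 2] = (1.0 - dP) * d_filler_dg
    jac[..., 2, 0] = -reject
    jac[..., 2, 1] = (1.0 - dP) * d_reject_db
    jac[..., 2, 2] = (1.0 - dP) * d_reject_dg
    # culprit-absent tree
    jac[..., 3, 3] = -suspect_pick
    jac[..., 3, 1] = (1.0 - dA) * d_suspect_db
    jac[..., 3, 2] = (1.0 - dA) * d_suspect_dg
    jac[..., 4, 3] = -filler_pick
    jac[..., 4, 1] = (1.0 - dA) * d_filler_db
    jac[..., 4, 2] = (1.0 - dA) * d_filler_dg
    jac[..., 5, 3] = 1.0 - reject
    jac[..., 5, 1] = (1.0 - dA) * d_reject_db
    jac[..., 5, 2] = (1.0 - dA) * d_reject_dg
    return jac


def category_probabilities(
    params: ConditionParams,
    sampling_constant: float = DEFAULT_SAMPLING_CONSTANT,
) -> CategoryProbabilities:
    """Map 2-HT parameters to the six response-category probabilities.

    Culprit-present tree::

        P(culprit)  = dP + (1-dP)*b + (1-dP)*(1-b)*g*c
        P(filler)   = (1-dP)*(1-b)*g*(1-c)
        P(reject)   = (1-dP)*(1-b)*(1-g)

    Culprit-absent tree::

        P(suspect)  = (1-dA)*b + (1-dA)*(1-b)*g*c
        P(filler)   = (1-dA)*(1-b)*g*(1-c)
        P(reject)   = dA + (1-dA)*(1-b)*(1-g)

    where ``c`` is the suspect-sampling constant ``1/n``.
    """
    if not isinstance(params, ConditionParams):
        params = ConditionParams(*params)
    c = float(sampling_constant)
    if not (0.0 < c < 1.0):
        raise ValidationError(
            f"parameter 'sampling_constant' must lie in (0, 1), got {c}"
        )
    probs = tree_probabilities(params.as_array(), c)
    return CategoryProbabilities(*probs.tolist())


def expected_counts(
    probs: CategoryProbabilities, n_cp: float, n_ca: float
) -> np.ndarray:
    """Expected frequencies for the six categories at given tree totals."""
    if n_cp < 0 or n_ca < 0:
        raise ValidationError("tree totals must be non-negative")
    return np.concatenate([n_cp * probs.cp(), n_ca * probs.ca()])


def validate_dataset(dataset: Iterable[LineupCounts]) -> list[LineupCounts]:
    """Check a multi-condition dataset and return it ordered by actual delay.

    Rejects duplicate condition labels and conditions with an empty tree.
    Ties in the delay are broken by the input order (stable sort).
    """
    conditions = list(dataset)
    if not conditions:
        raise ValidationError("dataset contains no conditions")
    seen: set[str] = set()
    for cond in conditions:
        if cond.condition_id in seen:
            raise ValidationError(f"duplicate condition label {cond.condition_id!r}")
        seen.add(cond.condition_id)
        if cond.cp_total <= 0:
            raise ValidationError(
                f"condition {cond.condition_id!r}: culprit-present tree has no responses"
            )
        if cond.ca_total <= 0:
            raise ValidationError(
                f"condition {cond.condition_id!r}: culprit-absent tree has no responses"
            )
    return sorted(conditions, key=lambda cond: cond.actual_delay_days)


# ---------------------------------------------------------------------------
# Restrictions and model specifications
# ---------------------------------------------------------------------------

Slot = tuple[str, str]  # (parameter family, condition label)


@dataclass(frozen=True)
class RestrictionSet:
    """Equality and fixed-value constraints defining a testable model.

    ``equality_classes`` is a tuple of groups; each group is a tuple of
    ``(family, condition)`` slots constrained to share one free parameter.
    ``fixed_values`` maps slots to constants in [0, 1]; fixing any member of
    an equality class fixes the whole class.
    """

    equality_classes: tuple[tuple[Slot, ...], ...] = ()
    fixed_values: Mapping[Slot, float] = field(default_factory=dict)

    def equate(self, family: str, conditions: Sequence[str]) -> "RestrictionSet":
        """Return a new set with ``family`` equated across ``conditions``."""
        group = tuple((family, cond) for cond in conditions)
        return replace(self, equality_classes=self.equality_classes + (group,))

    def fix(self, family: str, condition: str, value: float) -> "RestrictionSet":
        fixed = dict(self.fixed_values)
        fixed[(family, condition)] = _check_prob(f"{family}[{condition}]", value)
        return replace(self, fixed_values=fixed)


@dataclass(frozen=True)
class ModelSpec:
    """A multi-condition 2-HT model: conditions, restrictions, sampling constant."""

    conditions: tuple[str, ...]
    restrictions: RestrictionSet = field(default_factory=RestrictionSet)
    sampling_constant: float = DEFAULT_SAMPLING_CONSTANT

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if len(set(self.conditions)) != len(self.conditions):
            raise ValidationError("condition labels must be unique")
        if not (0.0 < self.sampling_constant < 1.0):
            raise ValidationError(
                f"sampling_constant must lie in (0, 1), got {self.sampling_constant}"
            )
        known = set(self.conditions)
        for group in self.restrictions.equality_classes:
            for fam, cond in group:
                self._check_slot(fam, cond, known)
        for (fam, cond), value in self.restrictions.fixed_values.items():
            self._check_slot(fam, cond, known)
            _check_prob(f"{fam}[{cond}]", value)

    @staticmethod
    def _check_slot(fam: str, cond: str, known: set[str]) -> None:
        if fam not in PARAM_FAMILIES:
            raise ValidationError(f"unknown parameter family {fam!r}")
        if cond not in known:
            raise ValidationError(f"restriction refers to unknown condition {cond!r}")

    @classmethod
    def base(
        cls,
        conditions: Sequence[str],
        sampling_constant: float = DEFAULT_SAMPLING_CONSTANT,
    ) -> "ModelSpec":
        """The base model: ``b`` equated across conditions, everything else free."""
        conditions = tuple(conditions)
        restrictions = RestrictionSet().equate("b", conditions)
        return cls(conditions, restrictions, sampling_constant)

    @classmethod
    def saturated(
        cls,
        conditions: Sequence[str],
        sampling_constant: float = DEFAULT_SAMPLING_CONSTANT,
    ) -> "ModelSpec":
        """All 4 parameters free in every condition (zero data degrees of freedom)."""
        return cls(tuple(conditions), RestrictionSet(), sampling_constant)

    def with_equated(self, family: str) -> "ModelSpec":
        """Return a spec adding an equality of ``family`` across all conditions."""
        return replace(
            self, restrictions=self.restrictions.equate(family, self.conditions)
        )

    def with_fixed(self, family: str, value: float, conditions=None) -> "ModelSpec":
        restrictions = self.restrictions
        for cond in conditions if conditions is not None else self.conditions:
            restrictions = restrictions.fix(family, cond, value)
        return replace(self, restrictions=restrictions)

    def parameter_map(self) -> "ParameterMap":
        return ParameterMap(self)


class ParameterMap:
    """Index structure between a :class:`ModelSpec` and its free-parameter vector.

    Resolves the restriction set into disjoint parameter classes via
    union-find, assigns one free coordinate per unfixed class, and provides
    the expand/contract maps used by the likelihood code.
    """

    def __init__(self, spec: ModelSpec) -> None:
        self.spec = spec
        conditions = spec.conditions
        slots: list[Slot] = [
            (fam, cond) for fam in PARAM_FAMILIES for cond in conditions
        ]
        index = {slot: i for i, slot in enumerate(slots)}
        parent = list(range(len(slots)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i: int, j: int) -> None:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

        for group in spec.restrictions.equality_classes:
            first = index[group[0]]
            for slot in group[1:]:
                union(first, index[slot])

        fixed_root: dict[int, float] = {}
        for slot, value in spec.restrictions.fixed_values.items():
            root = find(index[slot])
            if root in fixed_root and fixed_root[root] != value:
                raise ValidationError(
                    f"slot {slot} is fixed to conflicting values "
                    f"({fixed_root[root]} vs {value})"
                )
            fixed_root[root] = float(value)

        members: dict[int, list[Slot]] = {}
        for slot in slots:
            members.setdefault(find(index[slot]), []).append(slot)

        n_cond = len(conditions)
        cond_pos = {cond: j for j, cond in enumerate(conditions)}
        fam_pos = {fam: f for f, fam in enumerate(PARAM_FAMILIES)}
        self.free_index = np.full((n_cond, 4), -1, dtype=int)
        self.fixed_theta = np.zeros((n_cond, 4), dtype=float)
        self.free_names: list[str] = []
        self.free_members: list[tuple[Slot, ...]] = []
        self.slot_symbol: dict[Slot, str | float] = {}

        for root in sorted(members):
            group = members[root]
            if root in fixed_root:
                value = fixed_root[root]
                for fam, cond in group:
                    self.fixed_theta[cond_pos[cond], fam_pos[fam]] = value
                    self.slot_symbol[(fam, cond)] = value
                continue
            name = self._class_name(group, conditions)
            k = len(self.free_names)
            self.free_names.append(name)
            self.free_members.append(tuple(group))
            for fam, cond in group:
                self.free_index[cond_pos[cond], fam_pos[fam]] = k
                self.slot_symbol[(fam, cond)] = name
        self.n_free = len(self.free_names)
        self._free_mask = self.free_index >= 0

    @staticmethod
    def _class_name(group: Sequence[Slot], conditions: Sequence[str]) -> str:
        families = {fam for fam, _ in group}
        if len(families) == 1:
            fam = next(iter(families))
            conds = {cond for _, cond in group}
            if conds == set(conditions):
                return fam
            if len(group) == 1:
                return f"{fam}[{group[0][1]}]"
            ordered = [cond for cond in conditions if cond in conds]
            return f"{fam}[{'='.join(ordered)}]"
        return "=".join(f"{fam}[{cond}]" for fam, cond in group)

    def expand(self, x: np.ndarray) -> np.ndarray:
        """Free vector -> full ``(n_conditions, 4)`` parameter array."""
        theta = self.fixed_theta.copy()
        theta[self._free_mask] = np.asarray(x, dtype=float)[
            self.free_index[self._free_mask]
        ]
        return theta

    def contract_gradient(self, grad_theta: np.ndarray) -> np.ndarray:
        """Accumulate a full-parameter gradient onto the free coordinates."""
        g = np.zeros(self.n_free)
        np.add.at(g, self.free_index[self._free_mask], grad_theta[self._free_mask])
        return g

    def estimates_dict(self, x: np.ndarray) -> dict[str, float]:
        return {name: float(v) for name, v in zip(self.free_names, x)}


# ---------------------------------------------------------------------------
# EQN export
# ---------------------------------------------------------------------------

#: branch structure of one condition: (tree, category, slots multiplied along
#: the branch, each tagged + for the parameter or - for its complement, and a
#: flag for the sampling constant: +1 multiply by c, -1 by (1-c), 0 absent)
_BRANCHES: tuple[tuple[str, str, tuple[tuple[str, int], ...], int], ...] = (
    ("cp", "culprit_id", (("dP", +1),), 0),
    ("cp", "culprit_id", (("dP", -1), ("b", +1)), 0),
    ("cp", "culprit_id", (("dP", -1), ("b", -1), ("g", +1)), +1),
    ("cp", "filler_id", (("dP", -1), ("b", -1), ("g", +1)), -1),
    ("cp", "rejection", (("dP", -1), ("b", -1), ("g", -1)), 0),
    ("ca", "suspect_id", (("b", +1),), 0),
    ("ca", "suspect_id", (("b", -1), ("g", +1)), +1),
    ("ca", "filler_id", (("b", -1), ("g", +1)), -1),
    ("ca", "rejection", (("dA", +1),), 0),
    ("ca", "rejection", (("dA", -1), ("b", -1), ("g", -1)), 0),
)


def export_eqn(spec: ModelSpec) -> str:
    """Write the model as branch-per-line EQN text.

    One line per processing-tree branch: tree name, response category, and the
    product of parameter terms along the branch.  Parameters shared through
    equality restrictions appear under a single symbol; fixed parameters and
    the sampling constant appear as numeric literals.  The culprit-absent tree
    multiplies every non-detection branch by ``(1 - dA)``.
    """
    if not spec.conditions:
        raise ValidationError("model specification declares no conditions")
    pmap = spec.parameter_map()
    c = spec.sampling_constant

    def term(slot_value: str | float, sign: int) -> str:
        if isinstance(slot_value, str):
            return slot_value if sign > 0 else f"(1-{slot_value})"
        value = slot_value if sign > 0 else 1.0 - slot_value
        return f"{value:.5f}"

    lines = []
    for cond in spec.conditions:
        for tree, category, slots, c_flag in _BRANCHES:
            factors = []
            if tree == "ca":
                # every CA branch except explicit dA is conditional on 1-dA
                if slots[0][0] != "dA":
                    factors.append(term(pmap.slot_symbol[("dA", cond)], -1))
            for fam, sign in slots:
                factors.append(term(pmap.slot_symbol[(fam, cond)], sign))
            if c_flag:
                factors.append(term(c, c_flag))
            lines.append(f"{tree}_{cond} {category} {'*'.join(factors)}")
    return "\n".join(lines) + "\n"


def counts_matrix(dataset: Sequence[LineupCounts]) -> np.ndarray:
    """Stack a dataset into a ``(n_conditions, 6)`` count matrix."""
    return np.stack([cond.as_array() for cond in dataset])
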