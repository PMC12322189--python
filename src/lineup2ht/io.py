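"""CSV and YAML input/output.

Counts CSV dialect (one row per condition)::

    condition_id,nominal_delay,actual_delay_days,cp_culprit,cp_filler,
    cp_reject,ca_suspect,ca_filler,ca_reject

Restriction YAML files declare equality classes and fixed values by
parameter family, e.g.::

    equal:
      b: all            # one shared b across every condition
      dP: [one_day, one_week]
    fixed:
      dA: {one_month: 0.0}
    sampling_constant: 0.16667
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .model import (
    DEFAULT_SAMPLING_CONSTANT,
    LineupCounts,
    ModelSpec,
    RestrictionSet,
    ValidationError,
    validate_dataset,
)
from .simulate import SimDesign
from .curves import CurveFit

__all__ = [
    "read_counts_csv",
    "write_counts_csv",
    "read_model_yaml",
    "read_design_yaml",
]

_COLUMNS = [
    "condition_id", "nominal_delay", "actual_delay_days",
    "cp_culprit", "cp_filler", "cp_reject",
    "ca_suspect", "ca_filler", "ca_reject",
]


def read_counts_csv(path) -> list[LineupCounts]:
    """Load and validate a per-condition counts table."""
    frame = pd.read_csv(path)
    missing = [col for col in _COLUMNS if col not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    dataset = []
    for i, row in frame.iterrows():
        try:
            dataset.append(
                LineupCounts(
                    str(row["condition_id"]),
                    str(row["nominal_delay"]),
                    float(row["actual_delay_days"]),
                    *(int(row[col]) for col in _COLUMNS[3:]),
                )
            )
        except (ValueError, TypeError) as err:
            raise ValidationError(f"{path}: row {i + 1}: {err}") from err
    return validate_dataset(dataset)


def write_counts_csv(dataset: Sequence[LineupCounts], path) -> None:
    frame = pd.DataFrame(
        [[getattr(cond, col) for col in _COLUMNS] for cond in dataset],
        columns=_COLUMNS,
    )
    frame.to_csv(path, index=False)


def _conditions_for(entry, conditions: Sequence[str]) -> list[str]:
    if entry == "all":
        return list(conditions)
    if isinstance(entry, (list, tuple)):
        return [str(c) for c in entry]
    raise ValidationError(f"expected 'all' or a list of conditions, got {entry!r}")


def read_model_yaml(path, conditions: Sequence[str]) -> ModelSpec:
    """Build a :class:`ModelSpec` from a restriction YAML file.

    ``conditions`` supplies the condition labels (typically from the counts
    CSV, ordered by delay); the YAML refers to them by name or via ``all``.
    """
    with open(path) as handle:
        doc = yaml.safe_load(handle) or {}
    restrictions = RestrictionSet()
    for family, entry in (doc.get("equal") or {}).items():
        restrictions = restrictions.equate(
            str(family), _conditions_for(entry, conditions)
        )
    for family, entry in (doc.get("fixed") or {}).items():
        if isinstance(entry, dict):
            for cond, value in entry.items():
                restrictions = restrictions.fix(str(family), str(cond), float(value))
        else:
            for cond in conditions:
                restrictions = restrictions.fix(str(family), cond, float(entry))
    constant = float(doc.get("sampling_constant", DEFAULT_SAMPLING_CONSTANT))
    return ModelSpec(tuple(conditions), restrictions, constant)


def read_design_yaml(path) -> SimDesign:
    """Build a :class:`~lineup2ht.simulate.SimDesign` from YAML.

    ``dp`` may be a list of per-condition values or a mapping
    ``{family: modified_power, lambda: ..., psi: ...}`` evaluated at the
    delays (``beta`` and a fixed ``lambda`` for the Wickelgren family).
    """
    with open(path) as handle:
        doc = yaml.safe_load(handle) or {}
    kwargs = {}
    for key in ("delays", "participants", "condition_ids"):
        if key in doc:
            kwargs[key] = tuple(doc[key])
    for key in ("b", "g", "dA", "sampling_constant", "seed"):
        if key in doc:
            kwargs[key] = doc[key]
    dp = doc.get("dp")
    if isinstance(dp, dict):
        family = dp.pop("family")
        fixed = {"lambda": float(dp.pop("lambda"))} if family == "wickelgren_simplified" else {}
        kwargs["dp"] = CurveFit(
            family, {k: float(v) for k, v in dp.items()},
            r_squared=float("nan"), ss_res=float("nan"),
            delays=(), values=(), fixed=fixed,
        )
    elif dp is not None:
        kwargs["dp"] = tuple(float(v) for v in dp)
    return SimDesign(**kwargs)


def packaged_data_path(name: str = "delay_study.csv") -> Path:
    """Path to a data file shipped inside the package."""
    return Path(__file__).parent / "data" / name


def packaged_config_path(name: str) -> Path:
    return Path(__file__).parent / "configs" / name
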