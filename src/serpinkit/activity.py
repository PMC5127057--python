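"""Residual-activity and group-summary arithmetic for inhibition panels."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from .assay_io import ActivityMeasurement
from .errors import DomainError, InputError

__all__ = [
    "GroupSummary",
    "percent_residual",
    "percent_inhibition",
    "fold_change",
    "summarize_groups",
]


@dataclass
class GroupSummary:
    group_label: str
    n: int
    mean_activity: float
    sem: float


def percent_residual(with_inhibitor: float, control: float) -> float:
    """Residual activity as a percent of the uninhibited control."""
    if control <= 0:
        raise DomainError(f"control rate must be > 0, got {control}")
    return 100.0 * with_inhibitor / control


def percent_inhibition(with_inhibitor: float, control: float) -> float:
    """Complement of the residual: 100 - percent_residual."""
    return 100.0 - percent_residual(with_inhibitor, control)


def fold_change(treated: GroupSummary, control: GroupSummary) -> float:
    if control.mean_activity <= 0:
        raise DomainError(
            f"control group {control.group_label!r} mean must be > 0, "
            f"got {control.mean_activity}"
        )
    return treated.mean_activity / control.mean_activity


def summarize_groups(measurements: Sequence[ActivityMeasurement]) -> list[GroupSummary]:
    """Per-group mean and SEM (sample sd with n-1, divided by sqrt(n)).

    Group order follows first appearance in the input.
    """
    if not measurements:
        raise InputError("no measurements supplied")
    order: list[str] = []
    groups: dict[str, list[float]] = {}
    for m in measurements:
        if m.group_label not in groups:
            order.append(m.group_label)
            groups[m.group_label] = []
        groups[m.group_label].append(m.activity)

    out = []
    for label in order:
        vals = groups[label]
        n = len(vals)
        mean = sum(vals) / n
        if n == 1:
            warnings.warn(
                f"group {label!r} has a single replicate; SEM reported as 0",
                stacklevel=2,
            )
            sem = 0.0
        else:
            var = sum((v - mean) ** 2 for v in vals) / (n - 1)
            sem = math.sqrt(var) / math.sqrt(n)
        out.append(GroupSummary(group_label=label, n=n, mean_activity=mean, sem=sem))
    return out
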