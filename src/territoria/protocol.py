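"""Field-protocol support for intrusion experiments.

Encodes the 12-direction semi-random trial schedule used in playback
fieldwork: trials run towards every 30 degrees, ordered in three orthogonal
"crosses" so that each territory is spanned uniformly early on — the first
trial direction is random, the second is its complement (+180), the third
and fourth are +90/+270 in random order, and the remaining eight directions
repeat the pattern within the leftover directions.

Also provides validation of recorded trial sets against a plan (direction
permutation, non-responses, duplicates) and a representation of the four
general intrusion-experiment setups (approaching/removing a fixed-intensity
cue, increasing/decreasing cue intensity at a fixed distance).  Only the
fixed-intensity setups yield reaction-horizon geometry directly;
fixed-distance setups require a separate calibration and are carried as
metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .simulate import TrialSet

FIELD_DIRECTIONS: tuple[int, ...] = tuple(range(0, 360, 30))


class Setup(Enum):
    APPROACH_FIXED_INTENSITY = "approach_fixed_intensity"
    REMOVE_FIXED_INTENSITY = "remove_fixed_intensity"
    INCREASE_FIXED_DISTANCE = "increase_fixed_distance"
    DECREASE_FIXED_DISTANCE = "decrease_fixed_distance"

    @property
    def yields_reaction_horizon(self) -> bool:
        return self in (
            Setup.APPROACH_FIXED_INTENSITY,
            Setup.REMOVE_FIXED_INTENSITY,
        )


@dataclass(frozen=True)
class TrialPlan:
    """An ordered 12-direction schedule for one individual."""

    individual: str
    directions: tuple[int, ...]
    setup: Setup = Setup.APPROACH_FIXED_INTENSITY

    def __post_init__(self) -> None:
        if sorted(self.directions) != sorted(FIELD_DIRECTIONS):
            raise ValueError("directions must be a permutation of 0,30,...,330")


def _cross(rng: np.random.Generator, remaining: list[int]) -> list[int]:
    """One 4-direction 'cross': base, +180, then +90/+270 in random order."""
    base = int(remaining[rng.integers(len(remaining))])
    right, left = (base + 90) % 360, (base + 270) % 360
    lateral = [right, left] if rng.random() < 0.5 else [left, right]
    return [base, (base + 180) % 360, *lateral]


def schedule_directions(rng: np.random.Generator) -> list[int]:
    """Semi-random order of the 12 field directions (three crosses)."""
    remaining = list(FIELD_DIRECTIONS)
    order: list[int] = []
    for _ in range(3):
        cross = _cross(rng, remaining)
        order.extend(cross)
        remaining = [d for d in remaining if d not in cross]
    return order


def make_plan(
    individual: str,
    rng: np.random.Generator,
    setup: Setup = Setup.APPROACH_FIXED_INTENSITY,
) -> TrialPlan:
    return TrialPlan(individual=individual,
                     directions=tuple(schedule_directions(rng)), setup=setup)


@dataclass
class ValidationEntry:
    level: str  # "ok" | "warning" | "failure"
    individual: str
    message: str


@dataclass
class ValidationReport:
    entries: list[ValidationEntry] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not any(e.level == "failure" for e in self.entries)

    @property
    def warnings(self) -> list[ValidationEntry]:
        return [e for e in self.entries if e.level == "warning"]

    def add(self, level: str, individual: str, message: str) -> None:
        self.entries.append(ValidationEntry(level, individual, message))


def validate_trialset(trials, plan: TrialPlan | None = None) -> ValidationReport:
    """Check a recorded trial set: direction duplicates are failures,
    missing directions or non-responses are warnings (analysis proceeds —
    a territory may simply not extend in that direction).

    Accepts a :class:`TrialSet` or a raw sequence of trials (the latter is
    what a field spreadsheet parses to before constraints are enforced).
    """
    report = ValidationReport()
    trial_list = trials.trials if isinstance(trials, TrialSet) else list(trials)
    by_individual: dict[str, list] = {}
    for t in trial_list:
        by_individual.setdefault(t.individual, []).append(t)
    for ind, ts in sorted(by_individual.items()):
        dirs = [t.direction for t in ts]
        dupes = {d for d in dirs if dirs.count(d) > 1}
        for d in sorted(dupes):
            report.add("failure", ind, f"duplicate direction {d:g}")
        expected = set(plan.directions) if plan is not None else set(FIELD_DIRECTIONS)
        missing = expected - {int(d) for d in dirs if float(d).is_integer()}
        for d in sorted(missing):
            report.add("warning", ind, f"no trial towards {d} degrees")
        for t in ts:
            if not t.responded:
                report.add(
                    "warning", ind,
                    f"non-response at {t.direction:g} degrees (no endpoint)",
                )
        if not dupes and not missing and all(t.responded for t in ts):
            report.add("ok", ind, "complete 12-direction response set")
    return report
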