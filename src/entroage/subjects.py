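"""Subjects and basal metabolic rate.

BMR follows the Harris–Benedict regression

    BMR = 66.5 + 13.76 W + 5.003 H − 5.755 A   [kcal/day]

with weight W in kg, height H in cm and age A in years; daily caloric need is
BMR times a single activity multiplier (default 1.2, light activity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Any, Mapping

from .thermo import MetabolicConstants, default_db

__all__ = [
    "HEALTH_STATES",
    "Subject",
    "bmr_harris_benedict",
    "bmr_rounded",
    "daily_caloric_need",
    "subject_from_mapping",
    "read_subject",
]

HEALTH_STATES = ("healthy", "childpugh_A", "childpugh_B", "childpugh_C")


@dataclass(frozen=True)
class Subject:
    """A dieting individual.

    ``body_mass_basis`` is the mass used to express entropy per kg of body
    mass; it defaults to the weight at diet onset and is deliberately not
    updated as weight changes during a scenario.
    """

    weight: float        # kg
    height: float        # cm
    age: float           # years
    body_mass_basis: float | None = None
    health_state: str = "healthy"

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"weight must be positive, got {self.weight}")
        if self.height <= 0:
            raise ValueError(f"height must be positive, got {self.height}")
        if self.age < 0:
            raise ValueError(f"age must be non-negative, got {self.age}")
        if self.health_state not in HEALTH_STATES:
            raise ValueError(
                f"health_state {self.health_state!r} not one of {HEALTH_STATES}"
            )
        if self.body_mass_basis is None:
            object.__setattr__(self, "body_mass_basis", self.weight)
        elif self.body_mass_basis <= 0:
            raise ValueError("body_mass_basis must be positive")

    @property
    def bmi(self) -> float:
        """Body mass index, kg/m^2."""
        return self.weight / (self.height / 100.0) ** 2


def bmr_harris_benedict(subject: Subject) -> float:
    """Basal metabolic rate in kcal/day, full precision."""
    return (
        66.5
        + 13.76 * subject.weight
        + 5.003 * subject.height
        - 5.755 * subject.age
    )


def bmr_rounded(subject: Subject) -> int:
    """BMR reported to the nearest integer kcal/day."""
    return round(bmr_harris_benedict(subject))


def daily_caloric_need(
    subject: Subject,
    constants: MetabolicConstants | None = None,
) -> float:
    """Daily caloric need, kcal/day: BMR times the activity multiplier."""
    constants = constants or default_db().constants
    return bmr_harris_benedict(subject) * constants.caloric_need_multiplier


def subject_from_mapping(payload: Mapping[str, Any]) -> Subject:
    """Build a Subject from the serialized key set (weight_kg, height_cm, ...)."""
    return Subject(
        weight=float(payload["weight_kg"]),
        height=float(payload["height_cm"]),
        age=float(payload["age_years"]),
        body_mass_basis=(
            float(payload["body_mass_basis_kg"])
            if payload.get("body_mass_basis_kg") is not None
            else None
        ),
        health_state=payload.get("health_state", "healthy"),
    )


def read_subject(path: str) -> Subject:
    """Read a Subject from a JSON or YAML file."""
    text = open(path, "r", encoding="utf-8").read()
    if path.endswith((".yaml", ".yml")):
        import yaml

        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)
    return subject_from_mapping(payload)
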