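"""Published diet plans and subject presets.

Two families of diet plans are shipped:

* ``IF_DIETS`` — the intermittent-fasting plans for 80 kg subjects aged 25
  and 50 (weight-maintaining / weight-gain / weight-loss variants).  Note
  that the source material labels these inconsistently between its
  composition and exchange tables (the 318/99/59 g plan labelled
  "weight-maintaining" reproduces the oxygen uptake printed for the
  "weight-gain" row, and vice versa); everything in this package is keyed to
  the diet *composition*, and the names below follow the composition table.
* ``NAFLD_DIETS`` — plans for 100 kg obese patients: one for a healthy obese
  person and one per Child–Pugh class of fatty-liver disease.

Subject presets cover the three study subjects.  The NAFLD preset's height
(170 cm) and age (40, the disease-onset age) are package choices; the source
specifies only the 100 kg mass and BMI > 30.
"""

from __future__ import annotations

from .stoichiometry import Diet
from .subjects import Subject

__all__ = [
    "IF_DIETS",
    "NAFLD_DIETS",
    "DIET_PRESETS",
    "SUBJECT_PRESETS",
    "diet",
    "subject",
]

IF_DIETS: dict[str, Diet] = {
    "if_maintain_25": Diet(318, 99, 59, kcal=2210, name="if_maintain_25"),
    "if_maintain_50": Diet(295, 86, 54, kcal=2010, name="if_maintain_50"),
    "if_gain_25": Diet(276, 94, 48, kcal=1912, name="if_gain_25"),
    "if_gain_50": Diet(257, 74, 43, kcal=1711, name="if_gain_50"),
    "if_loss_25": Diet(242, 68, 47, kcal=1663, name="if_loss_25"),
    "if_loss_50": Diet(225, 67, 38, kcal=1510, name="if_loss_50"),
}

NAFLD_DIETS: dict[str, Diet] = {
    "healthy_obese": Diet(430, 150, 98, kcal=3100, name="healthy_obese"),
    "childpugh_A": Diet(428, 130, 92, kcal=3000, name="childpugh_A"),
    "childpugh_B": Diet(416, 160, 110, kcal=3200, name="childpugh_B"),
    "childpugh_C": Diet(470, 165, 79, kcal=3300, name="childpugh_C"),
}

DIET_PRESETS: dict[str, Diet] = {**IF_DIETS, **NAFLD_DIETS}

SUBJECT_PRESETS: dict[str, Subject] = {
    "if_25": Subject(weight=80, height=170, age=25),
    "if_50": Subject(weight=80, height=170, age=50),
    "nafld_obese": Subject(weight=100, height=170, age=40),
}


def diet(name: str) -> Diet:
    """Look up a shipped diet plan by name."""
    try:
        return DIET_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown diet preset {name!r}; known: {sorted(DIET_PRESETS)}"
        ) from None


def subject(name: str) -> Subject:
    """Look up a shipped subject preset by name."""
    try:
        return SUBJECT_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown subject preset {name!r}; known: {sorted(SUBJECT_PRESETS)}"
        ) from None
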