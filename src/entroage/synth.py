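"""Synthetic diet plans and subjects.

Generates guideline-shaped diet tables so every pipeline stage can be
exercised without external data.  A diet is defined by a calorie target and a
macronutrient calorie split; grams follow from the Atwater factors (4 kcal/g
for carbohydrate and protein, 9 kcal/g for fat).  The split defaults are
constrained to the acceptable macronutrient distribution ranges (protein
10–35%, carbohydrate 45–65%, fat 20–35% of calories), and typical adult
calorie targets fall in 1800–3000 kcal/day.

Optional multiplicative lognormal noise (given as a coefficient of
variation) perturbs each macronutrient mass independently while keeping it
positive; the noise multiplier has mean 1, so generated diets are unbiased
around the noise-free plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .stoichiometry import MACRONUTRIENTS, Diet
from .subjects import Subject
from .presets import SUBJECT_PRESETS

__all__ = [
    "ATWATER_KCAL_PER_G",
    "GUIDELINE_SPLIT_RANGES",
    "DietGeneratorConfig",
    "generate_diets",
    "generate_subject",
]

#: kcal per gram of macronutrient.
ATWATER_KCAL_PER_G: Mapping[str, float] = {
    "carbohydrate": 4.0,
    "protein": 4.0,
    "fat": 9.0,
}

#: Acceptable macronutrient distribution ranges, as fractions of calories.
GUIDELINE_SPLIT_RANGES: Mapping[str, tuple[float, float]] = {
    "protein": (0.10, 0.35),
    "carbohydrate": (0.45, 0.65),
    "fat": (0.20, 0.35),
}


@dataclass(frozen=True)
class DietGeneratorConfig:
    """Configuration of the synthetic diet generator.

    ``macro_split`` gives the fraction of calories per macronutrient and must
    sum to one; by default it must also lie inside the guideline envelope
    (set ``enforce_guidelines=False`` to generate deliberately unbalanced
    plans).  ``noise_cv`` is the per-macronutrient coefficient of variation
    of the multiplicative noise.
    """

    kcal_target: float
    macro_split: Mapping[str, float] = field(
        default_factory=lambda: {"carbohydrate": 0.55, "protein": 0.20, "fat": 0.25}
    )
    noise_cv: float = 0.0
    seed: int = 0
    n: int = 1
    enforce_guidelines: bool = True

    def __post_init__(self) -> None:
        if self.kcal_target <= 0:
            raise ValueError("kcal_target must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n < 1:
            raise ValueError("n must be at least 1")
        missing = set(MACRONUTRIENTS) - set(self.macro_split)
        if missing:
            raise ValueError(f"macro_split missing {sorted(missing)}")
        total = sum(self.macro_split[m] for m in MACRONUTRIENTS)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"macro_split must sum to 1, got {total}")
        if self.enforce_guidelines:
            for macro, (lo, hi) in GUIDELINE_SPLIT_RANGES.items():
                f = self.macro_split[macro]
                if not lo <= f <= hi:
                    raise ValueError(
                        f"{macro} split {f} outside the guideline range "
                        f"[{lo}, {hi}] (pass enforce_guidelines=False to allow)"
                    )


def _noise_free_grams(config: DietGeneratorConfig) -> dict[str, float]:
    return {
        m: config.kcal_target * config.macro_split[m] / ATWATER_KCAL_PER_G[m]
        for m in MACRONUTRIENTS
    }


def generate_diets(config: DietGeneratorConfig) -> list[Diet]:
    """Generate ``config.n`` diets; identical output for identical seeds."""
    base = _noise_free_grams(config)
    rng = np.random.default_rng(config.seed)
    diets: list[Diet] = []
    if config.noise_cv > 0:
        # lognormal multiplier with mean 1 and the requested CV
        sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))
        mu = -0.5 * sigma**2
    for i in range(config.n):
        if config.noise_cv > 0:
            mult = {m: float(rng.lognormal(mu, sigma)) for m in MACRONUTRIENTS}
        else:
            mult = {m: 1.0 for m in MACRONUTRIENTS}
        grams = {m: base[m] * mult[m] for m in MACRONUTRIENTS}
        kcal = sum(grams[m] * ATWATER_KCAL_PER_G[m] for m in MACRONUTRIENTS)
        diets.append(
            Diet(
                carbohydrate=grams["carbohydrate"],
                protein=grams["protein"],
                fat=grams["fat"],
                kcal=kcal,
                name=f"synthetic_{i}",
            )
        )
    return diets


def generate_subject(profile: str) -> Subject:
    """Return a study-subject preset (if_25, if_50 or nafld_obese)."""
    try:
        return SUBJECT_PRESETS[profile]
    except KeyError:
        raise KeyError(
            f"unknown subject preset {profile!r}; known: {sorted(SUBJECT_PRESETS)}"
        ) from None
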