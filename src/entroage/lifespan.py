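"""Entropic age: lifetime entropy budget, disease adjustment, projections.

An individual is assumed to generate a fixed total of 11,404 kJ/(kg K) of
specific entropy over a lifetime.  Given the entropy already accumulated at
some age and one or more annual generation rates going forward, the expected
lifespan is the age at which the running total reaches the budget.

Disease raises the effective annual rate: a one-year survival fraction f
converts a healthy rate r into r / f (e.g. Child–Pugh class C, f = 0.44,
turns 119.9 into 272.5 kJ/(kg K year)).  Autophagy triggered by sustained
fasting is modelled as a 10–25% reduction of the annual rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

from .entropy import entropy_generation
from .stoichiometry import Diet, profile_for_state
from .subjects import Subject, subject_from_mapping
from .thermo import SECONDS_PER_YEAR, ThermoDB, default_db

__all__ = [
    "Segment",
    "EntropyLedger",
    "SurvivalAdjustment",
    "LifespanEstimate",
    "ScenarioError",
    "accumulate",
    "disease_adjusted_rate",
    "autophagy_adjusted_segment",
    "project_lifespan",
    "constant_rate_lifespan",
    "scenario_compare",
    "load_scenario",
    "run_scenario",
]


class ScenarioError(ValueError):
    """Invalid ledger or scenario configuration."""


@dataclass(frozen=True)
class Segment:
    """One stretch of life at a constant annual entropy rate.

    ``duration`` is in years; ``None`` marks the final, open-ended segment.
    """

    rate: float               # kJ/(kg K year)
    duration: float | None = None

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ScenarioError(f"segment rate must be positive, got {self.rate}")
        if self.duration is not None and self.duration < 0:
            raise ScenarioError("segment duration must be non-negative")


@dataclass(frozen=True)
class EntropyLedger:
    """Accumulated specific entropy at an age, plus the future rate schedule."""

    age_start: float                 # years
    accumulated: float               # kJ/(kg K) already generated
    segments: Sequence[Segment]
    limit: float = 11404.0           # kJ/(kg K) lifetime budget

    def __post_init__(self) -> None:
        if self.age_start < 0:
            raise ScenarioError("age_start must be non-negative")
        if self.accumulated < 0:
            raise ScenarioError("accumulated entropy must be non-negative")
        if self.limit <= 0:
            raise ScenarioError("entropy limit must be positive")
        if self.accumulated > self.limit + 1e-9:
            raise ScenarioError(
                f"accumulated {self.accumulated} exceeds the limit {self.limit}"
            )
        if not self.segments:
            raise ScenarioError("at least one segment is required")
        if self.segments[-1].duration is not None:
            raise ScenarioError("the final segment must be open-ended")
        object.__setattr__(self, "segments", tuple(self.segments))


@dataclass(frozen=True)
class SurvivalAdjustment:
    """One-year survival fraction of a disease state."""

    survival_fraction: float
    horizon: float = 1.0      # years; the adjustment is applied per year

    def __post_init__(self) -> None:
        if not 0.0 < self.survival_fraction <= 1.0:
            raise ScenarioError(
                f"survival_fraction must be in (0, 1], got {self.survival_fraction}"
            )


@dataclass(frozen=True)
class LifespanEstimate:
    """Projected lifespan, full precision and the nearest-integer report."""

    expected_lifespan: float     # years of age when the budget is exhausted
    remaining_years: float       # years left from the ledger's age_start

    @property
    def rounded(self) -> int:
        return round(self.expected_lifespan)


def accumulate(rate: float, years: float) -> float:
    """Entropy generated at a constant annual rate over ``years``, kJ/(kg K)."""
    if rate < 0 or years < 0:
        raise ValueError("rate and years must be non-negative")
    return rate * years


def disease_adjusted_rate(healthy_rate: float, adj: SurvivalAdjustment) -> float:
    """Annual rate of a disease state: healthy rate / one-year survival."""
    return healthy_rate / adj.survival_fraction


def autophagy_adjusted_segment(rate: float, reduction: float) -> float:
    """Annual rate reduced by an autophagy-linked fraction (typically 0.10–0.25)."""
    if not 0.0 <= reduction < 1.0:
        raise ValueError(f"reduction must be in [0, 1), got {reduction}")
    return rate * (1.0 - reduction)


def project_lifespan(ledger: EntropyLedger) -> LifespanEstimate:
    """Age at which the accumulated entropy reaches the lifetime budget."""
    acc = ledger.accumulated
    age = ledger.age_start
    if acc >= ledger.limit:
        return LifespanEstimate(expected_lifespan=age, remaining_years=0.0)
    for seg in ledger.segments:
        remaining = ledger.limit - acc
        if seg.duration is None or seg.rate * seg.duration >= remaining:
            age += remaining / seg.rate
            return LifespanEstimate(
                expected_lifespan=age,
                remaining_years=age - ledger.age_start,
            )
        acc += seg.rate * seg.duration
        age += seg.duration
    raise AssertionError("unreachable: final segment is open-ended")


def constant_rate_lifespan(
    rate_kw_per_kgK: float, limit: float | None = None
) -> float:
    """Lifespan from birth (years) for a power-style entropy rate, kW/(kg K)."""
    if rate_kw_per_kgK <= 0:
        raise ValueError("rate must be positive")
    if limit is None:
        limit = default_db().constants.lifespan_entropy_limit_kJ_per_kgK
    return limit / (rate_kw_per_kgK * SECONDS_PER_YEAR)


def scenario_compare(
    base: EntropyLedger, alternative: EntropyLedger
) -> tuple[float, int]:
    """Years of life gained by the alternative schedule over the baseline.

    Both ledgers must start from the same age and accumulated entropy.
    """
    if (
        abs(base.age_start - alternative.age_start) > 1e-9
        or abs(base.accumulated - alternative.accumulated) > 1e-9
        or abs(base.limit - alternative.limit) > 1e-9
    ):
        raise ScenarioError(
            "ledgers must share age_start, accumulated entropy and limit"
        )
    gained = (
        project_lifespan(alternative).expected_lifespan
        - project_lifespan(base).expected_lifespan
    )
    return gained, round(gained)


# ------------------------------------------------------------- scenario I/O

def load_scenario(path: str) -> dict:
    """Read a scenario configuration from YAML or JSON."""
    text = open(path, "r", encoding="utf-8").read()
    if path.endswith((".yaml", ".yml")):
        import yaml

        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)
    if not isinstance(payload, Mapping):
        raise ScenarioError(f"scenario file {path} must contain a mapping")
    return dict(payload)


def _resolve_diet(spec: Any) -> Diet:
    from . import presets

    if isinstance(spec, str):
        return presets.diet(spec)
    return Diet(
        carbohydrate=float(spec["carbohydrate_g"]),
        protein=float(spec["protein_g"]),
        fat=float(spec["fat_g"]),
        kcal=spec.get("kcal"),
        name=spec.get("name"),
    )


def _resolve_rate(
    spec: Mapping[str, Any],
    subject: Subject | None,
    db: ThermoDB,
) -> float:
    """Annual rate of one scenario segment.

    Either an explicit ``rate`` (kJ/(kg K year)) or a ``diet`` (preset name
    or macronutrient mapping) run through the pipeline with ``profile`` (a
    health state; defaults to healthy).  Optional modifiers:
    ``survival_fraction`` divides the rate, ``autophagy_reduction`` scales it
    down.
    """
    if "rate" in spec:
        rate = float(spec["rate"])
    elif "diet" in spec:
        if subject is None:
            raise ScenarioError("a subject is required to compute a rate from a diet")
        diet = _resolve_diet(spec["diet"])
        state = spec.get("profile", "healthy")
        profile = profile_for_state(state, db)
        rate = entropy_generation(diet, subject, profile, db).annual_specific
    else:
        raise ScenarioError(f"segment needs 'rate' or 'diet': {dict(spec)}")
    if "survival_fraction" in spec:
        rate = disease_adjusted_rate(
            rate, SurvivalAdjustment(float(spec["survival_fraction"]))
        )
    if "autophagy_reduction" in spec:
        rate = autophagy_adjusted_segment(rate, float(spec["autophagy_reduction"]))
    return rate


def run_scenario(config: Mapping[str, Any], db: ThermoDB | None = None) -> dict:
    """Evaluate a lifespan scenario configuration.

    Schema (YAML/JSON)::

        name: childpugh_C
        onset_age: 40
        limit: 11404                 # optional, kJ/(kg K)
        subject: nafld_obese         # preset name or {weight_kg, height_cm, ...}
        pre_onset: {rate: 119.9}     # or {diet: ..., profile: ...}; or
                                     # accumulated: 4796 directly
        baseline: {rate: 272.5}      # segment spec, see _resolve_rate
        alternative: {rate: 98.8}    # optional second schedule

    Returns a JSON-ready report with rates, accumulated entropy at onset,
    projected lifespans (full precision and rounded) and years gained.
    """
    db = db or default_db()
    from . import presets

    subject: Subject | None = None
    if "subject" in config:
        spec = config["subject"]
        subject = (
            presets.subject(spec) if isinstance(spec, str) else subject_from_mapping(spec)
        )
    onset_age = float(config["onset_age"])
    if subject is not None and subject.age > onset_age:
        raise ScenarioError(
            f"subject age {subject.age} is past the onset age {onset_age}"
        )
    limit = float(
        config.get("limit", db.constants.lifespan_entropy_limit_kJ_per_kgK)
    )
    if "accumulated" in config:
        accumulated = float(config["accumulated"])
        pre_rate = accumulated / onset_age if onset_age > 0 else None
    else:
        pre_rate = _resolve_rate(config["pre_onset"], subject, db)
        accumulated = accumulate(pre_rate, onset_age)

    report: dict[str, Any] = {
        "name": config.get("name"),
        "onset_age": onset_age,
        "limit_kJ_per_kgK": limit,
        "pre_onset_rate_kJ_per_kgK_year": pre_rate,
        "accumulated_kJ_per_kgK": accumulated,
    }
    ledgers: dict[str, EntropyLedger] = {}
    for key in ("baseline", "alternative"):
        if key not in config:
            continue
        rate = _resolve_rate(config[key], subject, db)
        ledger = EntropyLedger(
            age_start=onset_age,
            accumulated=accumulated,
            segments=[Segment(rate=rate)],
            limit=limit,
        )
        ledgers[key] = ledger
        est = project_lifespan(ledger)
        report[key] = {
            "annual_rate_kJ_per_kgK_year": rate,
            "expected_lifespan_years": est.expected_lifespan,
            "expected_lifespan_rounded": est.rounded,
            "remaining_years": est.remaining_years,
        }
    if "baseline" not in ledgers:
        raise ScenarioError("scenario requires at least a 'baseline' segment")
    if "alternative" in ledgers:
        gained, gained_rounded = scenario_compare(
            ledgers["baseline"], ledgers["alternative"]
        )
    else:
        gained, gained_rounded = 0.0, 0
    report["years_gained"] = gained
    report["years_gained_rounded"] = gained_rounded
    return report
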