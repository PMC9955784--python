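"""Thermodynamic property database and metabolic constants.

The oxidation model needs seven species: the three model fuels (glucose for
carbohydrate, palmitic acid for fat, an average of 20 amino acids for
protein), the respiratory gases O2 and CO2, metabolic water, and urea.  Each
carries a formation enthalpy at 298 K, absolute entropies at 298 K and (for
the species that leave the body warm) 310 K, and — for the gases — ideal-gas
sensible enthalpies used to move between the two temperatures.

Conventions
-----------
* Enthalpies are kJ/kmol, entropies kJ/(kmol K), molar masses g/mol.
* Reactants (fuels, O2) enter the body at 298 K; products (CO2, H2O, urea)
  leave at body temperature 310 K.  CO2 and H2O are treated as ideal gases;
  the fuels and urea are condensed species whose sensible enthalpy between
  298 and 310 K is neglected.
* h(T) = h_form_298 + [h_sens(T) − h_sens(298)] where the sensible pair is
  available, otherwise h(T) = h_form_298.

The default database ships inside the package as JSON; every value can be
overridden through a mapping (or a JSON/YAML file) merged key-wise, so a user
who prefers e.g. exact IUPAC molar masses or liquid-phase water properties
can swap them in without touching code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from types import MappingProxyType
from typing import Any, Mapping

__all__ = [
    "ATOMIC_MASS",
    "KCAL_TO_KJ",
    "DAYS_PER_YEAR",
    "SECONDS_PER_YEAR",
    "SpeciesRecord",
    "MetabolicConstants",
    "ThermoDB",
    "SpeciesNotFoundError",
    "PropertyMissingError",
    "default_db",
    "load_overrides",
]

#: Standard atomic masses (g/mol), used only for consistency checks — the
#: working molar masses are the rounded values stored per species.
ATOMIC_MASS: Mapping[str, float] = MappingProxyType(
    {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}
)

KCAL_TO_KJ = 4.184
DAYS_PER_YEAR = 365.0
SECONDS_PER_YEAR = DAYS_PER_YEAR * 86400.0


class SpeciesNotFoundError(KeyError):
    """Raised when a species name does not resolve in the database."""


class PropertyMissingError(KeyError):
    """Raised when a required thermodynamic property is absent for a species."""


@dataclass(frozen=True)
class SpeciesRecord:
    """Thermodynamic record for one chemical species.

    ``formula`` maps element symbol to (possibly fractional) atom count,
    e.g. the average amino acid C4.57 H9.03 N1.27 O2.25 S0.046.
    """

    name: str
    formula: Mapping[str, float]
    molar_mass: float          # g/mol
    h_form_298: float          # kJ/kmol
    s_298: float               # kJ/(kmol K)
    h_sens_298: float | None = None   # kJ/kmol, ideal-gas sensible enthalpy
    h_sens_310: float | None = None
    s_310: float | None = None        # kJ/(kmol K)

    def __post_init__(self) -> None:
        object.__setattr__(self, "formula", MappingProxyType(dict(self.formula)))

    def formula_mass(self, exclude: tuple[str, ...] = ()) -> float:
        """Molar mass implied by the formula and standard atomic masses."""
        return sum(
            ATOMIC_MASS[el] * n for el, n in self.formula.items() if el not in exclude
        )

    def enthalpy(self, temperature: float) -> float:
        """h(T) in kJ/kmol.

        Sensible enthalpy between 298 K and ``temperature`` is included only
        when the tabulated pair exists (gases); condensed species use the
        formation enthalpy alone.
        """
        if abs(temperature - 298.0) < 0.5:
            return self.h_form_298
        if abs(temperature - 310.0) < 0.5:
            if self.h_sens_298 is not None and self.h_sens_310 is not None:
                return self.h_form_298 + (self.h_sens_310 - self.h_sens_298)
            return self.h_form_298
        raise PropertyMissingError(
            f"{self.name}: enthalpy tabulated only at 298 K and 310 K, "
            f"not {temperature} K"
        )

    def entropy(self, temperature: float) -> float:
        """s(T) in kJ/(kmol K) at one of the two tabulated temperatures."""
        if abs(temperature - 298.0) < 0.5:
            return self.s_298
        if abs(temperature - 310.0) < 0.5:
            if self.s_310 is None:
                raise PropertyMissingError(
                    f"{self.name}: entropy at 310 K is not tabulated"
                )
            return self.s_310
        raise PropertyMissingError(
            f"{self.name}: entropy tabulated only at 298 K and 310 K, "
            f"not {temperature} K"
        )


@dataclass(frozen=True)
class MetabolicConstants:
    """Scalar constants of the metabolic model.

    digestibility_healthy
        Fraction of each ingested macronutrient absorbed and oxidized in
        health (carbohydrate 0.99, protein 0.92, fat 0.95).
    oxidation_fractions
        Per Child–Pugh class replacement for the healthy digestibilities in
        liver disease.
    efficiency
        Metabolic efficiency η per fuel: the fraction of reaction enthalpy
        captured as ATP rather than released as heat.
    atp_yield
        mol ATP per mol fuel, reported alongside results (the heat route uses
        η directly).
    """

    digestibility_healthy: Mapping[str, float]
    oxidation_fractions: Mapping[str, Mapping[str, float]]
    efficiency: Mapping[str, float]
    atp_yield: Mapping[str, float]
    urea_urine_conc_g_per_L: float = 20.0
    urea_excreted_fraction: float = 0.65
    body_temperature_K: float = 310.15
    lifespan_entropy_limit_kJ_per_kgK: float = 11404.0
    caloric_need_multiplier: float = 1.2

    def violations(self) -> list[str]:
        out: list[str] = []

        def _chk_frac(label: str, value: float) -> None:
            if not 0.0 <= value <= 1.0:
                out.append(f"{label} = {value} outside [0, 1]")

        for macro, f in self.digestibility_healthy.items():
            _chk_frac(f"digestibility_healthy[{macro}]", f)
        for state, fracs in self.oxidation_fractions.items():
            for macro, f in fracs.items():
                _chk_frac(f"oxidation_fractions[{state}][{macro}]", f)
        for fuel, eta in self.efficiency.items():
            _chk_frac(f"efficiency[{fuel}]", eta)
        _chk_frac("urea_excreted_fraction", self.urea_excreted_fraction)
        if self.body_temperature_K <= 0:
            out.append("body_temperature_K must be positive")
        if self.lifespan_entropy_limit_kJ_per_kgK <= 0:
            out.append("lifespan_entropy_limit_kJ_per_kgK must be positive")
        if self.urea_urine_conc_g_per_L <= 0:
            out.append("urea_urine_conc_g_per_L must be positive")
        if self.caloric_need_multiplier <= 0:
            out.append("caloric_need_multiplier must be positive")
        return out


#: Names that resolve onto the canonical species keys.
_ALIASES = {
    "palmitic_acid": "palmitate",
    "palmitic acid": "palmitate",
    "amino_acid": "amino",
    "average_amino_acid": "amino",
    "oxygen": "O2",
    "carbon_dioxide": "CO2",
    "water": "H2O",
    "o2": "O2",
    "co2": "CO2",
    "h2o": "H2O",
}

#: Maximum relative mismatch between a stored molar mass and the mass implied
#: by the formula (the source table rounds to 180/256/119 etc.).
MOLAR_MASS_TOLERANCE = 0.015


class ThermoDB:
    """Immutable lookup facade over the species records and constants."""

    def __init__(
        self, species: Mapping[str, SpeciesRecord], constants: MetabolicConstants
    ) -> None:
        self._species = MappingProxyType(dict(species))
        self._constants = constants

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(self._species)

    @property
    def constants(self) -> MetabolicConstants:
        return self._constants

    def get_species(self, name: str) -> SpeciesRecord:
        key = _ALIASES.get(name, name)
        try:
            return self._species[key]
        except KeyError:
            raise SpeciesNotFoundError(
                f"unknown species {name!r}; known: {sorted(self._species)}"
            ) from None

    def check_consistency(self) -> list[str]:
        """Return all invariant violations (empty list for the shipped data)."""
        out: list[str] = []
        for rec in self._species.values():
            if rec.molar_mass <= 0:
                out.append(f"{rec.name}: molar_mass {rec.molar_mass} not positive")
                continue
            implied = rec.formula_mass()
            rel = abs(rec.molar_mass - implied) / implied
            if rel > MOLAR_MASS_TOLERANCE:
                out.append(
                    f"{rec.name}: molar_mass {rec.molar_mass} differs from "
                    f"formula mass {implied:.2f} by {rel:.1%}"
                )
        out.extend(self._constants.violations())
        return out

    # ------------------------------------------------------------------ load

    @classmethod
    def from_mapping(cls, payload: Mapping[str, Any]) -> "ThermoDB":
        species = {
            name: SpeciesRecord(name=name, **props)
            for name, props in payload["species"].items()
        }
        constants = MetabolicConstants(**payload["constants"])
        return cls(species, constants)

    @classmethod
    def default(cls, overrides: Mapping[str, Any] | None = None) -> "ThermoDB":
        """Load the shipped database, optionally merged with overrides.

        Overrides are merged key-wise: ``{"species": {"glucose": {"s_298":
        209.0}}}`` changes one number and leaves everything else intact.
        """
        payload = json.loads(
            resources.files("entroage.data").joinpath("species.json").read_text()
        )
        payload.pop("_notes", None)
        if overrides:
            payload = _deep_merge(payload, overrides)
        return cls.from_mapping(payload)


def _deep_merge(base: Mapping[str, Any], extra: Mapping[str, Any]) -> dict:
    merged = dict(base)
    for key, value in extra.items():
        if key in merged and isinstance(merged[key], Mapping) and isinstance(value, Mapping):
            merged[key] = _deep_merge(merged[key], value)
        else:
            merged[key] = value
    return merged


def load_overrides(path: str) -> dict:
    """Read a JSON or YAML override file for :meth:`ThermoDB.default`."""
    text = open(path, "r", encoding="utf-8").read()
    if path.endswith((".yaml", ".yml")):
        import yaml

        return yaml.safe_load(text) or {}
    return json.loads(text)


_DEFAULT: ThermoDB | None = None


def default_db() -> ThermoDB:
    """Shared instance of the shipped database (records are immutable)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = ThermoDB.default()
    return _DEFAULT
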