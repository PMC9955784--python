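"""Reaction enthalpies and daily heat release.

For each fuel the enthalpy of metabolism per mole,

    ΔH_R = Σ_products ν_p h_p(310 K) − [h_fuel(298 K) + ν_O2 h_O2(298 K)],

uses h(T) = h_form,298 + Δh_sensible for the gaseous species and the
formation enthalpy alone for condensed ones (urea, the fuels).  All three
oxidations are exothermic, so ΔH_R < 0.

A fraction η of that enthalpy is captured as ATP; the rest leaves the body as
heat:

    Q = Σ_fuels (1 − η_fuel) |ΔH_R,fuel| n_fuel   [kJ/day]

with η = 0.346 (glucose), 0.322 (palmitate) and 0.104 (average amino acid).
The ATP yields (32/106/8 mol ATP per mol fuel) are reported alongside but the
η route is the computation path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .stoichiometry import REACTIONS, FuelMoles
from .thermo import ThermoDB, default_db

__all__ = [
    "ReactionEnthalpy",
    "HeatResult",
    "reaction_enthalpy",
    "heat_release",
    "atp_moles",
]

_PRODUCT_SPECIES = {"co2": "CO2", "h2o": "H2O", "urea": "urea"}

T_IN = 298.0    # K, reactants enter at ambient standard temperature
T_OUT = 310.0   # K, products leave at body temperature


@dataclass(frozen=True)
class ReactionEnthalpy:
    """Enthalpy of metabolism of one fuel, kJ per mol of fuel (negative)."""

    fuel: str
    delta_h: float
    reactants_at: float = T_IN
    products_at: float = T_OUT


@dataclass(frozen=True)
class HeatResult:
    """Heat released to the surroundings, kJ/day, with per-fuel contributions."""

    q_released: float
    per_fuel: Mapping[str, float]


def reaction_enthalpy(fuel: str, db: ThermoDB | None = None) -> ReactionEnthalpy:
    """ΔH_R for one mole of ``fuel`` (kJ/mol), products warm, reactants ambient."""
    db = db or default_db()
    if fuel not in REACTIONS:
        raise ValueError(f"unknown fuel {fuel!r}; known: {sorted(REACTIONS)}")
    rxn = REACTIONS[fuel]
    products = sum(
        getattr(rxn, attr) * db.get_species(sp).enthalpy(T_OUT)
        for attr, sp in _PRODUCT_SPECIES.items()
        if getattr(rxn, attr) != 0.0
    )
    reactants = db.get_species(fuel).enthalpy(T_IN) + rxn.o2 * db.get_species(
        "O2"
    ).enthalpy(T_IN)
    return ReactionEnthalpy(fuel=fuel, delta_h=(products - reactants) / 1000.0)


def heat_release(fuels: FuelMoles, db: ThermoDB | None = None) -> HeatResult:
    """Daily heat export Q (kJ/day, positive magnitude) for the fuel moles."""
    db = db or default_db()
    eta = db.constants.efficiency
    per_fuel: dict[str, float] = {}
    for fuel in REACTIONS:
        n = fuels.moles(fuel)
        dh = reaction_enthalpy(fuel, db).delta_h
        per_fuel[fuel] = (1.0 - eta[fuel]) * abs(dh) * n
    return HeatResult(q_released=sum(per_fuel.values()), per_fuel=per_fuel)


def atp_moles(fuels: FuelMoles, db: ThermoDB | None = None) -> dict[str, float]:
    """Reported ATP production, mol/day per fuel plus a total."""
    db = db or default_db()
    yields = db.constants.atp_yield
    out = {fuel: yields[fuel] * fuels.moles(fuel) for fuel in REACTIONS}
    out["total"] = sum(out.values())
    return out
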