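"""Second-law entropy balance of the body and the annual specific rate.

The body is an open system at quasi-steady state (no entropy accumulates in
the tissues), so the daily entropy generation is

    Δs_gen = (Σ n s)_out − (Σ n s)_in + Q / T      [kJ/(K day)]

where the out-flow carries CO2, metabolic H2O and urea at body temperature
(310 K entropies), the in-flow carries the oxidized fuels and O2 at ambient
298 K entropies, Q is the positive magnitude of the heat exported by
metabolism and T = 310.15 K is body temperature.  Heat leaving the body
raises the entropy of the surroundings, so the Q/T term *adds* to the
generation attributed to the subject; with the shipped property set Δs_gen is
positive for every diet, as the second law requires.

The annual specific rate divides by a fixed body-mass basis:

    s_gen,annual = Δs_gen × 365 / m_basis         [kJ/(kg K year)]
"""

from __future__ import annotations

from dataclasses import dataclass

from .energetics import heat_release
from .stoichiometry import (
    Diet,
    ExchangeTable,
    FuelMoles,
    UtilizationProfile,
    fuel_moles,
    gas_exchange,
    oxidized_masses,
)
from .subjects import Subject
from .thermo import DAYS_PER_YEAR, ThermoDB, default_db

__all__ = ["FlowTerms", "EntropyRate", "flow_entropy", "entropy_generation", "rate_report"]

_T_IN = 298.0
_T_OUT = 310.0


@dataclass(frozen=True)
class FlowTerms:
    """The two flow-entropy terms of the balance, kJ/(K day)."""

    flow_out: float
    flow_in: float

    @property
    def net(self) -> float:
        return self.flow_out - self.flow_in


@dataclass(frozen=True)
class EntropyRate:
    """Entropy generation of one diet-day, whole body and per kg-year."""

    daily_gen: float          # kJ/(K day)
    annual_specific: float    # kJ/(kg K year)
    body_mass_basis: float    # kg
    temperature: float        # K
    flow: FlowTerms
    heat_over_T: float        # kJ/(K day)


def flow_entropy(
    exchange: ExchangeTable,
    fuels: FuelMoles,
    db: ThermoDB | None = None,
) -> FlowTerms:
    """Entropy carried by the material streams, kJ/(K day).

    Out: CO2, metabolic water and urea at 310 K.  In: the oxidized fuels and
    O2 at 298 K.  Moles are converted from the per-day mol columns; species
    entropies are tabulated per kmol, hence the 1e-3 factor.
    """
    db = db or default_db()
    out_term = (
        exchange.co2_mol * db.get_species("CO2").entropy(_T_OUT)
        + exchange.h2o_mol * db.get_species("H2O").entropy(_T_OUT)
        + exchange.urea_mol * db.get_species("urea").entropy(_T_OUT)
    ) / 1000.0
    in_term = (
        sum(
            fuels.moles(fuel) * db.get_species(fuel).entropy(_T_IN)
            for fuel in ("glucose", "palmitate", "amino")
        )
        + exchange.o2_mol * db.get_species("O2").entropy(_T_IN)
    ) / 1000.0
    return FlowTerms(flow_out=out_term, flow_in=in_term)


def entropy_generation(
    diet: Diet,
    subject: Subject,
    profile: UtilizationProfile,
    db: ThermoDB | None = None,
    days_per_year: float = DAYS_PER_YEAR,
) -> EntropyRate:
    """Run the balance for one diet under one utilization profile.

    The per-kg rate uses the subject's ``body_mass_basis`` (weight at diet
    onset), which is deliberately held fixed over a scenario.
    """
    db = db or default_db()
    fuels = fuel_moles(oxidized_masses(diet, profile), db)
    exchange = gas_exchange(fuels, db)
    flow = flow_entropy(exchange, fuels, db)
    temperature = db.constants.body_temperature_K
    heat_over_T = heat_release(fuels, db).q_released / temperature
    daily = flow.net + heat_over_T
    basis = subject.body_mass_basis
    return EntropyRate(
        daily_gen=daily,
        annual_specific=daily * days_per_year / basis,
        body_mass_basis=basis,
        temperature=temperature,
        flow=flow,
        heat_over_T=heat_over_T,
    )


def rate_report(rate: EntropyRate) -> dict:
    """JSON-ready report of an entropy rate with its term decomposition."""
    return {
        "daily_kJ_per_K": rate.daily_gen,
        "annual_kJ_per_kgK": rate.annual_specific,
        "body_mass_basis_kg": rate.body_mass_basis,
        "temperature_K": rate.temperature,
        "terms": {
            "flow_out": rate.flow.flow_out,
            "flow_in": rate.flow.flow_in,
            "heat_over_T": rate.heat_over_T,
        },
    }
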