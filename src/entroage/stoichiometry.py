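"""Diet → oxidized fuel moles → daily gas/waste exchange.

Macronutrient oxidation is modelled by three reactions:

    glucose      C6H12O6            +  6    O2 ->  6     CO2 +  6     H2O
    palmitate    C16H32O2           + 23    O2 -> 16     CO2 + 16     H2O
    amino acid   C4.57H9.03N1.27O2.25S0.046 + 4.75 O2
                                          -> 3.935 CO2 + 3.245 H2O + 0.635 CH4N2O

The average-amino-acid reaction routes dietary nitrogen to urea.  Sulfur
(S:C ratio 0.01 in the composite amino acid) is neglected in all balances.
Only the digested/oxidized share of each macronutrient enters the reactions:
healthy digestibilities are 0.99/0.92/0.95 (carbohydrate/protein/fat), and in
liver disease the Child–Pugh class oxidation fractions replace them.  Urine
mass follows from excreting 65% of the produced urea at 20 g/L; the
unabsorbed dry matter leaves as feces.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

import pandas as pd

from .thermo import ThermoDB, default_db

__all__ = [
    "MACRONUTRIENTS",
    "FUEL_FOR_MACRO",
    "Diet",
    "UtilizationProfile",
    "FuelMoles",
    "ExchangeTable",
    "OxidationReaction",
    "REACTIONS",
    "HEALTHY_PROFILE",
    "profile_for_state",
    "oxidized_masses",
    "fuel_moles",
    "gas_exchange",
    "urine_mass",
    "feces_mass",
    "exchange_table",
    "reaction_balance_violations",
    "read_diets_csv",
    "write_diets_csv",
    "write_exchange_csv",
]

MACRONUTRIENTS = ("carbohydrate", "protein", "fat")

#: Model fuel representing each macronutrient.
FUEL_FOR_MACRO = {"carbohydrate": "glucose", "protein": "amino", "fat": "palmitate"}


@dataclass(frozen=True)
class Diet:
    """Daily macronutrient masses of one diet plan (g/day); kcal informational."""

    carbohydrate: float
    protein: float
    fat: float
    kcal: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        for macro in MACRONUTRIENTS:
            if getattr(self, macro) < 0:
                raise ValueError(f"{macro} mass must be non-negative")

    def mass(self, macro: str) -> float:
        return float(getattr(self, macro))

    @property
    def total_mass(self) -> float:
        return self.carbohydrate + self.protein + self.fat

    def scaled(self, factor: float) -> "Diet":
        return Diet(
            self.carbohydrate * factor,
            self.protein * factor,
            self.fat * factor,
            kcal=None if self.kcal is None else self.kcal * factor,
            name=self.name,
        )


@dataclass(frozen=True)
class UtilizationProfile:
    """Fraction of each ingested macronutrient that is actually oxidized."""

    carbohydrate_fraction: float
    protein_fraction: float
    fat_fraction: float

    def __post_init__(self) -> None:
        for macro in MACRONUTRIENTS:
            f = self.fraction(macro)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{macro} fraction {f} outside [0, 1]")

    def fraction(self, macro: str) -> float:
        return float(getattr(self, f"{macro}_fraction"))


@dataclass(frozen=True)
class FuelMoles:
    """Daily moles of the three model fuels entering oxidation."""

    glucose: float
    palmitate: float
    amino: float

    def __post_init__(self) -> None:
        for fuel in ("glucose", "palmitate", "amino"):
            if getattr(self, fuel) < 0:
                raise ValueError(f"{fuel} moles must be non-negative")

    def moles(self, fuel: str) -> float:
        return float(getattr(self, fuel))


@dataclass(frozen=True)
class ExchangeTable:
    """Daily exchange of the body with its surroundings, in g/day.

    Mole columns are carried for the species where a molar flow is meaningful
    (the respiratory gases, metabolic water, urea).
    """

    o2: float
    co2: float
    metabolic_h2o: float
    urea_produced: float
    urea_excreted: float = 0.0
    urine: float = 0.0
    dry_feces: float = 0.0
    o2_mol: float = 0.0
    co2_mol: float = 0.0
    h2o_mol: float = 0.0
    urea_mol: float = 0.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if self.urea_excreted > self.urea_produced + 1e-9:
            raise ValueError("urea_excreted cannot exceed urea_produced")

    def as_dict(self, ndigits: int | None = 1) -> dict[str, float]:
        """Gram columns of the exchange, optionally rounded for reporting."""
        cols = (
            "o2", "co2", "metabolic_h2o", "urea_produced",
            "urea_excreted", "urine", "dry_feces",
        )
        out = {c: float(getattr(self, c)) for c in cols}
        if ndigits is not None:
            out = {c: round(v, ndigits) for c, v in out.items()}
        return out


@dataclass(frozen=True)
class OxidationReaction:
    """Stoichiometric coefficients per mole of fuel."""

    fuel: str
    o2: float
    co2: float
    h2o: float
    urea: float = 0.0


REACTIONS: Mapping[str, OxidationReaction] = {
    "glucose": OxidationReaction("glucose", o2=6.0, co2=6.0, h2o=6.0),
    "palmitate": OxidationReaction("palmitate", o2=23.0, co2=16.0, h2o=16.0),
    "amino": OxidationReaction("amino", o2=4.75, co2=3.935, h2o=3.245, urea=0.635),
}

#: Healthy digestibilities (carbohydrate, protein, fat).
HEALTHY_PROFILE = UtilizationProfile(0.99, 0.92, 0.95)


def profile_for_state(state: str, db: ThermoDB | None = None) -> UtilizationProfile:
    """Utilization profile for a health state.

    Healthy subjects use the digestibilities; Child–Pugh classes use the
    disease oxidation fractions (exactly one profile applies per state).
    """
    db = db or default_db()
    c = db.constants
    if state == "healthy":
        fracs = c.digestibility_healthy
    else:
        try:
            fracs = c.oxidation_fractions[state]
        except KeyError:
            raise ValueError(f"unknown health state {state!r}") from None
    return UtilizationProfile(
        carbohydrate_fraction=fracs["carbohydrate"],
        protein_fraction=fracs["protein"],
        fat_fraction=fracs["fat"],
    )


# --------------------------------------------------------------- operations


def oxidized_masses(diet: Diet, profile: UtilizationProfile) -> dict[str, float]:
    """Grams per day of each macronutrient that actually get oxidized."""
    return {m: diet.mass(m) * profile.fraction(m) for m in MACRONUTRIENTS}


def fuel_moles(
    oxidized: Mapping[str, float], db: ThermoDB | None = None
) -> FuelMoles:
    """Convert oxidized macronutrient grams to moles of the model fuels."""
    db = db or default_db()
    moles = {
        FUEL_FOR_MACRO[m]: oxidized[m] / db.get_species(FUEL_FOR_MACRO[m]).molar_mass
        for m in MACRONUTRIENTS
    }
    return FuelMoles(**moles)


def gas_exchange(fuels: FuelMoles, db: ThermoDB | None = None) -> ExchangeTable:
    """O2 uptake and CO2/H2O/urea production for the given fuel moles."""
    db = db or default_db()
    o2_mol = co2_mol = h2o_mol = urea_mol = 0.0
    for fuel, rxn in REACTIONS.items():
        n = fuels.moles(fuel)
        o2_mol += rxn.o2 * n
        co2_mol += rxn.co2 * n
        h2o_mol += rxn.h2o * n
        urea_mol += rxn.urea * n
    return ExchangeTable(
        o2=o2_mol * db.get_species("O2").molar_mass,
        co2=co2_mol * db.get_species("CO2").molar_mass,
        metabolic_h2o=h2o_mol * db.get_species("H2O").molar_mass,
        urea_produced=urea_mol * db.get_species("urea").molar_mass,
        o2_mol=o2_mol,
        co2_mol=co2_mol,
        h2o_mol=h2o_mol,
        urea_mol=urea_mol,
    )


def urine_mass(
    urea_produced: float, db: ThermoDB | None = None
) -> tuple[float, float]:
    """(urea excreted, urine mass) in g/day.

    65% of the produced urea is excreted at a urine urea concentration of
    20 g/L; urine density is taken as 1 g/mL.
    """
    if urea_produced < 0:
        raise ValueError("urea_produced must be non-negative")
    c = (db or default_db()).constants
    urea_excreted = c.urea_excreted_fraction * urea_produced
    urine_litres = urea_excreted / c.urea_urine_conc_g_per_L
    return urea_excreted, urine_litres * 1000.0


def feces_mass(diet: Diet, profile: UtilizationProfile) -> float:
    """Unabsorbed dry matter, g/day: sum of (1 − fraction) × intake."""
    return sum(
        (1.0 - profile.fraction(m)) * diet.mass(m) for m in MACRONUTRIENTS
    )


def exchange_table(
    diet: Diet,
    profile: UtilizationProfile = HEALTHY_PROFILE,
    db: ThermoDB | None = None,
) -> ExchangeTable:
    """Full daily exchange table for one diet under one utilization profile."""
    db = db or default_db()
    fuels = fuel_moles(oxidized_masses(diet, profile), db)
    gx = gas_exchange(fuels, db)
    urea_excreted, urine = urine_mass(gx.urea_produced, db)
    feces = feces_mass(diet, profile)
    return ExchangeTable(
        o2=gx.o2,
        co2=gx.co2,
        metabolic_h2o=gx.metabolic_h2o,
        urea_produced=gx.urea_produced,
        urea_excreted=urea_excreted,
        urine=urine,
        dry_feces=feces,
        o2_mol=gx.o2_mol,
        co2_mol=gx.co2_mol,
        h2o_mol=gx.h2o_mol,
        urea_mol=gx.urea_mol,
    )


# ------------------------------------------------------- conservation checks

#: Relative tolerance for the elemental and mass balances; the amino-acid
#: reaction coefficients are printed rounded to three decimals.
BALANCE_TOLERANCE = 0.003

_PRODUCT_SPECIES = {"co2": "CO2", "h2o": "H2O", "urea": "urea"}


def reaction_balance_violations(db: ThermoDB | None = None) -> list[str]:
    """Check C/H/O/N conservation and mass conservation for every reaction.

    Balances use the formula atom counts and formula-derived masses; sulfur is
    excluded throughout (it is dropped from the model).  Returns a list of
    human-readable violations, empty when everything balances within
    ``BALANCE_TOLERANCE``.
    """
    db = db or default_db()
    out: list[str] = []
    for fuel, rxn in REACTIONS.items():
        fuel_rec = db.get_species(fuel)
        sides: dict[str, dict[str, float]] = {"reactants": {}, "products": {}}
        for el, n in fuel_rec.formula.items():
            if el != "S":
                sides["reactants"][el] = sides["reactants"].get(el, 0.0) + n
        sides["reactants"]["O"] = sides["reactants"].get("O", 0.0) + 2.0 * rxn.o2
        for attr, species in _PRODUCT_SPECIES.items():
            coeff = getattr(rxn, attr)
            if coeff == 0.0:
                continue
            for el, n in db.get_species(species).formula.items():
                sides["products"][el] = sides["products"].get(el, 0.0) + coeff * n
        for el in sorted(set(sides["reactants"]) | set(sides["products"])):
            lhs = sides["reactants"].get(el, 0.0)
            rhs = sides["products"].get(el, 0.0)
            scale = max(abs(lhs), abs(rhs), 1e-12)
            if abs(lhs - rhs) / scale > BALANCE_TOLERANCE:
                out.append(
                    f"{fuel}: element {el} unbalanced ({lhs:.4f} vs {rhs:.4f})"
                )
        lhs_mass = fuel_rec.formula_mass(exclude=("S",)) + rxn.o2 * db.get_species(
            "O2"
        ).formula_mass()
        rhs_mass = sum(
            getattr(rxn, attr) * db.get_species(sp).formula_mass()
            for attr, sp in _PRODUCT_SPECIES.items()
        )
        if abs(lhs_mass - rhs_mass) / lhs_mass > BALANCE_TOLERANCE:
            out.append(
                f"{fuel}: mass unbalanced ({lhs_mass:.2f} g vs {rhs_mass:.2f} g)"
            )
    return out


_startup_violations = reaction_balance_violations()
if _startup_violations:  # pragma: no cover - guards against bad edits
    raise RuntimeError(
        "oxidation reactions do not balance: " + "; ".join(_startup_violations)
    )


# ------------------------------------------------------------------------ IO

_DIET_COLUMNS = ["name", "kcal", "carbohydrate_g", "protein_g", "fat_g"]


def read_diets_csv(path: str) -> list[Diet]:
    """Read diet plans from CSV (columns name, kcal, carbohydrate_g, protein_g, fat_g)."""
    frame = pd.read_csv(path)
    missing = [c for c in _DIET_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"diet CSV {path} missing columns: {missing}")
    return [
        Diet(
            carbohydrate=float(row.carbohydrate_g),
            protein=float(row.protein_g),
            fat=float(row.fat_g),
            kcal=None if pd.isna(row.kcal) else float(row.kcal),
            name=None if pd.isna(row.name) else str(row.name),
        )
        for row in frame.itertuples(index=False)
    ]


def write_diets_csv(diets: Iterable[Diet], path: str) -> None:
    frame = pd.DataFrame(
        [
            {
                "name": d.name,
                "kcal": d.kcal,
                "carbohydrate_g": d.carbohydrate,
                "protein_g": d.protein,
                "fat_g": d.fat,
            }
            for d in diets
        ],
        columns=_DIET_COLUMNS,
    )
    frame.to_csv(path, index=False)


def write_exchange_csv(
    rows: Mapping[str, ExchangeTable], path: str, ndigits: int = 1
) -> None:
    """Write exchange tables (one row per diet) with units in the headers."""
    records = []
    for name, table in rows.items():
        rec = {"diet": name}
        rec.update(
            {f"{k}_g_per_day": v for k, v in table.as_dict(ndigits=ndigits).items()}
        )
        records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False)
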