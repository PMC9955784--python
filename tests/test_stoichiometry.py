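"""Oxidation stoichiometry: fuel moles, gas exchange, urine, feces."""

import pytest
from hypothesis import given, strategies as st

from entroage import (
    Diet,
    FuelMoles,
    HEALTHY_PROFILE,
    UtilizationProfile,
    exchange_table,
    feces_mass,
    fuel_moles,
    gas_exchange,
    oxidized_masses,
    profile_for_state,
    urine_mass,
)
from entroage.stoichiometry import (
    MACRONUTRIENTS,
    FUEL_FOR_MACRO,
    read_diets_csv,
    reaction_balance_violations,
    write_diets_csv,
    write_exchange_csv,
)

ZERO_PROFILE = UtilizationProfile(0.0, 0.0, 0.0)
FULL_PROFILE = UtilizationProfile(1.0, 1.0, 1.0)


# ------------------------------------------------------------ oxidized mass

def test_oxidized_masses_componentwise_product():
    diet = Diet(430, 150, 98)
    ox = oxidized_masses(diet, HEALTHY_PROFILE)
    assert ox["protein"] == pytest.approx(138.0)
    assert ox["carbohydrate"] == pytest.approx(425.7)
    assert ox["fat"] == pytest.approx(93.1)
    assert oxidized_masses(diet, ZERO_PROFILE) == {m: 0.0 for m in MACRONUTRIENTS}


def test_fuel_moles_divide_by_molar_mass(db):
    fuels = fuel_moles({"carbohydrate": 180.0, "protein": 0.0, "fat": 0.0}, db)
    assert fuels.glucose == pytest.approx(1.0)
    fuels = fuel_moles({"carbohydrate": 425.7, "protein": 138.0, "fat": 93.1}, db)
    assert fuels.glucose == pytest.approx(2.365)
    assert fuels.amino == pytest.approx(138 / 119)
    assert fuels.palmitate == pytest.approx(93.1 / 256)


# ------------------------------------------------------------- gas exchange

def test_healthy_obese_exchange_matches_published_column(healthy_obese_diet, db):
    """The 430/150/98 g plan must reproduce O2 898, CO2 1081, H2O 428 g/day."""
    table = exchange_table(healthy_obese_diet, HEALTHY_PROFILE, db)
    assert round(table.o2) == 898
    assert round(table.co2) == 1081
    assert round(table.metabolic_h2o) == 428


def test_weight_maintaining_diet_gas_triple(maintain_25_diet, db):
    table = exchange_table(maintain_25_diet, HEALTHY_PROFILE, db)
    assert table.o2 == pytest.approx(613.2, abs=0.2)
    assert table.metabolic_h2o == pytest.approx(296.6, abs=0.2)
    assert table.co2 == pytest.approx(748.4, abs=0.2)


def test_zero_fuels_give_zero_exchange():
    table = gas_exchange(FuelMoles(0, 0, 0))
    assert table.o2 == table.co2 == table.metabolic_h2o == table.urea_produced == 0


def test_urea_only_from_protein(db):
    table = gas_exchange(FuelMoles(glucose=2.0, palmitate=1.0, amino=0.0), db)
    assert table.urea_produced == 0.0
    table = gas_exchange(FuelMoles(glucose=0.0, palmitate=0.0, amino=1.0), db)
    assert table.urea_mol == pytest.approx(0.635)


# ----------------------------------------------------------- urine & feces

def test_urine_mass_anchor(db):
    urea_excreted, urine = urine_mass(44.183, db)
    assert urea_excreted == pytest.approx(0.65 * 44.183)
    assert urine == pytest.approx(1436, abs=1)  # published table prints 1428


def test_urine_constants_cancel(db):
    _, urine = urine_mass(20.0 / 0.65, db)
    assert urine == pytest.approx(1000.0)  # exactly one litre
    assert urine_mass(0.0, db) == (0.0, 0.0)


def test_feces_is_unabsorbed_dry_matter():
    diet = Diet(430, 150, 98)
    assert feces_mass(diet, FULL_PROFILE) == 0.0
    assert feces_mass(diet, ZERO_PROFILE) == pytest.approx(diet.total_mass)
    assert feces_mass(diet, HEALTHY_PROFILE) == pytest.approx(21.2)


# ----------------------------------------------------- conservation checks

def test_reactions_conserve_elements_and_mass(db):
    assert reaction_balance_violations(db) == []


def test_unbalanced_reaction_is_detected():
    from entroage.thermo import ThermoDB

    bad = ThermoDB.default({"species": {"glucose": {"formula": {"C": 7, "H": 12, "O": 6}}}})
    violations = reaction_balance_violations(bad)
    assert any("glucose" in v and "C" in v for v in violations)


# ------------------------------------------------------ linearity & oracle

@given(
    carb=st.floats(0, 600), prot=st.floats(0, 300), fat=st.floats(0, 200),
    k=st.floats(0.1, 5),
)
def test_gas_exchange_is_linear_in_the_diet(carb, prot, fat, k):
    base = exchange_table(Diet(carb, prot, fat), HEALTHY_PROFILE)
    scaled = exchange_table(Diet(carb, prot, fat).scaled(k), HEALTHY_PROFILE)
    for col in ("o2", "co2", "metabolic_h2o", "urea_produced", "urine", "dry_feces"):
        assert getattr(scaled, col) == pytest.approx(k * getattr(base, col), rel=1e-9, abs=1e-9)


def _oracle_exchange(fuels: FuelMoles, db):
    """Independent recomputation from raw atomic balances (S dropped).

    Nitrogen fixes urea, carbon fixes CO2, hydrogen fixes water, and the
    oxygen deficit fixes O2 — no stoichiometric coefficients are used.
    """
    o2 = co2 = h2o = urea = 0.0
    for fuel in ("glucose", "palmitate", "amino"):
        n = fuels.moles(fuel)
        f = db.get_species(fuel).formula
        n_urea = n * f.get("N", 0.0) / 2.0
        n_co2 = n * f.get("C", 0.0) - n_urea
        n_h2o = (n * f.get("H", 0.0) - 4.0 * n_urea) / 2.0
        n_o2 = (2.0 * n_co2 + n_h2o + n_urea - n * f.get("O", 0.0)) / 2.0
        o2, co2, h2o, urea = o2 + n_o2, co2 + n_co2, h2o + n_h2o, urea + n_urea
    return (
        o2 * db.get_species("O2").molar_mass,
        co2 * db.get_species("CO2").molar_mass,
        h2o * db.get_species("H2O").molar_mass,
        urea * db.get_species("urea").molar_mass,
    )


def test_brute_force_oracle_equivalence_on_random_diets(db):
    """Coefficient-based exchange equals the atom-balance oracle (100 diets)."""
    import numpy as np

    rng = np.random.default_rng(20260926)
    for _ in range(100):
        carb, prot, fat = rng.uniform(0, 500, size=3)
        fuels = fuel_moles(oxidized_masses(Diet(carb, prot, fat), HEALTHY_PROFILE), db)
        table = gas_exchange(fuels, db)
        o2, co2, h2o, urea = _oracle_exchange(fuels, db)
        assert table.o2 == pytest.approx(o2, rel=1e-9)
        assert table.co2 == pytest.approx(co2, rel=1e-9)
        assert table.metabolic_h2o == pytest.approx(h2o, rel=1e-9)
        assert table.urea_produced == pytest.approx(urea, rel=1e-9)


# ------------------------------------------------------- profiles, IO, etc.

def test_disease_profiles_replace_digestibilities(db):
    a = profile_for_state("childpugh_A", db)
    assert (a.protein_fraction, a.fat_fraction, a.carbohydrate_fraction) == (0.28, 0.46, 0.88)
    c = profile_for_state("childpugh_C", db)
    assert (c.protein_fraction, c.fat_fraction, c.carbohydrate_fraction) == (0.24, 0.59, 0.88)
    with pytest.raises(ValueError):
        profile_for_state("childpugh_D", db)


def test_validation_rejects_bad_inputs():
    with pytest.raises(ValueError):
        Diet(-1, 0, 0)
    with pytest.raises(ValueError):
        UtilizationProfile(1.2, 0.5, 0.5)
    with pytest.raises(ValueError):
        FuelMoles(-0.1, 0, 0)
    with pytest.raises(ValueError):
        urine_mass(-5.0)


def test_diet_and_exchange_round_trip(tmp_path, healthy_obese_diet, db):
    diet_csv = tmp_path / "diets.csv"
    write_diets_csv([healthy_obese_diet], str(diet_csv))
    (loaded,) = read_diets_csv(str(diet_csv))
    assert loaded == healthy_obese_diet

    out_csv = tmp_path / "exchange.csv"
    table = exchange_table(healthy_obese_diet, HEALTHY_PROFILE, db)
    write_exchange_csv({"healthy_obese": table}, str(out_csv))
    import pandas as pd

    frame = pd.read_csv(out_csv)
    assert frame.loc[0, "o2_g_per_day"] == pytest.approx(round(table.o2, 1))
    assert all(c.endswith("_g_per_day") for c in frame.columns if c != "diet")


def test_macro_fuel_mapping_is_complete():
    assert set(FUEL_FOR_MACRO) == set(MACRONUTRIENTS)
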