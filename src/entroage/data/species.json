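{
  "_notes": [
    "Thermodynamic property set for the seven species of the oxidation model.",
    "Enthalpies in kJ/kmol, entropies in kJ/(kmol K), molar masses in g/mol.",
    "Molar masses are the rounded values used throughout the exchange arithmetic",
    "(180/256/119/32/44/18/60); exact IUPAC masses shift results by ~0.3%.",
    "Gas-phase sensible enthalpies (h_sens_*) are ideal-gas table values; CO2 and",
    "H2O formation enthalpies and the 298 K sensible anchors are standard",
    "thermochemical-table values. Urea: solid-phase formation enthalpy -333.1e3",
    "kJ/kmol and entropy 104.6 kJ/(kmol K) from standard tables. The average",
    "amino acid entropy is the specific value 1.401 kJ/(kg K) times 119 g/mol.",
    "All values are overridable via a user config merged key-wise."
  ],
  "species": {
    "glucose": {
      "formula": {"C": 6, "H": 12, "O": 6},
      "molar_mass": 180.0,
      "h_form_298": -1260000.0,
      "s_298": 212.0
    },
    "palmitate": {
      "formula": {"C": 16, "H": 32, "O": 2},
      "molar_mass": 256.0,
      "h_form_298": -835000.0,
      "s_298": 452.0
    },
    "amino": {
      "formula": {"C": 4.57, "H": 9.03, "N": 1.27, "O": 2.25, "S": 0.046},
      "molar_mass": 119.0,
      "h_form_298": -385000.0,
      "s_298": 166.719
    },
    "O2": {
      "formula": {"O": 2},
      "molar_mass": 32.0,
      "h_form_298": 0.0,
      "s_298": 218.0,
      "h_sens_298": 8682.0,
      "s_310": 220.0
    },
    "CO2": {
      "formula": {"C": 1, "O": 2},
      "molar_mass": 44.0,
      "h_form_298": -393520.0,
      "s_298": 213.8,
      "h_sens_298": 9364.0,
      "h_sens_310": 9807.0,
      "s_310": 243.0
    },
    "H2O": {
      "formula": {"H": 2, "O": 1},
      "molar_mass": 18.0,
      "h_form_298": -241820.0,
      "s_298": 188.8,
      "h_sens_298": 9904.0,
      "h_sens_310": 10302.0,
      "s_310": 219.0
    },
    "urea": {
      "formula": {"C": 1, "H": 4, "N": 2, "O": 1},
      "molar_mass": 60.0,
      "h_form_298": -333100.0,
      "s_298": 104.6,
      "s_310": 104.6
    }
  },
  "constants": {
    "digestibility_healthy": {"carbohydrate": 0.99, "protein": 0.92, "fat": 0.95},
    "oxidation_fractions": {
      "childpugh_A": {"carbohydrate": 0.88, "protein": 0.28, "fat": 0.46},
      "childpugh_B": {"carbohydrate": 0.86, "protein": 0.31, "fat": 0.55},
      "childpugh_C": {"carbohydrate": 0.88, "protein": 0.24, "fat": 0.59}
    },
    "efficiency": {"glucose": 0.346, "palmitate": 0.322, "amino": 0.104},
    "atp_yield": {"glucose": 32.0, "palmitate": 106.0, "amino": 8.0},
    "urea_urine_conc_g_per_L": 20.0,
    "urea_excreted_fraction": 0.65,
    "body_temperature_K": 310.15,
    "lifespan_entropy_limit_kJ_per_kgK": 11404.0,
    "caloric_need_multiplier": 1.2
  }
}
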