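"""Daily gas and waste exchange for a diet plan.

Takes the 3100 kcal plan of a 100 kg healthy obese subject (430 g
carbohydrate, 150 g protein, 98 g fat per day), applies the healthy
digestibilities (0.99/0.92/0.95) and the three oxidation reactions, and
prints what crosses the body boundary each day.
"""

from entroage import HEALTHY_PROFILE, exchange_table
from entroage.presets import diet

plan = diet("healthy_obese")
table = exchange_table(plan, HEALTHY_PROFILE)

print(f"diet: {plan.name} ({plan.kcal:.0f} kcal/day, "
      f"{plan.carbohydrate:.0f}/{plan.protein:.0f}/{plan.fat:.0f} g C/P/F)")
for key, value in table.as_dict(ndigits=1).items():
    print(f"  {key:>14}: {value:8.1f} g/day")

# O2 ~898 g/day enters with respiration; CO2 ~1081 g and metabolic water
# ~428 g leave through the lungs, ~1436 g of urine carries 65% of the urea
# at 20 g/L, and ~21 g of unabsorbed dry matter exits as feces.
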