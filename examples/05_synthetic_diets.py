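"""Synthetic guideline-constrained diet plans.

Generates noisy diet tables around a calorie target and macronutrient split
(inside the 10-35% protein / 45-65% carbohydrate / 20-35% fat envelope) and
pushes them through the exchange pipeline — the same path real plans take.
"""

from entroage import DietGeneratorConfig, HEALTHY_PROFILE, exchange_table, generate_diets

config = DietGeneratorConfig(
    kcal_target=2400,
    macro_split={"carbohydrate": 0.55, "protein": 0.20, "fat": 0.25},
    noise_cv=0.10,
    seed=42,
    n=5,
)
plans = generate_diets(config)

print(f"{'plan':>12} {'kcal':>7} {'carb':>6} {'prot':>6} {'fat':>6} {'O2 g/d':>7}")
for plan in plans:
    o2 = exchange_table(plan, HEALTHY_PROFILE).o2
    print(f"{plan.name:>12} {plan.kcal:7.0f} {plan.carbohydrate:6.1f} "
          f"{plan.protein:6.1f} {plan.fat:6.1f} {o2:7.1f}")

# With a 10% coefficient of variation the grams scatter around the
# noise-free plan (330/120/66.7 g); identical seeds reproduce identical
# tables, which is what the test suite relies on.
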