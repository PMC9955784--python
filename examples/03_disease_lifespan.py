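"""Lifespan projection under fatty-liver disease (Child-Pugh classes).

A subject lives healthily to 40 (accumulating 119.9 kJ/(kg K yr) x 40 =
4796 kJ/(kg K)), then develops disease. The one-year survival fraction of
each Child-Pugh class converts the healthy rate into a disease rate
(rate / survival), and the projection finds the age at which the 11,404
kJ/(kg K) budget is exhausted — with and without a therapeutic diet change.
"""

from entroage import (
    EntropyLedger,
    Segment,
    SurvivalAdjustment,
    accumulate,
    disease_adjusted_rate,
    project_lifespan,
    scenario_compare,
)

HEALTHY_RATE = 119.9           # kJ/(kg K year)
ONSET_AGE = 40
ACCUMULATED = accumulate(HEALTHY_RATE, ONSET_AGE)
SURVIVAL = {"A": 0.95, "B": 0.80, "C": 0.44}
DIET_CHANGE_RATE = {"A": 76.4, "B": 87.2, "C": 98.8}   # therapeutic plans

print(f"accumulated by age {ONSET_AGE}: {ACCUMULATED:.0f} kJ/(kg K)")
print(f"{'class':>5} {'rate':>7} {'lifespan':>9} {'changed':>8} {'gained':>7}")
for cls, f in SURVIVAL.items():
    rate = disease_adjusted_rate(HEALTHY_RATE, SurvivalAdjustment(f))
    base = EntropyLedger(ONSET_AGE, ACCUMULATED, [Segment(rate)])
    alt = EntropyLedger(ONSET_AGE, ACCUMULATED, [Segment(DIET_CHANGE_RATE[cls])])
    gained, gained_int = scenario_compare(base, alt)
    print(f"{cls:>5} {rate:7.1f} {project_lifespan(base).rounded:9d} "
          f"{project_lifespan(alt).rounded:8d} {gained_int:7d}")

# Class C is most severe: its 272.5 kJ/(kg K yr) rate exhausts the budget at
# 64 years, while the therapeutic diet stretches it to 107 — four extra
# decades from halving the entropy generation rate.
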