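"""Mass-conservation classification, overestimation flags, seasoning rates.

A frittata whose six parts total 312 g against a 150 g portion is the classic
runaway decomposition: classified 'exceeded' with the excess in grams, and
flagged because the total is more than a quarter over the base weight.
"""

from mealdecomp import classify_mass, flag_overestimation, seasoning_rate
from mealdecomp.llm import Decomposition

parts = {"eggs": 100.0, "bell peppers": 75.0, "onions": 40.0,
         "zucchini": 65.0, "cheddar cheese": 28.0, "herbs": 4.0}
outcome = classify_mass(150.0, sum(parts.values()), compound_name="Grilled Vegetable Frittata")
flag = flag_overestimation(150.0, sum(parts.values()))
print(f"{outcome.compound_name}: {outcome.category}, excess {outcome.excess_g:.0f} g")
print(f"ratio {flag.ratio:.2f} -> flagged: {flag.flagged}")

decs = [
    Decomposition("Chicken Marsala", {"chicken breast": 110.0, "marsala wine": 30.0, "salt": 2.0}),
    Decomposition("Hummus", {"chickpeas": 60.0, "tahini": 15.0}),
    Decomposition("Ratatouille", {"eggplant": 60.0, "zucchini": 50.0, "salt": 3.0}),
]
report = seasoning_rate(decs, denominator=31)
print(f"seasoning quantity given in {report.n_included_with_quantity} of {report.denominator}"
      f" common compounds = {report.rate}%")

# 2 of 31 compounds carry an explicit salt/pepper/sugar quantity: 6.5%.
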