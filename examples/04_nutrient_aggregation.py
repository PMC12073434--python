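"""Scale per-100 g nutrient profiles to part masses and total a compound.

A hummus decomposition is priced out nutrient by nutrient: each part's
profile is scaled by its mass, then summed over the union of nutrient keys.
"""

from mealdecomp import aggregate_compound, scale_profile
from mealdecomp.fooddata import NutrientProfile

PROFILES = {  # per 100 g
    "chickpeas": NutrientProfile({"protein": 8.9, "fat": 2.6, "carbohydrate": 27.4, "fiber": 7.6}),
    "tahini": NutrientProfile({"protein": 17.0, "fat": 53.8, "carbohydrate": 21.2, "fiber": 9.3}),
    "olive oil": NutrientProfile({"fat": 100.0}),
}
MASSES = {"chickpeas": 60.0, "tahini": 15.0, "olive oil": 10.0}

parts = [scale_profile(PROFILES[name], mass, name) for name, mass in MASSES.items()]
total = aggregate_compound(parts, "Hummus")
print(f"{total.compound_name}: {total.parts_mass_g:.0f} g decomposed mass")
for nutrient, amount in total.amounts.items():
    print(f"  {nutrient:13s} {amount:6.2f} g   (coverage {total.coverage[nutrient]:.2f})")

# Coverage below 1.0 flags nutrients some parts did not report (olive oil has
# no protein entry), so the silent zeros in the sum stay auditable.
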