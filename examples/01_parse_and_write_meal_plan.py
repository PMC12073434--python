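"""Parse a meal-plan HTML table, inspect it, and write it back out.

Shows the four-column table dialect, gram conversion of deciliter portions,
and the reporting of unparseable rows.
"""

from mealdecomp import parse_meal_plan, write_meal_plan

HTML = """
<table>
  <tr><th>Ingredient</th><th>Ingredient Details</th><th>Quantity</th><th>Portion Size (g, dL)</th></tr>
  <tr><td>Chicken Marsala</td><td>with mushrooms</td><td></td><td>200 g</td></tr>
  <tr><td>Milk (or plant-based milk)</td><td></td><td>1 cup</td><td>2 dL</td></tr>
  <tr><td>Mystery item</td><td></td><td></td><td>a splash</td></tr>
</table>
"""

parsed = parse_meal_plan(HTML, meal_type="dinner", plan_id="demo")
for item in parsed.plan.items:
    print(f"{item.name:30s} {item.portion_mass_g:6.1f} g")
print(f"unparseable rows: {parsed.unparseable_rows}")
print()
print(write_meal_plan(parsed.plan))

# The milk portion (2 dL) is converted to 200 g at density 1 g/mL; the row
# whose portion could not be read is reported, not silently dropped.
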