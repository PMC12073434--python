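"""Extract and parse a model's compound-ingredient decomposition response.

The response wraps its payload in dollar signs; the payload is a loose
dictionary of dictionaries mapping each compound ingredient to basic
ingredients with quantities.
"""

from mealdecomp import extract_delimited_payload, parse_decomposition_payload

RAW_RESPONSE = (
    "Sure, here is the breakdown you asked for: "
    "$‘Hummus’: ‘chickpeas’: ‘60 g’, ‘tahini’: ‘15 g’, ‘olive oil’: ‘10 g’, "
    "‘lemon juice’: ‘10 g’, ‘garlic’: ‘5 g’, "
    "“Scrambled Eggs”: ‘eggs’: ‘120 g’, ‘milk’: ‘20 g’, ‘butter’: ‘10 g’$ "
    "Let me know if you need anything else!"
)

payload = extract_delimited_payload(RAW_RESPONSE, step="decomposition")
for dec in parse_decomposition_payload(payload):
    total = dec.total_mass_g
    print(f"{dec.compound_name}: {total:.0f} g over {len(dec.parts)} basic ingredients")
    for name, mass in dec.parts.items():
        print(f"  {name:12s} {mass:5.0f} g")

# The surrounding chatter is discarded; curly and straight quotes parse the
# same, and part masses are in grams, ready for mass-conservation checks.
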