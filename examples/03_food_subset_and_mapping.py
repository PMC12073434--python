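"""Build a tiered candidate subset for a basic ingredient and map it.

The subset prefers curated records (SR Legacy, Foundation) and widens to
survey (FNDDS) and then Experimental/Branded only while it holds fewer than
the sufficiency threshold; the mapping prompt then lists only ids and
descriptions.
"""

from mealdecomp import MockBackend, SubsetPolicy, build_subset, render_prompt
from mealdecomp.llm import extract_delimited_payload, parse_fdcid_payload
from mealdecomp.synthetic import generate_food_store

store = generate_food_store(seed=0)
subset = build_subset("blueberries", store, SubsetPolicy(sufficiency_threshold=3))
print("candidate subset (tier, then ascending id):")
for rec in subset:
    print(f"  {rec.fdc_id}  {rec.data_type:10s}  {rec.description}")

candidates = [f"{r.fdc_id}: {r.description}" for r in subset]
prompt = render_prompt("mapping", {"food_item": "blueberries", "list_of_food_items": candidates})
backend = MockBackend(name="demo", seed=1)
raw = backend.complete(prompt, {"task": "mapping", "fdc_id": subset[0].fdc_id})
fdc_id = parse_fdcid_payload(extract_delimited_payload(raw, step="mapping"))
print(f"mapped fdcId: {fdc_id}")

# The chosen id resolves the ingredient even when several records share an
# identical description name.
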