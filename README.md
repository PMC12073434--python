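# mealdecomp

Tools for decomposing compound ingredients in meal plans and evaluating how
well language models do it.

Meal plans usually list dishes as finished products — *Chicken Marsala*,
*Hummus*, *Grilled Vegetable Frittata* — rather than as the basic ingredients
(chicken breast, olive oil, garlic, ...) that nutrient profiling, allergy
screening and meal customization actually need. `mealdecomp` implements the
full workflow for studying that decomposition step with a pluggable
language-model backend, aimed at nutrition-informatics researchers and
developers of dietary-planning tools:

1. **Meal-plan I/O** — a fixed four-column HTML-table dialect (Ingredient,
   Ingredient Details, Quantity, Portion Size (g, dL)) with quantity/unit
   parsing and gram conversion for liquid portions.
2. **Backend contract and prompts** — templates for meal generation,
   compound-ingredient decomposition and food-record mapping; responses carry
   their payload between dollar signs (`$Content$`) and the decomposition
   payload is a tolerant dictionary-of-dictionaries grammar. A deterministic
   mock backend makes the whole pipeline runnable offline.
3. **Food-composition store** — records shaped like USDA FoodData Central
   entries (fdcId, description, data type, per-100 g nutrients). Candidate
   subsets for mapping are built through a trust hierarchy: SR Legacy and
   Foundation first, then FNDDS, then Experimental/Branded, widening only
   while fewer than a sufficiency threshold of matches have been found.
4. **Nutrient math** — per-100 g profiles scaled to part masses
   (`amount × mass/100`) and summed per compound over the union of nutrient
   keys, with a coverage report for ragged panels.
5. **Decomposition metrics** — mass-conservation classification
   (match / exceeded / under within ε, default 0.5 g), an overestimation flag
   for part totals more than a quarter above the portion mass (ratio > 1.25,
   strict), seasoning-quantity rates, and median/IQR macronutrient summaries.
6. **Evaluation statistics** — per-plan confusion counts against ground-truth
   compound/basic labels; accuracy and F1 (harmonic mean of precision and
   recall) with t-distribution 95 % confidence intervals; pairwise model
   comparisons gated on a Shapiro–Wilk normality test of the paired
   differences (paired *t* when normality is not rejected, Wilcoxon
   signed-rank otherwise, α = 0.05); evaluator pooling; one-way ANOVA for
   macronutrient agreement.
7. **Synthetic data** — meal plans with known compound/basic labels, true
   decompositions that conserve mass exactly, simulated predictions with
   controlled sensitivity/specificity and mass-error models, and a fixture
   food store — so every stage has ground truth.

## Worked example

Classify the classic runaway decomposition — a 150 g frittata whose six
predicted parts total 312 g — then score a prediction set:

```python
from mealdecomp import classify_mass, flag_overestimation

parts = {"eggs": 100, "bell peppers": 75, "onions": 40,
         "zucchini": 65, "cheddar cheese": 28, "herbs": 4}
outcome = classify_mass(150.0, sum(parts.values()))
print(outcome.category, outcome.excess_g)   # exceeded 162.0
print(flag_overestimation(150.0, 312.0))    # ratio 2.08 -> flagged=True
```

The parts exceed the stated portion by 162 g — more than a quarter over the
base weight, so the compound is also flagged as overestimated.

Run the whole offline study (three simulated models, 15 plans, three
evaluators) from the shell:

```bash
mealdecomp all --seed 7 --out scratch/study
```

which prints, among other tables (see `examples/07_offline_study.py`):

```
large-a      overall      acc 0.927 (0.90-0.95)  f1 0.801 (0.70-0.90)
large-b      overall      acc 0.906 (0.88-0.94)  f1 0.766 (0.67-0.87)
small-c      overall      acc 0.790 (0.76-0.82)  f1 0.565 (0.47-0.66)
...
accuracy  large-a vs small-c           wilcoxon  stat 10.500 p 0.0000
```

Here the weakest simulated backend (sensitivity 0.70) is significantly worse
than both stronger ones on pooled plan-level scores, while the two strong
backends are statistically indistinguishable — the pattern the evaluation
framework is built to detect. Each stage persists line-delimited JSON
intermediates, so `mealdecomp evaluate --out scratch/study` recomputes the
report bit-for-bit from artifacts.

The `examples/` directory has one short script per capability; each prints
the numbers it computes and says what they mean.

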