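# Methods

This note documents the models, procedures and numerical choices behind
`mealdecomp`: what each stage assumes, which parameters matter, what the
synthetic-data generator does and does not emulate, and where the design was
genuinely open.

## The decomposition problem

A meal plan is an ordered list of items with portion masses. Some items are
*basic* ingredients (olive oil, garlic); others are *compound* dishes that a
model should (a) recognize as compound and (b) decompose into basic
ingredients with masses that ideally sum back to the stated portion. The
pipeline evaluates both abilities: identification is scored as a per-plan
binary classification against ground-truth labels, and decomposition quality
is scored by mass conservation, overestimation, seasoning handling, and the
plausibility of the aggregated nutrient totals.

## Meal-plan dialect and unit handling

Plans travel as a single HTML `<table>` with columns Ingredient, Ingredient
Details, Quantity, and Portion Size (g, dL). Column recognition is by header
substring, so minor header drift tolerated; the first table wins when a
document has several (with a warning). Portion sizes mix grams and
deciliters in one column without a stated conversion rule, so liquids convert
at density 1 g/mL by default (2 dL → 200 g), overridable per ingredient.
Bare numbers parse as grams with a logged warning rather than erroring,
because model output drifts. Rows that still fail to parse are returned in
an `unparseable_rows` list — the parse conserves row counts (items out +
unparseable rows = data rows in).

Ingredient identity is trimmed, whitespace-collapsed, casefolded text.
Parenthetical qualifiers are kept as distinguishing, so salad variants
"(with lemon vinaigrette)" and "(without lemon vinaigrette)" remain distinct
unique ingredients.

## Backend contract and payload grammar

Backends satisfy one contract: prompt text in, response text out. Every
prompt-driven step wraps its answer in dollar signs; extraction takes the
*first* complete `$...$` span and discards commentary, because models assume
one span but drift. Extraction failures trigger exactly one re-ask, then the
item fails into a logged failure manifest.

The decomposition payload is a dictionary of dictionaries, but the canonical
example format is not valid JSON ("'Compound': 'part': '50 g', ..."), so the
parser accepts two grammars over one tokenizer (curly quotes normalized to
straight): a braced, JSON-like form parsed by recursive descent, and a flat
quoted-pair form disambiguated by one-token lookahead — a key whose value is
followed by another colon opens a new compound; otherwise the pair is a
part/quantity entry of the current compound. The parser is total: it returns
a fully valid structure or raises a typed error, never a partial one.

The shipped `MockBackend` is deterministic in (model name, seed, prompt): a
SHA-256 digest of the triple seeds the generator that decides, e.g., whether
to inject a malformed (delimiter-free) response at the configured rate. The
re-ask appends whitespace to the prompt so a deterministic backend can draw a
fresh outcome; live adapters would simply resend.

## Food store and the subset hierarchy

Records carry (fdcId, description, dataType, per-100 g nutrient profile).
Candidate subsets for mapping are built tier by tier — {SR Legacy,
Foundation} → {FNDDS} → {Experimental, Branded} — widening only while the
accumulated match count is below a sufficiency threshold (default 3; the
notion of "insufficient" is not standardized, so it is configuration with a
logged default). Curated tiers come first because branded data is abundant
but noisy — an everyday ingredient can match thousands of branded records —
and many records share identical description names; the mapping step
disambiguates by id, which is exactly why prompts request the fdcId rather
than a description. Fixture-mode matching is case-insensitive substring
search over descriptions, ordered (tier, ascending fdcId) so prompts are
reproducible; nutrients are deliberately excluded from the subset handed to
the mapping prompt so the match is made on descriptions alone. A live client
must pace requests at `3600 / limit_per_hour` seconds (3.6 s at the
1000-requests-per-hour limit); the scheduler computes the spacing, and live
mode itself is an opt-in configuration contract, not shipped network code.

## Nutrient math

Profiles are per 100 g; scaling multiplies by `mass_g / 100`, and compound
totals sum element-wise over the union of nutrient keys with missing keys
treated as zero. Because real panels are ragged, every aggregate carries a
coverage map (fraction of parts reporting each nutrient) so silent zeros are
auditable. No cooking-loss correction is applied: ingredients do lose water
in preparation, but the pipeline reports stated masses as-is rather than
inventing an adjustment.

## Decomposition metrics

Mass conservation is a three-way classification of `excess = parts − portion`
against a tolerance ε: match (|excess| ≤ ε), exceeded, under. ε defaults to
0.5 g: "exact" matching with integer-gram model outputs is safe inside a
half-gram band, and ε is configurable. The overestimation flag fires when
`parts / portion > 1.25`, strictly — exactly one quarter over is not flagged;
the boundary choice is logged either way. Seasoning reporting counts
decompositions giving an explicit positive mass for any of {salt, pepper,
sugar} (token-level matching, so "black pepper" counts), over a configurable
denominator — typically the compound ingredients predicted by *all* models
under comparison. Macronutrient summaries are median and 25th/75th
percentiles with linear interpolation (the method is stated because IQR
conventions differ); rates round half-up to one decimal.

## Evaluation statistics

Per plan: tp = true compounds predicted, fp = basics predicted (plus
hallucinated names that resolve to no plan ingredient — dropping them would
inflate precision), fn = compounds missed, tn = the rest; counts always sum
to the plan's ingredient count. Accuracy = (tp+tn)/total; precision, recall,
F1 as usual, with conventions keeping scores defined on degenerate plans:
with no predictions, precision is 1 if there was also nothing to find else 0;
with no true compounds, recall is 1 if nothing was claimed else 0; F1 is 0
when both are 0. Each convention application is logged.

Confidence intervals on mean per-plan scores are t-distribution intervals
(identical values give a zero-width interval). Pairwise model comparisons
run Shapiro–Wilk on the paired differences: not rejected at α = 0.05 →
paired t-test; rejected → Wilcoxon signed-rank; all-zero differences are a
defined degenerate result (p = 1, no test run) because normality testing on a
constant is undefined. Constant *non-zero* differences hit the same
undefined Shapiro–Wilk and route to Wilcoxon, whose sign-rank logic still
applies, whereas the t statistic would be infinite. Pooling across
evaluators concatenates per-plan scores (3 evaluators × 15 plans → 45 pairs).
Macronutrient agreement across models uses classical one-way ANOVA. No
multiple-testing correction is applied by default; a Holm adjustment is
available for users who want family-wise control.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions: 15 plans cycling
breakfast/lunch/dinner, 5–9 ingredients per plan, compound prevalence 0.32
(roughly one compound to two basics), three evaluators. Compound dishes come
from a built-in lexicon of 30 dishes with hand-written part fractions;
60-plus basic ingredients all resolve in the fixture store. True part masses
are integer grams that sum *exactly* to the portion (largest part absorbs the
rounding residual, floor 1 g), so mass conservation holds by construction and
any downstream violation is attributable to the configured error model.

Simulated models flag each true compound with probability *sensitivity* and
each basic with probability 1 − *specificity*; decompositions of true
compounds are the true parts under a mass-error model (none; additive
Gaussian noise in grams; or a systematic scale-up by a fraction — 0.30 makes
every decomposition exceed the 1.25 overestimation threshold), rounded to
whole grams with a 1 g floor; seasonings are inserted with a configurable
probability. One master seed derives per-stage seeds by fixed offsets, so
stages are individually reproducible and whole runs are byte-identical.

What this shows and does not show: passing tests demonstrate that the
pipeline measures what it claims — mean accuracy over many plans recovers
πs + (1−π)q, and mean F1 its exact binomial-enumeration expectation
(`expected_f1_exact`), within Monte-Carlo error. They do not certify real
language-model behavior: real errors are correlated across ingredients and
plans, real part lists vary in length and naming, evaluators disagree, and
fixture nutrient panels are plausible magnitudes, not measured composition.
The generator emits one ground truth replicated across evaluators; it has no
inter-rater disagreement model.

## Pipeline and problem sizes

Stages persist line-delimited JSON before the next stage runs, so any stage
can be re-run from artifacts and the report is reproducible bit-for-bit;
failures land in per-stage failure manifests rather than truncating output.
Offline mode is the default and the only mode the tests exercise.

Default test-suite problem sizes are deliberately small (4–15 plans); the
metric-recovery check runs 200 plans × 20 ingredients with one evaluator,
chosen to put three Monte-Carlo standard errors around 0.005 of the target
accuracy — tight enough to catch real bias, and it completes in seconds.

## Known limitations

- Live-mode adapters (real LLM endpoints, the real food-data API) are a
  contract only; no network code ships.
- The flat payload grammar cannot represent a compound with zero parts and
  treats apostrophes inside single-quoted names as delimiters; the mock never
  emits such names, and a live adapter should prefer the braced form.
- Fixture-store search is substring-based, so short queries can match
  unrelated descriptions; the mapping mock always picks the first candidate.
- Nutrient unit harmonization beyond gram-denominated macronutrients is out
  of scope, as are energy density and dietary-reference scoring.
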