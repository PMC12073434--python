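"""Synthetic study generator: meal plans, ground truth, predictions, food store.

Everything the pipeline consumes can be generated here with known ground
truth, so every stage runs and is testable offline:

* meal plans whose items are drawn from a built-in lexicon of ~30 compound
  dishes (each with a hand-written, plausible part list) and ~60 basic
  ingredients, with the compound/basic label known by construction;
* true decompositions whose part masses sum *exactly* to the compound's
  portion mass (mass conservation holds by construction, so any violation
  observed downstream is attributable to the configured error model);
* simulated model predictions with controlled sensitivity (probability a
  true compound is flagged) and specificity (probability a basic ingredient
  is passed over), plus a configurable mass-error model and optional
  seasoning insertion;
* a fixture food store in which every basic ingredient resolves, with a
  configurable fraction of ingredients covered only by lower-trust tiers and
  a few deliberately duplicated description names.

Defaults mirror the study conditions: 15 plans split over breakfast, lunch
and dinner, roughly two-thirds basic to one-third compound ingredients
(prevalence 0.32).  A single master seed derives per-stage seeds by fixed
offsets, so each stage is individually reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binom

from .fooddata import FoodStore
from .llm import Decomposition
from .meal_plans import MealItem, MealPlan, MealType, normalize_name
from .stats import GroundTruthLabels, metrics_from_confusion, ConfusionCounts

__all__ = [
    "COMPOUND_LEXICON",
    "BASIC_LEXICON",
    "MassErrorModel",
    "SimulationConfig",
    "LabeledPlanSet",
    "ModelPredictions",
    "generate_plan_set",
    "simulate_predictions",
    "generate_food_store",
    "expected_accuracy",
    "expected_f1_exact",
]

# Compound dishes with part-mass fractions (normalized at use).  Names echo
# everyday dishes; part lists are culinarily plausible, not authoritative.
COMPOUND_LEXICON: dict[str, dict[str, float]] = {
    "Chicken Marsala": {"chicken breast": 0.55, "marsala wine": 0.15, "mushrooms": 0.15, "butter": 0.05, "flour": 0.05, "chicken broth": 0.05},
    "Chicken Cacciatore": {"chicken breast": 0.5, "tomatoes": 0.25, "bell peppers": 0.1, "onions": 0.1, "olive oil": 0.05},
    "Vegetable Ratatouille": {"eggplant": 0.3, "zucchini": 0.25, "tomatoes": 0.25, "onions": 0.1, "olive oil": 0.05, "garlic": 0.05},
    "Grilled Vegetable Frittata": {"eggs": 0.45, "bell peppers": 0.2, "onions": 0.1, "zucchini": 0.15, "cheddar cheese": 0.08, "parsley": 0.02},
    "Scrambled Eggs": {"eggs": 0.8, "milk": 0.12, "butter": 0.08},
    "Oatmeal with Fresh Fruit": {"oats": 0.35, "milk": 0.4, "blueberries": 0.15, "banana": 0.1},
    "Steel-Cut Oatmeal": {"oats": 0.4, "milk": 0.5, "honey": 0.1},
    "Whole Grain Pancakes": {"whole wheat flour": 0.4, "milk": 0.35, "eggs": 0.15, "baking powder": 0.02, "maple syrup": 0.08},
    "Whole Wheat Bagel with Light Cream Cheese": {"whole wheat flour": 0.7, "cream cheese": 0.25, "honey": 0.05},
    "Mixed Greens Salad": {"romaine lettuce": 0.5, "cucumber": 0.25, "carrots": 0.2, "olive oil": 0.05},
    "Mixed Greens Salad (with lemon vinaigrette)": {"romaine lettuce": 0.45, "cucumber": 0.25, "carrots": 0.15, "lemon juice": 0.1, "olive oil": 0.05},
    "Mixed Greens Salad (without lemon vinaigrette)": {"romaine lettuce": 0.55, "cucumber": 0.25, "carrots": 0.2},
    "Hummus": {"chickpeas": 0.6, "tahini": 0.15, "lemon juice": 0.1, "olive oil": 0.1, "garlic": 0.05},
    "Herb-Roasted Salmon": {"salmon": 0.85, "olive oil": 0.05, "rosemary": 0.03, "lemon juice": 0.07},
    "Greek Yogurt Parfait": {"greek yogurt": 0.6, "granola": 0.2, "strawberries": 0.15, "honey": 0.05},
    "Vegetable Stir-Fry": {"broccoli": 0.3, "bell peppers": 0.2, "carrots": 0.2, "soy sauce": 0.1, "rice": 0.15, "sesame oil": 0.05},
    "Quinoa Salad": {"quinoa": 0.5, "cucumber": 0.2, "tomatoes": 0.15, "feta cheese": 0.1, "olive oil": 0.05},
    "Lentil Soup": {"lentils": 0.35, "vegetable broth": 0.4, "carrots": 0.1, "onions": 0.1, "olive oil": 0.05},
    "Turkey Sandwich": {"whole wheat bread": 0.45, "turkey breast": 0.35, "romaine lettuce": 0.1, "tomatoes": 0.1},
    "Caprese Salad": {"tomatoes": 0.45, "mozzarella": 0.4, "basil": 0.05, "olive oil": 0.1},
    "Beef Chili": {"ground beef": 0.4, "kidney beans": 0.25, "tomatoes": 0.25, "onions": 0.08, "chili powder": 0.02},
    "Shrimp Scampi": {"shrimp": 0.5, "pasta": 0.3, "butter": 0.08, "garlic": 0.05, "lemon juice": 0.07},
    "Stuffed Bell Peppers": {"bell peppers": 0.4, "rice": 0.3, "ground beef": 0.2, "tomatoes": 0.1},
    "Tofu Curry": {"tofu": 0.4, "coconut milk": 0.35, "onions": 0.1, "curry powder": 0.05, "rice": 0.1},
    "Avocado Toast": {"whole wheat bread": 0.5, "avocado": 0.45, "lemon juice": 0.05},
    "Banana Smoothie": {"banana": 0.4, "milk": 0.45, "greek yogurt": 0.1, "honey": 0.05},
    "Pasta Primavera": {"pasta": 0.45, "zucchini": 0.2, "bell peppers": 0.15, "parmesan": 0.1, "olive oil": 0.1},
    "Chicken Caesar Wrap": {"tortilla": 0.3, "chicken breast": 0.4, "romaine lettuce": 0.15, "caesar dressing": 0.1, "parmesan": 0.05},
    "Mushroom Risotto": {"rice": 0.4, "mushrooms": 0.25, "vegetable broth": 0.25, "parmesan": 0.07, "butter": 0.03},
    "Fruit Salad": {"apples": 0.3, "oranges": 0.3, "strawberries": 0.2, "blueberries": 0.2},
}

# Basic ingredients that may appear as standalone plan items.
BASIC_LEXICON: tuple[str, ...] = (
    "olive oil", "garlic", "mushrooms", "chicken breast", "eggs", "milk",
    "butter", "oats", "blueberries", "strawberries", "banana", "honey",
    "whole wheat flour", "cream cheese", "romaine lettuce", "cucumber",
    "carrots", "lemon juice", "tomatoes", "eggplant", "basil", "parsley",
    "salmon", "rosemary", "chickpeas", "tahini", "greek yogurt", "spinach",
    "rice", "quinoa", "almonds", "walnuts", "maple syrup", "apples",
    "oranges", "celery", "potatoes", "sweet potatoes", "green beans",
    "broccoli", "cauliflower", "ground beef", "shrimp", "pasta",
    "whole wheat bread", "tofu", "lentils", "kidney beans", "bell peppers",
    "onions", "zucchini", "cheddar cheese", "mozzarella", "parmesan",
    "feta cheese", "turkey breast", "avocado", "granola", "salt",
    "black pepper", "sugar", "marsala wine", "chicken broth",
    "vegetable broth", "coconut milk", "soy sauce", "sesame oil",
    "baking powder", "tortilla", "caesar dressing", "curry powder",
    "chili powder",
)


@dataclass(frozen=True)
class MassErrorModel:
    """How simulated decompositions distort the true part masses.

    kind 'none' copies the truth; 'additive_noise' adds independent N(0, sd_g)
    grams to each part; 'systematic_overestimate' scales every part by
    (1 + fraction).  Perturbed masses round to whole grams and floor at 1 g,
    matching the integer-gram style of model outputs.
    """

    kind: str = "none"
    sd_g: float = 0.0
    fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "additive_noise", "systematic_overestimate"):
            raise ValueError(f"unknown mass error model {self.kind!r}")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_plans: int = 15
    ingredients_per_plan: tuple[int, int] = (5, 9)
    compound_prevalence: float = 0.32
    sensitivity: float = 0.9
    specificity: float = 0.9
    mass_error: MassErrorModel = field(default_factory=MassErrorModel)
    seasoning_inclusion_prob: float = 0.0
    n_evaluators: int = 3
    store_fallback_fraction: float = 0.1
    store_duplicate_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n_plans <= 0:
            raise ValueError("n_plans must be positive")
        lo, hi = self.ingredients_per_plan
        if not (0 < lo <= hi):
            raise ValueError("ingredients_per_plan must be a positive (low, high) range")
        for name in ("compound_prevalence", "sensitivity", "specificity", "seasoning_inclusion_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.compound_prevalence > 0 and not COMPOUND_LEXICON:
            raise ValueError("compound prevalence > 0 but the compound lexicon is empty")
        if self.ingredients_per_plan[1] > len(COMPOUND_LEXICON):
            # worst case: every slot draws a compound; names are unique per plan
            raise ValueError(
                f"ingredients_per_plan high bound {hi} exceeds the compound lexicon size {len(COMPOUND_LEXICON)}"
            )

    def stage_seed(self, offset: int) -> int:
        """Per-stage seed derived from the master seed by a fixed offset."""
        return (self.seed * 1000 + offset) % (2**31 - 1)


@dataclass(frozen=True)
class LabeledPlanSet:
    plans: tuple[MealPlan, ...]
    truth: Mapping[str, GroundTruthLabels]  # plan_id -> labels
    true_decompositions: Mapping[str, tuple[Decomposition, ...]]  # plan_id -> decompositions

    def compound_names(self, plan_id: str) -> set[str]:
        return {n for n, lab in self.truth[plan_id].labels.items() if lab == "compound"}


@dataclass(frozen=True)
class ModelPredictions:
    model_name: str
    predicted_compounds: Mapping[str, frozenset[str]]  # plan_id -> normalized names
    decompositions: Mapping[str, tuple[Decomposition, ...]]  # plan_id -> predicted decompositions


def _integer_split(total: int, fractions: Sequence[float], floor: int = 1) -> list[int]:
    """Split `total` grams over parts by fraction, exactly conserving the sum."""
    raw = [max(floor, round(total * f)) for f in fractions]
    residual = total - sum(raw)
    # push the residual onto the largest part, keeping every part >= floor
    order = sorted(range(len(raw)), key=lambda i: -raw[i])
    for i in order:
        adjust = max(floor - raw[i], residual)
        raw[i] += adjust
        residual -= adjust
        if residual == 0:
            break
    return raw


def generate_plan_set(config: SimulationConfig) -> LabeledPlanSet:
    """Generate meal plans with labeled ingredients and true decompositions.

    Each plan draws its item count uniformly from ``ingredients_per_plan``;
    each slot is a compound dish with probability ``compound_prevalence`` and
    a basic ingredient otherwise, names unique within a plan.  Compound
    portions are 100–400 g (rounded to 10 g), basics 10–250 g; true part
    masses follow the lexicon's fractions and sum exactly to the portion.
    Meal types cycle breakfast → lunch → dinner.  Deterministic per seed.
    """
    rng = np.random.default_rng(config.stage_seed(1))
    compounds = list(COMPOUND_LEXICON)
    basics = list(BASIC_LEXICON)
    meal_types = [MealType.BREAKFAST, MealType.LUNCH, MealType.DINNER]

    plans: list[MealPlan] = []
    truth: dict[str, GroundTruthLabels] = {}
    true_decs: dict[str, tuple[Decomposition, ...]] = {}
    for p in range(config.n_plans):
        plan_id = f"plan-{p + 1:03d}"
        lo, hi = config.ingredients_per_plan
        n_items = int(rng.integers(lo, hi + 1))
        is_compound = rng.random(n_items) < config.compound_prevalence
        n_comp = int(is_compound.sum())
        comp_names = list(rng.choice(compounds, size=n_comp, replace=False))
        basic_names = list(rng.choice(basics, size=n_items - n_comp, replace=False))
        items: list[MealItem] = []
        decs: list[Decomposition] = []
        ci = bi = 0
        for flag in is_compound:
            if flag:
                name = comp_names[ci]
                ci += 1
                mass = float(rng.integers(10, 41) * 10)  # 100-400 g
                items.append(MealItem(name=name, portion_mass_g=mass))
                part_names = list(COMPOUND_LEXICON[name])
                fracs = np.array([COMPOUND_LEXICON[name][k] for k in part_names], dtype=float)
                fracs /= fracs.sum()
                masses = _integer_split(int(mass), fracs.tolist())
                decs.append(
                    Decomposition(
                        compound_name=name,
                        parts={normalize_name(n): float(m) for n, m in zip(part_names, masses)},
                    )
                )
            else:
                name = basic_names[bi]
                bi += 1
                mass = float(rng.integers(1, 26) * 10)  # 10-250 g
                items.append(MealItem(name=name, portion_mass_g=mass))
        plans.append(MealPlan(meal_type=meal_types[p % 3], items=tuple(items), plan_id=plan_id))
        truth[plan_id] = GroundTruthLabels.from_names(
            evaluator_id="truth", plan_id=plan_id, compounds=comp_names, basics=basic_names
        )
        true_decs[plan_id] = tuple(decs)
    return LabeledPlanSet(plans=tuple(plans), truth=truth, true_decompositions=true_decs)


def _perturb(dec: Decomposition, model: MassErrorModel, rng: np.random.Generator) -> Decomposition:
    if model.kind == "none":
        return dec
    parts = {}
    for name, mass in dec.parts.items():
        if model.kind == "additive_noise":
            new = mass + rng.normal(0.0, model.sd_g)
        else:  # systematic_overestimate
            new = mass * (1.0 + model.fraction)
        parts[name] = float(max(1, round(new)))
    return Decomposition(compound_name=dec.compound_name, parts=parts)


def simulate_predictions(
    plan_set: LabeledPlanSet, config: SimulationConfig, model_name: str = "mock"
) -> ModelPredictions:
    """Simulate one model's compound predictions and decompositions.

    Each true compound is predicted with probability ``sensitivity``; each
    basic ingredient is falsely flagged with probability 1 − ``specificity``
    (its invented decomposition splits the portion 60/40 over two lexicon
    basics).  Predicted decompositions of true compounds are the true parts
    perturbed by the configured mass-error model; with probability
    ``seasoning_inclusion_prob`` a 1–3 g seasoning (salt, black pepper or
    sugar) is added.  Deterministic per (seed, model_name).
    """
    rng = np.random.default_rng(
        (config.stage_seed(2) + zlib.crc32(model_name.encode()) % 100003) % (2**31 - 1)
    )
    predicted: dict[str, frozenset[str]] = {}
    decompositions: dict[str, tuple[Decomposition, ...]] = {}
    for plan in plan_set.plans:
        labels = plan_set.truth[plan.plan_id].labels
        true_dec_by_name = {normalize_name(d.compound_name): d for d in plan_set.true_decompositions[plan.plan_id]}
        flagged: list[str] = []
        decs: list[Decomposition] = []
        for item in plan.items:
            key = normalize_name(item.name)
            if labels[key] == "compound":
                if rng.random() < config.sensitivity:
                    flagged.append(key)
                    decs.append(_perturb(true_dec_by_name[key], config.mass_error, rng))
            else:
                if rng.random() >= config.specificity:
                    flagged.append(key)
                    fillers = rng.choice(len(BASIC_LEXICON), size=2, replace=False)
                    total = max(2, int(item.portion_mass_g))
                    decs.append(
                        Decomposition(
                            compound_name=item.name,
                            parts={
                                normalize_name(BASIC_LEXICON[fillers[0]]): float(max(1, round(0.6 * total))),
                                normalize_name(BASIC_LEXICON[fillers[1]]): float(total - max(1, round(0.6 * total))),
                            },
                        )
                    )
        seasoned: list[Decomposition] = []
        for d in decs:
            if config.seasoning_inclusion_prob > 0 and rng.random() < config.seasoning_inclusion_prob:
                seasoning = ("salt", "black pepper", "sugar")[int(rng.integers(0, 3))]
                parts = dict(d.parts)
                parts[normalize_name(seasoning)] = float(rng.integers(1, 4))
                seasoned.append(Decomposition(compound_name=d.compound_name, parts=parts))
            else:
                seasoned.append(d)
        predicted[plan.plan_id] = frozenset(flagged)
        decompositions[plan.plan_id] = tuple(seasoned)
    return ModelPredictions(model_name=model_name, predicted_compounds=predicted, decompositions=decompositions)


# Plausible macronutrient ranges per 100 g, (low, high), used for fixture panels.
_NUTRIENT_RANGES = {
    "protein": (0.5, 25.0),
    "fat": (0.1, 20.0),
    "carbohydrate": (0.5, 60.0),
    "fiber": (0.0, 8.0),
}


def generate_food_store(
    lexicon: Sequence[str] | None = None,
    seed: int = 0,
    fallback_fraction: float = 0.1,
    duplicate_fraction: float = 0.05,
) -> FoodStore:
    """Build a fixture food store covering every basic ingredient.

    Each ingredient gets 1–3 records whose descriptions contain its name.
    A ``fallback_fraction`` of ingredients receive only FNDDS/Branded records
    (to exercise the tier fallback); a ``duplicate_fraction`` get two records
    sharing one identical description under distinct ids (the collision case
    the mapping step must disambiguate by id).  Nutrient panels are per 100 g
    with plausible macronutrient magnitudes, not real composition data.
    """
    if lexicon is None:
        names = sorted(set(BASIC_LEXICON) | {p for parts in COMPOUND_LEXICON.values() for p in parts})
    else:
        names = sorted(set(lexicon))
    if not names:
        raise ValueError("lexicon must be non-empty")
    rng = np.random.default_rng(seed)
    styles = ["raw", "cooked", "dried", "canned", "frozen"]
    records = []
    fdc_id = 10001
    n_fallback = int(round(fallback_fraction * len(names)))
    fallback_set = set(rng.choice(len(names), size=n_fallback, replace=False).tolist())
    for idx, name in enumerate(names):
        n_recs = int(rng.integers(1, 4))
        tier_types = (
            ["FNDDS", "Branded", "Experimental"] if idx in fallback_set else ["SR Legacy", "Foundation"]
        )
        descriptions = [f"{name.title()}, {styles[k % len(styles)]}" for k in range(n_recs)]
        if rng.random() < duplicate_fraction:
            descriptions.append(descriptions[0])  # identical-description collision
        for desc in descriptions:
            nutrients = {
                nut: round(float(rng.uniform(lo, hi)), 2) for nut, (lo, hi) in _NUTRIENT_RANGES.items()
            }
            records.append(
                {
                    "fdcId": fdc_id,
                    "description": desc,
                    "dataType": str(rng.choice(tier_types)),
                    "nutrients": nutrients,
                }
            )
            fdc_id += 1
    return FoodStore.from_records(records)


def expected_accuracy(sensitivity: float, specificity: float, prevalence: float) -> float:
    """Population accuracy of a sensitivity/specificity classifier: πs + (1−π)q."""
    return prevalence * sensitivity + (1.0 - prevalence) * specificity


def expected_f1_exact(
    sensitivity: float,
    specificity: float,
    prevalence: float,
    n_ingredients: int,
) -> float:
    """Exact expected per-plan F1 by enumeration over the binomial counts.

    For a plan of ``n_ingredients`` items, the number of true compounds is
    Binomial(n, prevalence); given c compounds, true positives are
    Binomial(c, sensitivity) and false positives Binomial(n − c,
    1 − specificity).  The expectation applies the same zero-denominator
    conventions as :func:`mealdecomp.stats.metrics_from_confusion`, so it is
    the exact mean of the per-plan F1 the pipeline reports.
    """
    n = n_ingredients
    total = 0.0
    for c in range(n + 1):
        pc = binom.pmf(c, n, prevalence)
        if pc == 0.0:
            continue
        for tp in range(c + 1):
            ptp = binom.pmf(tp, c, sensitivity)
            if ptp == 0.0:
                continue
            for fp in range(n - c + 1):
                pfp = binom.pmf(fp, n - c, 1.0 - specificity)
                if pfp == 0.0:
                    continue
                m = metrics_from_confusion(ConfusionCounts(tp=tp, fp=fp, fn=c - tp, tn=n - c - fp))
                total += pc * ptp * pfp * m.f1
    return total
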