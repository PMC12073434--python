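"""Decomposition-quality metrics: mass conservation, overestimation, seasonings.

A faithful decomposition distributes a compound ingredient's portion mass over
its basic parts, so the part masses should sum back to the portion mass.  The
classifier here calls the outcome a *match* within a small tolerance ε
(default 0.5 g — model outputs are typically whole grams), *exceeded* above
it, *under* below it.  A separate flag marks decompositions whose part total
exceeds the portion mass by more than one quarter (ratio strictly above 1.25).

Seasoning reporting counts decompositions that state an explicit positive mass
for at least one member of a seasoning set (salt, pepper, sugar by default),
as a percentage of a stated denominator.  Macronutrient summaries are median
and interquartile range with linear-interpolation percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

from .llm import Decomposition
from .meal_plans import normalize_name

__all__ = [
    "DEFAULT_SEASONINGS",
    "MassConservationOutcome",
    "OverestimationFlag",
    "SeasoningReport",
    "MacronutrientSummary",
    "classify_mass",
    "flag_overestimation",
    "seasoning_rate",
    "summarize_macronutrients",
    "match_rate_summary",
]

DEFAULT_SEASONINGS = frozenset({"salt", "pepper", "sugar"})
OVERESTIMATION_RATIO = 1.25


@dataclass(frozen=True)
class MassConservationOutcome:
    compound_name: str
    compound_mass_g: float
    parts_total_g: float
    category: str  # match | exceeded | under
    excess_g: float


@dataclass(frozen=True)
class OverestimationFlag:
    compound_name: str
    ratio: float
    flagged: bool


@dataclass(frozen=True)
class SeasoningReport:
    seasoning_set: frozenset[str]
    n_included_with_quantity: int
    denominator: int
    rate: float  # percentage, one-decimal half-up


@dataclass(frozen=True)
class MacronutrientSummary:
    nutrient: str
    median: float
    iqr_low: float
    iqr_high: float


def classify_mass(
    compound_mass_g: float,
    parts_total_g: float,
    epsilon: float = 0.5,
    compound_name: str = "",
) -> MassConservationOutcome:
    """Three-way mass-conservation classification with tolerance ε grams.

    match iff |excess| <= ε; exceeded iff excess > ε; under iff excess < -ε.
    The classification is exhaustive and mutually exclusive.
    """
    if compound_mass_g <= 0:
        raise ValueError(f"compound mass must be positive, got {compound_mass_g}")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    excess = parts_total_g - compound_mass_g
    if excess > epsilon:
        category = "exceeded"
    elif excess < -epsilon:
        category = "under"
    else:
        category = "match"
    return MassConservationOutcome(
        compound_name=compound_name,
        compound_mass_g=compound_mass_g,
        parts_total_g=parts_total_g,
        category=category,
        excess_g=excess,
    )


def flag_overestimation(
    compound_mass_g: float, parts_total_g: float, compound_name: str = ""
) -> OverestimationFlag:
    """Flag a decomposition whose part total exceeds the base weight by > 1/4.

    The boundary is strict: a ratio of exactly 1.25 is not flagged.
    """
    if compound_mass_g <= 0:
        raise ValueError(f"compound mass must be positive, got {compound_mass_g}")
    ratio = parts_total_g / compound_mass_g
    return OverestimationFlag(compound_name=compound_name, ratio=ratio, flagged=ratio > OVERESTIMATION_RATIO)


def _round_rate(rate: float) -> float:
    return float(Decimal(repr(rate)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def seasoning_rate(
    decompositions: Iterable[Decomposition],
    seasoning_set: Iterable[str] = DEFAULT_SEASONINGS,
    denominator: int | None = None,
) -> SeasoningReport:
    """Rate at which decompositions give an explicit quantity for a seasoning.

    A decomposition counts once if any part name contains a seasoning-set
    member with a positive mass.  ``denominator`` defaults to the number of
    decompositions supplied but is typically the number of compound
    ingredients common to every model under comparison.
    """
    seasonings = {normalize_name(s) for s in seasoning_set}
    decomposition_list = list(decompositions)
    if denominator is None:
        denominator = len(decomposition_list)
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    n = 0
    for d in decomposition_list:
        for part_name, mass in d.parts.items():
            tokens = set(normalize_name(part_name).replace(",", " ").split())
            if tokens & seasonings and mass > 0:
                n += 1
                break
    return SeasoningReport(
        seasoning_set=frozenset(seasonings),
        n_included_with_quantity=n,
        denominator=denominator,
        rate=_round_rate(100.0 * n / denominator),
    )


def summarize_macronutrients(
    totals: "Sequence | Mapping[str, Sequence[float]]",
    nutrients: Sequence[str] | None = None,
) -> list[MacronutrientSummary]:
    """Median and IQR (25th/75th percentile, linear interpolation) per nutrient.

    Accepts either per-compound nutrient totals (anything with an ``amounts``
    mapping, e.g. :class:`~mealdecomp.nutrients.CompoundNutrientTotal`) or a
    prebuilt ``{nutrient: values}`` mapping.  With totals, ``nutrients``
    selects which keys to summarize (default: union of keys, in first-seen
    order); a total missing a nutrient contributes zero for it.
    """
    if isinstance(totals, Mapping):
        values_by_nutrient: Mapping[str, Sequence[float]] = totals
    else:
        totals = list(totals)
        if not totals:
            raise ValueError("no nutrient totals supplied")
        if nutrients is None:
            seen: list[str] = []
            for t in totals:
                for k in t.amounts:
                    if k not in seen:
                        seen.append(k)
            nutrients = seen
        values_by_nutrient = {n: [t.amounts.get(n, 0.0) for t in totals] for n in nutrients}
    if not values_by_nutrient:
        raise ValueError("no nutrient values supplied")
    out = []
    for nutrient, values in values_by_nutrient.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0:
            raise ValueError(f"no values for nutrient {nutrient!r}")
        lo, med, hi = np.percentile(arr, [25, 50, 75], method="linear")
        out.append(MacronutrientSummary(nutrient=nutrient, median=float(med), iqr_low=float(lo), iqr_high=float(hi)))
    return out


def match_rate_summary(outcomes: Sequence[MassConservationOutcome]) -> tuple[float, float, float]:
    """Fractions of (match, exceeded, under) outcomes; they sum to 1."""
    if not outcomes:
        raise ValueError("no outcomes supplied")
    n = len(outcomes)
    counts = {"match": 0, "exceeded": 0, "under": 0}
    for o in outcomes:
        counts[o.category] += 1
    return (counts["match"] / n, counts["exceeded"] / n, counts["under"] / n)
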