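"""Meal-plan data model and the HTML-table dialect shared by every pipeline stage.

A meal plan is an ordered list of items, each with an ingredient name, an
optional household-measure quantity (cups, slices, ...), a portion mass in
grams, and free-text details.  Plans travel between stages as a single HTML
``<table>`` with the columns ``Ingredient``, ``Ingredient Details``,
``Quantity`` and ``Portion Size (g, dL)``; :func:`parse_meal_plan` and
:func:`write_meal_plan` are exact inverses on valid plans.

Liquid portions stated in dL or mL are converted to grams assuming a density
of 1 g/mL unless a per-ingredient density is supplied.  Bare numbers with no
unit are read as grams (with a warning) because model output drifts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from lxml import html as lxml_html

logger = logging.getLogger(__name__)

__all__ = [
    "Unit",
    "Quantity",
    "MealItem",
    "MealPlan",
    "MealType",
    "ParsedPlan",
    "MealPlanFormatError",
    "MealPlanSchemaError",
    "QuantityParseError",
    "parse_quantity",
    "parse_meal_plan",
    "write_meal_plan",
    "normalize_name",
    "unique_ingredient_names",
]

COLUMNS = ("Ingredient", "Ingredient Details", "Quantity", "Portion Size (g, dL)")


class MealPlanFormatError(ValueError):
    """No usable ``<table>`` was found in the input text."""


class MealPlanSchemaError(ValueError):
    """The table is missing a required column."""


class QuantityParseError(ValueError):
    """A quantity string had no numeric magnitude."""


class Unit(str, Enum):
    GRAM = "g"
    DECILITER = "dL"
    MILLILITER = "mL"
    CUP = "cup"
    SLICE = "slice"
    PIECE = "piece"

    @property
    def mass_convertible(self) -> bool:
        """True for units a density converts straight to grams."""
        return self in (Unit.GRAM, Unit.DECILITER, Unit.MILLILITER)


class MealType(str, Enum):
    BREAKFAST = "breakfast"
    LUNCH = "lunch"
    DINNER = "dinner"


_UNIT_ALIASES = {
    "g": Unit.GRAM,
    "gram": Unit.GRAM,
    "grams": Unit.GRAM,
    "dl": Unit.DECILITER,
    "ml": Unit.MILLILITER,
    "cup": Unit.CUP,
    "cups": Unit.CUP,
    "slice": Unit.SLICE,
    "slices": Unit.SLICE,
    "piece": Unit.PIECE,
    "pieces": Unit.PIECE,
}

# grams per one unit at density 1 g/mL
_MASS_FACTORS = {Unit.GRAM: 1.0, Unit.MILLILITER: 1.0, Unit.DECILITER: 100.0}


@dataclass(frozen=True)
class Quantity:
    """A magnitude with a unit from the closed household/mass set."""

    magnitude: float
    unit: Unit

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError(f"quantity magnitude must be >= 0, got {self.magnitude}")

    def mass_g(self, density_g_per_ml: float = 1.0) -> float:
        """Convert to grams; only mass-convertible units are accepted."""
        if self.unit not in _MASS_FACTORS:
            raise ValueError(f"unit {self.unit.value!r} is not mass-convertible")
        factor = _MASS_FACTORS[self.unit]
        if self.unit is Unit.GRAM:
            return self.magnitude
        return self.magnitude * factor * density_g_per_ml


@dataclass(frozen=True)
class MealItem:
    name: str
    portion_mass_g: float
    quantity: Quantity | None = None
    details: str = ""

    def __post_init__(self) -> None:
        if not self.name.strip():
            raise ValueError("meal item name must be non-empty")
        if self.portion_mass_g < 0:
            raise ValueError("portion_mass_g must be >= 0")


@dataclass(frozen=True)
class MealPlan:
    meal_type: MealType
    items: tuple[MealItem, ...]
    plan_id: str = ""

    def ingredient_names(self) -> tuple[str, ...]:
        return tuple(item.name for item in self.items)


@dataclass(frozen=True)
class ParsedPlan:
    """A parse result: the plan plus any rows that could not be parsed.

    Unparseable rows are reported, never silently dropped, so row counts are
    conserved: data rows in == items out + unparseable rows.
    """

    plan: MealPlan
    unparseable_rows: tuple[tuple[int, str], ...] = ()


_QUANTITY_RE = re.compile(r"^\s*([0-9]+(?:\.[0-9]+)?)\s*([A-Za-z]*)\s*$")


def parse_quantity(text: str) -> Quantity:
    """Parse strings like ``"50 g"``, ``"2 dL"`` or ``"3 slices"``.

    A bare number is read as grams with a logged warning.  The decimal
    separator is always the dot, independent of locale.
    """
    if not text or not text.strip():
        raise QuantityParseError("empty quantity string")
    m = _QUANTITY_RE.match(text)
    if m is None:
        raise QuantityParseError(f"cannot parse quantity {text!r}")
    magnitude = float(m.group(1))
    unit_text = m.group(2)
    if not unit_text:
        logger.warning("bare numeric quantity %r read as grams", text)
        return Quantity(magnitude, Unit.GRAM)
    unit = _UNIT_ALIASES.get(unit_text.lower())
    if unit is None:
        raise QuantityParseError(f"unknown unit {unit_text!r} in {text!r}")
    return Quantity(magnitude, unit)


def normalize_name(name: str) -> str:
    """Canonical ingredient-name key: trim, collapse whitespace, casefold.

    Parenthetical qualifiers are kept: variants such as
    'Mixed Greens Salad (with lemon vinaigrette)' stay distinct.
    """
    return re.sub(r"\s+", " ", name.strip()).casefold()


def unique_ingredient_names(names: Iterable[str]) -> list[str]:
    """De-duplicate ingredient names under :func:`normalize_name`.

    Returns the distinct names in first-seen order (original spelling of the
    first occurrence).
    """
    seen: dict[str, str] = {}
    for name in names:
        key = normalize_name(name)
        if key not in seen:
            seen[key] = re.sub(r"\s+", " ", name.strip())
    return list(seen.values())


def _header_role(text: str) -> str | None:
    t = normalize_name(text)
    if "portion" in t:
        return "portion"
    if "detail" in t:
        return "details"
    if "quantity" in t:
        return "quantity"
    if "ingredient" in t:
        return "name"
    return None


def parse_meal_plan(
    html_text: str,
    meal_type: MealType | str = MealType.LUNCH,
    plan_id: str = "",
    densities_g_per_ml: Mapping[str, float] | None = None,
) -> ParsedPlan:
    """Parse the first ``<table>`` in *html_text* into a :class:`MealPlan`.

    The header row must name at least an Ingredient column and a Portion Size
    column.  dL/mL portions are converted to grams with density 1 g/mL unless
    ``densities_g_per_ml`` (keyed by normalized ingredient name) overrides it.
    Rows that fail to parse are collected in ``unparseable_rows``.
    """
    meal_type = MealType(meal_type)
    try:
        doc = lxml_html.fromstring(html_text)
    except Exception as exc:  # lxml raises several parse errors
        raise MealPlanFormatError(f"input is not parseable HTML: {exc}") from exc
    tables = doc.xpath("//table")
    if not tables:
        raise MealPlanFormatError("no <table> element found")
    if len(tables) > 1:
        logger.warning("multiple tables found; using the first, ignoring %d", len(tables) - 1)
    table = tables[0]

    rows = table.xpath(".//tr")
    if not rows:
        raise MealPlanSchemaError("table has no rows")
    header_cells = rows[0].xpath("./th|./td")
    col_roles: dict[int, str] = {}
    for i, cell in enumerate(header_cells):
        role = _header_role(cell.text_content())
        if role is not None and role not in col_roles.values():
            col_roles[i] = role
    roles = set(col_roles.values())
    if "name" not in roles or "portion" not in roles:
        raise MealPlanSchemaError(
            f"required columns missing: need Ingredient and Portion Size, found {sorted(roles)}"
        )

    items: list[MealItem] = []
    bad_rows: list[tuple[int, str]] = []
    for row_idx, row in enumerate(rows[1:], start=1):
        cells = row.xpath("./td|./th")
        if not cells:
            continue
        fields = {role: cells[i].text_content().strip() for i, role in col_roles.items() if i < len(cells)}
        name = fields.get("name", "")
        portion_text = fields.get("portion", "")
        try:
            if not name.strip():
                raise ValueError("empty ingredient name")
            portion_q = parse_quantity(portion_text)
            density = 1.0
            if densities_g_per_ml:
                density = densities_g_per_ml.get(normalize_name(name), 1.0)
            mass = portion_q.mass_g(density)
            quantity = None
            qtext = fields.get("quantity", "")
            if qtext:
                try:
                    quantity = parse_quantity(qtext)
                except QuantityParseError:
                    quantity = None  # household measure is optional metadata
            items.append(
                MealItem(
                    name=re.sub(r"\s+", " ", name.strip()),
                    portion_mass_g=mass,
                    quantity=quantity,
                    details=fields.get("details", ""),
                )
            )
        except (QuantityParseError, ValueError) as exc:
            logger.warning("row %d unparseable: %s", row_idx, exc)
            bad_rows.append((row_idx, str(exc)))
    plan = MealPlan(meal_type=meal_type, items=tuple(items), plan_id=plan_id)
    return ParsedPlan(plan=plan, unparseable_rows=tuple(bad_rows))


def _format_quantity(q: Quantity | None) -> str:
    if q is None:
        return ""
    mag = f"{q.magnitude:g}"
    return f"{mag} {q.unit.value}"


def _escape(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    )


def write_meal_plan(plan: MealPlan) -> str:
    """Serialize a plan to the table dialect :func:`parse_meal_plan` accepts.

    Output is deterministic and preserves item order; portion masses are
    written in grams.
    """
    lines = ["<table>", "  <tr>" + "".join(f"<th>{_escape(c)}</th>" for c in COLUMNS) + "</tr>"]
    for item in plan.items:
        cells = (
            item.name,
            item.details,
            _format_quantity(item.quantity),
            f"{item.portion_mass_g:g} g",
        )
        lines.append("  <tr>" + "".join(f"<td>{_escape(c)}</td>" for c in cells) + "</tr>")
    lines.append("</table>")
    return "\n".join(lines)
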