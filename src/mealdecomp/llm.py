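"""Language-model backend contract, prompt templates, and response parsing.

Three prompt-driven steps shape the pipeline: meal generation, compound
ingredient decomposition, and mapping a basic ingredient to a food-record id.
Each step's response carries its payload between dollar-sign delimiters
(``$Content$``); the decomposition payload is a dictionary of dictionaries in
a loose quoted-pair style that is not valid JSON, so a small tolerant parser
handles both that style and strict JSON-like text.

Backends are a contract — send prompt text, receive text — so live adapters
for any provider can plug in without touching the pipeline.  The repository
ships and tests only :class:`MockBackend`, a deterministic offline stand-in
driven by structured context from the synthetic-data generator.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from typing import Any, Mapping, Protocol, Sequence

import numpy as np

from .meal_plans import QuantityParseError, normalize_name, parse_quantity

logger = logging.getLogger(__name__)

__all__ = [
    "PROMPT_TEMPLATES",
    "Decomposition",
    "BackendResponse",
    "Backend",
    "MockBackend",
    "TemplateError",
    "PayloadExtractionError",
    "DecompositionParseError",
    "render_prompt",
    "extract_delimited_payload",
    "parse_decomposition_payload",
    "parse_fdcid_payload",
    "format_decompositions",
    "ask_with_retry",
]


class TemplateError(KeyError):
    """A placeholder in the template has no binding."""


class PayloadExtractionError(ValueError):
    """No complete ``$...$`` span was found in a backend response."""


class DecompositionParseError(ValueError):
    """The decomposition payload is not a readable dictionary of dictionaries."""


PROMPT_TEMPLATES: dict[str, str] = {
    "meal_generation": (
        "Create a detailed one-day <INPUT_meal_type> plan. Ensure the meal plan "
        "includes precise portion sizes, specific quantities or weights of "
        "individual ingredients, and diverse cooking methods. Include compound "
        "ingredients like Chicken Cacciatore, Vegetable Ratatouille, or similar. "
        "However, avoid including ingredients included in the following list: "
        "<INPUT_list>, Structure the results in a formatted HTML format similar "
        "to the provided example: <INPUT_html_format>."
    ),
    "decomposition": (
        "Analyze the meal plan provided in an HTML table (enclosed within "
        "<table> and </table> tags): <INPUT_meal_plan>. Identify compound "
        "ingredients listed under the ‘Ingredient’ column that consist of multiple "
        "basic ingredients. Use the ‘Ingredient Details’ column for additional "
        "information. For each identified compound ingredient, report the names "
        "of these items along with their specific ingredients and estimated "
        "quantities based on the ‘Portion Size (g, dL)’ column, formatted in a "
        "dictionary of dictionaries. Ensure all ingredients are specific (e.g., "
        "‘carrots’, ‘spinach’, etc., instead of ‘vegetables’). If items can be "
        "further broken down, do it. Example format: ‘Complex Food Item 1’: "
        "‘Ingredient 1’: ‘50 g’, ‘Ingredient 2’: ‘100 g’, “Complex Food Item 2”: "
        "‘Ingredient 1’: ‘200 g’, ‘Ingredient 2’: ‘150 g’. Return only the "
        "formatted dictionary encapsulated by dollar signs ($Content$). "
        "Dictionary should not contain any comments. If no complex food items "
        "meeting the criteria are identified, return an empty dictionary. Ensure "
        "that the quantities of each ingredient accurately reflect the specified "
        "portion size within each compound ingredient as detailed in the meal "
        "plan. For ingredients where the exact quantity cannot be determined, "
        "provide a reasonable estimate instead of leaving it unspecified."
    ),
    "mapping": (
        "You are tasked with matching a given ingredient <food_item> to the most "
        "appropriate one from the following list of ingredients: "
        "<list_of_food_items>. Each ingredient possesses unique characteristics "
        "that influence its compatibility with others. Your objective is to "
        "identify which ingredient from the list best complements the given one, "
        "considering factors such as flavor profile, cooking methods, and "
        "culinary traditions. Return only the ‘fdcId’ value of the best match "
        "encapsulated in dollar signs (e.g., $21341$). Do not include any "
        "comments."
    ),
}

_PLACEHOLDER_RE = re.compile(
    r"<(INPUT_meal_type|INPUT_list|INPUT_html_format|INPUT_meal_plan|food_item|list_of_food_items)>"
)


def render_prompt(template_id: str, bindings: Mapping[str, Any]) -> str:
    """Substitute every placeholder of a template with its binding.

    Sequence bindings (the meal-generation exclusion list, the mapping
    candidate list) render as comma-separated text; an empty list renders as
    the empty string.  A placeholder with no binding raises
    :class:`TemplateError`.
    """
    template = PROMPT_TEMPLATES[template_id]

    def _sub(match: re.Match[str]) -> str:
        key = match.group(1)
        if key not in bindings:
            raise TemplateError(f"missing binding for placeholder <{key}> in {template_id!r}")
        value = bindings[key]
        if isinstance(value, str):
            return value
        if isinstance(value, (list, tuple)):
            return ", ".join(str(v) for v in value)
        return str(value)

    return _PLACEHOLDER_RE.sub(_sub, template)


@dataclass(frozen=True)
class Decomposition:
    """One compound ingredient's breakdown into basic-ingredient masses (g).

    Part names are normalized (trimmed, whitespace-collapsed, casefolded);
    all masses are strictly positive and the map is non-empty.
    """

    compound_name: str
    parts: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.parts:
            raise ValueError(f"decomposition of {self.compound_name!r} has no parts")
        for name, mass in self.parts.items():
            if mass <= 0:
                raise ValueError(f"part {name!r} of {self.compound_name!r} has non-positive mass {mass}")

    @property
    def total_mass_g(self) -> float:
        return float(sum(self.parts.values()))


@dataclass(frozen=True)
class BackendResponse:
    raw_text: str
    payload: str | None = None


class Backend(Protocol):
    """Contract every backend adapter satisfies: prompt text in, text out."""

    name: str

    def complete(self, prompt_text: str, context: Mapping[str, Any] | None = None) -> str: ...


_DOLLAR_SPAN_RE = re.compile(r"\$([^$]*)\$")


def extract_delimited_payload(raw: str, step: str = "response") -> str:
    """Return the content of the first complete ``$...$`` span.

    Surrounding commentary is discarded.  Zero or unbalanced delimiters raise
    :class:`PayloadExtractionError` naming the pipeline step.
    """
    m = _DOLLAR_SPAN_RE.search(raw)
    if m is None:
        raise PayloadExtractionError(f"{step}: no complete $...$ span in response")
    return m.group(1)


# --- decomposition payload grammar -----------------------------------------
# Accepts both strict JSON-like text and the loose quoted-pair style
#   'Compound 1': 'Ing 1': '50 g', 'Ing 2': '100 g', 'Compound 2': ...
# Curly quotes are normalized to straight quotes before tokenizing.

_QUOTE_MAP = str.maketrans({"‘": "'", "’": "'", "“": '"', "”": '"'})

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<lbrace>\{) | (?P<rbrace>\}) | (?P<colon>:) | (?P<comma>,)
      | '(?P<sq>[^']*)' | "(?P<dq>[^"]*)"
      | (?P<atom>[^{}:,\s'"][^{}:,'"]*)
    )""",
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise DecompositionParseError(f"unreadable text at offset {pos}: {text[pos:pos + 20]!r}")
            break
        pos = m.end()
        kind = m.lastgroup
        if kind in ("sq", "dq", "atom"):
            tokens.append(("str", (m.group(kind) or "").strip()))
        elif kind is not None:
            tokens.append((kind, m.group(0).strip()))
    return tokens


def _parse_braced(tokens: list[tuple[str, str]], i: int) -> tuple[Any, int]:
    kind, val = tokens[i]
    if kind == "str":
        return val, i + 1
    if kind != "lbrace":
        raise DecompositionParseError(f"expected value, got {val!r}")
    i += 1
    out: dict[str, Any] = {}
    if i < len(tokens) and tokens[i][0] == "rbrace":
        return out, i + 1
    while True:
        if i >= len(tokens) or tokens[i][0] != "str":
            raise DecompositionParseError("expected a quoted key")
        key = tokens[i][1]
        if i + 1 >= len(tokens) or tokens[i + 1][0] != "colon":
            raise DecompositionParseError(f"expected ':' after key {key!r}")
        value, i = _parse_braced(tokens, i + 2)
        out[key] = value
        if i >= len(tokens):
            raise DecompositionParseError("unterminated dictionary")
        if tokens[i][0] == "comma":
            i += 1
            continue
        if tokens[i][0] == "rbrace":
            return out, i + 1
        raise DecompositionParseError(f"expected ',' or '}}', got {tokens[i][1]!r}")


def _parse_flat(tokens: list[tuple[str, str]]) -> dict[str, dict[str, str]]:
    """Parse the brace-less paper style via one-token lookahead.

    ``'X': 'Y'`` where the token after ``'Y'`` is a colon means ``'X'`` opens
    a new compound and ``'Y'`` is its first ingredient key; otherwise ``'Y'``
    is a quantity string belonging to the current compound.
    """
    out: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    i = 0
    n = len(tokens)
    while i < n:
        if tokens[i][0] == "comma":
            i += 1
            continue
        if tokens[i][0] != "str" or i + 1 >= n or tokens[i + 1][0] != "colon":
            raise DecompositionParseError(f"expected \"'key':\" at token {i}")
        key = tokens[i][1]
        if i + 2 >= n or tokens[i + 2][0] != "str":
            raise DecompositionParseError(f"expected a value after key {key!r}")
        follows_colon = i + 3 < n and tokens[i + 3][0] == "colon"
        if follows_colon:
            current = out.setdefault(key, {})
            i += 2
        else:
            if current is None:
                raise DecompositionParseError(f"ingredient pair {key!r} appears before any compound name")
            current[key] = tokens[i + 2][1]
            i += 3
    return out


def parse_decomposition_payload(payload: str) -> list[Decomposition]:
    """Parse an extracted decomposition payload into :class:`Decomposition` rows.

    An empty dictionary (``{}`` or blank text) yields an empty list.  Either
    the parse succeeds completely or a typed error is raised — never a
    partially filled structure.
    """
    text = payload.translate(_QUOTE_MAP).strip()
    if not text or text == "{}":
        return []
    tokens = _tokenize(text)
    if not tokens:
        return []
    if tokens[0][0] == "lbrace":
        tree, end = _parse_braced(tokens, 0)
        if end != len(tokens):
            raise DecompositionParseError("trailing text after dictionary")
        if not isinstance(tree, dict):
            raise DecompositionParseError("payload is not a dictionary")
    else:
        tree = _parse_flat(tokens)

    result: list[Decomposition] = []
    for compound, parts in tree.items():
        if not isinstance(parts, dict):
            raise DecompositionParseError(f"value of {compound!r} is not a dictionary")
        masses: dict[str, float] = {}
        for name, qty_text in parts.items():
            if not isinstance(qty_text, str):
                raise DecompositionParseError(f"quantity of {name!r} is not text")
            try:
                qty = parse_quantity(qty_text)
            except QuantityParseError as exc:
                raise DecompositionParseError(str(exc)) from exc
            mass = qty.mass_g()
            if mass <= 0:
                raise ValueError(f"part {name!r} of {compound!r} has non-positive mass {mass}")
            masses[normalize_name(name)] = mass
        result.append(Decomposition(compound_name=re.sub(r"\s+", " ", compound.strip()), parts=masses))
    return result


def format_decompositions(decompositions: Sequence[Decomposition]) -> str:
    """Serialize decompositions to the quoted-pair payload style."""
    if not decompositions:
        return "{}"
    chunks = []
    for d in decompositions:
        pairs = ", ".join(f"'{name}': '{mass:g} g'" for name, mass in d.parts.items())
        chunks.append(f"'{d.compound_name}': {pairs}")
    return ", ".join(chunks)


def parse_fdcid_payload(payload: str) -> int:
    """Parse a food-record identifier; whitespace tolerated."""
    text = payload.strip()
    if not re.fullmatch(r"[0-9]+", text):
        raise ValueError(f"fdcId payload is not numeric: {payload!r}")
    return int(text)


class MockBackend:
    """Deterministic offline backend driven by structured context.

    The response to a request depends only on the rendered prompt, the
    context, and the seed, so whole pipeline runs are byte-reproducible.
    ``malformed_rate`` injects responses without delimiters at the stated
    rate, for parser-robustness tests.
    """

    def __init__(self, name: str = "mock", seed: int = 0, malformed_rate: float = 0.0) -> None:
        if not 0.0 <= malformed_rate <= 1.0:
            raise ValueError("malformed_rate must be in [0, 1]")
        self.name = name
        self.seed = seed
        self.malformed_rate = malformed_rate
        self.request_log: list[dict[str, str]] = []

    def _rng(self, prompt_text: str) -> np.random.Generator:
        digest = hashlib.sha256(f"{self.name}|{self.seed}|{prompt_text}".encode()).digest()
        return np.random.default_rng(int.from_bytes(digest[:8], "big"))

    def complete(self, prompt_text: str, context: Mapping[str, Any] | None = None) -> str:
        context = context or {}
        rng = self._rng(prompt_text)
        task = context.get("task", "echo")
        if task == "decomposition":
            payload = format_decompositions(context["decompositions"])
        elif task == "mapping":
            payload = str(context["fdc_id"])
        elif task == "meal_generation":
            payload = context["html"]
        else:
            payload = context.get("payload", "")
        if rng.random() < self.malformed_rate:
            response = f"I could not format that as requested. {payload}"
        else:
            response = f"${payload}$"
        self.request_log.append({"prompt": prompt_text, "response": response})
        return response


def ask_with_retry(
    backend: Backend,
    prompt_text: str,
    context: Mapping[str, Any] | None = None,
    step: str = "response",
) -> str:
    """Send a prompt; on a malformed response, re-ask once, then fail.

    Returns the extracted payload.  Two consecutive extraction failures
    propagate :class:`PayloadExtractionError` for the caller to log and skip.
    """
    raw = backend.complete(prompt_text, context)
    try:
        return extract_delimited_payload(raw, step)
    except PayloadExtractionError:
        logger.warning("%s: malformed response from %s, re-asking once", step, backend.name)
        raw = backend.complete(prompt_text + " ", context)
        return extract_delimited_payload(raw, step)
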