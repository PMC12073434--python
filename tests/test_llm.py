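"""Prompt rendering, delimited-payload extraction, and response parsing."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mealdecomp.llm import (
    PROMPT_TEMPLATES,
    Decomposition,
    DecompositionParseError,
    MockBackend,
    PayloadExtractionError,
    TemplateError,
    ask_with_retry,
    extract_delimited_payload,
    format_decompositions,
    parse_decomposition_payload,
    parse_fdcid_payload,
    render_prompt,
)
from mealdecomp.meal_plans import MealItem, MealPlan, MealType, write_meal_plan

PLACEHOLDERS = {
    "meal_generation": {"INPUT_meal_type", "INPUT_list", "INPUT_html_format"},
    "decomposition": {"INPUT_meal_plan"},
    "mapping": {"food_item", "list_of_food_items"},
}


class TestTemplates:
    @pytest.mark.parametrize("template_id", sorted(PROMPT_TEMPLATES))
    def test_each_template_contains_exactly_its_placeholders(self, template_id):
        text = PROMPT_TEMPLATES[template_id]
        for ph in PLACEHOLDERS[template_id]:
            assert f"<{ph}>" in text
        for other_id, others in PLACEHOLDERS.items():
            if other_id != template_id:
                for ph in others - PLACEHOLDERS[template_id]:
                    assert f"<{ph}>" not in text

    def test_delimiter_convention_is_stated_in_templates(self):
        assert "$Content$" in PROMPT_TEMPLATES["decomposition"]
        assert "$21341$" in PROMPT_TEMPLATES["mapping"]


class TestRenderPrompt:
    def test_meal_generation_substitution_complete(self):
        text = render_prompt(
            "meal_generation",
            {"INPUT_meal_type": "breakfast", "INPUT_list": [], "INPUT_html_format": "<table></table>"},
        )
        assert "breakfast" in text
        assert "<INPUT" not in text

    def test_exclusion_list_renders_comma_separated(self):
        text = render_prompt(
            "meal_generation",
            {"INPUT_meal_type": "lunch", "INPUT_list": ["hummus", "oats"], "INPUT_html_format": ""},
        )
        assert "hummus, oats" in text

    def test_mapping_lists_all_candidate_descriptions(self):
        candidates = ["101: Blueberries, raw", "102: Blueberries, frozen"]
        text = render_prompt("mapping", {"food_item": "blueberries", "list_of_food_items": candidates})
        for c in candidates:
            assert c in text

    def test_decomposition_embeds_plan_html(self):
        plan = MealPlan(MealType.LUNCH, (MealItem("Hummus", 100.0),), "p")
        html = write_meal_plan(plan)
        text = render_prompt("decomposition", {"INPUT_meal_plan": html})
        assert html in text
        assert "<INPUT_meal_plan>" not in text

    def test_missing_binding_raises(self):
        with pytest.raises(TemplateError):
            render_prompt("mapping", {"food_item": "salt"})


class TestExtractPayload:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("$21341$", "21341"),
            ("Sure! $x$ hope this helps", "x"),
            ("$first$ and $second$", "first"),
            ("$$", ""),
        ],
    )
    def test_first_span_extracted(self, raw, expected):
        assert extract_delimited_payload(raw) == expected

    @pytest.mark.parametrize("raw", ["no delimiters here", "unbalanced $ here", ""])
    def test_missing_delimiters_raise_named_error(self, raw):
        with pytest.raises(PayloadExtractionError, match="mapping step"):
            extract_delimited_payload(raw, step="mapping step")

    @settings(max_examples=50, deadline=None)
    @given(payload=st.text(alphabet=st.characters(blacklist_characters="$"), min_size=1))
    def test_extraction_idempotent_on_extracted_payloads(self, payload):
        extracted = extract_delimited_payload(f"chatter ${payload}$ more")
        assert extracted == payload
        # an already-extracted payload has no delimiters left to extract
        with pytest.raises(PayloadExtractionError):
            extract_delimited_payload(extracted)


PAPER_STYLE = (
    "‘Complex Food Item 1’: ‘Ingredient 1’: ‘50 g’, ‘Ingredient 2’: ‘100 g’, "
    "“Complex Food Item 2”: ‘Ingredient 1’: ‘200 g’, ‘Ingredient 2’: ‘150 g’"
)


class TestParseDecomposition:
    def test_quoted_pair_style(self):
        decs = parse_decomposition_payload(PAPER_STYLE)
        assert [d.compound_name for d in decs] == ["Complex Food Item 1", "Complex Food Item 2"]
        assert decs[0].parts == {"ingredient 1": 50.0, "ingredient 2": 100.0}
        assert decs[1].parts == {"ingredient 1": 200.0, "ingredient 2": 150.0}

    @pytest.mark.parametrize("empty", ["{}", "", "   "])
    def test_empty_dictionary(self, empty):
        assert parse_decomposition_payload(empty) == []

    def test_mixed_quote_styles_equal_canonical(self):
        canonical = "{'A': {'x': '50 g', 'y': '100 g'}}"
        variants = [
            '{"A": {"x": "50 g", "y": "100 g"}}',
            "‘A’: ‘x’: ‘50 g’, ‘y’: ‘100 g’",
            "“A”: “x”: “50 g”, ‘y’: ‘100 g’",
        ]
        expected = parse_decomposition_payload(canonical)
        for v in variants:
            assert parse_decomposition_payload(v) == expected

    def test_deciliter_quantities_convert(self):
        decs = parse_decomposition_payload("'Soup': 'broth': '2 dL', 'salt': '1 g'")
        assert decs[0].parts["broth"] == 200.0

    @pytest.mark.parametrize(
        "bad",
        [
            "'A': 'x'",               # ingredient pair before any compound
            "'A': {'x': }",           # missing value
            "'A': {'x': '50 g'",      # unterminated
            "'A': 'x': 'heavy'",      # non-numeric quantity
            "junk : : :",
        ],
    )
    def test_invalid_payloads_raise_typed_error(self, bad):
        with pytest.raises((DecompositionParseError, ValueError)):
            parse_decomposition_payload(bad)

    def test_non_positive_mass_is_value_error(self):
        with pytest.raises(ValueError):
            parse_decomposition_payload("'A': 'x': '0 g'")

    def test_round_trip_through_formatter(self):
        decs = [
            Decomposition("Hummus", {"chickpeas": 60.0, "tahini": 15.0}),
            Decomposition("Fruit Salad", {"apples": 50.0}),
        ]
        assert parse_decomposition_payload(format_decompositions(decs)) == decs


class TestParseFdcId:
    @pytest.mark.parametrize("payload, expected", [("21341", 21341), (" 7 ", 7), ("0042", 42)])
    def test_numeric(self, payload, expected):
        assert parse_fdcid_payload(payload) == expected

    @pytest.mark.parametrize("bad", ["abc", "12.5", "-3", "12 34", ""])
    def test_non_numeric_raises(self, bad):
        with pytest.raises(ValueError):
            parse_fdcid_payload(bad)


class TestMockBackend:
    def test_same_request_and_seed_byte_identical(self):
        ctx = {"task": "mapping", "fdc_id": 101}
        r1 = MockBackend(seed=5).complete("map it", ctx)
        r2 = MockBackend(seed=5).complete("map it", ctx)
        assert r1 == r2

    def test_different_seeds_may_differ_but_stay_well_formed(self):
        ctx = {"task": "mapping", "fdc_id": 101}
        for seed in range(5):
            raw = MockBackend(seed=seed).complete("map it", ctx)
            assert extract_delimited_payload(raw) == "101"

    def test_malformed_rate_zero_always_extractable(self):
        backend = MockBackend(seed=1, malformed_rate=0.0)
        for i in range(20):
            raw = backend.complete(f"prompt {i}", {"task": "mapping", "fdc_id": i + 1})
            assert extract_delimited_payload(raw) == str(i + 1)

    def test_malformed_rate_one_always_fails_extraction(self):
        backend = MockBackend(seed=1, malformed_rate=1.0)
        for i in range(20):
            raw = backend.complete(f"prompt {i}", {"task": "mapping", "fdc_id": i + 1})
            with pytest.raises(PayloadExtractionError):
                extract_delimited_payload(raw)

    def test_retry_fails_after_two_malformed_responses(self):
        backend = MockBackend(seed=1, malformed_rate=1.0)
        with pytest.raises(PayloadExtractionError):
            ask_with_retry(backend, "prompt", {"task": "mapping", "fdc_id": 9})
        assert len(backend.request_log) == 2
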