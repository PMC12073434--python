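import pytest

from mealdecomp.fooddata import FoodStore
from mealdecomp.meal_plans import MealItem, MealPlan, MealType, Quantity, Unit


@pytest.fixture
def six_record_store() -> FoodStore:
    """Tiny store with a known tier layout for 'blueberries' queries."""
    return FoodStore.from_records(
        [
            {"fdcId": 1, "description": "Blueberries, raw", "dataType": "SR Legacy",
             "nutrients": {"protein": 0.7, "carbohydrate": 14.5}},
            {"fdcId": 2, "description": "Blueberries, frozen", "dataType": "Foundation",
             "nutrients": {"protein": 0.4, "carbohydrate": 12.2}},
            {"fdcId": 3, "description": "Blueberries, dried", "dataType": "SR Legacy",
             "nutrients": {"protein": 2.5, "carbohydrate": 80.0}},
            {"fdcId": 4, "description": "Blueberries, canned", "dataType": "FNDDS",
             "nutrients": {"protein": 0.6, "carbohydrate": 15.0}},
            {"fdcId": 5, "description": "Blueberries muffin mix", "dataType": "Branded",
             "nutrients": {"protein": 4.0, "carbohydrate": 70.0}},
            {"fdcId": 6, "description": "Chicken breast, raw", "dataType": "Foundation",
             "nutrients": {"protein": 22.5, "fat": 2.6}},
        ]
    )


@pytest.fixture
def one_row_plan() -> MealPlan:
    return MealPlan(
        meal_type=MealType.DINNER,
        items=(MealItem(name="Chicken Marsala", portion_mass_g=200.0),),
        plan_id="fixture-1",
    )


@pytest.fixture
def four_item_plan() -> MealPlan:
    return MealPlan(
        meal_type=MealType.BREAKFAST,
        items=(
            MealItem(name="Scrambled Eggs", portion_mass_g=150.0,
                     quantity=Quantity(1, Unit.CUP), details="with chives"),
            MealItem(name="whole wheat bread", portion_mass_g=58.0,
                     quantity=Quantity(2, Unit.SLICE)),
            MealItem(name="Milk (or plant-based milk)", portion_mass_g=200.0,
                     quantity=Quantity(2, Unit.DECILITER)),
            MealItem(name="blueberries", portion_mass_g=80.0),
        ),
        plan_id="fixture-4",
    )
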