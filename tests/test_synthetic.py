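"""Synthetic generator: determinism, label prevalence, error models, store."""

import numpy as np
import pytest
from scipy.stats import binom

from mealdecomp.fooddata import SubsetPolicy, build_subset
from mealdecomp.massmetrics import classify_mass, flag_overestimation
from mealdecomp.meal_plans import normalize_name
from mealdecomp.stats import ConfusionCounts, metrics_from_confusion
from mealdecomp.synthetic import (
    BASIC_LEXICON,
    COMPOUND_LEXICON,
    MassErrorModel,
    SimulationConfig,
    expected_accuracy,
    expected_f1_exact,
    generate_food_store,
    generate_plan_set,
    simulate_predictions,
)


def _config(**kwargs):
    defaults = dict(seed=7, n_plans=15, ingredients_per_plan=(5, 9), compound_prevalence=0.32)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestGeneratePlanSet:
    def test_deterministic_per_seed(self):
        a = generate_plan_set(_config())
        b = generate_plan_set(_config())
        assert a == b

    def test_different_seeds_differ(self):
        assert generate_plan_set(_config(seed=1)) != generate_plan_set(_config(seed=2))

    def test_realized_prevalence_within_binomial_bounds(self):
        config = _config(n_plans=15, seed=7)
        plan_set = generate_plan_set(config)
        n_items = sum(len(p.items) for p in plan_set.plans)
        n_compound = sum(
            1 for t in plan_set.truth.values() for lab in t.labels.values() if lab == "compound"
        )
        lo, hi = binom.ppf([0.005, 0.995], n_items, 0.32)
        assert lo <= n_compound <= hi

    def test_zero_prevalence_all_basic(self):
        plan_set = generate_plan_set(_config(compound_prevalence=0.0))
        labels = [lab for t in plan_set.truth.values() for lab in t.labels.values()]
        assert set(labels) == {"basic"}
        assert all(not d for d in plan_set.true_decompositions.values())

    def test_true_decompositions_conserve_mass_exactly(self):
        plan_set = generate_plan_set(_config(compound_prevalence=0.8))
        checked = 0
        for plan in plan_set.plans:
            portions = {normalize_name(i.name): i.portion_mass_g for i in plan.items}
            for dec in plan_set.true_decompositions[plan.plan_id]:
                assert dec.total_mass_g == portions[normalize_name(dec.compound_name)]
                checked += 1
        assert checked > 0

    def test_compound_names_come_from_lexicon(self):
        plan_set = generate_plan_set(_config(compound_prevalence=0.5))
        known = {normalize_name(n) for n in COMPOUND_LEXICON}
        for t in plan_set.truth.values():
            for name, lab in t.labels.items():
                if lab == "compound":
                    assert name in known

    def test_impossible_config_rejected(self):
        with pytest.raises(ValueError):
            _config(ingredients_per_plan=(5, len(COMPOUND_LEXICON) + 1))


class TestSimulatePredictions:
    def test_perfect_model_reproduces_truth(self):
        plan_set = generate_plan_set(_config())
        preds = simulate_predictions(plan_set, _config(sensitivity=1.0, specificity=1.0))
        for plan in plan_set.plans:
            assert preds.predicted_compounds[plan.plan_id] == plan_set.compound_names(plan.plan_id)
            for dec in preds.decompositions[plan.plan_id]:
                portion = {normalize_name(i.name): i.portion_mass_g for i in plan.items}[
                    normalize_name(dec.compound_name)
                ]
                assert classify_mass(portion, dec.total_mass_g).category == "match"

    def test_zero_sensitivity_predicts_nothing_compound(self):
        plan_set = generate_plan_set(_config())
        preds = simulate_predictions(plan_set, _config(sensitivity=0.0, specificity=1.0))
        assert all(not s for s in preds.predicted_compounds.values())

    def test_systematic_overestimate_30pct_always_flagged(self):
        config = _config(
            sensitivity=1.0,
            specificity=1.0,
            mass_error=MassErrorModel(kind="systematic_overestimate", fraction=0.30),
        )
        plan_set = generate_plan_set(config)
        preds = simulate_predictions(plan_set, config)
        n = 0
        for plan in plan_set.plans:
            portions = {normalize_name(i.name): i.portion_mass_g for i in plan.items}
            for dec in preds.decompositions[plan.plan_id]:
                assert flag_overestimation(
                    portions[normalize_name(dec.compound_name)], dec.total_mass_g
                ).flagged
                n += 1
        assert n > 0

    def test_seasoning_probability_one_seasons_every_decomposition(self):
        config = _config(sensitivity=1.0, specificity=1.0, seasoning_inclusion_prob=1.0)
        preds = simulate_predictions(generate_plan_set(config), config)
        seasonings = {"salt", "black pepper", "sugar"}
        for decs in preds.decompositions.values():
            for d in decs:
                assert set(d.parts) & seasonings

    def test_deterministic_per_seed_and_model_name(self):
        plan_set = generate_plan_set(_config())
        a = simulate_predictions(plan_set, _config(), model_name="m1")
        b = simulate_predictions(plan_set, _config(), model_name="m1")
        c = simulate_predictions(plan_set, _config(), model_name="m2")
        assert a == b
        assert a.predicted_compounds != c.predicted_compounds or a.decompositions != c.decompositions


class TestGenerateFoodStore:
    def test_default_store_resolves_most_basics_in_tier1(self):
        store = generate_food_store(seed=0, fallback_fraction=0.1)
        policy = SubsetPolicy()
        tier1_hits = 0
        basics = sorted(set(BASIC_LEXICON))
        for name in basics:
            subset = build_subset(name, store, policy)
            assert subset, f"no record for {name!r}"
            if any(r.data_type in ("SR Legacy", "Foundation") for r in subset):
                tier1_hits += 1
        assert tier1_hits / len(basics) >= 0.85

    def test_fallback_fraction_one_forces_lower_tiers(self):
        store = generate_food_store(seed=0, fallback_fraction=1.0)
        for name in ("salt", "eggs", "milk"):
            subset = build_subset(name, store)
            assert subset
            assert all(r.data_type not in ("SR Legacy", "Foundation") for r in subset)

    def test_seeded_duplicate_descriptions_share_distinct_ids(self):
        store = generate_food_store(seed=0, duplicate_fraction=1.0)
        by_desc = {}
        for rec in store.records():
            by_desc.setdefault(rec.description, []).append(rec.fdc_id)
        dup_groups = [ids for ids in by_desc.values() if len(ids) > 1]
        assert dup_groups
        for ids in dup_groups:
            assert len(set(ids)) == len(ids)

    def test_profiles_on_100g_basis(self):
        store = generate_food_store(seed=3)
        rec = store.records()[0]
        assert store.nutrients(rec.fdc_id).basis_mass_g == 100.0


class TestAnalyticBaselines:
    def test_expected_accuracy_formula(self):
        assert expected_accuracy(0.9, 0.9, 0.32) == pytest.approx(0.9)
        assert expected_accuracy(1.0, 0.5, 0.25) == pytest.approx(0.25 + 0.75 * 0.5)

    def test_expected_f1_single_ingredient_closed_form(self):
        # with one ingredient per plan the conventions make E[F1] = pi*s + (1-pi)*q
        s, q, pi = 0.9, 0.8, 0.3
        assert expected_f1_exact(s, q, pi, 1) == pytest.approx(pi * s + (1 - pi) * q)

    def test_expected_f1_matches_monte_carlo(self):
        s, q, pi, n = 0.9, 0.9, 0.32, 10
        rng = np.random.default_rng(0)
        reps = 4000
        sims = np.empty(reps)
        for r in range(reps):
            c = rng.binomial(n, pi)
            tp = rng.binomial(c, s)
            fp = rng.binomial(n - c, 1 - q)
            sims[r] = metrics_from_confusion(
                ConfusionCounts(tp=tp, fp=fp, fn=c - tp, tn=n - c - fp)
            ).f1
        mc_se = sims.std(ddof=1) / np.sqrt(reps)
        assert abs(sims.mean() - expected_f1_exact(s, q, pi, n)) < 4 * mc_se
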