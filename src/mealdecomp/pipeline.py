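"""Seven-stage study orchestration with persisted, resumable intermediates.

Stages: plan generation → compound decomposition (via a backend) → candidate
subset creation → mapping to food records → nutrient retrieval/scaling →
aggregation → evaluation.  Every stage writes line-delimited JSON (plus the
meal-plan HTML and the fixture store) into the output directory before the
next stage runs, so a later stage can be re-run from persisted artifacts and
reproduces its outputs bit-for-bit.

Offline mode is the default and the only mode the test suite exercises: a
deterministic mock backend answers every prompt from the synthetic ground
truth, with per-model error rates injected by the simulation layer.  Live
mode is a configuration contract (API key, pacing) for users who wire real
adapters; it is opt-in and never required.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

from . import massmetrics, nutrients as nutrient_math, stats
from .fooddata import FoodStore, SubsetPolicy, build_subset, get_nutrients
from .llm import (
    Decomposition,
    MockBackend,
    PayloadExtractionError,
    ask_with_retry,
    parse_decomposition_payload,
    parse_fdcid_payload,
    render_prompt,
)
from .meal_plans import MealPlan, normalize_name, parse_meal_plan, write_meal_plan
from .stats import GroundTruthLabels
from .synthetic import (
    LabeledPlanSet,
    MassErrorModel,
    SimulationConfig,
    generate_food_store,
    generate_plan_set,
    simulate_predictions,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BackendSpec",
    "StudyConfig",
    "StudyReport",
    "ConfigError",
    "validate_config",
    "run_study",
    "stage_generate",
    "stage_decompose",
    "stage_map",
    "stage_nutrients",
    "stage_evaluate",
    "render_report_text",
]


class ConfigError(ValueError):
    """Raised with the complete list of configuration violations."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(errors))


@dataclass(frozen=True)
class BackendSpec:
    """One simulated model: its name and error profile."""

    name: str
    sensitivity: float = 0.9
    specificity: float = 0.9
    mass_error: MassErrorModel = field(default_factory=MassErrorModel)
    seasoning_inclusion_prob: float = 0.0
    malformed_rate: float = 0.0


@dataclass(frozen=True)
class StudyConfig:
    out_dir: str
    master_seed: int
    mode: str = "offline"
    backends: tuple[BackendSpec, ...] = (
        BackendSpec("model-a", 0.95, 0.95),
        BackendSpec("model-b", 0.90, 0.90),
        BackendSpec("model-c", 0.70, 0.85),
    )
    simulation: SimulationConfig | None = None
    epsilon_g: float = 0.5
    ci_level: float = 0.95
    alpha: float = 0.05
    fixture_store_path: str | None = None
    api_key: str | None = None
    subset_policy: SubsetPolicy = field(default_factory=SubsetPolicy)

    def sim(self) -> SimulationConfig:
        return self.simulation or SimulationConfig(seed=self.master_seed)


def validate_config(config: StudyConfig) -> StudyConfig:
    """Validate, reporting every violation at once; returns the config."""
    errors: list[str] = []
    if config.mode not in ("offline", "live"):
        errors.append(f"mode must be 'offline' or 'live', got {config.mode!r}")
    if config.mode == "live" and not config.api_key:
        errors.append("live mode requires an api_key setting")
    if not config.backends:
        errors.append("at least one backend must be configured")
    if len({b.name for b in config.backends}) != len(config.backends):
        errors.append("backend names must be unique")
    if config.epsilon_g < 0:
        errors.append("epsilon_g must be >= 0")
    if not 0 < config.ci_level < 1:
        errors.append("ci_level must be in (0, 1)")
    if not 0 < config.alpha < 1:
        errors.append("alpha must be in (0, 1)")
    if not config.out_dir:
        errors.append("out_dir must be set")
    if errors:
        raise ConfigError(errors)
    return config


@dataclass(frozen=True)
class StudyReport:
    """All result tables of one study run; every cell traces to an artifact."""

    metric_tables: Mapping[str, Any]  # accuracy/f1 per evaluator per model + CIs
    pairwise: Mapping[str, Any]  # test kinds, statistics, p-values
    mass_conservation: Mapping[str, Any]  # per-model match/exceeded/under fractions
    overestimation: Mapping[str, Any]  # per-model flagged compound lists
    seasoning: Mapping[str, Any]
    macronutrients: Mapping[str, Any]
    anova: Mapping[str, Any]
    manifest: Mapping[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------- persistence


def _write_jsonl(path: Path, records: Sequence[Mapping[str, Any]]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def _read_jsonl(path: Path) -> list[dict[str, Any]]:
    with path.open() as fh:
        return [json.loads(line) for line in fh if line.strip()]


def _load_plan_set(out: Path, sim: SimulationConfig) -> LabeledPlanSet:
    """Reconstruct the labeled plan set from persisted stage-1 artifacts."""
    plans: list[MealPlan] = []
    truth: dict[str, GroundTruthLabels] = {}
    for rec in _read_jsonl(out / "plans.jsonl"):
        parsed = parse_meal_plan(rec["html"], meal_type=rec["meal_type"], plan_id=rec["plan_id"])
        plans.append(parsed.plan)
        truth[rec["plan_id"]] = GroundTruthLabels(
            evaluator_id="truth", plan_id=rec["plan_id"], labels=rec["labels"]
        )
    true_decs: dict[str, tuple[Decomposition, ...]] = {}
    for rec in _read_jsonl(out / "true_decompositions.jsonl"):
        true_decs.setdefault(rec["plan_id"], ())
        true_decs[rec["plan_id"]] += (
            Decomposition(compound_name=rec["compound"], parts=rec["parts"]),
        )
    for plan in plans:
        true_decs.setdefault(plan.plan_id, ())
    return LabeledPlanSet(plans=tuple(plans), truth=truth, true_decompositions=true_decs)


# --------------------------------------------------------------------- stages


def stage_generate(config: StudyConfig) -> LabeledPlanSet:
    """Stage 1: generate plans, ground truth and the fixture store; persist."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim()
    plan_set = generate_plan_set(sim)
    if config.fixture_store_path:
        store = FoodStore.from_json(config.fixture_store_path)
    else:
        store = generate_food_store(
            seed=sim.stage_seed(3),
            fallback_fraction=sim.store_fallback_fraction,
            duplicate_fraction=sim.store_duplicate_fraction,
        )
    store.to_json(out / "store.json")
    _write_jsonl(
        out / "plans.jsonl",
        [
            {
                "plan_id": p.plan_id,
                "meal_type": p.meal_type.value,
                "html": write_meal_plan(p),
                "labels": dict(plan_set.truth[p.plan_id].labels),
            }
            for p in plan_set.plans
        ],
    )
    _write_jsonl(
        out / "true_decompositions.jsonl",
        [
            {"plan_id": pid, "compound": d.compound_name, "parts": dict(d.parts)}
            for pid, decs in plan_set.true_decompositions.items()
            for d in decs
        ],
    )
    # evaluator labels: each evaluator reviews every plan (identical labels)
    _write_jsonl(
        out / "ground_truth.jsonl",
        [
            {
                "evaluator_id": f"evaluator-{e + 1}",
                "plan_id": p.plan_id,
                "labels": dict(plan_set.truth[p.plan_id].labels),
            }
            for e in range(sim.n_evaluators)
            for p in plan_set.plans
        ],
    )
    return plan_set


def stage_decompose(config: StudyConfig) -> None:
    """Stage 2: each backend identifies and decomposes compound ingredients.

    The simulation layer decides, per backend error profile, which compounds
    the model 'sees' and how it distorts masses; the mock backend then emits a
    delimited dictionary-of-dictionaries response which is extracted and
    parsed exactly as a live response would be.  Failures are recorded in a
    failure manifest, never silently dropped.
    """
    out = Path(config.out_dir)
    sim = config.sim()
    plan_set = _load_plan_set(out, sim)
    for spec in config.backends:
        sim_b = replace(
            sim,
            sensitivity=spec.sensitivity,
            specificity=spec.specificity,
            mass_error=spec.mass_error,
            seasoning_inclusion_prob=spec.seasoning_inclusion_prob,
        )
        predictions = simulate_predictions(plan_set, sim_b, model_name=spec.name)
        backend = MockBackend(name=spec.name, seed=sim.stage_seed(4), malformed_rate=spec.malformed_rate)
        records, failures = [], []
        for plan in plan_set.plans:
            prompt = render_prompt("decomposition", {"INPUT_meal_plan": write_meal_plan(plan)})
            context = {"task": "decomposition", "decompositions": predictions.decompositions[plan.plan_id]}
            try:
                payload = ask_with_retry(backend, prompt, context, step=f"decomposition/{plan.plan_id}")
                parsed = parse_decomposition_payload(payload)
            except PayloadExtractionError as exc:
                failures.append({"plan_id": plan.plan_id, "error": str(exc)})
                continue
            records.append(
                {
                    "plan_id": plan.plan_id,
                    "payload": payload,
                    "decompositions": [
                        {"compound": d.compound_name, "parts": dict(d.parts)} for d in parsed
                    ],
                }
            )
        _write_jsonl(out / "decompositions" / f"{spec.name}.jsonl", records)
        _write_jsonl(out / "decompositions" / f"{spec.name}.failures.jsonl", failures)


def stage_map(config: StudyConfig) -> None:
    """Stages 3–4: build candidate subsets and map each part to a record id.

    The subset for a part is built tier by tier from the store; the mapping
    prompt lists only (fdcId, description) pairs, and the mock backend answers
    with the first candidate's id (candidates are in deterministic
    (tier, fdcId) order).  Parts with an empty subset are logged and skipped.
    """
    out = Path(config.out_dir)
    store = FoodStore.from_json(out / "store.json")
    for spec in config.backends:
        records, failures = [], []
        for rec in _read_jsonl(out / "decompositions" / f"{spec.name}.jsonl"):
            for dec in rec["decompositions"]:
                for part_name in dec["parts"]:
                    subset = build_subset(part_name, store, config.subset_policy)
                    if not subset:
                        failures.append({"plan_id": rec["plan_id"], "part": part_name, "error": "empty subset"})
                        continue
                    candidates = [f"{r.fdc_id}: {r.description}" for r in subset]
                    prompt = render_prompt(
                        "mapping", {"food_item": part_name, "list_of_food_items": candidates}
                    )
                    backend = MockBackend(name=spec.name, seed=config.sim().stage_seed(5))
                    payload = ask_with_retry(
                        backend, prompt, {"task": "mapping", "fdc_id": subset[0].fdc_id}, step="mapping"
                    )
                    records.append(
                        {
                            "plan_id": rec["plan_id"],
                            "compound": dec["compound"],
                            "part": part_name,
                            "mass_g": dec["parts"][part_name],
                            "fdc_id": parse_fdcid_payload(payload),
                        }
                    )
        _write_jsonl(out / "mappings" / f"{spec.name}.jsonl", records)
        _write_jsonl(out / "mappings" / f"{spec.name}.failures.jsonl", failures)


def stage_nutrients(config: StudyConfig) -> None:
    """Stages 5–6: retrieve per-100 g profiles, scale to part masses, aggregate."""
    out = Path(config.out_dir)
    store = FoodStore.from_json(out / "store.json")
    for spec in config.backends:
        by_compound: dict[tuple[str, str], list] = {}
        for rec in _read_jsonl(out / "mappings" / f"{spec.name}.jsonl"):
            profile = get_nutrients(rec["fdc_id"], store)
            scaled = nutrient_math.scale_profile(profile, rec["mass_g"], ingredient_name=rec["part"])
            by_compound.setdefault((rec["plan_id"], rec["compound"]), []).append(scaled)
        records = []
        for (plan_id, compound), parts in by_compound.items():
            total = nutrient_math.aggregate_compound(parts, compound)
            records.append(
                {
                    "plan_id": plan_id,
                    "compound": compound,
                    "parts_mass_g": total.parts_mass_g,
                    "amounts": dict(total.amounts),
                    "coverage": dict(total.coverage),
                }
            )
        _write_jsonl(out / "nutrient_totals" / f"{spec.name}.jsonl", records)


def _evaluate_metrics(config: StudyConfig, out: Path) -> tuple[dict, dict]:
    truth_records = _read_jsonl(out / "ground_truth.jsonl")
    evaluators = sorted({r["evaluator_id"] for r in truth_records})
    plan_ids = sorted({r["plan_id"] for r in truth_records})
    truth_by = {
        (r["evaluator_id"], r["plan_id"]): GroundTruthLabels(
            evaluator_id=r["evaluator_id"], plan_id=r["plan_id"], labels=r["labels"]
        )
        for r in truth_records
    }
    predicted: dict[str, dict[str, set[str]]] = {}
    for spec in config.backends:
        per_plan: dict[str, set[str]] = {pid: set() for pid in plan_ids}
        for rec in _read_jsonl(out / "decompositions" / f"{spec.name}.jsonl"):
            per_plan[rec["plan_id"]] = {normalize_name(d["compound"]) for d in rec["decompositions"]}
        predicted[spec.name] = per_plan

    tables: dict[str, Any] = {}
    scores: dict[str, dict[str, dict[str, list[float]]]] = {"accuracy": {}, "f1": {}}
    for spec in config.backends:
        per_eval = {}
        for metric in scores:
            scores[metric][spec.name] = {}
        for ev in evaluators:
            accs, f1s, conf_total = [], [], stats.ConfusionCounts(0, 0, 0, 0)
            for pid in plan_ids:
                c = stats.confusion(truth_by[(ev, pid)], predicted[spec.name][pid])
                m = stats.metrics_from_confusion(c)
                accs.append(m.accuracy)
                f1s.append(m.f1)
                conf_total = conf_total + c
            scores["accuracy"][spec.name][ev] = accs
            scores["f1"][spec.name][ev] = f1s
            mean_a, lo_a, hi_a = stats.mean_ci(accs, config.ci_level)
            mean_f, lo_f, hi_f = stats.mean_ci(f1s, config.ci_level)
            per_eval[ev] = {
                "accuracy": {"mean": mean_a, "ci": [lo_a, hi_a]},
                "f1": {"mean": mean_f, "ci": [lo_f, hi_f]},
                "confusion": dataclasses.asdict(conf_total),
                "n_plans": len(plan_ids),
            }
        pooled_acc = stats.pool_evaluators(scores["accuracy"][spec.name])
        pooled_f1 = stats.pool_evaluators(scores["f1"][spec.name])
        mean_a, lo_a, hi_a = stats.mean_ci(pooled_acc, config.ci_level)
        mean_f, lo_f, hi_f = stats.mean_ci(pooled_f1, config.ci_level)
        per_eval["overall"] = {
            "accuracy": {"mean": mean_a, "ci": [lo_a, hi_a]},
            "f1": {"mean": mean_f, "ci": [lo_f, hi_f]},
            "n_pooled": len(pooled_acc),
        }
        tables[spec.name] = per_eval

    pairwise: dict[str, Any] = {}
    names = [b.name for b in config.backends]
    for metric in ("accuracy", "f1"):
        pairwise[metric] = {}
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                key = f"{a} vs {b}"
                entry = {}
                for ev in evaluators:
                    cmp_ = stats.paired_compare(
                        scores[metric][a][ev], scores[metric][b][ev], alpha=config.alpha
                    )
                    entry[ev] = dataclasses.asdict(cmp_)
                cmp_ = stats.paired_compare(
                    stats.pool_evaluators(scores[metric][a]),
                    stats.pool_evaluators(scores[metric][b]),
                    alpha=config.alpha,
                )
                entry["pooled"] = dataclasses.asdict(cmp_)
                pairwise[metric][key] = entry
    return tables, pairwise


def _evaluate_decomposition(config: StudyConfig, out: Path) -> tuple[dict, dict, dict, dict, dict]:
    plan_portion: dict[tuple[str, str], float] = {}
    for rec in _read_jsonl(out / "plans.jsonl"):
        parsed = parse_meal_plan(rec["html"], meal_type=rec["meal_type"], plan_id=rec["plan_id"])
        for item in parsed.plan.items:
            plan_portion[(rec["plan_id"], normalize_name(item.name))] = item.portion_mass_g

    mass_summary: dict[str, Any] = {}
    overestimation: dict[str, Any] = {}
    seasoning: dict[str, Any] = {}
    macronutrients: dict[str, Any] = {}
    decs_by_model: dict[str, list[tuple[str, Decomposition]]] = {}
    for spec in config.backends:
        decs: list[tuple[str, Decomposition]] = []
        for rec in _read_jsonl(out / "decompositions" / f"{spec.name}.jsonl"):
            for d in rec["decompositions"]:
                decs.append((rec["plan_id"], Decomposition(compound_name=d["compound"], parts=d["parts"])))
        decs_by_model[spec.name] = decs

        outcomes, flags = [], []
        for pid, d in decs:
            portion = plan_portion.get((pid, normalize_name(d.compound_name)))
            if portion is None or portion <= 0:
                continue
            outcomes.append(
                massmetrics.classify_mass(portion, d.total_mass_g, config.epsilon_g, d.compound_name)
            )
            flags.append(massmetrics.flag_overestimation(portion, d.total_mass_g, d.compound_name))
        if outcomes:
            match, exceeded, under = massmetrics.match_rate_summary(outcomes)
            mass_summary[spec.name] = {
                "match": match, "exceeded": exceeded, "under": under, "n": len(outcomes),
            }
        overestimation[spec.name] = sorted({f.compound_name for f in flags if f.flagged})

        totals = [
            nutrient_math.CompoundNutrientTotal(
                compound_name=rec["compound"], amounts=rec["amounts"], parts_mass_g=rec["parts_mass_g"]
            )
            for rec in _read_jsonl(out / "nutrient_totals" / f"{spec.name}.jsonl")
        ]
        if totals:
            macronutrients[spec.name] = {
                s.nutrient: {"median": s.median, "iqr": [s.iqr_low, s.iqr_high]}
                for s in massmetrics.summarize_macronutrients(totals)
            }

    # seasoning rates over the compounds predicted by every model
    name_sets = [
        {normalize_name(d.compound_name) for _, d in decs} for decs in decs_by_model.values()
    ]
    common = set.intersection(*name_sets) if name_sets else set()
    for spec in config.backends:
        representative: dict[str, Decomposition] = {}
        for _, d in decs_by_model[spec.name]:
            key = normalize_name(d.compound_name)
            if key not in common:
                continue
            has_seasoning = bool(
                {normalize_name(p) for p in d.parts}
                & {"salt", "pepper", "sugar", "black pepper"}
            )
            if key not in representative or has_seasoning:
                representative[key] = d
        if common:
            report = massmetrics.seasoning_rate(
                representative.values(), denominator=len(common)
            )
            seasoning[spec.name] = {
                "n_included_with_quantity": report.n_included_with_quantity,
                "denominator": report.denominator,
                "rate_percent": report.rate,
            }

    # one-way ANOVA across models per macronutrient
    anova: dict[str, Any] = {}
    for nutrient in ("protein", "fat", "carbohydrate", "fiber"):
        groups = []
        for spec in config.backends:
            values = [
                rec["amounts"].get(nutrient, 0.0)
                for rec in _read_jsonl(out / "nutrient_totals" / f"{spec.name}.jsonl")
            ]
            if len(values) >= 2:
                groups.append(values)
        if len(groups) >= 2:
            F, p = stats.anova_oneway(*groups)
            anova[nutrient] = {"F": F, "p": p}
    return mass_summary, overestimation, seasoning, macronutrients, anova


def stage_evaluate(config: StudyConfig) -> StudyReport:
    """Stage 7: compute every result table from the persisted intermediates."""
    out = Path(config.out_dir)
    tables, pairwise = _evaluate_metrics(config, out)
    mass_summary, overestimation, seasoning, macronutrients, anova = _evaluate_decomposition(config, out)
    manifest = {
        "mode": config.mode,
        "master_seed": config.master_seed,
        "backends": [b.name for b in config.backends],
        "epsilon_g": config.epsilon_g,
        "ci_level": config.ci_level,
        "artifacts": sorted(str(p.relative_to(out)) for p in out.rglob("*.jsonl")),
    }
    report = StudyReport(
        metric_tables=tables,
        pairwise=pairwise,
        mass_conservation=mass_summary,
        overestimation=overestimation,
        seasoning=seasoning,
        macronutrients=macronutrients,
        anova=anova,
        manifest=manifest,
    )
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True))
    (out / "report.txt").write_text(render_report_text(report))
    return report


def run_study(config: StudyConfig) -> StudyReport:
    """Run all stages in order and return the report."""
    validate_config(config)
    if config.mode == "live":
        raise NotImplementedError("live mode requires wiring a real backend adapter")
    stage_generate(config)
    stage_decompose(config)
    stage_map(config)
    stage_nutrients(config)
    return stage_evaluate(config)


def render_report_text(report: StudyReport) -> str:
    """Human-readable summary of the report tables."""
    lines = ["# Study report", ""]
    lines.append("## Identification performance (mean, 95% CI)")
    for model, per_eval in report.metric_tables.items():
        for ev, row in per_eval.items():
            a, f = row["accuracy"], row["f1"]
            lines.append(
                f"{model:12s} {ev:12s} acc {a['mean']:.3f} ({a['ci'][0]:.2f}-{a['ci'][1]:.2f})"
                f"  f1 {f['mean']:.3f} ({f['ci'][0]:.2f}-{f['ci'][1]:.2f})"
            )
    lines.append("")
    lines.append("## Pairwise comparisons (pooled)")
    for metric, pairs in report.pairwise.items():
        for pair, entry in pairs.items():
            p = entry["pooled"]
            lines.append(
                f"{metric:9s} {pair:28s} {p['test_kind']:9s} stat {p['statistic']:.3f} p {p['p_value']:.4f}"
            )
    lines.append("")
    lines.append("## Mass conservation (fraction of decompositions)")
    for model, row in report.mass_conservation.items():
        lines.append(
            f"{model:12s} match {row['match']:.2f}  exceeded {row['exceeded']:.2f}  under {row['under']:.2f}  (n={row['n']})"
        )
    lines.append("")
    lines.append("## Compounds overestimated by more than one quarter")
    for model, names in report.overestimation.items():
        lines.append(f"{model:12s} {', '.join(names) if names else '(none)'}")
    lines.append("")
    if report.seasoning:
        lines.append("## Seasoning quantities provided (of common compounds)")
        for model, row in report.seasoning.items():
            lines.append(
                f"{model:12s} {row['n_included_with_quantity']}/{row['denominator']} = {row['rate_percent']}%"
            )
        lines.append("")
    if report.macronutrients:
        lines.append("## Macronutrient totals per compound: median (IQR), percentiles by linear interpolation")
        for model, rows in report.macronutrients.items():
            for nutrient, s in rows.items():
                lines.append(
                    f"{model:12s} {nutrient:13s} {s['median']:.2f} g (IQR: {s['iqr'][0]:.2f}-{s['iqr'][1]:.2f})"
                )
        lines.append("")
    if report.anova:
        lines.append("## One-way ANOVA across models")
        for nutrient, row in report.anova.items():
            lines.append(f"{nutrient:13s} F = {row['F']:.3f}, p = {row['p']:.3f}")
    return "\n".join(lines) + "\n"
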