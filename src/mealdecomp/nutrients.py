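"""Scaling per-100 g nutrient profiles to real masses and aggregating them.

A store profile gives amounts per 100 g of an ingredient; scaling multiplies
every amount by ``mass_g / 100``.  A compound ingredient's total is the
element-wise sum over its parts on the union of nutrient keys, with absent
keys treated as zero — real records have ragged nutrient panels, so every
aggregate carries a coverage map (fraction of parts reporting each nutrient)
to keep those silent zeros auditable.  No cooking-loss correction is applied:
masses are taken as stated.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .fooddata import NutrientProfile

__all__ = ["ScaledProfile", "CompoundNutrientTotal", "scale_profile", "aggregate_compound", "write_totals_table"]


@dataclass(frozen=True)
class ScaledProfile:
    ingredient_name: str
    mass_g: float
    amounts: Mapping[str, float]


@dataclass(frozen=True)
class CompoundNutrientTotal:
    compound_name: str
    amounts: Mapping[str, float]
    parts_mass_g: float
    coverage: Mapping[str, float] = field(default_factory=dict)


def scale_profile(profile: NutrientProfile, mass_g: float, ingredient_name: str = "") -> ScaledProfile:
    """Scale a per-100 g profile to ``mass_g`` grams of the ingredient."""
    if mass_g < 0:
        raise ValueError(f"mass_g must be >= 0, got {mass_g}")
    factor = mass_g / profile.basis_mass_g
    return ScaledProfile(
        ingredient_name=ingredient_name,
        mass_g=mass_g,
        amounts={name: amount * factor for name, amount in profile.amounts.items()},
    )


def aggregate_compound(parts: Sequence[ScaledProfile], compound_name: str) -> CompoundNutrientTotal:
    """Sum scaled part profiles into one compound total.

    Works on the union of nutrient keys; a part missing a nutrient contributes
    zero and lowers that nutrient's coverage fraction.  An empty part list
    yields all-zero totals (degenerate but legal).
    """
    keys: list[str] = []
    for p in parts:
        for k in p.amounts:
            if k not in keys:
                keys.append(k)
    totals = {k: sum(p.amounts.get(k, 0.0) for p in parts) for k in keys}
    coverage = (
        {k: sum(k in p.amounts for p in parts) / len(parts) for k in keys} if parts else {}
    )
    return CompoundNutrientTotal(
        compound_name=compound_name,
        amounts=totals,
        parts_mass_g=float(sum(p.mass_g for p in parts)),
        coverage=coverage,
    )


def write_totals_table(totals: Sequence[CompoundNutrientTotal], nutrients: Sequence[str] | None = None) -> str:
    """Render per-compound totals as a tab-delimited table (text)."""
    if nutrients is None:
        seen: list[str] = []
        for t in totals:
            for k in t.amounts:
                if k not in seen:
                    seen.append(k)
        nutrients = seen
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(["compound", "parts_mass_g", *nutrients])
    for t in totals:
        writer.writerow(
            [t.compound_name, f"{t.parts_mass_g:g}", *(f"{t.amounts.get(n, 0.0):.4g}" for n in nutrients)]
        )
    return buf.getvalue()
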