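"""Food-composition store with a data-type trust hierarchy.

Records mimic the shape of USDA FoodData Central entries: an integer ``fdcId``,
a description, a data type drawn from {SR Legacy, Foundation, FNDDS,
Experimental, Branded}, and a nutrient profile on the 100 g basis.  Candidate
subsets for the mapping step are built tier by tier — curated types first
(SR Legacy, Foundation), then survey data (FNDDS), then Experimental and
Branded — widening only while the match count stays below a sufficiency
threshold.  Branded entries are plentiful but noisy (thousands of records can
share one everyday ingredient name), which is why they sit in the last tier.

The offline store is a JSON fixture; a live-mode client would satisfy the same
contracts with the remote API plus the request pacing that
:func:`schedule_requests` computes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "DATA_TYPES",
    "FoodRecord",
    "NutrientProfile",
    "SubsetPolicy",
    "FoodStore",
    "LookupError_",
    "build_subset",
    "get_nutrients",
    "schedule_requests",
]

DATA_TYPES = ("SR Legacy", "Foundation", "FNDDS", "Experimental", "Branded")


class LookupError_(KeyError):
    """An fdcId was requested that the store does not contain."""


@dataclass(frozen=True)
class FoodRecord:
    fdc_id: int
    description: str
    data_type: str

    def __post_init__(self) -> None:
        if self.fdc_id <= 0:
            raise ValueError("fdc_id must be a positive integer")
        if self.data_type not in DATA_TYPES:
            raise ValueError(f"unknown data_type {self.data_type!r}; expected one of {DATA_TYPES}")


@dataclass(frozen=True)
class NutrientProfile:
    """Nutrient amounts per 100 g (or 100 mL for liquids) of one record."""

    amounts: Mapping[str, float]
    basis_mass_g: float = 100.0

    def __post_init__(self) -> None:
        for name, amount in self.amounts.items():
            if amount < 0:
                raise ValueError(f"nutrient {name!r} has negative amount {amount}")


@dataclass(frozen=True)
class SubsetPolicy:
    """Tier ordering and the sufficiency threshold for subset creation.

    The default threshold of 3 is a configuration choice: the hierarchy widens
    to the next tier whenever fewer matches than this have accumulated.
    """

    tier1: tuple[str, ...] = ("SR Legacy", "Foundation")
    tier2: tuple[str, ...] = ("FNDDS",)
    tier3: tuple[str, ...] = ("Experimental", "Branded")
    sufficiency_threshold: int = 3

    def __post_init__(self) -> None:
        tiers = (*self.tier1, *self.tier2, *self.tier3)
        if sorted(tiers) != sorted(DATA_TYPES):
            raise ValueError("tiers must be disjoint and exhaust the data-type set")
        if self.sufficiency_threshold <= 0:
            raise ValueError("sufficiency_threshold must be positive")

    @property
    def tiers(self) -> tuple[tuple[str, ...], ...]:
        return (self.tier1, self.tier2, self.tier3)


class FoodStore:
    """In-memory food-composition store backed by a JSON fixture.

    Fixture dialect: an array of objects
    ``{"fdcId": int, "description": str, "dataType": str,
    "nutrients": {name: amountPer100g}}``.
    """

    def __init__(self, records: Iterable[tuple[FoodRecord, NutrientProfile]]) -> None:
        self._records: dict[int, FoodRecord] = {}
        self._profiles: dict[int, NutrientProfile] = {}
        for record, profile in records:
            if record.fdc_id in self._records:
                raise ValueError(f"duplicate fdcId {record.fdc_id}")
            self._records[record.fdc_id] = record
            self._profiles[record.fdc_id] = profile

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, fdc_id: int) -> bool:
        return fdc_id in self._records

    def records(self) -> list[FoodRecord]:
        return sorted(self._records.values(), key=lambda r: r.fdc_id)

    def record(self, fdc_id: int) -> FoodRecord:
        try:
            return self._records[fdc_id]
        except KeyError:
            raise LookupError_(f"fdcId {fdc_id} not in store") from None

    def search(self, query: str) -> list[FoodRecord]:
        """Case-insensitive substring match on description, fdcId order."""
        q = query.strip().casefold()
        return [r for r in self.records() if q in r.description.casefold()]

    @classmethod
    def from_json(cls, path: str | Path) -> "FoodStore":
        data = json.loads(Path(path).read_text())
        return cls.from_records(data)

    @classmethod
    def from_records(cls, data: Sequence[Mapping]) -> "FoodStore":
        pairs = []
        for obj in data:
            record = FoodRecord(
                fdc_id=int(obj["fdcId"]),
                description=str(obj["description"]),
                data_type=str(obj["dataType"]),
            )
            profile = NutrientProfile(amounts={str(k): float(v) for k, v in obj.get("nutrients", {}).items()})
            pairs.append((record, profile))
        return cls(pairs)

    def to_json(self, path: str | Path) -> None:
        data = [
            {
                "fdcId": r.fdc_id,
                "description": r.description,
                "dataType": r.data_type,
                "nutrients": dict(self._profiles[r.fdc_id].amounts),
            }
            for r in self.records()
        ]
        Path(path).write_text(json.dumps(data, indent=1))

    def nutrients(self, fdc_id: int) -> NutrientProfile:
        if fdc_id not in self._profiles:
            raise LookupError_(f"fdcId {fdc_id} not in store")
        return self._profiles[fdc_id]


def build_subset(query: str, store: FoodStore, policy: SubsetPolicy | None = None) -> list[FoodRecord]:
    """Build the candidate subset for one basic ingredient, tier by tier.

    Tier-1 matches come first; lower tiers are appended only while the match
    count is below ``policy.sufficiency_threshold``.  The result is ordered by
    (tier, ascending fdcId) so downstream prompts are reproducible.  Only
    (fdcId, description) are meant to travel downstream — nutrient content is
    deliberately kept out of the mapping prompt so the match is made on the
    description alone.
    """
    if not query.strip():
        raise ValueError("query must be non-empty")
    policy = policy or SubsetPolicy()
    if len(store) == 0:
        logger.warning("build_subset(%r): store is empty", query)
        return []
    matches = store.search(query)
    by_type: dict[str, list[FoodRecord]] = {}
    for rec in matches:
        by_type.setdefault(rec.data_type, []).append(rec)

    result: list[FoodRecord] = []
    for tier in policy.tiers:
        if len(result) >= policy.sufficiency_threshold:
            break
        tier_records = sorted(
            (r for t in tier for r in by_type.get(t, [])), key=lambda r: r.fdc_id
        )
        result.extend(tier_records)
    if not result:
        logger.warning("build_subset(%r): no match in any tier", query)
    return result


def get_nutrients(fdc_id: int, store: FoodStore) -> NutrientProfile:
    """Fetch the nutrient profile for a record, always on the 100 g basis."""
    return store.nutrients(fdc_id)


def schedule_requests(n_requests: int, limit_per_hour: float) -> float:
    """Minimum uniform spacing in seconds between live-API requests.

    A limit of 1000 requests per hour per address implies one request every
    3.6 s; a live-mode client must never issue requests closer together.
    """
    if limit_per_hour <= 0:
        raise ValueError("limit_per_hour must be positive")
    if n_requests < 0:
        raise ValueError("n_requests must be non-negative")
    return 3600.0 / limit_per_hour
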