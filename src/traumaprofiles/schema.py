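"""Data model for questionnaire items, outcomes and their serialized schema.

A survey instrument is described by three pieces: binary trauma/stressor
items (rule antecedents), Likert symptom items rated 1-4, and outcome
definitions that turn a Likert subscale mean into a binary psychopathology
indicator (rule consequents). The :class:`Schema` bundles all three and can
be round-tripped through a YAML config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

ROLES = ("antecedent", "consequent")
POLARITIES = ("positive", "negated")
SECTIONS = (
    "trauma",
    "family",
    "economic",
    "social",
    "basic_needs",
    "physical",
    "outcome",
)

#: Likert response range used throughout (1 = not at all ... 4 = extremely).
LIKERT_MIN = 1
LIKERT_MAX = 4


class SchemaError(ValueError):
    """Raised for invalid item/outcome definitions or config files."""


@dataclass(frozen=True)
class ItemDefinition:
    """One binary questionnaire variable.

    Parameters
    ----------
    item_id:
        Short stable token, unique within a dataset (e.g. ``"body_aches"``).
    label:
        Full questionnaire text for reports.
    role:
        ``"antecedent"`` (may appear on a rule's left-hand side) or
        ``"consequent"`` (outcome indicator; only ever a right-hand side).
    polarity:
        ``"positive"``, or ``"negated"`` for a derived complement item, in
        which case ``base_item_id`` names the positive item it negates.
    section:
        Questionnaire section the item belongs to.
    """

    item_id: str
    label: str
    role: str = "antecedent"
    polarity: str = "positive"
    section: str = "trauma"
    base_item_id: str | None = None

    def __post_init__(self) -> None:
        if not self.item_id:
            raise SchemaError("item_id must be non-empty")
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for {self.item_id!r}")
        if self.polarity not in POLARITIES:
            raise SchemaError(
                f"unknown polarity {self.polarity!r} for {self.item_id!r}"
            )
        if self.section not in SECTIONS:
            raise SchemaError(
                f"unknown section {self.section!r} for {self.item_id!r}"
            )
        if self.polarity == "negated" and not self.base_item_id:
            raise SchemaError(
                f"negated item {self.item_id!r} must reference a base item"
            )


@dataclass(frozen=True)
class OutcomeSpec:
    """Discretization rule: flag a respondent when a subscale mean crosses a
    threshold.

    ``mean_threshold`` is inclusive: a respondent whose mean over the
    non-missing subscale entries is exactly the threshold is flagged. The
    customary thresholds are 2.0 ("some" symptoms, *a little bit* on
    average) and 3.0 ("severe", *quite a bit* on average). Respondents who
    answered fewer than ``min_answered_fraction`` of the subscale items are
    flagged missing and later excluded from mining rather than imputed.
    """

    outcome_id: str
    subscale_item_ids: tuple[str, ...]
    mean_threshold: float
    min_answered_fraction: float = 0.8
    label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "subscale_item_ids", tuple(self.subscale_item_ids))
        if not self.outcome_id:
            raise SchemaError("outcome_id must be non-empty")
        if not self.subscale_item_ids:
            raise SchemaError(f"outcome {self.outcome_id!r} has an empty subscale")
        if not (LIKERT_MIN <= self.mean_threshold <= LIKERT_MAX):
            raise SchemaError(
                f"mean_threshold {self.mean_threshold} outside "
                f"[{LIKERT_MIN}, {LIKERT_MAX}] for {self.outcome_id!r}"
            )
        if not (0 < self.min_answered_fraction <= 1):
            raise SchemaError(
                f"min_answered_fraction must lie in (0, 1], got "
                f"{self.min_answered_fraction} for {self.outcome_id!r}"
            )


@dataclass(frozen=True)
class Schema:
    """Instrument description: binary items, Likert items and outcomes."""

    items: tuple[ItemDefinition, ...]
    likert_item_ids: tuple[str, ...] = ()
    outcomes: tuple[OutcomeSpec, ...] = ()
    missing_markers: tuple[str, ...] = ("", "NA")

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "likert_item_ids", tuple(self.likert_item_ids))
        object.__setattr__(self, "outcomes", tuple(self.outcomes))
        object.__setattr__(self, "missing_markers", tuple(self.missing_markers))
        ids = [it.item_id for it in self.items] + list(self.likert_item_ids) + [
            o.outcome_id for o in self.outcomes
        ]
        dup = _first_duplicate(ids)
        if dup is not None:
            raise SchemaError(f"duplicate item_id {dup!r} in schema")
        likert = set(self.likert_item_ids)
        for out in self.outcomes:
            missing = [i for i in out.subscale_item_ids if i not in likert]
            if missing:
                raise SchemaError(
                    f"outcome {out.outcome_id!r} references unknown Likert "
                    f"item(s) {missing}"
                )

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def outcome(self, outcome_id: str) -> OutcomeSpec:
        for out in self.outcomes:
            if out.outcome_id == outcome_id:
                return out
        raise SchemaError(f"unknown outcome {outcome_id!r}")

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "items": [
                {
                    "id": it.item_id,
                    "label": it.label,
                    "section": it.section,
                    **({"role": it.role} if it.role != "antecedent" else {}),
                }
                for it in self.items
            ],
        }
        if self.likert_item_ids:
            d["likert_items"] = list(self.likert_item_ids)
        if self.outcomes:
            d["outcomes"] = [
                {
                    "id": o.outcome_id,
                    "items": list(o.subscale_item_ids),
                    "threshold": o.mean_threshold,
                    "min_answered_fraction": o.min_answered_fraction,
                    **({"label": o.label} if o.label else {}),
                }
                for o in self.outcomes
            ]
        d["missing"] = list(self.missing_markers)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8"
        )

    @classmethod
    def from_dict(cls, d: dict) -> "Schema":
        try:
            raw_items = d["items"]
        except KeyError:
            raise SchemaError("schema config must define 'items'") from None
        items = []
        for entry in raw_items:
            if isinstance(entry, str):
                entry = {"id": entry}
            items.append(
                ItemDefinition(
                    item_id=str(entry["id"]),
                    label=str(entry.get("label", entry["id"])),
                    role=str(entry.get("role", "antecedent")),
                    polarity=str(entry.get("polarity", "positive")),
                    section=str(entry.get("section", "trauma")),
                    base_item_id=entry.get("base_item_id"),
                )
            )
        outcomes = []
        for entry in d.get("outcomes", []):
            outcomes.append(
                OutcomeSpec(
                    outcome_id=str(entry["id"]),
                    subscale_item_ids=tuple(str(i) for i in entry["items"]),
                    mean_threshold=float(entry["threshold"]),
                    min_answered_fraction=float(
                        entry.get("min_answered_fraction", 0.8)
                    ),
                    label=entry.get("label"),
                )
            )
        return cls(
            items=tuple(items),
            likert_item_ids=tuple(str(i) for i in d.get("likert_items", [])),
            outcomes=tuple(outcomes),
            missing_markers=tuple(str(m) for m in d.get("missing", ("", "NA"))),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Schema":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise SchemaError(f"schema file {path} is not a mapping")
        return cls.from_dict(d)


def negated_item(base: ItemDefinition, item_id: str | None = None) -> ItemDefinition:
    """Derive the logical-complement item of a positive antecedent item."""
    if base.role == "consequent":
        raise SchemaError(f"cannot negate consequent item {base.item_id!r}")
    if base.polarity == "negated":
        raise SchemaError(f"cannot negate already-negated item {base.item_id!r}")
    return replace(
        base,
        item_id=item_id or f"not_{base.item_id}",
        label=f"Not: {base.label}",
        polarity="negated",
        base_item_id=base.item_id,
    )


def _first_duplicate(ids: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            return i
        seen.add(i)
    return None


def check_unique_ids(ids: Sequence[str], context: str) -> None:
    dup = _first_duplicate(ids)
    if dup is not None:
        raise SchemaError(f"duplicate item_id {dup!r} in {context}")
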