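"""Respondent-level data containers and the questionnaire -> transactions step.

The mining core works on a :class:`TransactionDataset`: a respondents x items
binary matrix whose columns are antecedent items (traumas/stressors, possibly
negated complements) followed by consequent items (binary psychopathology
indicators derived from Likert subscale means).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .schema import (
    LIKERT_MAX,
    LIKERT_MIN,
    ItemDefinition,
    OutcomeSpec,
    Schema,
    SchemaError,
    check_unique_ids,
    negated_item,
)

_TRUE = {"1", "yes", "true", "y"}
_FALSE = {"0", "no", "false", "n"}


class DataError(ValueError):
    """Raised for malformed response files or inconsistent matrices."""


@dataclass
class LikertMatrix:
    """Respondents x symptom-items matrix of 1-4 severity ratings.

    Missing answers are stored as ``NaN``; every non-missing entry is an
    integer in [1, 4].
    """

    values: np.ndarray
    item_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.item_ids = tuple(self.item_ids)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.item_ids):
            raise DataError("LikertMatrix shape does not match item_ids")
        check_unique_ids(self.item_ids, "LikertMatrix")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (
            (finite != np.round(finite)).any()
            or finite.min() < LIKERT_MIN
            or finite.max() > LIKERT_MAX
        ):
            raise DataError(
                f"Likert entries must be integers in "
                f"[{LIKERT_MIN}, {LIKERT_MAX}] or missing"
            )

    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]

    def columns(self, item_ids: Sequence[str]) -> np.ndarray:
        idx = []
        for i in item_ids:
            try:
                idx.append(self.item_ids.index(i))
            except ValueError:
                raise DataError(f"unknown Likert item {i!r}") from None
        return self.values[:, idx]


@dataclass
class TransactionDataset:
    """Binary respondents x items matrix plus the item definitions.

    One row per respondent ("transaction"); a 1 in column *j* means the
    respondent endorsed item *j*.
    """

    items: tuple[ItemDefinition, ...]
    matrix: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.items = tuple(self.items)
        self.matrix = np.ascontiguousarray(np.asarray(self.matrix))
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.items):
            raise DataError("matrix shape does not match item definitions")
        if self.matrix.dtype != bool:
            vals = np.unique(self.matrix)
            if not np.isin(vals, (0, 1)).all():
                raise DataError("transaction matrix entries must be 0 or 1")
            self.matrix = self.matrix.astype(bool)
        check_unique_ids(self.item_ids, "TransactionDataset")

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    @property
    def n_respondents(self) -> int:
        return self.matrix.shape[0]

    @property
    def antecedent_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items if it.role == "antecedent")

    @property
    def consequent_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items if it.role == "consequent")

    def column(self, item_id: str) -> np.ndarray:
        try:
            j = self.item_ids.index(item_id)
        except ValueError:
            raise DataError(f"unknown item {item_id!r}") from None
        return self.matrix[:, j]

    def item(self, item_id: str) -> ItemDefinition:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise DataError(f"unknown item {item_id!r}")

    def fingerprint(self) -> str:
        """Content hash of the matrix and column layout (hex sha256)."""
        h = hashlib.sha256()
        h.update(",".join(self.item_ids).encode())
        h.update(np.packbits(self.matrix, axis=None).tobytes())
        return h.hexdigest()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix.astype(np.int8), columns=list(self.item_ids)
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, items: Sequence[ItemDefinition]
    ) -> "TransactionDataset":
        ids = [it.item_id for it in items]
        missing = [i for i in ids if i not in frame.columns]
        if missing:
            raise DataError(f"columns missing from frame: {missing}")
        return cls(items=tuple(items), matrix=frame[ids].to_numpy())


def load_responses(
    path: str | Path, schema: Schema
) -> tuple[TransactionDataset, LikertMatrix]:
    """Read a UTF-8 CSV of questionnaire responses.

    Binary columns accept yes/no, true/false, 0/1 (case-insensitive); any
    other non-missing value is an error reported with its row and column.
    Likert columns accept integers 1-4 or one of the schema's missing
    markers, which are preserved as missing values.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing_markers = set(schema.missing_markers)

    def _require(col: str) -> pd.Series:
        if col not in raw.columns:
            raise DataError(f"column {col!r} required by schema not in {path}")
        return raw[col]

    bin_cols = []
    for it in schema.items:
        col = _require(it.item_id)
        vals = np.empty(len(col), dtype=bool)
        for row, cell in enumerate(col):
            c = cell.strip().lower()
            if c in _TRUE:
                vals[row] = True
            elif c in _FALSE:
                vals[row] = False
            else:
                raise DataError(
                    f"unparseable binary value {cell!r} at row {row}, "
                    f"column {it.item_id!r}"
                )
        bin_cols.append(vals)
    matrix = (
        np.column_stack(bin_cols)
        if bin_cols
        else np.zeros((len(raw), 0), dtype=bool)
    )
    dataset = TransactionDataset(items=schema.items, matrix=matrix)

    lik_cols = []
    for lid in schema.likert_item_ids:
        col = _require(lid)
        vals = np.empty(len(col), dtype=float)
        for row, cell in enumerate(col):
            c = cell.strip()
            if c in missing_markers:
                vals[row] = np.nan
                continue
            try:
                v = int(c)
            except ValueError:
                raise DataError(
                    f"unparseable Likert value {cell!r} at row {row}, "
                    f"column {lid!r}"
                ) from None
            if not (LIKERT_MIN <= v <= LIKERT_MAX):
                raise DataError(
                    f"Likert value {v} outside [{LIKERT_MIN}, {LIKERT_MAX}] "
                    f"at row {row}, column {lid!r}"
                )
            vals[row] = v
        lik_cols.append(vals)
    likert = LikertMatrix(
        values=(
            np.column_stack(lik_cols)
            if lik_cols
            else np.zeros((len(raw), 0))
        ),
        item_ids=schema.likert_item_ids,
    )
    return dataset, likert


def discretize_outcome(likert: LikertMatrix, spec: OutcomeSpec) -> np.ndarray:
    """Binary outcome flag per respondent from a subscale mean.

    Returns a float vector: 1.0 if the mean over the respondent's
    non-missing subscale entries is >= ``spec.mean_threshold`` (inclusive)
    and the answered fraction is >= ``spec.min_answered_fraction``; 0.0 if
    the mean falls below the threshold with sufficient answers; ``NaN``
    (excluded from mining) when too few items were answered.
    """
    sub = likert.columns(spec.subscale_item_ids)
    if sub.shape[1] == 0:
        raise DataError(f"outcome {spec.outcome_id!r} has an empty subscale")
    answered = (~np.isnan(sub)).sum(axis=1)
    if likert.n_respondents and answered.max() == 0:
        raise DataError(
            f"all subscale entries missing for every respondent "
            f"({spec.outcome_id!r})"
        )
    frac = answered / sub.shape[1]
    with np.errstate(invalid="ignore"):
        means = np.nanmean(np.where(np.isnan(sub), np.nan, sub), axis=1)
    flags = np.where(means >= spec.mean_threshold, 1.0, 0.0)
    flags[frac < spec.min_answered_fraction] = np.nan
    return flags


def build_transactions(
    binary_items: TransactionDataset,
    outcomes: Sequence[tuple[OutcomeSpec | str, np.ndarray]],
    negation_ids: Sequence[str] = (),
) -> TransactionDataset:
    """Assemble the final mining dataset.

    Outcome columns (from :func:`discretize_outcome`) are appended as
    role="consequent" items; for every id in ``negation_ids`` a derived
    complement item (polarity="negated") is appended. Respondents with any
    missing outcome flag are dropped; the drop count is recorded on the
    returned dataset as ``n_dropped``.
    """
    if not outcomes:
        raise DataError("no outcome columns supplied; nothing to mine toward")
    n = binary_items.n_respondents
    cols = [binary_items.matrix]
    items: list[ItemDefinition] = list(binary_items.items)

    for nid in negation_ids:
        base = binary_items.item(nid)
        derived = negated_item(base)  # validates role/polarity
        items.append(derived)
        cols.append(~binary_items.column(nid)[:, None])

    keep = np.ones(n, dtype=bool)
    outcome_cols = []
    for spec, flags in outcomes:
        flags = np.asarray(flags, dtype=float)
        if flags.shape != (n,):
            raise DataError("outcome column length does not match respondents")
        if isinstance(spec, OutcomeSpec):
            oid, label = spec.outcome_id, spec.label or spec.outcome_id
        else:
            oid = label = str(spec)
        items.append(
            ItemDefinition(
                item_id=oid, label=label, role="consequent", section="outcome"
            )
        )
        keep &= ~np.isnan(flags)
        outcome_cols.append(flags)
    for flags in outcome_cols:
        cols.append((flags[:, None] > 0.5))

    matrix = np.column_stack([c.astype(bool) for c in cols])[keep]
    return TransactionDataset(
        items=tuple(items), matrix=matrix, n_dropped=int(n - keep.sum())
    )


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding, as used for printed prevalence tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def prevalence_table(dataset: TransactionDataset) -> pd.DataFrame:
    """Per-item endorsement counts and percentages (half-up, one decimal)."""
    if dataset.n_respondents == 0:
        raise DataError("cannot tabulate an empty dataset")
    n = dataset.n_respondents
    counts = dataset.matrix.sum(axis=0)
    return pd.DataFrame(
        {
            "item_id": list(dataset.item_ids),
            "label": [it.label for it in dataset.items],
            "section": [it.section for it in dataset.items],
            "count": counts.astype(int),
            "percent": [round_half_up(100.0 * c / n, 1) for c in counts],
        }
    )
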