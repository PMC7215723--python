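"""Constrained association-rule mining with a fixed consequent.

The miner searches for rules ``LHS => RHS`` where the antecedent LHS is a
set of trauma/stressor items and the consequent RHS is a single binary
psychopathology indicator. A rule is kept when

* ``support(LHS ∪ RHS) >= min_support`` (the fraction of respondents who
  endorsed every antecedent item *and* the outcome; thresholding the joint
  support implies ``support(LHS) >= min_support`` as well),
* ``confidence = support(LHS ∪ RHS) / support(LHS) >= min_confidence``, and
* ``|LHS| + 1 <= max_rule_length``.

Both thresholds are inclusive. Frequent antecedents are found level-wise
(Apriori): a candidate is only ever counted if all of its proper subsets
are frequent, which is sound because joint support is anti-monotone in the
antecedent. Counting uses bit-packed row masks with vectorised popcounts.

Redundancy pruning follows the minimal-antecedent principle: a rule is
removed when a rule with the same consequent and a non-empty proper subset
of its antecedent reaches at least the same confidence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset import DataError, TransactionDataset

_EPS = 1e-12


class MiningError(ValueError):
    """Raised for invalid mining configurations."""


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds and item selection for one mining run.

    ``max_rule_length`` counts the antecedent items plus the single
    consequent, so the default of 5 allows up to four antecedents.
    ``antecedent_ids=None`` means every antecedent-role item in the dataset.
    """

    min_support: float
    min_confidence: float
    max_rule_length: int = 5
    consequent_ids: tuple[str, ...] = ()
    antecedent_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "consequent_ids", tuple(self.consequent_ids))
        if self.antecedent_ids is not None:
            object.__setattr__(self, "antecedent_ids", tuple(self.antecedent_ids))
        if not (0 < self.min_support <= 1):
            raise MiningError(f"min_support must lie in (0, 1], got {self.min_support}")
        if not (0 < self.min_confidence <= 1):
            raise MiningError(
                f"min_confidence must lie in (0, 1], got {self.min_confidence}"
            )
        if self.max_rule_length < 2:
            raise MiningError(
                f"max_rule_length must be >= 2, got {self.max_rule_length}"
            )

    def to_dict(self) -> dict:
        return {
            "min_support": self.min_support,
            "min_confidence": self.min_confidence,
            "max_rule_length": self.max_rule_length,
            "consequent_ids": list(self.consequent_ids),
            "antecedent_ids": (
                None if self.antecedent_ids is None else list(self.antecedent_ids)
            ),
        }


@dataclass(frozen=True)
class Rule:
    """One association rule LHS => RHS with its empirical statistics.

    ``n_rule``/``n_lhs`` are the integer respondent counts behind
    ``support_rule`` and ``support_lhs``; confidence equals
    ``n_rule / n_lhs`` exactly.
    """

    lhs: frozenset[str]
    rhs: str
    support_lhs: float
    support_rule: float
    confidence: float
    n_rule: int
    n_lhs: int

    @property
    def lhs_sorted(self) -> tuple[str, ...]:
        return tuple(sorted(self.lhs))

    def sort_key(self) -> tuple:
        return (-self.confidence, -self.support_rule, self.lhs_sorted, self.rhs)

    def to_dict(self) -> dict:
        return {
            "lhs": list(self.lhs_sorted),
            "rhs": self.rhs,
            "support": self.support_rule,
            "support_lhs": self.support_lhs,
            "confidence": self.confidence,
            "n": self.n_rule,
            "n_lhs": self.n_lhs,
        }


@dataclass(frozen=True)
class RuleSet:
    """Deterministically ordered mining result.

    Rules are sorted by descending confidence, then descending rule support,
    then lexicographically by the sorted antecedent ids.
    """

    rules: tuple[Rule, ...]
    config: MiningConfig
    dataset_fingerprint: str
    n_respondents: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", tuple(self.rules))

    def __len__(self) -> int:
        return len(self.rules)

    def for_consequent(self, rhs: str) -> tuple[Rule, ...]:
        return tuple(r for r in self.rules if r.rhs == rhs)

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "dataset_fingerprint": self.dataset_fingerprint,
            "n_respondents": self.n_respondents,
            "rules": [r.to_dict() for r in self.rules],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_frame(self) -> pd.DataFrame:
        """Flat table, one row per rule, antecedents joined by ``|``."""
        return pd.DataFrame(
            {
                "lhs": ["|".join(r.lhs_sorted) for r in self.rules],
                "rhs": [r.rhs for r in self.rules],
                "support": [r.support_rule for r in self.rules],
                "support_lhs": [r.support_lhs for r in self.rules],
                "confidence": [r.confidence for r in self.rules],
                "n": [r.n_rule for r in self.rules],
                "n_lhs": [r.n_lhs for r in self.rules],
            }
        )

    @classmethod
    def from_dict(cls, d: dict) -> "RuleSet":
        rules = tuple(
            Rule(
                lhs=frozenset(r["lhs"]),
                rhs=r["rhs"],
                support_lhs=r["support_lhs"],
                support_rule=r["support"],
                confidence=r["confidence"],
                n_rule=r["n"],
                n_lhs=r["n_lhs"],
            )
            for r in d["rules"]
        )
        cfg = d["config"]
        return cls(
            rules=rules,
            config=MiningConfig(
                min_support=cfg["min_support"],
                min_confidence=cfg["min_confidence"],
                max_rule_length=cfg["max_rule_length"],
                consequent_ids=tuple(cfg["consequent_ids"]),
                antecedent_ids=(
                    None
                    if cfg["antecedent_ids"] is None
                    else tuple(cfg["antecedent_ids"])
                ),
            ),
            dataset_fingerprint=d["dataset_fingerprint"],
            n_respondents=d.get("n_respondents", 0),
        )

    @classmethod
    def from_json(cls, text: str) -> "RuleSet":
        return cls.from_dict(json.loads(text))


# --------------------------------------------------------------------------
# Counting primitives


def _pack(col: np.ndarray) -> np.ndarray:
    return np.packbits(col)


def _count(packed: np.ndarray) -> int:
    return int(np.bitwise_count(packed).sum())


def support(itemset: Iterable[str], dataset: TransactionDataset) -> float:
    """Fraction of respondents endorsing every item in ``itemset``."""
    ids = tuple(itemset)
    if not ids:
        raise MiningError("support of the empty itemset is undefined here")
    mask = np.ones(dataset.n_respondents, dtype=bool)
    for i in ids:
        mask &= dataset.column(i)
    return mask.sum() / dataset.n_respondents


def _min_count(threshold: float, n: int) -> int:
    """Smallest positive integer count c with c / n >= threshold (inclusive)."""
    return max(1, int(np.ceil(threshold * n - _EPS)))


def _apriori(
    columns: Sequence[tuple[str, np.ndarray]],
    n_respondents: int,
    min_count: int,
    max_size: int,
    base_mask: np.ndarray | None = None,
    trace: list | None = None,
) -> dict[tuple[str, ...], tuple[int, np.ndarray, np.ndarray | None]]:
    """Level-wise frequent-itemset search over bit-packed masks.

    ``columns`` are (item_id, boolean column) pairs; itemsets are tuples of
    ids ordered by their position in ``columns``. When ``base_mask`` is
    given, frequency is measured on ``support(X ∪ base)`` (the
    fixed-consequent constraint) and each entry additionally carries the
    packed mask of X alone. ``trace``, if supplied, records every candidate
    that is actually counted — used to verify that no candidate with an
    infrequent proper subset is ever evaluated.

    Returns ``{itemset: (count, packed_joint_mask, packed_plain_mask)}``.
    """
    order = {item_id: k for k, (item_id, _) in enumerate(columns)}
    packed_base = None if base_mask is None else _pack(base_mask)

    frequent: dict[tuple[str, ...], tuple[int, np.ndarray, np.ndarray | None]] = {}
    level: dict[tuple[str, ...], tuple[int, np.ndarray, np.ndarray | None]] = {}
    for item_id, col in columns:
        plain = _pack(col)
        joint = plain if packed_base is None else plain & packed_base
        if trace is not None:
            trace.append(frozenset((item_id,)))
        count = _count(joint)
        if count >= min_count:
            level[(item_id,)] = (
                count,
                joint,
                None if packed_base is None else plain,
            )
    frequent.update(level)

    size = 1
    while level and size < max_size:
        prev = level
        prev_keys = set(prev)
        level = {}
        # group (k-1)-itemsets sharing their first k-2 items; joining two
        # members of a group yields a candidate k-itemset
        groups: dict[tuple[str, ...], list[tuple[str, ...]]] = {}
        for key in prev:
            groups.setdefault(key[:-1], []).append(key)
        for prefix, members in sorted(
            groups.items(), key=lambda kv: tuple(order[i] for i in kv[0])
        ):
            members.sort(key=lambda key: order[key[-1]])
            for a, b in combinations(members, 2):
                cand = a + (b[-1],)
                # Apriori pruning: every proper (k-1)-subset must be frequent
                if size >= 2 and any(
                    cand[:j] + cand[j + 1 :] not in prev_keys
                    for j in range(len(cand) - 2)
                ):
                    continue
                if trace is not None:
                    trace.append(frozenset(cand))
                count_a, joint_a, plain_a = prev[a]
                _, joint_b, plain_b = prev[b]
                joint = joint_a & joint_b
                count = _count(joint)
                if count >= min_count:
                    plain = (
                        None if plain_a is None else plain_a & plain_b
                    )
                    level[cand] = (count, joint, plain)
        frequent.update(level)
        size += 1
    return frequent


def frequent_itemsets(
    dataset: TransactionDataset,
    min_support: float,
    max_size: int,
    item_ids: Sequence[str] | None = None,
    trace: list | None = None,
) -> dict[frozenset[str], float]:
    """All itemsets with ``support >= min_support`` and ``size <= max_size``."""
    if not (0 < min_support <= 1):
        raise MiningError(f"min_support must lie in (0, 1], got {min_support}")
    if max_size < 1:
        raise MiningError(f"max_size must be >= 1, got {max_size}")
    ids = tuple(item_ids) if item_ids is not None else dataset.item_ids
    columns = [(i, dataset.column(i)) for i in ids]
    n = dataset.n_respondents
    found = _apriori(
        columns, n, _min_count(min_support, n), max_size, trace=trace
    )
    return {frozenset(k): cnt / n for k, (cnt, _, _) in found.items()}


def _resolve_config(
    dataset: TransactionDataset, config: MiningConfig
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Validate consequents/antecedents against the dataset's item roles."""
    if not config.consequent_ids:
        raise MiningError("config must name at least one consequent")
    consequent_roles = set(dataset.consequent_ids)
    for rid in config.consequent_ids:
        if rid not in consequent_roles:
            role = "antecedent" if rid in dataset.antecedent_ids else "missing"
            raise MiningError(
                f"consequent {rid!r} is {role} in this dataset"
            )
    if config.antecedent_ids is None:
        antecedents = dataset.antecedent_ids
    else:
        valid = set(dataset.antecedent_ids)
        for aid in config.antecedent_ids:
            if aid not in valid:
                raise MiningError(f"antecedent {aid!r} not in dataset")
        antecedents = config.antecedent_ids
    return antecedents, config.consequent_ids


def generate_rules(
    dataset: TransactionDataset,
    config: MiningConfig,
    trace: list | None = None,
) -> list[Rule]:
    """Every rule meeting the support, confidence and length thresholds.

    For each consequent the antecedent lattice is searched with frequency
    measured on ``support(LHS ∪ {consequent})``; confidence is then the exact
    count ratio ``n(LHS ∪ RHS) / n(LHS)``.
    """
    antecedents, consequents = _resolve_config(dataset, config)
    n = dataset.n_respondents
    if n == 0:
        raise MiningError("cannot mine an empty dataset")
    min_count = _min_count(config.min_support, n)
    rules: list[Rule] = []
    for rhs in consequents:
        columns = [(i, dataset.column(i)) for i in antecedents]
        found = _apriori(
            columns,
            n,
            min_count,
            config.max_rule_length - 1,
            base_mask=dataset.column(rhs),
            trace=trace,
        )
        for key, (n_rule, _, plain) in found.items():
            n_lhs = _count(plain)
            confidence = n_rule / n_lhs  # n_lhs >= n_rule >= min_count >= 1
            if confidence + _EPS >= config.min_confidence:
                rules.append(
                    Rule(
                        lhs=frozenset(key),
                        rhs=rhs,
                        support_lhs=n_lhs / n,
                        support_rule=n_rule / n,
                        confidence=confidence,
                        n_rule=n_rule,
                        n_lhs=n_lhs,
                    )
                )
    rules.sort(key=Rule.sort_key)
    return rules


def _dominates(sub: Rule, sup: Rule) -> bool:
    """True when ``sub`` makes ``sup`` redundant (exact integer comparison)."""
    return sub.n_rule * sup.n_lhs >= sup.n_rule * sub.n_lhs


def prune_redundant(rules: Sequence[Rule]) -> list[Rule]:
    """Drop rules whose antecedent strictly contains a sub-rule's antecedent
    (same consequent) without exceeding its confidence.

    A rule survives only if it is strictly more confident than every rule in
    the input built on a non-empty proper subset of its antecedent.
    """
    by_key = {(r.rhs, r.lhs): r for r in rules}
    kept: list[Rule] = []
    for rule in rules:
        ids = rule.lhs_sorted
        dominated = False
        for size in range(1, len(ids)):
            for subset in combinations(ids, size):
                sub = by_key.get((rule.rhs, frozenset(subset)))
                if sub is not None and _dominates(sub, rule):
                    dominated = True
                    break
            if dominated:
                break
        if not dominated:
            kept.append(rule)
    return kept


def mine_profiles(dataset: TransactionDataset, config: MiningConfig) -> RuleSet:
    """End-to-end mining: generate rules, prune redundant ones, order them."""
    if dataset.n_respondents == 0:
        raise MiningError("cannot mine an empty dataset")
    if not dataset.antecedent_ids or not dataset.consequent_ids:
        raise MiningError(
            "dataset needs at least one antecedent and one consequent item"
        )
    rules = prune_redundant(generate_rules(dataset, config))
    rules.sort(key=Rule.sort_key)
    return RuleSet(
        rules=tuple(rules),
        config=config,
        dataset_fingerprint=dataset.fingerprint(),
        n_respondents=dataset.n_respondents,
    )
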