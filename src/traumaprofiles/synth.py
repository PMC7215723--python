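"""Synthetic questionnaire data with known structure.

The study population these generators emulate is a post-war survivor sample
answering a trauma/stressor questionnaire: ~100 binary exposure items with
heterogeneous marginal prevalences and Likert symptom subscales whose means
are discretized into "some" (mean >= 2) and "severe" (mean >= 3) outcome
flags. Items are independent Bernoulli draws by default — only marginal
prevalences are calibrated — and antecedent -> outcome dependencies are
introduced exclusively by planting rules with prescribed support and
confidence, so that miner recovery can be tested against a known ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import catalog
from .dataset import (
    DataError,
    LikertMatrix,
    TransactionDataset,
    build_transactions,
    discretize_outcome,
)
from .schema import ItemDefinition, OutcomeSpec, SchemaError


class SynthesisError(ValueError):
    """Raised for invalid or infeasible generator targets."""


@dataclass(frozen=True)
class PlantedRule:
    """A dependency to inject: respondents holding every ``lhs`` item are
    flagged on ``rhs`` with probability ~``target_confidence``, and the joint
    (LHS and RHS) fraction of the sample is ~``target_support``."""

    lhs_item_ids: frozenset[str]
    rhs_outcome_id: str
    target_support: float
    target_confidence: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "lhs_item_ids", frozenset(self.lhs_item_ids))
        if not self.lhs_item_ids:
            raise SynthesisError("planted rule needs a non-empty antecedent")
        if self.rhs_outcome_id in self.lhs_item_ids:
            raise SynthesisError("consequent cannot appear in the antecedent")
        if not (0 < self.target_support <= 1):
            raise SynthesisError(
                f"target_support must lie in (0, 1], got {self.target_support}"
            )
        if not (0 < self.target_confidence <= 1):
            raise SynthesisError(
                f"target_confidence must lie in (0, 1], got "
                f"{self.target_confidence}"
            )
        if self.target_support > self.target_confidence:
            raise SynthesisError(
                "target_support cannot exceed target_confidence "
                f"({self.target_support} > {self.target_confidence})"
            )


@dataclass(frozen=True)
class SyntheticProfile:
    """Full description of one synthetic dataset.

    ``item_specs`` are (item_id, marginal prevalence) pairs;
    ``subscale_specs`` are (name, k items, target "some" prevalence, target
    "severe" prevalence) tuples, each yielding outcomes ``some_<name>`` and
    ``severe_<name>``. The seed is mandatory: generation is deterministic.
    """

    n_respondents: int
    item_specs: tuple[tuple[str, float], ...]
    subscale_specs: tuple[tuple[str, int, float, float], ...] = ()
    planted_rules: tuple[PlantedRule, ...] = ()
    negation_ids: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_specs", tuple(self.item_specs))
        object.__setattr__(self, "subscale_specs", tuple(self.subscale_specs))
        object.__setattr__(self, "planted_rules", tuple(self.planted_rules))
        object.__setattr__(self, "negation_ids", tuple(self.negation_ids))
        if self.n_respondents < 1:
            raise SynthesisError("n_respondents must be >= 1")
        for item_id, p in self.item_specs:
            if not (0 <= p <= 1):
                raise SynthesisError(
                    f"prevalence {p} outside [0, 1] for {item_id!r}"
                )
        for name, k, some, severe in self.subscale_specs:
            if k < 1:
                raise SynthesisError(f"subscale {name!r} needs >= 1 item")
            if not (0 <= severe <= some <= 1):
                raise SynthesisError(
                    f"subscale {name!r} requires 0 <= severe <= some <= 1, "
                    f"got some={some}, severe={severe}"
                )


def default_profile(
    n: int = catalog.STUDY_N,
    seed: int = 0,
    planted_rules: Sequence[PlantedRule] = (),
    negation_ids: Sequence[str] = (),
) -> SyntheticProfile:
    """Profile calibrated to the catalog's observed marginals."""
    return SyntheticProfile(
        n_respondents=n,
        item_specs=tuple(catalog.catalog_prevalences().items()),
        subscale_specs=tuple(
            (name, catalog.DEFAULT_SUBSCALE_K, some / 100.0, severe / 100.0)
            for name, some, severe in catalog.SUBSCALES
        ),
        planted_rules=tuple(planted_rules),
        negation_ids=tuple(negation_ids),
        seed=seed,
    )


# --------------------------------------------------------------------------
# Binary items


def generate_binary_items(
    n: int,
    item_specs: Sequence[tuple[str, float]],
    seed: int | np.random.SeedSequence,
    definitions: Mapping[str, ItemDefinition] | None = None,
) -> TransactionDataset:
    """Independent Bernoulli draws, one column per (item_id, prevalence)."""
    if n < 1:
        raise SynthesisError("n must be >= 1")
    rng = np.random.default_rng(seed)
    items = []
    cols = []
    for item_id, p in item_specs:
        if not (0 <= p <= 1):
            raise SynthesisError(f"prevalence {p} outside [0, 1] for {item_id!r}")
        if definitions and item_id in definitions:
            items.append(definitions[item_id])
        else:
            items.append(
                ItemDefinition(item_id=item_id, label=item_id, section="trauma")
            )
        cols.append(rng.random(n) < p)
    return TransactionDataset(items=tuple(items), matrix=np.column_stack(cols))


# --------------------------------------------------------------------------
# Likert subscales

def _composition_counts(k: int, lo: int = 1, hi: int = 4) -> np.ndarray:
    """comp[m, s] = number of ways m scores in [lo, hi] sum to s."""
    comp = np.zeros((k + 1, hi * k + 1))
    comp[0, 0] = 1.0
    for m in range(1, k + 1):
        for v in range(lo, hi + 1):
            comp[m, v:] += comp[m - 1, : comp.shape[1] - v]
    return comp


def _sample_scores_for_sums(
    sums: np.ndarray, k: int, comp: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniformly random score vectors (n, k), entries 1..4, with given row sums."""
    n = sums.shape[0]
    out = np.zeros((n, k), dtype=float)
    remaining = sums.astype(int).copy()
    smax = comp.shape[1] - 1
    for j in range(k):
        m = k - j - 1  # items left after this one
        # weight of assigning value v: compositions of the remainder
        weights = np.zeros((n, 4))
        for v in range(1, 5):
            rem = remaining - v
            ok = (rem >= 0) & (rem <= smax)
            weights[ok, v - 1] = comp[m, rem[ok]]
        totals = weights.sum(axis=1, keepdims=True)
        cdf = np.cumsum(weights, axis=1) / totals
        draws = (rng.random((n, 1)) < cdf).argmax(axis=1) + 1
        out[:, j] = draws
        remaining -= draws
    assert (remaining == 0).all()
    return out


def generate_likert_subscale(
    n: int,
    k: int,
    target_some: float,
    target_severe: float,
    seed: int | np.random.SeedSequence,
    item_prefix: str = "item",
) -> LikertMatrix:
    """Likert scores whose discretized prevalences hit the two targets.

    Each respondent draws a severity band — mean below 2, mean in [2, 3),
    or mean at/above 3 — with probabilities (1 - target_some,
    target_some - target_severe, target_severe); the k integer scores are
    then uniform over the compositions whose mean lands in that band. After
    discretization at thresholds 2.0 and 3.0 the flagged fractions are
    binomial around the targets.
    """
    if n < 1 or k < 1:
        raise SynthesisError("n and k must be >= 1")
    if not (0 <= target_severe <= target_some <= 1):
        raise SynthesisError(
            f"need 0 <= target_severe <= target_some <= 1, got "
            f"some={target_some}, severe={target_severe}"
        )
    rng = np.random.default_rng(seed)
    probs = np.array(
        [1.0 - target_some, target_some - target_severe, target_severe]
    )
    bands = rng.choice(3, size=n, p=probs / probs.sum())
    comp = _composition_counts(k)
    # sum ranges per band: mean < 2, 2 <= mean < 3, mean >= 3 (inclusive
    # thresholds on the mean <=> integer cutoffs on the sum)
    ranges = [(k, 2 * k - 1), (2 * k, 3 * k - 1), (3 * k, 4 * k)]
    sums = np.zeros(n, dtype=int)
    for b, (lo, hi) in enumerate(ranges):
        idx = np.flatnonzero(bands == b)
        if idx.size == 0:
            continue
        w = comp[k, lo : hi + 1]
        sums[idx] = rng.choice(
            np.arange(lo, hi + 1), size=idx.size, p=w / w.sum()
        )
    values = _sample_scores_for_sums(sums, k, comp, rng)
    return LikertMatrix(
        values=values,
        item_ids=tuple(f"{item_prefix}_{j + 1}" for j in range(k)),
    )


def _resample_bands(
    likert: LikertMatrix,
    subscale_ids: Sequence[str],
    rows: np.ndarray,
    bands: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Rewrite ``rows`` of a subscale in-place to land in the given bands."""
    if rows.size == 0:
        return
    k = len(subscale_ids)
    comp = _composition_counts(k)
    ranges = [(k, 2 * k - 1), (2 * k, 3 * k - 1), (3 * k, 4 * k)]
    sums = np.zeros(rows.size, dtype=int)
    for b, (lo, hi) in enumerate(ranges):
        idx = np.flatnonzero(bands == b)
        if idx.size == 0:
            continue
        w = comp[k, lo : hi + 1]
        sums[idx] = rng.choice(np.arange(lo, hi + 1), size=idx.size, p=w / w.sum())
    scores = _sample_scores_for_sums(sums, k, comp, rng)
    col_idx = [likert.item_ids.index(i) for i in subscale_ids]
    likert.values[np.ix_(rows, col_idx)] = scores


# --------------------------------------------------------------------------
# Rule planting


def plant_rule(
    dataset: TransactionDataset,
    rule: PlantedRule,
    seed: int | np.random.SeedSequence,
) -> TransactionDataset:
    """Rewrite rows so the rule holds at its target support and confidence.

    The edit is minimal in the number of touched cells: outcome flags among
    antecedent-complete rows are flipped first; if too few rows carry the
    full antecedent, rows missing the fewest antecedent items are recruited
    (and surplus rows are demoted by clearing one antecedent cell). Rows not
    involved in the rule are left untouched. Realized support and confidence
    are exact integer ratios within rounding of the targets; infeasible
    targets raise :class:`SynthesisError`.
    """
    rng = np.random.default_rng(seed)
    matrix = dataset.matrix.copy()
    n = dataset.n_respondents
    ids = dataset.item_ids
    try:
        lhs_idx = [ids.index(i) for i in sorted(rule.lhs_item_ids)]
        rhs_idx = ids.index(rule.rhs_outcome_id)
    except ValueError as exc:
        raise SynthesisError(f"planted rule references unknown item: {exc}")

    n_lhs_target = int(round(n * rule.target_support / rule.target_confidence))
    n_both_target = int(round(rule.target_confidence * n_lhs_target))
    if n_lhs_target > n:
        raise SynthesisError(
            f"infeasible targets: support {rule.target_support} at confidence "
            f"{rule.target_confidence} needs {n_lhs_target} antecedent-complete "
            f"rows but the dataset has only {n}"
        )
    if n_lhs_target < 1:
        raise SynthesisError("targets round to an empty antecedent block")

    lhs_cols = matrix[:, lhs_idx]
    complete = lhs_cols.all(axis=1)
    n_complete = int(complete.sum())
    if n_complete < n_lhs_target:
        # recruit rows missing the fewest antecedent items, ties broken at random
        candidates = np.flatnonzero(~complete)
        missing = (~lhs_cols[candidates]).sum(axis=1)
        order = rng.permutation(candidates.size)
        chosen = candidates[order[np.argsort(missing[order], kind="stable")]]
        chosen = chosen[: n_lhs_target - n_complete]
        matrix[np.ix_(chosen, lhs_idx)] = True
    elif n_complete > n_lhs_target:
        surplus = rng.choice(
            np.flatnonzero(complete), size=n_complete - n_lhs_target, replace=False
        )
        drop_col = rng.integers(0, len(lhs_idx), size=surplus.size)
        matrix[surplus, np.asarray(lhs_idx)[drop_col]] = False

    complete = matrix[:, lhs_idx].all(axis=1)
    flagged = complete & matrix[:, rhs_idx]
    n_flagged = int(flagged.sum())
    if n_flagged < n_both_target:
        pool = np.flatnonzero(complete & ~matrix[:, rhs_idx])
        add = rng.choice(pool, size=n_both_target - n_flagged, replace=False)
        matrix[add, rhs_idx] = True
    elif n_flagged > n_both_target:
        pool = np.flatnonzero(flagged)
        remove = rng.choice(pool, size=n_flagged - n_both_target, replace=False)
        matrix[remove, rhs_idx] = False

    return TransactionDataset(
        items=dataset.items, matrix=matrix, n_dropped=dataset.n_dropped
    )


def dataset_from_blocks(
    items: Sequence[ItemDefinition],
    blocks: Sequence[tuple[int, Sequence[str]]],
) -> TransactionDataset:
    """Deterministic dataset from (row count, endorsed item ids) blocks.

    Useful for constructing worked examples and fixtures whose supports and
    confidences are exact by design; no randomness is involved.
    """
    ids = [it.item_id for it in items]
    idx = {i: j for j, i in enumerate(ids)}
    rows = []
    for count, pattern in blocks:
        if count < 0:
            raise SynthesisError("block counts must be non-negative")
        row = np.zeros(len(ids), dtype=bool)
        for i in pattern:
            if i not in idx:
                raise SynthesisError(f"block references unknown item {i!r}")
            row[idx[i]] = True
        rows.extend([row] * count)
    if not rows:
        raise SynthesisError("blocks describe an empty dataset")
    return TransactionDataset(items=tuple(items), matrix=np.vstack(rows))


# --------------------------------------------------------------------------
# Full instrument


def generate_prpwpq_like(
    profile: SyntheticProfile,
) -> tuple[TransactionDataset, LikertMatrix, dict]:
    """Full synthetic survey: binary items + Likert subscales + outcomes.

    Composes the three generators, appends the discretized outcomes (and any
    requested negated items) as extra transaction columns, and plants the
    profile's rules. When planting flips an outcome flag, the respondent's
    Likert rows are re-drawn in the band matching the final (some, severe)
    flag pair, so re-discretizing the returned Likert matrix reproduces the
    returned outcome columns. The manifest records every target alongside
    the statistics realized in the returned matrices.
    """
    ss = np.random.SeedSequence(profile.seed)
    n_sub = len(profile.subscale_specs)
    # one child seed per stochastic stage: binary items, each subscale,
    # each planted rule, and the post-plant Likert resync
    seeds = ss.spawn(2 + n_sub + len(profile.planted_rules))
    resync_seed = seeds[1 + n_sub + len(profile.planted_rules)]
    defs = {it.item_id: it for it in catalog.catalog_items()}
    binary = generate_binary_items(
        profile.n_respondents, profile.item_specs, seeds[0], definitions=defs
    )

    likert_blocks: list[LikertMatrix] = []
    outcomes: list[tuple[OutcomeSpec, np.ndarray]] = []
    outcome_specs: dict[str, OutcomeSpec] = {}
    for j, (name, k, some, severe) in enumerate(profile.subscale_specs):
        block = generate_likert_subscale(
            profile.n_respondents, k, some, severe, seeds[1 + j], item_prefix=name
        )
        likert_blocks.append(block)
        for prefix, thr in (("some", 2.0), ("severe", 3.0)):
            spec = OutcomeSpec(
                outcome_id=f"{prefix}_{name}",
                subscale_item_ids=block.item_ids,
                mean_threshold=thr,
                label=f"{prefix.capitalize()} {name}",
            )
            outcome_specs[spec.outcome_id] = spec
            outcomes.append((spec, discretize_outcome(block, spec)))

    likert = LikertMatrix(
        values=(
            np.column_stack([b.values for b in likert_blocks])
            if likert_blocks
            else np.zeros((profile.n_respondents, 0))
        ),
        item_ids=tuple(i for b in likert_blocks for i in b.item_ids),
    )

    dataset = build_transactions(binary, outcomes, profile.negation_ids)

    planted_stats = []
    n_rules = len(profile.planted_rules)
    for j, rule in enumerate(profile.planted_rules):
        before = {
            oid: dataset.column(oid).copy() for oid in dataset.consequent_ids
        }
        dataset = plant_rule(dataset, rule, seeds[1 + n_sub + j])
        _sync_outcome_implications(dataset)
        _resync_likert(
            dataset, likert, profile.subscale_specs, before, resync_seed
        )
        lhs_mask = np.ones(dataset.n_respondents, dtype=bool)
        for i in rule.lhs_item_ids:
            lhs_mask &= dataset.column(i)
        joint = lhs_mask & dataset.column(rule.rhs_outcome_id)
        planted_stats.append(
            {
                "lhs": sorted(rule.lhs_item_ids),
                "rhs": rule.rhs_outcome_id,
                "target_support": rule.target_support,
                "target_confidence": rule.target_confidence,
                "realized_support": joint.sum() / dataset.n_respondents,
                "realized_confidence": float(joint.sum() / lhs_mask.sum()),
                "n_lhs": int(lhs_mask.sum()),
                "n_rule": int(joint.sum()),
            }
        )

    manifest = {
        "seed": profile.seed,
        "n_respondents": dataset.n_respondents,
        "n_dropped": dataset.n_dropped,
        "item_targets": {i: p for i, p in profile.item_specs},
        "item_realized": {
            i: float(dataset.column(i).mean())
            for i, _ in profile.item_specs
        },
        "outcome_targets": {
            f"some_{name}": some
            for name, _, some, _ in profile.subscale_specs
        }
        | {
            f"severe_{name}": severe
            for name, _, _, severe in profile.subscale_specs
        },
        "outcome_realized": {
            oid: float(dataset.column(oid).mean())
            for oid in dataset.consequent_ids
        },
        "planted_rules": planted_stats,
        "fingerprint": dataset.fingerprint(),
    }
    return dataset, likert, manifest


def _sync_outcome_implications(dataset: TransactionDataset) -> None:
    """Keep severe_<name> => some_<name> after planting edits a flag."""
    ids = dataset.item_ids
    for oid in dataset.consequent_ids:
        if oid.startswith("severe_"):
            some_id = "some_" + oid[len("severe_") :]
            if some_id in ids:
                j_some = ids.index(some_id)
                j_sev = ids.index(oid)
                dataset.matrix[:, j_some] |= dataset.matrix[:, j_sev]


def _resync_likert(
    dataset: TransactionDataset,
    likert: LikertMatrix,
    subscale_specs: Sequence[tuple[str, int, float, float]],
    before: Mapping[str, np.ndarray],
    seed: np.random.SeedSequence,
) -> None:
    """Re-draw Likert rows whose outcome flags were changed by planting."""
    rng = np.random.default_rng(seed)
    for name, k, _, _ in subscale_specs:
        some_id, severe_id = f"some_{name}", f"severe_{name}"
        if some_id not in dataset.item_ids:
            continue
        some = dataset.column(some_id)
        severe = dataset.column(severe_id)
        changed = (some != before[some_id]) | (severe != before[severe_id])
        rows = np.flatnonzero(changed)
        if rows.size == 0:
            continue
        bands = np.where(severe[rows], 2, np.where(some[rows], 1, 0))
        sub_ids = tuple(f"{name}_{j + 1}" for j in range(k))
        _resample_bands(likert, sub_ids, rows, bands, rng)
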