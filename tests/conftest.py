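"""Shared fixtures: the ten-transaction worked example and block-design
datasets with a known survivor set of rules."""

from __future__ import annotations

import numpy as np
import pytest

from traumaprofiles import (
    ItemDefinition,
    TransactionDataset,
    build_transactions,
    dataset_from_blocks,
)


def make_items(antecedents, consequents=()):
    items = [
        ItemDefinition(item_id=i, label=i, role="antecedent", section="trauma")
        for i in antecedents
    ]
    items += [
        ItemDefinition(item_id=i, label=i, role="consequent", section="outcome")
        for i in consequents
    ]
    return tuple(items)


#: The ten-transaction worked example over items A, B and outcome O.
F1_TRANSACTIONS = (
    ("A", "O"),
    ("A", "O"),
    ("A", "O"),
    ("A", "B", "O"),
    ("A", "B"),
    ("A", "B"),
    ("B", "O"),
    ("O",),
    ("A", "O"),
    ("A",),
)


@pytest.fixture
def f1() -> TransactionDataset:
    items = make_items(["A", "B"], ["O"])
    return dataset_from_blocks(items, [(1, t) for t in F1_TRANSACTIONS])


def random_dataset(rng, n_items=8, n_rows=150, n_consequents=1):
    """Random independent binary dataset for differential tests."""
    ants = [f"i{k}" for k in range(n_items)]
    cons = [f"o{k}" for k in range(n_consequents)]
    items = make_items(ants, cons)
    p = rng.uniform(0.1, 0.9, size=n_items + n_consequents)
    matrix = rng.random((n_rows, n_items + n_consequents)) < p
    return TransactionDataset(items=items, matrix=matrix)


# ---------------------------------------------------------------------------
# Block-design datasets whose pruned rule set is known exactly by design.
#
# The "some anxiety" design reproduces the structure of five overlapping
# some-anxiety profiles from the survivor study: all share body aches; one
# antecedent is a proper subset of another (differing by the negated item),
# so pruning must keep both only because the longer rule is strictly more
# confident. Row blocks: three outcome-positive blocks carry the rule
# patterns; deflator blocks (outcome-negative) push every non-profile
# sub-antecedent below the confidence threshold while leaving every
# superset's confidence exactly equal to a profile's (hence pruned).

A, T, S, F, K, R, W = (
    "body_aches",
    "problems_travel",
    "lack_proper_security",
    "fear_of_death",
    "cannot_talk_freely",
    "losing_rights",
    "been_raped",
)
NR = "not_been_raped"

SOME_ANXIETY_PROFILES = (
    frozenset({A, T, S}),
    frozenset({A, T, F}),
    frozenset({A, K}),
    frozenset({A, K, NR}),
    frozenset({A, R, T}),
)

_SOME_BLOCKS = (
    # (count, endorsed items incl. been_raped status, outcome flag)
    (1700, (A, T, S, F, R, W), 1),
    (1600, (A, K), 1),          # been_raped = 0 -> carries the negated item
    (100, (A, K, W), 1),
    (148, (A, T, S, F, R, W), 0),
    (139, (A, K), 0),
    (25, (A, K, W), 0),
    (60, (A, S, F, R, W), 0),
    (60, (A, T, W), 0),
    (50, (A,), 0),
    (60, (T, S, F, R, W), 0),
    (500, (T, S, F, K, R), 0),
    (558, (W,), 0),
)


def some_anxiety_fixture() -> TransactionDataset:
    binary = dataset_from_blocks(
        make_items([A, T, S, F, K, R, W]),
        [(c, pat) for c, pat, _ in _SOME_BLOCKS],
    )
    flags = np.concatenate(
        [np.full(c, float(o)) for c, _, o in _SOME_BLOCKS]
    )
    return build_transactions(
        binary, [("some_anxiety", flags)], negation_ids=[W]
    )


SEVERE_ANXIETY_PROFILES = (
    frozenset({"backache", "problems_travel", "been_kidnapped"}),
    frozenset(
        {
            "lack_medical_facilities",
            "staying_away_from_relatives",
            "other_family_kidnapped",
        }
    ),
    frozenset(
        {"problems_using_hands_legs", "problems_keeping_clean", "losing_community"}
    ),
)


def severe_anxiety_fixture() -> TransactionDataset:
    item_ids = sorted(set().union(*SEVERE_ANXIETY_PROFILES))
    blocks: list[tuple[int, tuple, int]] = []
    for profile in SEVERE_ANXIETY_PROFILES:
        trio = tuple(sorted(profile))
        blocks.append((200, trio, 1))
        blocks.append((17, trio, 0))
        for j in range(3):
            pair = trio[:j] + trio[j + 1 :]
            blocks.append((30, pair, 0))
    used = sum(c for c, _, _ in blocks)
    blocks.append((5000 - used, (), 0))
    binary = dataset_from_blocks(
        make_items(item_ids), [(c, pat) for c, pat, _ in blocks]
    )
    flags = np.concatenate([np.full(c, float(o)) for c, _, o in blocks])
    return build_transactions(binary, [("severe_anxiety", flags)])
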