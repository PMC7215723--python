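"""Brute-force reference miner for differential testing.

Enumerates every admissible antecedent set by direct counting over the rows,
with no candidate generation, no bit packing and no shared code with the
level-wise miner. Rules are thresholded and pruned straight from the
definitions: a rule is redundant when *any* non-empty proper subset of its
antecedent predicts the same consequent with at least the same confidence,
whether or not that sub-antecedent itself passes the thresholds. (For rules
that pass both thresholds this is equivalent to pruning against passing
sub-rules only — a sub-antecedent at least as confident as a passing rule
passes the confidence threshold itself, and passes the support threshold by
anti-monotonicity — which the test suite verifies.)

Intentionally quadratic-ish and restricted to small item universes.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

from .dataset import TransactionDataset
from .mining import MiningConfig, MiningError, Rule, RuleSet, _resolve_config

#: Exhaustive enumeration stays tractable only for small item universes.
MAX_ORACLE_ITEMS = 16


def brute_force_oracle(
    dataset: TransactionDataset, config: MiningConfig
) -> RuleSet:
    """Mine by exhaustive enumeration; must equal ``mine_profiles`` exactly."""
    antecedents, consequents = _resolve_config(dataset, config)
    if len(antecedents) > MAX_ORACLE_ITEMS:
        raise MiningError(
            f"{len(antecedents)} antecedent items exceed the oracle bound "
            f"of {MAX_ORACLE_ITEMS}"
        )
    n = dataset.n_respondents
    if n == 0:
        raise MiningError("cannot mine an empty dataset")

    # one frozenset of endorsed item ids per respondent
    relevant = tuple(antecedents) + tuple(consequents)
    rows = [
        frozenset(i for i in relevant if bool(dataset.column(i)[r]))
        for r in range(n)
    ]

    def n_containing(itemset: frozenset[str]) -> int:
        return sum(1 for row in rows if itemset <= row)

    max_lhs = config.max_rule_length - 1
    lhs_counts: dict[frozenset[str], int] = {}
    for size in range(1, max_lhs + 1):
        for combo in combinations(antecedents, size):
            lhs_counts[frozenset(combo)] = n_containing(frozenset(combo))

    rules: list[Rule] = []
    conf: dict[tuple[str, frozenset[str]], Fraction] = {}
    for rhs in consequents:
        for lhs, n_lhs in lhs_counts.items():
            if n_lhs == 0:
                continue
            n_rule = n_containing(lhs | {rhs})
            conf[(rhs, lhs)] = Fraction(n_rule, n_lhs)
            # inclusive thresholds, with the same float tolerance the
            # contract states for the main miner
            if n_rule >= config.min_support * n - 1e-12 and (
                n_rule / n_lhs >= config.min_confidence - 1e-12
            ):
                rules.append(
                    Rule(
                        lhs=lhs,
                        rhs=rhs,
                        support_lhs=n_lhs / n,
                        support_rule=n_rule / n,
                        confidence=n_rule / n_lhs,
                        n_rule=n_rule,
                        n_lhs=n_lhs,
                    )
                )

    # prune against every proper sub-antecedent, by definition
    kept = []
    for rule in rules:
        dominated = False
        for size in range(1, len(rule.lhs)):
            for combo in combinations(sorted(rule.lhs), size):
                sub = frozenset(combo)
                if (rule.rhs, sub) in conf and conf[(rule.rhs, sub)] >= conf[
                    (rule.rhs, rule.lhs)
                ]:
                    dominated = True
                    break
            if dominated:
                break
        if not dominated:
            kept.append(rule)

    kept.sort(key=Rule.sort_key)
    return RuleSet(
        rules=tuple(kept),
        config=config,
        dataset_fingerprint=dataset.fingerprint(),
        n_respondents=n,
    )
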