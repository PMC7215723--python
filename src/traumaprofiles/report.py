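"""Human-readable reports: rules grouped by consequent, prevalence appendix.

Support and confidence are displayed rounded to two decimals; serialized
rule files keep full precision.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .dataset import TransactionDataset, prevalence_table
from .mining import RuleSet


def _label(item_id: str, labels: Mapping[str, str] | None) -> str:
    if labels and item_id in labels:
        return labels[item_id]
    return item_id


def rule_line(rule, labels: Mapping[str, str] | None = None) -> str:
    lhs = ", ".join(_label(i, labels) for i in rule.lhs_sorted)
    rhs = _label(rule.rhs, labels)
    return (
        f"{{{lhs}}} => {{{rhs}}} "
        f"(support {rule.support_rule:.2f}, confidence {rule.confidence:.2f})"
    )


def summarize(ruleset: RuleSet) -> str:
    """One line per consequent: rule count and support/confidence ranges."""
    lines = []
    for rhs in ruleset.config.consequent_ids:
        rules = ruleset.for_consequent(rhs)
        if not rules:
            lines.append(f"{rhs}: 0 rules")
            continue
        supports = [r.support_rule for r in rules]
        confs = [r.confidence for r in rules]
        lines.append(
            f"{rhs}: {len(rules)} rule{'s' if len(rules) != 1 else ''}, "
            f"support {min(supports):.2f}-{max(supports):.2f}, "
            f"confidence {min(confs):.2f}-{max(confs):.2f}"
        )
    return "\n".join(lines)


def render_report(
    ruleset: RuleSet,
    prevalences: pd.DataFrame | None = None,
    labels: Mapping[str, str] | None = None,
    dataset: TransactionDataset | None = None,
) -> str:
    """Markdown document: one section per consequent, rules in canonical
    order, plus an optional prevalence appendix."""
    if prevalences is None and dataset is not None:
        prevalences = prevalence_table(dataset)
    if labels is None and prevalences is not None:
        labels = dict(zip(prevalences["item_id"], prevalences["label"]))

    cfg = ruleset.config
    out = [
        "# Trauma/stressor profiles",
        "",
        f"Mined at min support {cfg.min_support}, min confidence "
        f"{cfg.min_confidence}, max rule length {cfg.max_rule_length} "
        f"(n = {ruleset.n_respondents} respondents).",
        "",
    ]
    for rhs in cfg.consequent_ids:
        rules = ruleset.for_consequent(rhs)
        out.append(f"## Profiles for: {_label(rhs, labels)}")
        out.append("")
        if not rules:
            out.append(
                f"No rules meet the thresholds (support >= {cfg.min_support}, "
                f"confidence >= {cfg.min_confidence})."
            )
        else:
            for j, rule in enumerate(rules, 1):
                out.append(f"{j}. {rule_line(rule, labels)}")
        out.append("")

    if prevalences is not None:
        out.append("## Item prevalences")
        out.append("")
        out.append("| item | section | n | % |")
        out.append("|---|---|---:|---:|")
        for _, row in prevalences.iterrows():
            out.append(
                f"| {row['label']} | {row['section']} | {row['count']} "
                f"| {row['percent']} |"
            )
        out.append("")
    return "\n".join(out)
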