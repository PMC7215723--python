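"""Mine trauma/stressor profiles from a small hand-built dataset.

Ten respondents over two stressor items (A, B) and one outcome flag (O).
The miner keeps every rule whose joint support and confidence clear the
thresholds, then drops rules whose antecedent contains a simpler rule's
antecedent without being more confident.
"""

import traumaprofiles as tp

items = (
    tp.ItemDefinition(item_id="A", label="Stressor A", section="social"),
    tp.ItemDefinition(item_id="B", label="Stressor B", section="economic"),
    tp.ItemDefinition(
        item_id="O", label="Outcome flag", role="consequent", section="outcome"
    ),
)
transactions = [
    ("A", "O"), ("A", "O"), ("A", "O"), ("A", "B", "O"), ("A", "B"),
    ("A", "B"), ("B", "O"), ("O",), ("A", "O"), ("A",),
]
dataset = tp.dataset_from_blocks(items, [(1, t) for t in transactions])

config = tp.MiningConfig(
    min_support=0.1, min_confidence=0.3, consequent_ids=("O",)
)
all_rules = tp.generate_rules(dataset, config)
ruleset = tp.mine_profiles(dataset, config)

print("all rules passing the thresholds:")
for rule in all_rules:
    print(" ", tp.rule_line(rule))
print("after redundancy pruning:")
for rule in ruleset.rules:
    print(" ", tp.rule_line(rule))
print(
    "\n{A, B} => {O} was pruned: {A} alone predicts O with confidence "
    "0.62 >= 0.33, so the longer antecedent adds complexity without accuracy."
)
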