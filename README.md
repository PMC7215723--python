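# traumaprofiles

Association-rule profiles of traumas and stressors that predict
psychopathology in disaster-survivor questionnaire data.

Practitioners entering a post-disaster setting need to know *which
combinations* of traumatic experiences and daily stressors mark the
survivors most at risk of anxiety or depression. Regression-style analyses
that collapse stressors into composite scores cannot answer that question,
and network or cluster analyses are hard for field teams to run and read.
Association rule learning gives interpretable answers directly: rules of the
form

```
{body aches, problems with travel, lack of proper security} => {some anxiety}
```

read as "respondents reporting all three stressors also report at least some
anxiety, with quantified frequency and accuracy". This package implements
that pipeline end to end for questionnaire data such as the Penn/RESIST/
Peradeniya War Problems Questionnaire (PRPWPQ): 106 binary trauma/stressor
items plus anxiety and depression symptom subscales rated 1–4.

## Method

Each respondent is a binary *transaction* over the item set `I = L ∪ R`,
where `L` holds the trauma/stressor items (optionally including configured
logical complements such as "not been raped") and `R` holds binary outcome
flags obtained by discretizing Likert subscale means: *some* symptoms when
the mean is ≥ 2 ("a little bit"), *severe* when it is ≥ 3 ("quite a bit"),
both inclusive. For a rule `LHS ⟹ RHS` with `LHS ⊆ L`, `RHS ∈ R`:

- **support** = |{d ∈ D : LHS ∪ RHS ⊆ d}| / |D| — the fraction of
  respondents endorsing every antecedent item *and* the outcome;
- **confidence** = support(LHS ∪ RHS) / support(LHS) — the rule's
  conditional accuracy.

Rules must satisfy `support ≥ ϑ`, `confidence ≥ ε` (both inclusive) and
`|LHS| + 1 ≤ 5`. Frequent antecedents are found with the Apriori algorithm
(level-wise search; a candidate is counted only when all of its proper
subsets are frequent, justified by the anti-monotonicity of support), using
bit-packed row masks with vectorised popcounts. Finally, *redundant* rules
are pruned: a rule is dropped when a rule with the same consequent and a
non-empty proper subset of its antecedent reaches at least the same
confidence, so every reported profile is minimal for its accuracy.

Because survey microdata of this kind is rarely shareable, the package
includes a first-class synthetic generator: independent Bernoulli items at
configured marginal prevalences, Likert subscales drawn from a three-band
severity mixture so the discretized flags hit target prevalences, and a
rule-planting operation that minimally edits rows to realize a chosen
support/confidence — giving a known ground truth for recovery tests. A
brute-force mining oracle (pure enumeration, no shared code with the miner)
backs the differential test suite.

## Worked example

`python examples/planted_rule_recovery.py` plants a three-stressor rule at
support 0.33 / confidence 0.92 into 2,000 synthetic respondents whose
outcome flag otherwise holds at its 0.671 base rate, then mines at
thresholds ϑ = 0.3, ε = 0.9:

```
planted: support 0.3300 (target 0.33), confidence 0.9205 (target 0.92)
mined 1 rule(s) at thresholds (0.3, 0.9):
  {Body aches, Lack of proper security, Problems with travel} => {Some anxiety} (support 0.33, confidence 0.92)

Only the full three-item antecedent survives: every sub-profile falls below
confidence 0.9 because rows outside the planted block carry the outcome at
its 0.67 base rate.
```

The planted statistics are exact count ratios recomputed from the realized
matrix (660 of 717 antecedent-complete respondents flagged ⇒ confidence
0.9205), and pruning removes nothing here because no simpler antecedent
reaches the confidence bound. See also `examples/mine_profiles.py` (how
pruning discards a redundant two-item rule on a ten-respondent example) and
`examples/simulate_survey.py` (the full 337 × 110 instrument simulation).

## Command line

```
traumaprofiles simulate --n 337 --seed 42 --out synth.csv
traumaprofiles mine --input synth.csv --schema synth.csv.schema.yaml \
    --min-support 0.3 --min-confidence 0.9 --consequent some_anxiety \
    --output rules.json
traumaprofiles report --rules rules.json --schema synth.csv.schema.yaml
traumaprofiles prevalence --input synth.csv --schema synth.csv.schema.yaml
```

Per-outcome threshold overrides are accepted as
`--consequent severe_depression=0.01,0.9` (rare outcomes need lower support
thresholds). An empty rule set is reported explicitly and exits 0.

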