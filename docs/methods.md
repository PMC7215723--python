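# Methods

## Data model

A survey instrument is described by a `Schema`: binary trauma/stressor items
(`role=antecedent`), Likert symptom items rated 1 (*not at all*) to 4
(*extremely*), and outcome definitions that discretize a subscale mean into
a binary flag (`role=consequent`). The mining input is a
`TransactionDataset` — a respondents × items boolean matrix whose columns
are the antecedent items (plus any configured negated complements) followed
by the outcome flags. With the full 106-item bank and two subscales each
contributing a "some" and a "severe" flag, a respondent's transaction is a
110-long binary vector.

### Discretization

A respondent is flagged for an outcome when the mean of their non-missing
subscale answers is at or above the threshold: 2.0 for "some" symptoms, 3.0
for "severe". Both comparisons are inclusive, so a respondent averaging
exactly "a little bit" is flagged — the flags are screening indicators, not
clinical diagnoses, and no validated clinical cut-offs exist for this
instrument; the thresholds are user-settable parameters.

Missing answers are never imputed. The mean is taken over answered items,
and a respondent who answered fewer than `min_answered_fraction` (default
0.8) of a subscale is flagged *missing* and excluded from mining when
transactions are assembled; the drop count is recorded on the dataset.
Imputing symptom severities would manufacture outcome flags from no data,
which is worse for a screening use-case than losing a respondent.

### Negated items

Observed profiles occasionally involve the *absence* of an experience
("not been raped"). Negations are supported as explicitly configured derived
items — a `polarity=negated` column equal to the complement of its base
item — and are off by default, since negating all 106 items would silently
double the search space and flood the output with high-support absence
items.

## Mining

For a rule `LHS ⟹ RHS` (single consequent; observed profiles have
exactly one):

- support(X) = fraction of respondents endorsing every item in X;
- the support threshold ϑ applies to `support(LHS ∪ RHS)` — the count of
  respondents who answered yes to *all* variables of the rule, which is
  also what a practitioner cares about (how many at-risk respondents the
  profile actually captures). This automatically enforces
  `support(LHS) ≥ ϑ`;
- confidence = `support(LHS ∪ RHS) / support(LHS) ≥ ε`;
- `|LHS| + 1 ≤ max_rule_length`, default 5 (so at most four antecedents).

Both thresholds are inclusive (≥). Internally each count is an integer and
confidence is an exact count ratio; threshold comparisons use a 1e-12
absolute tolerance so that a fraction equal to the threshold is never lost
to floating-point representation.

The search is a standard Apriori level-wise scan, run per consequent over
antecedent itemsets with frequency measured on `support(X ∪ {r})` — a valid
anti-monotone measure for fixed `r`, which keeps the lattice restricted to
the antecedent items instead of the full item universe. Candidate k-sets
are generated by joining (k−1)-sets sharing a prefix and are counted only
if every proper subset is frequent; this obligation is observable through a
counting trace and verified in the tests. Row sets are kept as bit-packed
masks (`numpy.packbits`) and counted with vectorised popcounts, which keeps
the full-instrument run at permissive thresholds (ϑ = 0.01 on 337 × 110)
around a second.

### Redundancy pruning

A rule `LHSj ⟹ Rk` is removed when some rule `LHSi ⟹ Rk` in the mined set
has `LHSi ⊂ LHSj` (non-empty, proper) and confidence at least as high.
Comparisons use exact integer cross-multiplication
(`n_rule_i · n_lhs_j ≥ n_rule_j · n_lhs_i`), so ties prune deterministically
in favour of the shorter antecedent. Restricting comparisons to
threshold-passing sub-rules is equivalent to comparing against *all* proper
sub-antecedents: a sub-antecedent at least as confident as a passing rule
passes ε by that very inequality and passes ϑ by anti-monotonicity. The
test suite verifies this equivalence on random instances rather than taking
the argument on faith.

### Ordering and determinism

Rule sets are ordered by descending confidence, then descending rule
support, then lexicographically by sorted antecedent ids. Identical input
and configuration produce byte-identical serialized output; rule files
carry full floating precision while reports display two decimals.

### Oracle

`brute_force_oracle` re-mines by exhaustive enumeration over every
antecedent subset (direct row counting on Python sets, pruning from the
definition against all sub-antecedents) and must equal `mine_profiles`
exactly. It shares no counting or candidate-generation code with the miner
and refuses more than 16 antecedent items.

## Synthetic data

The generator emulates the structure of a survivor survey at the study's
scale — n = 337 respondents by default, 106 binary items at the observed
marginal prevalences (built into `catalog`), and anxiety/depression
subscales whose discretized flags match the observed outcome prevalences
(67.1 / 21.4 / 63.8 / 15.1 percent).

- **Binary items** are independent Bernoulli draws. Only marginals are
  available for the instrument, so no inter-item correlation structure is
  fabricated; dependencies enter exclusively through planted rules.
- **Likert subscales** draw a latent severity band per respondent —
  mean < 2, mean in [2, 3), mean ≥ 3 — with probabilities
  (1 − some, some − severe, severe), then emit k integer scores uniform
  over the compositions whose sum lands in the band (sampled exactly via a
  composition-count table). A band mixture is used instead of a continuous
  latent-normal model because only the two threshold prevalences are
  known, and the mixture hits both by construction. Subscale length
  k = 5 by default; the instrument's true subscale lengths are not part of
  the catalog, and k only affects within-band granularity, not the flag
  prevalences.
- **Planting** edits the minimum number of cells needed: it first fixes the
  number of antecedent-complete rows (recruiting rows missing the fewest
  antecedent items, or demoting surplus rows by clearing one cell), then
  flips outcome flags among complete rows to the target count. Realized
  support and confidence are exact integer ratios within rounding of the
  targets; a confidence target of 1.0 is realized exactly. Infeasible
  targets (support above confidence, or a sample too small to host the
  antecedent block) raise an error rather than being clipped.
- In the full-instrument generator, planting operates on the outcome flag
  columns; affected respondents' Likert rows are then re-drawn in the band
  implied by their final (some, severe) flag pair, and the severe ⇒ some
  implication is restored, so the returned Likert matrix re-discretizes to
  exactly the returned flags.
- Seeds are explicit everywhere (`numpy.random.SeedSequence` children per
  generation stage); there is no global random state. Missing-data
  simulation is not implemented.

What passing tests on this data do *not* show: real questionnaire items are
correlated (economic stressors co-occur; symptom flags correlate with most
stressors), so rule counts and confidences on real data will differ from
the independent-items baseline. The generator's purpose is ground truth for
the machinery — calibration of marginals and exact recovery of planted
dependencies — not epidemiological realism.

## Numerical and design notes

- Percentages in prevalence tables round half-up to one decimal (the
  convention of printed survey tables); rule statistics in reports use
  standard 2-decimal float formatting.
- `min_count` for a support threshold is `max(1, ceil(ϑ·n − 1e-12))`: an
  itemset passes iff its count/n is at least ϑ, and empty antecedents are
  never considered.
- The CLI mines each requested consequent in its own run (equivalent to a
  joint run, since consequents do not interact) and accepts per-consequent
  threshold overrides — rare outcomes such as severe depression need a much
  lower ϑ (0.01–0.03) than common ones (0.3) for any rule to clear the
  respondent-count bar.
- Degenerate inputs: an empty dataset, a dataset without consequent-role
  items, zero outcome columns, unknown item ids, Likert values outside 1–4
  and unparseable binary cells are all hard errors carrying the offending
  row/column or id.

## Known limitations

- Independent-Bernoulli items understate the redundancy pruning load seen
  on correlated real data, where many overlapping profiles pass thresholds.
- Planting several rules that share antecedent items edits overlapping row
  sets; targets are realized in planting order, and a later rule can
  disturb an earlier rule's realized statistics. Plant disjoint or nested
  rules when exact multi-rule ground truth is needed.
- The miner enumerates frequent antecedent sets exhaustively up to the
  length cap; with very low ϑ on wide, highly correlated data the frequent
  lattice can grow combinatorially. The fixed-consequent constraint and the
  cap at four antecedents keep instrument-scale runs fast.
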