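# mcda-prefs

Multi-criteria decision analysis (MCDA) for ranking competing intervention
options by stakeholder preference, with pairwise preference elicitation and
Monte Carlo uncertainty analysis.

The package was built around a concrete decision problem: which of four
nudge-intervention types — Computerised Interface, Built Environment,
Written Communication, Face-to-Face Interactions — should NHS hospital
quality-improvement teams take forward to optimise medication use?  Each
intervention is judged on ten implementation criteria (patient needs, cost,
adaptability, ...), each measured on a three-point quality ladder, and the
criteria are weighted by the elicited preferences of 356 quality improvers.
All of that study's data (criteria, performance matrix, group preference
values) ships as plain-CSV fixtures, and every component generalises to
arbitrary criteria, level ladders and alternatives.

## The model

An alternative *j* is scored by the additive value function

```
V_j = Σ_i  S_ij · W_i
```

where *W_i* is the weight of criterion *i* (percent, Σ W_i = 100) and
*S_ij* the within-criterion score of *j*'s assigned performance level.  In
the tabulated form used here, each (criterion, level) carries a part-worth
value with worst level = 0 and best level = *W_i*, so *V_j* is the plain sum
of the assigned level values and the best conceivable alternative scores
100.  An unweighted companion model codes levels 1..L and sums the codes.

Three further components surround the scoring:

- **PAPRIKA elicitation** (`mcda.paprika`): weights are derived from a
  respondent's answers to adaptive pairwise trade-off questions — two
  hypothetical alternatives differing on exactly two criteria, each better
  on one, so neither dominates.  Answers propagate by transitivity over the
  implied value increments; unresolved questions are chosen to maximise
  expected eliminations; the respondent's level values are then fitted by a
  two-stage linear programme (maximise the common preference margin, then
  minimise total value mass), and a group value system is the mean across
  respondents.  An exhaustive mode ranks *every* undominated pair of full
  profiles for small problems, pinning down the complete profile ranking.
- **Probabilistic sensitivity analysis** (`mcda.psa`): Monte Carlo over
  Dirichlet-distributed weights (mean = elicited weights, concentration
  kappa), gamma-distributed score contributions (mean-preserving,
  coefficient of variation cv), or both; reports per-alternative means,
  95% percentile intervals and first-rank acceptability.
- **Synthetic respondents** (`mcda.synthetic`): latent additive value
  functions plus a logistic choice rule stand in for the original survey
  population, so elicitation, aggregation and their error behaviour are
  testable end to end without the (undeposited) raw survey data.

## Worked example

```
python examples/score_interventions.py
```

```
Intervention type        unweighted (/30)  weighted (/100)
Computerised Interface     25        First    83.8    First
Built Environment          24       Second    79.6   Second
Written Communication      22  Joint third    71.6    Third
Face-to-Face               22  Joint third    67.8   Fourth
```

The unweighted model (criteria equally important) ties Written
Communication and Face-to-Face at 22 of 30; weighting by the elicited
preferences breaks the tie (71.6 vs 67.8 of 100) because stakeholders put
more value on low cost and available resources — where Written
Communication performs well — than on face-to-face strengths such as
evidence and organisational visibility.  The most important criterion is
whether an intervention addresses patient needs (17.6% of the total
weight); the least is the planning required to implement it (7.8%).

`examples/uncertainty_analysis.py` propagates score and weight uncertainty
(1000 iterations each scenario) and shows the ranking is stable: the
Computerised Interface wins 85% of iterations under score noise and 100%
under weight noise.  `examples/elicit_preferences.py` simulates a small
respondent cohort and recovers the group weights from their pairwise
answers; `examples/custom_problem.py` runs the pipeline on a freshly
generated problem, including the red/amber/green matrix view.

A thin CLI wraps the same functions:

```
mcda replicate --psa          # re-derive the packaged study end to end
mcda score --criteria c.csv --matrix m.csv --values v.csv --out scores.json
mcda psa --criteria c.csv --matrix m.csv --values v.csv --scenario both
mcda simulate cohort --n 50 --center v.csv --criteria c.csv --out j.jsonl
mcda elicit replay --criteria c.csv --judgements j.jsonl --out group.csv
mcda validate                 # cross-check the packaged fixtures
```

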