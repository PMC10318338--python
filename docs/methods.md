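# Methods

## The decision model

The package implements a value-measurement MCDA.  A decision problem is a
set of criteria, each with an ordered ladder of qualitative performance
levels (worst first), a performance matrix assigning every alternative one
level per criterion, and a value system giving each (criterion, level) a
part-worth in percent.  Value systems are normalised so each criterion's
worst level is worth 0, its best level is worth the criterion weight
`W_i`, and weights sum to 100; an alternative's total is then the plain sum
of its assigned level values, `V_j = Σ_i S_ij · W_i` in the usual additive
notation, with 100 the best conceivable score.  The companion unweighted
model codes levels 1..L and sums the codes; it represents the
"all criteria equally important" baseline.

Ranking is dense over tied groups: equal totals (within a configurable
tolerance, default 0 — exact equality) share a rank rendered
"Joint *n*th", and the next distinct total takes the next consecutive
ordinal.  Fixture arithmetic is done in `decimal.Decimal` end to end, so
the published one-decimal totals are reproduced bit-exactly rather than to
within binary-float drift; computed (float-valued) value systems flow
through the same code paths.

## Packaged study fixtures

The packaged decision problem is the NHS medication-optimisation study:
four nudge-intervention types against ten implementation criteria drawn
from the Consolidated Framework for Implementation Research, with group
preference values elicited from 356 quality improvers.  The published
tables carry two internal inconsistencies, which we preserve rather than
repair, following the principle that the score table — whose columns sum
exactly to the published totals — is the reproducible source:

- the qualitative matrix lists Built Environment / available resources at
  the top level while the score table scores it at the middle level (2
  unweighted, 4.4 weighted);
- the score table's unweighted half puts every alternative at the middle
  patient-needs level (code 2) while its weighted half credits each the
  top-level value 17.6 (the middle value would be 10.4, and no single level
  assignment reproduces both published totals).

The package therefore ships two replication matrices (differing only on
the patient-needs row) plus the qualitative matrix verbatim, and
`validate_paper_fixtures()` reports exactly these two discrepancies as
warnings.  Similarly, the published weight table prints "Medium resources"
as 4.5 where the score table uses 4.4; the packaged value table follows the
score table.  Replication refuses to run on altered fixtures (SHA-256
checksums).

## Preference elicitation (PAPRIKA)

Weights are elicited from pairwise trade-off questions: two hypothetical
alternatives defined on exactly two criteria, each strictly better on one,
so neither dominates and the answer reveals which single-criterion upgrade
the respondent values more.  For criteria with `L` levels there are
`C(L,2)²` such questions per criterion pair — 9 for two three-level
criteria, 405 for the study's 10 × 3 design.

Internally each question compares two value *increments* (criterion, lower
level → higher level).  The session keeps a reflexive-transitive relation
over all increments, seeded with the structural facts that a wider upgrade
strictly exceeds any upgrade it properly contains (levels are strictly
ordered), and updates it incrementally after each answer; a pair is
resolved when the relation orders it (either way, or ties it).  The next
question is the unresolved pair whose two strict answers would resolve the
most other unresolved pairs, ties broken by enumeration order — on the
10 × 3 study design a noiseless respondent answers roughly 120 of the 405
questions explicitly.  Answers that imply a strict-preference cycle raise
an inconsistency error carrying a shortest witness cycle; inconsistent
respondents are rejected, not repaired.

Two-criterion questions cannot determine how a gain spread over three or
more criteria trades off against a concentrated one.  For small problems
(up to ~2000 full profiles) an exhaustive mode therefore continues to
undominated pairs of *full* profiles — the "potentially all pairwise
rankings" idea — propagating each answer to every profile pair with the
same difference pattern (additivity: common levels cancel) and closing
under transitivity, in stages of increasing question width.  With it, a
noiseless respondent's complete profile ranking is recovered exactly; the
large-problem survey emulation keeps two-criterion questions, as the
original survey did.

Level values are fitted per respondent by a two-stage linear programme
(scipy's HiGHS/`linprog`): values are non-negative, non-decreasing within
each criterion with a strict step of at least the margin `m` between
consecutive levels, every elicited strict preference must hold with margin
`m`, indifferences hold exactly, and best levels sum to 100.  Stage one
maximises `m` (a Chebyshev-centre-like choice that keeps the solution away
from the constraint boundary); stage two fixes `m` and minimises the total
value mass, making the solution unique and deterministic.  The margin floor
`ε` defaults to 1e-3 on the 0–100 scale, far below reporting resolution;
scaling `ε` leaves all fitted pairwise orders unchanged.  Ordinal answers
bound the value vector to a polytope, not a point, so the fit carries an
irreducible positioning error (a few points per weight for loose
two-criterion question sets, under one point at the exhaustive information
limit); group aggregation averages much of it away.  Group values are the
arithmetic means of level values across respondents, weights the mean
best-level values — means, matching the study's "mean preference values"
aggregation (medians were the plausible alternative; means keep the
best-level sum at exactly 100 by linearity).

## Synthetic respondents

The original survey responses were never deposited, so the generator
emulates them.  A synthetic respondent holds a latent value system and
answers a question with probability `logistic(β·Δ)` of choosing the
left profile, `Δ` being the latent value difference; `β = ∞` is a
deterministic truth-teller (exact ties answered "indifferent"), `β = 0` a
coin flip.  The logistic rule is the standard single-knob discrete-choice
noise model; the study reports nothing about respondent error, so `β` is a
free simulation parameter.  Cohorts draw each respondent's weight vector
from a Dirichlet centred on a reference value system with concentration
`κ_pop` (default 200, giving a few points of between-respondent spread —
the study reports no respondent-level variance to calibrate against) and
rescale the centre's within-criterion ladder to the drawn weight.  Noisy
sessions that turn out cyclic are rejected and resampled (bounded
retries), mirroring the exclusion of inconsistent respondents.

What passing the recovery tests shows: the pipeline inverts its own
generative model — latent additive values, logistic noise, Dirichlet
dispersion — at the study's scale (50 respondents recover the group
weights to well under 2 points per criterion).  Real respondents need not
follow an additive model or logistic noise, may answer path-dependently or
inattentively, and the real survey's proprietary question-selection rule
is unknown; none of that is emulated, so the tests validate the machinery,
not the original survey's external validity.

## Probabilistic sensitivity analysis

Per iteration the weighted totals are recomputed from perturbed inputs and
the winner recorded; results are means, equal-tailed 2.5–97.5 percentile
intervals (the published report says "95% CI" without a method), and
first-rank acceptability.  Weight uncertainty draws the weight vector from
`Dirichlet(κ · W/100)` — mean equal to the elicited weights, so expected
totals equal deterministic totals — and rescales each criterion's level
values proportionally.  Score uncertainty replaces each nonzero
contribution `c` by a gamma draw with mean `c` and standard deviation
`cv·c` (shape `1/cv²`, scale `c·cv²`); zeros stay exactly zero.  The
combined scenario applies the weight rescale first, then gamma noise on
the rescaled contributions.  Gamma noise is applied to the weighted
contributions (not the 1–3 ordinal codes), keeping all scenarios on one
scale.

Neither the Dirichlet concentration nor the gamma dispersion used in the
original analysis is recoverable from its report ("the means of observed
data were used as parameters" fixes only the mean), so `κ` (default 100)
and `cv` (default 0.1) are explicit calibration knobs chosen to give
interval widths of the same order as the published ones; PSA results are
therefore read as rank-order statements — the published per-scenario means
and the "chosen 78 times out of 100" figure are matched qualitatively
(same winner, same rank order), not numerically.  First-rank ties within
an iteration are broken uniformly at random from the iteration's RNG
stream; all results are bit-reproducible given the seed.

## Numerical and design choices

- Exact `Decimal` addition for fixture scoring; floats elsewhere.
- Dense tie-aware ranking with tolerance 0 by default; "Joint third" with
  no subsequent "Fourth" follows dense (not competition) ranking.
- Unweighted coding is `rank + 1` (1 = worst), matching the published
  1/2/3 cells.
- The closure treats nested same-criterion increments as strictly ordered;
  with two-level criteria an empty judgement set closes to the reflexive
  identities only.
- Question-order tie-breaks and the question enumeration itself are
  lexicographic in (criterion pair, level indices), so sessions are
  deterministic given the answer source.
- Sizes used by the shipped checks, chosen to exercise each property at
  the smallest scale where it is informative: closure-vs-oracle on all
  instance shapes up to 3 criteria × 3 levels; complete-ranking recovery
  at 3 × 3 (27 profiles, 351 pairs); cohort recovery at n = 50 on the
  10-criterion study design; PSA at the study's 1000 iterations.

## Known limitations

- The elicitation's LP point estimate is one defensible choice inside the
  feasibility polytope; bootstrap or Bayesian uncertainty for fitted
  values is not implemented.
- The exhaustive session is exponential in the number of criteria and is
  guarded accordingly; large problems get two-criterion questions only.
- Gamma perturbation can push an iteration's total above 100; totals are
  not truncated or renormalised (whether the original analysis did is
  unstated).
- RAG rendering is defined only for three-level ladders, by construction
  of the red/amber/green convention.
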