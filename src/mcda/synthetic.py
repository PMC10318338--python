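"""Synthetic survey respondents and random decision-problem instances.

The real elicitation data behind the packaged group weights (356 NHS quality
improvers answering adaptive trade-off questions) was never deposited, so
this module emulates it: each synthetic respondent carries a latent additive
value system and answers each two-criterion question with a logistic choice
rule,

    P(choose left) = 1 / (1 + exp(-beta * (V(left) - V(right)))),

where beta is an inverse temperature — beta = inf is a deterministic
truth-teller (exact ties answered "indifferent"), beta = 0 a coin flip.
Cohorts disperse respondents around a centre value system by drawing each
respondent's criterion weights from a Dirichlet concentrated on the centre
weights and scaling the centre's within-criterion value ladder to the drawn
weight.

Random problem instances (criteria, matrix, value system) for property tests
are generated constructively valid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import (
    Criterion,
    PerformanceLevel,
    PerformanceMatrix,
    ValidationError,
    ValueSystem,
)
from .paprika import (
    ElicitationSession,
    ExhaustiveSession,
    InconsistencyError,
    JudgementSet,
    Profile,
)


@dataclass
class RespondentSpec:
    """Latent truth of one synthetic respondent."""

    true_values: ValueSystem
    beta: float = math.inf  # inverse temperature of the logistic choice rule
    respondent_id: str = "r0"

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValidationError("choice-noise beta must be >= 0")

    def profile_value(self, profile: Profile) -> float:
        return float(
            sum(float(self.true_values.value(cid, label)) for cid, label in profile.items())
        )


@dataclass
class CohortSpec:
    """A population of synthetic respondents around a centre value system."""

    n: int
    center: ValueSystem
    kappa_pop: float = 200.0  # Dirichlet concentration of respondent weights
    beta: float = math.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("cohort size must be >= 1")
        if not self.kappa_pop > 0:
            raise ValidationError("kappa_pop must be > 0")


def answer_question(
    spec: RespondentSpec, left: Profile, right: Profile, rng: np.random.Generator
) -> str:
    """The respondent's choice for one question: "left", "right" or
    "indifferent" (the latter only from a truth-teller facing an exact tie)."""
    delta = spec.profile_value(left) - spec.profile_value(right)
    if math.isinf(spec.beta):
        if delta > 0:
            return "left"
        if delta < 0:
            return "right"
        return "indifferent"
    p_left = 1.0 / (1.0 + math.exp(-spec.beta * delta))
    return "left" if rng.random() < p_left else "right"


def simulate_session(
    spec: RespondentSpec,
    criteria: Sequence[Criterion],
    rng: np.random.Generator | None = None,
    on_inconsistent: str = "resample",
    max_retries: int = 10,
    exhaustive: bool = False,
) -> JudgementSet:
    """Run the adaptive question loop to exhaustion for one respondent.

    With ``exhaustive=True`` the session continues past two-criterion
    questions until every undominated pair of *full* profiles is ranked
    (practical for small instances only), which is what pins down the
    respondent's complete profile ranking.

    A truth-teller (beta = inf) is always consistent.  Noisy respondents can
    contradict themselves; by default the whole session is rejected and
    resampled (bounded retries), mirroring the exclusion of inconsistent
    respondents from a real survey — pass ``on_inconsistent="raise"`` to get
    the :class:`~mcda.paprika.InconsistencyError` instead.
    """
    if on_inconsistent not in ("resample", "raise"):
        raise ValidationError(f"invalid on_inconsistent mode {on_inconsistent!r}")
    rng = rng if rng is not None else np.random.default_rng(0)
    last_error: InconsistencyError | None = None
    attempts = max_retries + 1 if on_inconsistent == "resample" else 1
    for _ in range(attempts):
        session = ExhaustiveSession(criteria) if exhaustive else ElicitationSession(criteria)
        try:
            while True:
                q = session.next_question()
                if q is None:
                    break
                left, right = q
                choice = answer_question(spec, left, right, rng)
                session.record(left, right, choice, spec.respondent_id)
        except InconsistencyError as err:
            last_error = err
            continue
        return JudgementSet(
            respondent_id=spec.respondent_id,
            judgements=session.judgements,
            provenance="simulated",
        )
    raise InconsistencyError(
        f"respondent {spec.respondent_id!r} stayed inconsistent over "
        f"{attempts} attempt(s)",
        witness=last_error.witness if last_error else [],
    )


def _scaled_respondent_values(
    center: ValueSystem, criteria: Sequence[Criterion], weights: np.ndarray
) -> ValueSystem:
    """Centre value ladder rescaled per criterion to the drawn weights
    (weights on the 0-100 scale, summing to 100)."""
    values: dict[tuple[str, str], float] = {}
    for crit, w in zip(criteria, weights):
        center_w = float(center.weight(crit.id))
        for lv in crit.levels:
            base = float(center.value(crit.id, lv.label))
            values[(crit.id, lv.label)] = base / center_w * float(w) if center_w else 0.0
    return ValueSystem(level_values=values)


def generate_cohort(
    cohort: CohortSpec, criteria: Sequence[Criterion]
) -> list[JudgementSet]:
    """Simulate ``cohort.n`` independent respondents; reproducible by seed."""
    rng = np.random.default_rng(cohort.seed)
    center_w = np.array([float(cohort.center.weight(c.id)) for c in criteria])
    alpha = cohort.kappa_pop * center_w / center_w.sum()
    out = []
    for i in range(cohort.n):
        w = rng.dirichlet(alpha) * 100.0
        spec = RespondentSpec(
            true_values=_scaled_respondent_values(cohort.center, criteria, w),
            beta=cohort.beta,
            respondent_id=f"r{i}",
        )
        out.append(simulate_session(spec, criteria, rng))
    return out


def random_instance(
    n_alternatives: int,
    n_criteria: int,
    n_levels: int,
    seed: int = 0,
) -> tuple[list[Criterion], PerformanceMatrix, ValueSystem]:
    """A random, constructively valid decision problem.

    Criterion weights are a flat Dirichlet draw scaled to 100; intermediate
    level values are sorted uniforms within each criterion's weight; the
    matrix assigns each alternative a uniformly random level per criterion.
    """
    if n_alternatives < 1 or n_criteria < 1 or n_levels < 2:
        raise ValidationError("need >= 1 alternative, >= 1 criterion, >= 2 levels")
    rng = np.random.default_rng(seed)
    criteria = [
        Criterion(
            id=f"c{i + 1}",
            name=f"Criterion {i + 1}",
            domain_tag="synthetic",
            levels=tuple(
                PerformanceLevel(label=f"L{r}", rank=r) for r in range(n_levels)
            ),
        )
        for i in range(n_criteria)
    ]
    weights = rng.dirichlet(np.ones(n_criteria)) * 100.0
    level_values: dict[tuple[str, str], float] = {}
    for crit, w in zip(criteria, weights):
        inner = np.sort(rng.uniform(0.0, 1.0, size=n_levels - 2)) if n_levels > 2 else np.array([])
        ladder = np.concatenate([[0.0], inner, [1.0]]) * float(w)
        for lv, v in zip(crit.levels, ladder):
            level_values[(crit.id, lv.label)] = float(v)
    alternatives = [f"A{i + 1}" for i in range(n_alternatives)]
    assignments = {
        (alt, crit.id): crit.levels[int(rng.integers(n_levels))].label
        for alt in alternatives
        for crit in criteria
    }
    return (
        criteria,
        PerformanceMatrix(alternatives=alternatives, assignments=assignments),
        ValueSystem(level_values=level_values),
    )
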