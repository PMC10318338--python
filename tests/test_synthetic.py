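"""Synthetic respondents: choice rule, sessions, cohorts, random instances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcda.core import ValidationError, validate_matrix
from mcda.paprika import InconsistencyError, dump_judgements, solve_respondent_values
from mcda.paprika import aggregate_group
from mcda.synthetic import (
    CohortSpec,
    RespondentSpec,
    answer_question,
    generate_cohort,
    random_instance,
    simulate_session,
)


@pytest.fixture(scope="module")
def small_instance():
    return random_instance(1, 3, 3, seed=2)


def test_truth_teller_is_deterministic(small_instance):
    crits, _, vs = small_instance
    spec = RespondentSpec(true_values=vs, beta=math.inf)
    rng = np.random.default_rng(0)
    left = {"c1": "L2", "c2": "L0"}
    right = {"c1": "L0", "c2": "L2"}
    expect = "left" if float(vs.weight("c1")) > float(vs.weight("c2")) else "right"
    assert all(answer_question(spec, left, right, rng) == expect for _ in range(20))
    # exact tie -> indifferent
    assert answer_question(spec, left, left, rng) == "indifferent"


def test_zero_beta_is_a_coin_flip(small_instance):
    crits, _, vs = small_instance
    spec = RespondentSpec(true_values=vs, beta=0.0)
    rng = np.random.default_rng(1)
    left = {"c1": "L2", "c2": "L0"}
    right = {"c1": "L0", "c2": "L2"}
    freq = np.mean(
        [answer_question(spec, left, right, rng) == "left" for _ in range(10_000)]
    )
    assert freq == pytest.approx(0.5, abs=0.02)


def test_logistic_choice_frequency_matches_closed_form():
    """beta=2 with a value difference of 1 chooses left at logistic(2)."""
    from mcda.core import Criterion, PerformanceLevel, ValueSystem

    crits = [
        Criterion(id=c, name=c, domain_tag="",
                  levels=(PerformanceLevel("lo", 0), PerformanceLevel("hi", 1)))
        for c in ("a", "b")
    ]
    vs = ValueSystem(
        level_values={("a", "lo"): 0.0, ("a", "hi"): 50.5, ("b", "lo"): 0.0, ("b", "hi"): 49.5}
    )
    spec = RespondentSpec(true_values=vs, beta=2.0)
    rng = np.random.default_rng(2)
    left = {"a": "hi", "b": "lo"}
    right = {"a": "lo", "b": "hi"}  # delta = +1
    freq = np.mean(
        [answer_question(spec, left, right, rng) == "left" for _ in range(10_000)]
    )
    assert freq == pytest.approx(1 / (1 + math.exp(-2.0)), abs=0.01)


def test_negative_beta_rejected(small_instance):
    _, _, vs = small_instance
    with pytest.raises(ValidationError):
        RespondentSpec(true_values=vs, beta=-1.0)


def test_truth_teller_session_is_consistent_and_solvable(small_instance):
    crits, _, vs = small_instance
    js = simulate_session(
        RespondentSpec(true_values=vs), crits, np.random.default_rng(0),
        on_inconsistent="raise",
    )
    model = solve_respondent_values(js, crits)
    assert model.reproduces(js)


def test_symmetric_truth_yields_equal_fitted_weights():
    from mcda.core import Criterion, PerformanceLevel, ValueSystem

    crits = [
        Criterion(id=c, name=c, domain_tag="",
                  levels=(PerformanceLevel("lo", 0), PerformanceLevel("hi", 1)))
        for c in ("a", "b")
    ]
    vs = ValueSystem(
        level_values={("a", "lo"): 0.0, ("a", "hi"): 50.0, ("b", "lo"): 0.0, ("b", "hi"): 50.0}
    )
    js = simulate_session(RespondentSpec(true_values=vs), crits, np.random.default_rng(0))
    model = solve_respondent_values(js, crits)
    assert model.level_values[("a", "hi")] == pytest.approx(50.0, abs=1e-6)
    assert model.level_values[("b", "hi")] == pytest.approx(50.0, abs=1e-6)


def test_noisy_cohort_mostly_consistent(small_instance):
    """Moderate choice noise (beta=1) rarely produces cyclic respondents
    (seeded regression check, 30 sessions)."""
    crits, _, vs = small_instance
    rng = np.random.default_rng(42)
    ok = 0
    for i in range(30):
        spec = RespondentSpec(true_values=vs, beta=1.0, respondent_id=f"r{i}")
        try:
            simulate_session(spec, crits, rng, on_inconsistent="raise")
            ok += 1
        except InconsistencyError:
            pass
    assert ok >= 24  # >= 80%


def test_recovery_error_non_decreasing_with_noise(small_instance):
    """More choice noise never improves single-respondent weight recovery
    (fixed truth and seeds; equality allowed when no noisy flip occurs)."""
    crits, _, vs = small_instance
    errors = []
    for beta in (math.inf, 4.0, 1.0):
        errs = []
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            js = simulate_session(RespondentSpec(true_values=vs, beta=beta), crits, rng)
            m = solve_respondent_values(js, crits)
            errs.append(
                max(
                    abs(m.level_values[(c.id, c.best.label)] - float(vs.weight(c.id)))
                    for c in crits
                )
            )
        errors.append(np.mean(errs))
    assert errors[0] <= errors[1] + 1e-9 <= errors[2] + 2e-9


def test_degenerate_cohort_recovers_center(small_instance):
    """A single dispersion-free truth-teller, questioned to the information
    limit (every undominated full-profile pair), is recovered near-exactly.
    Ordinal answers bound values to a polytope rather than a point, so the
    tolerance reflects the polytope's width, not numerical error."""
    crits, _, vs = small_instance
    spec = RespondentSpec(true_values=vs, beta=math.inf)
    js = simulate_session(spec, crits, np.random.default_rng(0), exhaustive=True)
    model = solve_respondent_values(js, crits)
    agg = aggregate_group([model])
    for c in crits:
        assert float(agg.weight(c.id)) == pytest.approx(float(vs.weight(c.id)), abs=1.0)


def test_cohort_reproducible_by_seed(small_instance):
    crits, _, vs = small_instance
    spec = CohortSpec(n=2, center=vs, kappa_pop=100.0, beta=2.0, seed=7)
    a = generate_cohort(spec, crits)
    b = generate_cohort(spec, crits)
    assert dump_judgements(a) == dump_judgements(b)
    c = generate_cohort(
        CohortSpec(n=2, center=vs, kappa_pop=100.0, beta=2.0, seed=8), crits
    )
    assert dump_judgements(a) != dump_judgements(c)


@settings(max_examples=15, derandomize=True, deadline=None)
@given(
    n_alt=st.integers(1, 5),
    n_crit=st.integers(2, 6),
    n_lvl=st.integers(2, 4),
    seed=st.integers(0, 10_000),
)
def test_random_instances_are_constructively_valid(n_alt, n_crit, n_lvl, seed):
    crits, matrix, vs = random_instance(n_alt, n_crit, n_lvl, seed)
    assert validate_matrix(matrix, crits).ok
    vs.validate(crits)
    assert len(matrix.alternatives) == n_alt


def test_paper_shaped_instance():
    crits, matrix, vs = random_instance(4, 10, 3, seed=0)
    assert (len(matrix.alternatives), len(crits)) == (4, 10)
    assert validate_matrix(matrix, crits).ok


def test_instance_size_guards():
    with pytest.raises(ValidationError):
        random_instance(0, 2, 2, seed=0)
    with pytest.raises(ValidationError):
        random_instance(1, 1, 1, seed=0)
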