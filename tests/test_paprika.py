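"""Elicitation mechanics: pair enumeration, closure, adaptive loop, solver.

The closure is checked against an independent pure-Python Floyd-Warshall
oracle over the explicit increment graph, and the solver against exhaustive
comparison of all full profiles under the latent truth.
"""

import itertools
import math

import numpy as np
import pytest

from mcda.core import ConfigurationError, Criterion, PerformanceLevel
from mcda.paprika import (
    ElicitationSession,
    ExhaustiveSession,
    InconsistencyError,
    Judgement,
    JudgementSet,
    RespondentModel,
    aggregate_group,
    dump_judgements,
    enumerate_undominated_pairs,
    load_judgements,
    solve_respondent_values,
    transitive_closure,
)
from mcda.synthetic import RespondentSpec, random_instance, simulate_session


def two_level_criteria(n):
    return [
        Criterion(
            id=f"c{i}", name=f"c{i}", domain_tag="",
            levels=(PerformanceLevel("lo", 0), PerformanceLevel("hi", 1)),
        )
        for i in range(n)
    ]


def brute_force_undominated_pairs(criteria):
    """Independent enumeration: all unordered pairs of two-criterion profiles
    where each profile is strictly better on exactly one criterion."""
    pairs = set()
    for ci, cj in itertools.combinations(criteria, 2):
        profiles = [
            {ci.id: a.label, cj.id: b.label} for a in ci.levels for b in cj.levels
        ]
        for p, q in itertools.combinations(profiles, 2):
            ra_p, rb_p = ci.level(p[ci.id]).rank, cj.level(p[cj.id]).rank
            ra_q, rb_q = ci.level(q[ci.id]).rank, cj.level(q[cj.id]).rank
            if (ra_p > ra_q and rb_p < rb_q) or (ra_p < ra_q and rb_p > rb_q):
                key = frozenset(
                    [tuple(sorted(p.items())), tuple(sorted(q.items()))]
                )
                pairs.add(key)
    return pairs


@pytest.mark.parametrize(
    "n_crit,n_lvl,expected",
    [(2, 3, 9), (2, 2, 1), (10, 3, 405), (3, 3, 27)],
)
def test_undominated_pair_counts_match_brute_force(n_crit, n_lvl, expected):
    crits, _, _ = random_instance(1, n_crit, n_lvl, seed=0)
    pairs = enumerate_undominated_pairs(crits)
    assert len(pairs) == expected
    keys = {
        frozenset([tuple(sorted(l.items())), tuple(sorted(r.items()))])
        for l, r in pairs
    }
    assert keys == brute_force_undominated_pairs(crits)
    assert len(keys) == len(pairs)  # deduplicated


def test_pair_enumeration_needs_two_criteria():
    crits, _, _ = random_instance(1, 2, 2, seed=0)
    with pytest.raises(ConfigurationError):
        enumerate_undominated_pairs(crits[:1])


def test_transitivity_chains_across_criteria():
    crits = two_level_criteria(3)
    up = {c.id: "hi" for c in crits}
    dn = {c.id: "lo" for c in crits}
    j1 = Judgement.make(  # upgrade on c0 beats upgrade on c1
        {"c0": "hi", "c1": "lo"}, {"c0": "lo", "c1": "hi"}, "left"
    )
    j2 = Judgement.make(  # upgrade on c1 beats upgrade on c2
        {"c1": "hi", "c2": "lo"}, {"c1": "lo", "c2": "hi"}, "left"
    )
    rel = transitive_closure([j1, j2], crits)
    assert rel.compare({"c0": "hi", "c2": "lo"}, {"c0": "lo", "c2": "hi"}) == ">"


def test_empty_closure_resolves_nothing_for_two_level_criteria():
    crits = two_level_criteria(3)
    rel = transitive_closure([], crits)
    ge, gt = rel.matrices
    assert (ge == np.eye(3, dtype=bool)).all()
    assert not gt.any()


def test_cycle_raises_with_witness():
    crits = two_level_criteria(3)

    def j(a, b):
        return Judgement.make(
            {a: "hi", b: "lo"}, {a: "lo", b: "hi"}, "left"
        )

    with pytest.raises(InconsistencyError) as err:
        transitive_closure([j("c0", "c1"), j("c1", "c2"), j("c2", "c0")], crits)
    assert len(err.value.witness) >= 2


def _oracle_closure(n, edges):
    """Floyd-Warshall-style fixpoint over (weak, strict) labelled edges."""
    ge = [[i == j for j in range(n)] for i in range(n)]
    gt = [[False] * n for _ in range(n)]
    for x, y, strict in edges:
        ge[x][y] = True
        gt[x][y] = gt[x][y] or strict
    changed = True
    while changed:
        changed = False
        for k in range(n):
            for i in range(n):
                if not ge[i][k]:
                    continue
                for j in range(n):
                    if ge[k][j]:
                        if not ge[i][j]:
                            ge[i][j] = changed = True
                        if (gt[i][k] or gt[k][j]) and not gt[i][j]:
                            gt[i][j] = changed = True
    return ge, gt


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_closure_matches_brute_force_oracle(seed):
    """Random consistent answer subsets on 3 criteria x 3 levels: the
    incremental closure equals an independent Floyd-Warshall fixpoint."""
    rng = np.random.default_rng(seed)
    crits, _, vs = random_instance(1, 3, 3, seed=seed)
    spec = RespondentSpec(true_values=vs)
    pairs = enumerate_undominated_pairs(crits)
    subset = [p for p in pairs if rng.random() < 0.5]
    judgements = []
    from mcda.synthetic import answer_question

    for left, right in subset:
        judgements.append(
            Judgement.make(left, right, answer_question(spec, left, right, rng))
        )
    rel = transitive_closure(judgements, crits)
    ge, gt = rel.matrices

    # rebuild the same edge set independently: nested-increment structure
    # (a wider upgrade strictly exceeds one it contains) plus the judgements
    edges = []
    for inc_a, inc_b in itertools.permutations(rel.increments, 2):
        if (
            inc_a.criterion_id == inc_b.criterion_id
            and inc_a.lo <= inc_b.lo
            and inc_b.hi <= inc_a.hi
            and (inc_a.lo, inc_a.hi) != (inc_b.lo, inc_b.hi)
        ):
            edges.append((rel.index[inc_a], rel.index[inc_b], True))
    from mcda.paprika import _judgement_increments

    for j in judgements:
        x, y, r = _judgement_increments(j, rel.by_id)
        xi, yi = rel.index[x], rel.index[y]
        if r == ">":
            edges.append((xi, yi, True))
        elif r == "<":
            edges.append((yi, xi, True))
        else:
            edges.append((xi, yi, False))
            edges.append((yi, xi, False))
    oge, ogt = _oracle_closure(len(rel.increments), edges)
    assert (ge == np.array(oge)).all()
    assert (gt == np.array(ogt)).all()


def test_adaptive_session_asks_fewer_questions_than_pairs():
    crits, _, vs = random_instance(1, 4, 3, seed=5)
    js = simulate_session(RespondentSpec(true_values=vs), crits, np.random.default_rng(0))
    assert len(js) < len(enumerate_undominated_pairs(crits))


def test_first_question_maximises_expected_elimination():
    """The opening question of a fresh session is an argmax of the
    brute-force elimination count over all candidate pairs."""
    crits, _, _ = random_instance(1, 2, 3, seed=0)
    session = ElicitationSession(crits)
    question = session.next_question()

    def eliminations(x, y):
        total = 0
        for strict_pair in ((x, y), (y, x)):
            probe = ElicitationSession(crits)
            probe.relation._closure.add(*strict_pair, strict=True)
            total += len(session.unresolved_pairs()) - len(probe.unresolved_pairs())
        return total

    scores = {pair: eliminations(*pair) for pair in session.unresolved_pairs()}
    x, y, _ = __import__("mcda.paprika", fromlist=["_judgement_increments"])._judgement_increments(
        Judgement.make(*question, "indifferent"), session.relation.by_id
    )
    asked = (session.relation.index[x], session.relation.index[y])
    assert scores[asked] == max(scores.values())
    # maximal elimination requires engaging the middle level
    asked_levels = {r for prof in question for r in
                    [session.relation.by_id[c].level(l).rank for c, l in prof.items()]}
    assert 1 in asked_levels


def test_session_exhausts_and_last_pair_is_served():
    crits, _, vs = random_instance(1, 2, 2, seed=0)
    session = ElicitationSession(crits)
    q = session.next_question()
    assert q is not None
    assert len(session.unresolved_pairs()) == 1  # 2x2 has a single pair
    session.record(*q, "left")
    assert session.exhausted
    assert session.next_question() is None


def test_solver_trivial_normalisation():
    crits = two_level_criteria(1)
    model = solve_respondent_values([], crits)
    assert model.level_values[("c0", "lo")] == 0.0
    assert model.level_values[("c0", "hi")] == pytest.approx(100.0)


def test_solver_swap_indifference_forces_equal_weights():
    crits = two_level_criteria(2)
    j = Judgement.make({"c0": "hi", "c1": "lo"}, {"c0": "lo", "c1": "hi"}, "indifferent")
    model = solve_respondent_values([j], crits)
    assert model.level_values[("c0", "hi")] == pytest.approx(50.0)
    assert model.level_values[("c1", "hi")] == pytest.approx(50.0)


def test_solver_reproduces_every_judgement(criteria, values):
    js = simulate_session(
        RespondentSpec(true_values=values), criteria, np.random.default_rng(2)
    )
    model = solve_respondent_values(js, criteria)
    assert model.reproduces(js)
    assert model.margin > 0


def test_solver_infeasible_on_contradiction():
    crits = two_level_criteria(2)
    left = {"c0": "hi", "c1": "lo"}
    right = {"c0": "lo", "c1": "hi"}
    with pytest.raises(InconsistencyError):
        solve_respondent_values(
            [Judgement.make(left, right, "left"), Judgement.make(left, right, "right")],
            crits,
        )


def test_epsilon_scale_leaves_fitted_order_unchanged():
    crits, _, vs = random_instance(1, 3, 3, seed=11)
    js = simulate_session(RespondentSpec(true_values=vs), crits, np.random.default_rng(3))
    m1 = solve_respondent_values(js, crits, epsilon=1e-3)
    m2 = solve_respondent_values(js, crits, epsilon=1e-1)
    profiles = [
        dict(zip([c.id for c in crits], combo))
        for combo in itertools.product(*[[l.label for l in c.levels] for c in crits])
    ]
    for p, q in itertools.combinations(profiles, 2):
        d1 = m1.profile_value(p) - m1.profile_value(q)
        d2 = m2.profile_value(p) - m2.profile_value(q)
        assert np.sign(round(d1, 6)) == np.sign(round(d2, 6))


def test_noiseless_exhaustive_session_recovers_complete_ranking():
    """With every undominated full-profile pair ranked, the fitted values
    order all profile pairs exactly as the latent truth does."""
    crits, _, vs = random_instance(1, 3, 3, seed=7)
    spec = RespondentSpec(true_values=vs)
    js = simulate_session(spec, crits, np.random.default_rng(1), exhaustive=True)
    model = solve_respondent_values(js, crits)
    profiles = [
        dict(zip([c.id for c in crits], combo))
        for combo in itertools.product(*[[l.label for l in c.levels] for c in crits])
    ]
    for p, q in itertools.combinations(profiles, 2):
        dt = spec.profile_value(p) - spec.profile_value(q)
        df = model.profile_value(p) - model.profile_value(q)
        st = 0 if abs(dt) < 1e-9 else (1 if dt > 0 else -1)
        sf = 0 if abs(df) < 1e-9 else (1 if df > 0 else -1)
        assert st == sf, f"{p} vs {q}: truth {dt}, fit {df}"


def test_exhaustive_session_guards_large_instances(criteria):
    with pytest.raises(ConfigurationError, match="exhaustive"):
        ExhaustiveSession(criteria)  # 3^10 profiles


def test_aggregate_group_idempotent_and_symmetric():
    crits = two_level_criteria(2)
    a = RespondentModel(
        "a", {("c0", "lo"): 0.0, ("c0", "hi"): 60.0, ("c1", "lo"): 0.0, ("c1", "hi"): 40.0}, 1.0
    )
    b = RespondentModel(
        "b", {("c0", "lo"): 0.0, ("c0", "hi"): 40.0, ("c1", "lo"): 0.0, ("c1", "hi"): 60.0}, 1.0
    )
    same = aggregate_group([a, a])
    assert float(same.weight("c0")) == pytest.approx(60.0)
    mixed = aggregate_group([a, b])
    assert float(mixed.weight("c0")) == pytest.approx(50.0)
    assert float(mixed.weight("c1")) == pytest.approx(50.0)


def test_aggregate_group_rejects_mismatched_criteria():
    a = RespondentModel("a", {("c0", "lo"): 0.0, ("c0", "hi"): 100.0}, 1.0)
    b = RespondentModel("b", {("c1", "lo"): 0.0, ("c1", "hi"): 100.0}, 1.0)
    with pytest.raises(ConfigurationError):
        aggregate_group([a, b])


def test_judgement_jsonl_round_trip():
    crits, _, vs = random_instance(1, 2, 3, seed=4)
    js = simulate_session(
        RespondentSpec(true_values=vs, respondent_id="r7"),
        crits,
        np.random.default_rng(0),
    )
    text = dump_judgements([js])
    (back,) = load_judgements(text)
    assert back.respondent_id == "r7"
    assert [
        (j.left, j.right, j.choice) for j in back
    ] == [(j.left, j.right, j.choice) for j in js]
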