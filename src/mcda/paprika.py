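"""PAPRIKA-style pairwise preference elicitation.

The method asks a respondent to choose between two hypothetical alternatives
that differ on exactly two criteria, each better on one of them (an
*undominated* pair), so every question forces a genuine trade-off.  Under an
additive value model each such question compares two single-criterion value
*increments*: "is upgrading criterion i from level a to level b worth more
than upgrading criterion j from level c to level d?".  Answers propagate by
transitivity over the increment order, so most of the potential questions
are never asked explicitly; the session adaptively picks the question whose
possible answers are expected to resolve the most still-open pairs.

Once every undominated pair is resolved (explicitly or by implication), a
respondent's level values are recovered by linear programming: values are
anchored at 0 for each criterion's worst level, forced non-decreasing with
a strict step between consecutive levels, constrained to honour every
elicited strict preference with a common margin and every indifference
exactly, and normalised so the all-best profile scores 100.  The solver
maximises the common margin, then minimises the total value mass as a
deterministic tie-break.

Group preferences are the arithmetic mean of the respondents' level values,
criterion weights being the mean best-level values.
"""

from __future__ import annotations

import itertools
import json
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .core import ConfigurationError, Criterion, MCDAError, ValidationError, ValueSystem

Profile = Mapping[str, str]  # criterion id -> level label (sparse)


class InconsistencyError(MCDAError):
    """A set of judgements implies a strict-preference cycle."""

    def __init__(self, message: str, witness: list | None = None):
        super().__init__(message)
        self.witness = witness or []


@dataclass(frozen=True)
class Judgement:
    """One answered trade-off question."""

    left: tuple[tuple[str, str], ...]  # frozen (criterion id, level label) pairs
    right: tuple[tuple[str, str], ...]
    choice: str  # "left" | "right" | "indifferent"
    respondent_id: str = ""

    @staticmethod
    def make(left: Profile, right: Profile, choice: str, respondent_id: str = "") -> "Judgement":
        if choice not in ("left", "right", "indifferent"):
            raise ValidationError(f"invalid choice {choice!r}")
        return Judgement(
            left=tuple(sorted(left.items())),
            right=tuple(sorted(right.items())),
            choice=choice,
            respondent_id=respondent_id,
        )

    @property
    def left_profile(self) -> dict[str, str]:
        return dict(self.left)

    @property
    def right_profile(self) -> dict[str, str]:
        return dict(self.right)


@dataclass
class JudgementSet:
    """All judgements of one respondent, in the order they were given."""

    respondent_id: str
    judgements: list[Judgement] = field(default_factory=list)
    provenance: str = "replayed"  # or "simulated"

    def __iter__(self):
        return iter(self.judgements)

    def __len__(self) -> int:
        return len(self.judgements)


# ---------------------------------------------------------------------------
# Increments: the single-criterion upgrades a two-criterion question compares.


@dataclass(frozen=True)
class Increment:
    criterion_id: str
    lo: int  # worse level rank
    hi: int  # better level rank


def _criterion_increments(crit: Criterion) -> list[Increment]:
    return [
        Increment(crit.id, lo, hi)
        for lo, hi in itertools.combinations(range(crit.n_levels), 2)
    ]


def _pair_profiles(
    x: Increment, y: Increment, by_id: Mapping[str, Criterion]
) -> tuple[dict[str, str], dict[str, str]]:
    """The two undominated profiles whose comparison pits increment x against y.

    The left profile is better on x's criterion, the right on y's.
    """
    ci, cj = by_id[x.criterion_id], by_id[y.criterion_id]
    left = {ci.id: ci.levels[x.hi].label, cj.id: cj.levels[y.lo].label}
    right = {ci.id: ci.levels[x.lo].label, cj.id: cj.levels[y.hi].label}
    return left, right


def _judgement_increments(
    j: Judgement, by_id: Mapping[str, Criterion]
) -> tuple[Increment, Increment, str]:
    """Decompose a two-criterion judgement into (preferred-side increment on
    one criterion, other-side increment, relation in {'>', '<', '='})
    oriented as (left-better increment, right-better increment, relation of
    left vs right)."""
    left, right = j.left_profile, j.right_profile
    if set(left) != set(right) or len(left) != 2:
        raise ValidationError(
            "judgement profiles must be defined on the same two criteria"
        )
    better_left = None
    better_right = None
    for cid in left:
        crit = by_id[cid]
        rl, rr = crit.level(left[cid]).rank, crit.level(right[cid]).rank
        if rl > rr:
            better_left = Increment(cid, rr, rl)
        elif rr > rl:
            better_right = Increment(cid, rl, rr)
    if better_left is None or better_right is None:
        raise ValidationError("judgement pair is dominated; no trade-off to elicit")
    rel = {"left": ">", "right": "<", "indifferent": "="}[j.choice]
    return better_left, better_right, rel


# ---------------------------------------------------------------------------
# Transitive closure over the increment order.


class _Closure:
    """Incrementally maintained reflexive-transitive preference relation.

    ``ge[a, b]`` means increment a is worth at least as much as b; ``gt``
    marks the strictly-greater pairs.  Adding an edge closes the relation via
    one boolean outer product (the new pairs must route through the edge).
    """

    def __init__(self, n: int):
        self.n = n
        self.ge = np.eye(n, dtype=bool)
        self.gt = np.zeros((n, n), dtype=bool)
        self.edges: list[tuple[int, int, bool]] = []  # asserted (x >= y, strict)

    def add(self, x: int, y: int, strict: bool) -> None:
        col = self.ge[:, x].copy()
        row = self.ge[y, :].copy()
        new_ge = np.outer(col, row)
        if strict:
            new_gt = new_ge
        else:
            new_gt = np.outer(self.gt[:, x], row) | np.outer(col, self.gt[y, :])
        self.ge |= new_ge
        self.gt |= new_gt
        self.edges.append((x, y, strict))
        if self.gt.diagonal().any():
            raise InconsistencyError(
                "strict-preference cycle detected",
                witness=self._witness(x, y),
            )

    def add_tie(self, x: int, y: int) -> None:
        self.add(x, y, strict=False)
        self.add(y, x, strict=False)

    def _witness(self, x: int, y: int) -> list[int]:
        """Shortest asserted-edge path y -> ... -> x closing the cycle."""
        adj: dict[int, list[int]] = {}
        for a, b, _ in self.edges:
            adj.setdefault(a, []).append(b)
        prev = {y: None}
        q = deque([y])
        while q:
            node = q.popleft()
            if node == x:
                path = []
                while node is not None:
                    path.append(node)
                    node = prev[node]
                return list(reversed(path)) + [y]
            for nxt in adj.get(node, ()):  # pragma: no branch
                if nxt not in prev:
                    prev[nxt] = node
                    q.append(nxt)
        return [x, y]

    def resolved(self, x: int, y: int) -> bool:
        return bool(
            self.gt[x, y] or self.gt[y, x] or (self.ge[x, y] and self.ge[y, x])
        )

    def relation(self, x: int, y: int) -> str | None:
        if self.gt[x, y]:
            return ">"
        if self.gt[y, x]:
            return "<"
        if self.ge[x, y] and self.ge[y, x]:
            return "="
        return None


class PreferenceRelation:
    """Closure of a judgement set over single-criterion value increments.

    Structural knowledge is built in: within a criterion, a wider level
    upgrade is strictly worth more than any upgrade it properly contains
    (levels are strictly ordered).
    """

    def __init__(self, criteria: Sequence[Criterion]):
        self.criteria = list(criteria)
        self.by_id = {c.id: c for c in criteria}
        self.increments: list[Increment] = []
        for crit in self.criteria:
            self.increments.extend(_criterion_increments(crit))
        self.index = {inc: i for i, inc in enumerate(self.increments)}
        self._closure = _Closure(len(self.increments))
        for crit in self.criteria:
            incs = _criterion_increments(crit)
            for a, b in itertools.permutations(incs, 2):
                if a.lo <= b.lo and b.hi <= a.hi and (a.lo, a.hi) != (b.lo, b.hi):
                    self._closure.add(self.index[a], self.index[b], strict=True)

    def add_judgement(self, j: Judgement) -> None:
        x, y, rel = _judgement_increments(j, self.by_id)
        xi, yi = self.index[x], self.index[y]
        if rel == ">":
            self._closure.add(xi, yi, strict=True)
        elif rel == "<":
            self._closure.add(yi, xi, strict=True)
        else:
            self._closure.add_tie(xi, yi)

    def compare_increments(self, x: Increment, y: Increment) -> str | None:
        return self._closure.relation(self.index[x], self.index[y])

    def compare(self, left: Profile, right: Profile) -> str | None:
        """Relation of two undominated two-criterion profiles, or None if
        the judgements made so far do not determine it."""
        x, y, _ = _judgement_increments(
            Judgement.make(left, right, "indifferent"), self.by_id
        )
        return self.compare_increments(x, y)

    @property
    def matrices(self) -> tuple[np.ndarray, np.ndarray]:
        return self._closure.ge.copy(), self._closure.gt.copy()


def transitive_closure(
    judgements: Iterable[Judgement], criteria: Sequence[Criterion]
) -> PreferenceRelation:
    """Close a set of judgements under transitivity (and the within-criterion
    additive structure).  Raises :class:`InconsistencyError` on a strict cycle,
    identifying a witness."""
    rel = PreferenceRelation(criteria)
    for j in judgements:
        rel.add_judgement(j)
    return rel


# ---------------------------------------------------------------------------
# Question enumeration and the adaptive session.


def enumerate_undominated_pairs(
    criteria: Sequence[Criterion], pair_order: int = 2
) -> list[tuple[dict[str, str], dict[str, str]]]:
    """All unordered undominated pairs of two-criterion profiles.

    Each pair pits one criterion's level upgrade against another's, so for
    criteria with L levels there are C(L, 2)^2 pairs per criterion pair.
    Order is deterministic: lexicographic in (criterion pair, level indices).
    """
    if pair_order != 2:
        raise ConfigurationError("only two-criterion trade-off questions are supported")
    if len(criteria) < 2:
        raise ConfigurationError("need at least 2 criteria to elicit trade-offs")
    by_id = {c.id: c for c in criteria}
    out = []
    for ci, cj in itertools.combinations(criteria, 2):
        for x in _criterion_increments(ci):
            for y in _criterion_increments(cj):
                out.append(_pair_profiles(x, y, by_id))
    return out


class ElicitationSession:
    """Adaptive questioning loop for one respondent.

    Repeatedly call :meth:`next_question`, collect an answer, and feed it to
    :meth:`record`; ``next_question`` returns ``None`` when every undominated
    pair is resolved (asked or implied).
    """

    def __init__(self, criteria: Sequence[Criterion], allow_indifference: bool = True):
        if len(criteria) < 2:
            raise ConfigurationError("need at least 2 criteria to elicit trade-offs")
        self.relation = PreferenceRelation(criteria)
        self.allow_indifference = allow_indifference
        self.judgements: list[Judgement] = []
        by_id = self.relation.by_id
        self._pairs: list[tuple[int, int]] = []
        for ci, cj in itertools.combinations(self.relation.criteria, 2):
            for x in _criterion_increments(ci):
                for y in _criterion_increments(cj):
                    self._pairs.append((self.relation.index[x], self.relation.index[y]))

    def unresolved_pairs(self) -> list[tuple[int, int]]:
        c = self.relation._closure
        return [(x, y) for x, y in self._pairs if not c.resolved(x, y)]

    @property
    def exhausted(self) -> bool:
        return not self.unresolved_pairs()

    def next_question(self) -> tuple[dict[str, str], dict[str, str]] | None:
        """The unresolved pair whose answers resolve the most other pairs.

        The score of a candidate is the total number of currently-unresolved
        pairs that would become resolved across its two strict answers (the
        expected elimination, up to the uniform 1/2 factor); ties fall back
        to enumeration order.
        """
        open_pairs = self.unresolved_pairs()
        if not open_pairs:
            return None
        c = self.relation._closure
        ge = c.ge
        ua = np.fromiter((p[0] for p in open_pairs), dtype=np.intp)
        ub = np.fromiter((p[1] for p in open_pairs), dtype=np.intp)
        best_idx, best_score = 0, -1
        for k, (x, y) in enumerate(open_pairs):
            colx_a, colx_b = ge[ua, x], ge[ub, x]
            rowy_a, rowy_b = ge[y, ua], ge[y, ub]
            n_left = int(((colx_a & rowy_b) | (colx_b & rowy_a)).sum())
            coly_a, coly_b = ge[ua, y], ge[ub, y]
            rowx_a, rowx_b = ge[x, ua], ge[x, ub]
            n_right = int(((coly_a & rowx_b) | (coly_b & rowx_a)).sum())
            score = n_left + n_right
            if score > best_score:
                best_idx, best_score = k, score
        x, y = open_pairs[best_idx]
        return _pair_profiles(
            self.relation.increments[x], self.relation.increments[y], self.relation.by_id
        )

    def record(self, left: Profile, right: Profile, choice: str, respondent_id: str = "") -> None:
        j = Judgement.make(left, right, choice, respondent_id)
        self.relation.add_judgement(j)
        self.judgements.append(j)


class ExhaustiveSession:
    """The "potentially all pairwise rankings" stage over full profiles.

    Two-criterion questions cannot determine how a gain spread over three or
    more criteria trades off against a concentrated one, so recovering a
    respondent's *complete* profile ranking requires ranking every
    undominated pair of full profiles.  This session does exactly that,
    feasible only for small instances (the profile lattice grows as L^n):
    answers are propagated to every profile pair sharing the same difference
    pattern (additivity: common levels cancel) and closed under transitivity,
    and questions are asked in stages — pairs differing on fewer criteria
    first — until every pair is resolved.

    Questions are presented sparsely, on the differing criteria only, like
    the two-criterion surveys.
    """

    def __init__(self, criteria: Sequence[Criterion], max_profiles: int = 2048):
        if len(criteria) < 2:
            raise ConfigurationError("need at least 2 criteria to elicit trade-offs")
        self.criteria = list(criteria)
        self.by_id = {c.id: c for c in criteria}
        n_profiles = 1
        for c in criteria:
            n_profiles *= c.n_levels
        if n_profiles > max_profiles:
            raise ConfigurationError(
                f"{n_profiles} full profiles exceeds the exhaustive-session limit "
                f"({max_profiles}); use the two-criterion session for large instances"
            )
        self.profiles: list[tuple[int, ...]] = list(
            itertools.product(*[range(c.n_levels) for c in criteria])
        )
        self._index = {p: i for i, p in enumerate(self.profiles)}
        n = len(self.profiles)
        P = np.array(self.profiles)
        dom = (P[:, None, :] >= P[None, :, :]).all(axis=2)
        self.ge = dom.copy()
        self.gt = dom & ~np.eye(n, dtype=bool)  # strict level order: dominance is strict
        self.gt &= ~dom.T  # equal profiles only on the diagonal; guard anyway
        # group undominated ordered pairs by their difference signature
        self._classes: dict[tuple, list[tuple[int, int]]] = {}
        self._class_order: list[tuple] = []
        for a, b in itertools.combinations(range(n), 2):
            if dom[a, b] or dom[b, a]:
                continue
            sig = self._signature(self.profiles[a], self.profiles[b])
            if sig not in self._classes:
                self._classes[sig] = []
                self._class_order.append(sig)
            self._classes[sig].append((a, b))
        # stage order: fewer differing criteria first, then lexicographic
        self._class_order.sort(key=lambda sig: (len(sig), sig))
        self.judgements: list[Judgement] = []

    def _signature(self, p: tuple[int, ...], q: tuple[int, ...]) -> tuple:
        return tuple(
            (k, p[k], q[k]) for k in range(len(self.criteria)) if p[k] != q[k]
        )

    def _sparse(self, sig: tuple) -> tuple[dict[str, str], dict[str, str]]:
        left = {
            self.criteria[k].id: self.criteria[k].levels[pl].label for k, pl, _ in sig
        }
        right = {
            self.criteria[k].id: self.criteria[k].levels[ql].label for k, _, ql in sig
        }
        return left, right

    def _resolved(self, a: int, b: int) -> bool:
        return bool(self.gt[a, b] or self.gt[b, a] or (self.ge[a, b] and self.ge[b, a]))

    def unresolved_signatures(self) -> list[tuple]:
        out = []
        for sig in self._class_order:
            a, b = self._classes[sig][0]
            if not self._resolved(a, b):
                out.append(sig)
        return out

    @property
    def exhausted(self) -> bool:
        return not self.unresolved_signatures()

    def next_question(self) -> tuple[dict[str, str], dict[str, str]] | None:
        open_sigs = self.unresolved_signatures()
        if not open_sigs:
            return None
        return self._sparse(open_sigs[0])

    def record(
        self, left: Profile, right: Profile, choice: str, respondent_id: str = ""
    ) -> None:
        j = Judgement.make(left, right, choice, respondent_id)
        lp, rp = j.left_profile, j.right_profile
        ranks = {
            cid: (self.by_id[cid].level(lp[cid]).rank, self.by_id[cid].level(rp[cid]).rank)
            for cid in lp
        }
        cid_index = {c.id: k for k, c in enumerate(self.criteria)}
        sig = tuple(
            sorted((cid_index[cid], pl, ql) for cid, (pl, ql) in ranks.items() if pl != ql)
        )
        if sig not in self._classes:
            mirror = tuple(sorted((k, ql, pl) for k, pl, ql in sig))
            if mirror not in self._classes:
                raise ValidationError("judgement does not match an undominated profile pair")
            sig = mirror
            choice = {"left": "right", "right": "left", "indifferent": "indifferent"}[choice]
        for a, b in self._classes[sig]:
            if choice == "left":
                self.gt[a, b] = self.ge[a, b] = True
            elif choice == "right":
                self.gt[b, a] = self.ge[b, a] = True
            else:
                self.ge[a, b] = self.ge[b, a] = True
        self._close()
        if self.gt.diagonal().any():
            raise InconsistencyError("strict-preference cycle over full profiles")
        self.judgements.append(j)

    def _close(self) -> None:
        ge = self.ge.astype(np.uint8)
        while True:
            nxt = ((ge @ ge) > 0).astype(np.uint8)
            nxt |= ge
            if (nxt == ge).all():
                break
            ge = nxt
        gec = ge > 0
        gt = ((ge @ self.gt.astype(np.uint8) @ ge) > 0)
        self.ge = gec
        self.gt = gt

    def compare(self, left: Profile, right: Profile) -> str | None:
        a = self._index[tuple(self.by_id[c.id].level(left[c.id]).rank for c in self.criteria)]
        b = self._index[tuple(self.by_id[c.id].level(right[c.id]).rank for c in self.criteria)]
        if self.gt[a, b]:
            return ">"
        if self.gt[b, a]:
            return "<"
        if self.ge[a, b] and self.ge[b, a]:
            return "="
        return None


# ---------------------------------------------------------------------------
# Value recovery (linear programming) and group aggregation.


@dataclass
class RespondentModel:
    """One respondent's fitted level values, normalised to a 0-100 scale."""

    respondent_id: str
    level_values: dict[tuple[str, str], float]
    margin: float

    def value_system(self) -> ValueSystem:
        return ValueSystem(level_values=dict(self.level_values))

    def profile_value(self, profile: Profile) -> float:
        return sum(self.level_values[(cid, label)] for cid, label in profile.items())

    def reproduces(self, judgements: Iterable[Judgement], tol: float = 1e-6) -> bool:
        """True iff every strict judgement holds with positive margin and
        every indifference within ``tol``."""
        for j in judgements:
            d = self.profile_value(j.left_profile) - self.profile_value(j.right_profile)
            if j.choice == "left" and d <= 0:
                return False
            if j.choice == "right" and d >= 0:
                return False
            if j.choice == "indifferent" and abs(d) > tol:
                return False
        return True


def solve_respondent_values(
    judgements: Iterable[Judgement],
    criteria: Sequence[Criterion],
    epsilon: float = 1e-3,
    respondent_id: str = "",
) -> RespondentModel:
    """Fit level values honouring a consistent judgement set.

    Two-stage LP: maximise the common strict-preference margin m (>= epsilon,
    applied to both elicited strict preferences and consecutive-level steps),
    then, holding m at its optimum, minimise the total value mass so the
    solution is unique and deterministic.  The all-best profile is pinned to
    100, each worst level to 0.  Scaling epsilon leaves all fitted pairwise
    orders unchanged (the constraint set is homothetic in m).
    """
    judgements = list(judgements)
    by_id = {c.id: c for c in criteria}
    var_index: dict[tuple[str, int], int] = {}
    for crit in criteria:
        for rank in range(1, crit.n_levels):
            var_index[(crit.id, rank)] = len(var_index)
    n_v = len(var_index)
    m_idx = n_v  # margin variable is last

    def profile_coeffs(row: np.ndarray, profile: Mapping[str, str], sign: float) -> None:
        for cid, label in profile.items():
            rank = by_id[cid].level(label).rank
            if rank >= 1:
                row[var_index[(cid, rank)]] += sign

    A_ub, b_ub, A_eq, b_eq = [], [], [], []
    for crit in criteria:  # consecutive-level steps of at least m
        for rank in range(1, crit.n_levels):
            row = np.zeros(n_v + 1)
            row[var_index[(crit.id, rank)]] -= 1.0
            if rank > 1:
                row[var_index[(crit.id, rank - 1)]] += 1.0
            row[m_idx] = 1.0
            A_ub.append(row)
            b_ub.append(0.0)
    for j in judgements:
        row = np.zeros(n_v + 1)
        if j.choice == "indifferent":
            profile_coeffs(row, j.left_profile, 1.0)
            profile_coeffs(row, j.right_profile, -1.0)
            A_eq.append(row)
            b_eq.append(0.0)
        else:
            better, worse = (
                (j.left_profile, j.right_profile)
                if j.choice == "left"
                else (j.right_profile, j.left_profile)
            )
            profile_coeffs(row, better, -1.0)
            profile_coeffs(row, worse, 1.0)
            row[m_idx] = 1.0
            A_ub.append(row)
            b_ub.append(0.0)
    norm = np.zeros(n_v + 1)  # best levels sum to 100
    for crit in criteria:
        norm[var_index[(crit.id, crit.n_levels - 1)]] = 1.0
    A_eq.append(norm)
    b_eq.append(100.0)

    bounds = [(0.0, 100.0)] * n_v + [(epsilon, 100.0)]
    c1 = np.zeros(n_v + 1)
    c1[m_idx] = -1.0
    res1 = linprog(
        c1, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
        A_eq=np.array(A_eq), b_eq=np.array(b_eq), bounds=bounds, method="highs",
    )
    if not res1.success:
        raise InconsistencyError(
            f"no additive value system honours the judgements (LP: {res1.message})"
        )
    m_star = res1.x[m_idx]
    bounds[m_idx] = (m_star * (1 - 1e-9), m_star)
    c2 = np.ones(n_v + 1)
    c2[m_idx] = 0.0
    res2 = linprog(
        c2, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
        A_eq=np.array(A_eq), b_eq=np.array(b_eq), bounds=bounds, method="highs",
    )
    x = res2.x if res2.success else res1.x  # stage 2 is a refinement only
    level_values: dict[tuple[str, str], float] = {}
    for crit in criteria:
        for lv in crit.levels:
            v = 0.0 if lv.rank == 0 else float(x[var_index[(crit.id, lv.rank)]])
            level_values[(crit.id, lv.label)] = v
    return RespondentModel(
        respondent_id=respondent_id, level_values=level_values, margin=float(m_star)
    )


def aggregate_group(models: Sequence[RespondentModel]) -> ValueSystem:
    """Group value system: arithmetic mean of each level value across
    respondents; criterion weights are the mean best-level values."""
    if not models:
        raise ConfigurationError("aggregate_group needs at least one model")
    keys = set(models[0].level_values)
    for m in models[1:]:
        if set(m.level_values) != keys:
            raise ConfigurationError("respondent models cover different criteria/levels")
    out = {
        key: float(np.mean([m.level_values[key] for m in models])) for key in keys
    }
    return ValueSystem(level_values=out)


# ---------------------------------------------------------------------------
# JSONL (de)serialisation of judgement sets.


def dump_judgements(sets: Iterable[JudgementSet]) -> str:
    lines = []
    for js in sets:
        for j in js:
            lines.append(
                json.dumps(
                    {
                        "respondent_id": js.respondent_id,
                        "left": j.left_profile,
                        "right": j.right_profile,
                        "choice": j.choice,
                    }
                )
            )
    return "\n".join(lines) + ("\n" if lines else "")


def load_judgements(text: str) -> list[JudgementSet]:
    """Parse a judgements JSONL document into per-respondent sets (order of
    first appearance)."""
    sets: dict[str, JudgementSet] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        doc = json.loads(line)
        rid = str(doc["respondent_id"])
        js = sets.setdefault(rid, JudgementSet(respondent_id=rid))
        js.judgements.append(Judgement.make(doc["left"], doc["right"], doc["choice"], rid))
    return list(sets.values())
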