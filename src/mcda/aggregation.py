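"""Additive scoring and tie-aware ranking of alternatives.

Two models are supported.  The *unweighted* model codes each criterion's
levels 1..L (worst = 1) and sums the codes.  The *weighted* model is the
additive value function

    V_j = sum_i S_ij * W_i

realised as the sum over criteria of the tabulated level value (part-worth)
of the alternative's assigned level — each tabulated value already being the
product of the within-criterion score and the criterion weight.  Fixture
values are :class:`~decimal.Decimal`, so published one-decimal totals are
reproduced exactly.

Ranking is dense over tied groups: alternatives whose scores are equal
(within a policy tolerance) share a rank rendered "Joint <ordinal>", and the
next distinct score takes the next consecutive ordinal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Mapping, Sequence

import pandas as pd

from .core import (
    Criterion,
    Number,
    PerformanceMatrix,
    ValueSystem,
    validate_matrix,
    ValidationError,
)

_ORDINALS = (
    "First", "Second", "Third", "Fourth", "Fifth",
    "Sixth", "Seventh", "Eighth", "Ninth", "Tenth",
)


def _ordinal(i: int) -> str:
    return _ORDINALS[i - 1] if i <= len(_ORDINALS) else f"{i}th"


@dataclass(frozen=True)
class RankingPolicy:
    """How equal scores are grouped: dense ranking with a score tolerance.

    ``tolerance=0`` (the default) means only exactly equal scores tie, which
    is the right choice for exact-decimal fixture arithmetic.
    """

    tolerance: float = 0.0

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValidationError("ranking tolerance must be >= 0")


@dataclass
class ScoreTable:
    """Per-alternative contributions, totals and dense tie-aware ranks."""

    contributions: dict[tuple[str, str], Number]  # (alternative, criterion) -> value
    totals: dict[str, Number]
    ranks: dict[str, int]  # dense rank, 1-based
    rank_labels: dict[str, str]  # "First", "Joint third", ...

    def to_frame(self) -> pd.DataFrame:
        """Alternatives x criteria contribution table with total and rank."""
        alts = list(self.totals)
        crits = sorted({cid for (_, cid) in self.contributions})
        df = pd.DataFrame(
            {cid: [float(self.contributions[(a, cid)]) for a in alts] for cid in crits},
            index=alts,
        )
        df["total"] = [float(self.totals[a]) for a in alts]
        df["rank"] = [self.rank_labels[a] for a in alts]
        return df

    def to_dict(self) -> dict:
        return {
            alt: {
                "total": float(self.totals[alt]),
                "rank": self.ranks[alt],
                "rank_label": self.rank_labels[alt],
                "contributions": {
                    cid: float(v)
                    for (a, cid), v in self.contributions.items()
                    if a == alt
                },
            }
            for alt in self.totals
        }


def unweighted_total(
    matrix: PerformanceMatrix, criteria: Sequence[Criterion], alternative: str
) -> int:
    """Sum of 1-based ordinal level codes across criteria for one alternative."""
    if alternative not in matrix.alternatives:
        raise KeyError(f"unknown alternative {alternative!r}")
    total = 0
    for crit in criteria:
        label = matrix.level_label(alternative, crit.id)
        total += crit.level(label).ordinal_points
    return total


def weighted_value(
    value_system: ValueSystem, assignment: Mapping[str, str]
) -> Number:
    """Additive total V_j for one alternative's criterion -> level assignment.

    Sums the tabulated level values; with Decimal-valued systems the result
    is exact.  A level missing from the value system raises
    :class:`~mcda.core.ConfigurationError` naming the cell.
    """
    values = [value_system.value(cid, label) for cid, label in assignment.items()]
    total: Number = sum(values) if values else 0
    return total


def rank_alternatives(
    scores: Mapping[str, Number], policy: RankingPolicy | None = None
) -> ScoreTable:
    """Dense tie-aware ranking of a score map (higher is better)."""
    if not scores:
        raise ValidationError("rank_alternatives needs at least one alternative")
    policy = policy or RankingPolicy()
    ordered = sorted(scores.items(), key=lambda kv: (-float(kv[1]), list(scores).index(kv[0])))
    ranks: dict[str, int] = {}
    groups: list[list[str]] = []
    for alt, score in ordered:
        if groups and abs(float(score) - float(scores[groups[-1][-1]])) <= policy.tolerance:
            groups[-1].append(alt)
        else:
            groups.append([alt])
    labels: dict[str, str] = {}
    for gi, group in enumerate(groups, start=1):
        word = _ordinal(gi)
        for alt in group:
            ranks[alt] = gi
            labels[alt] = f"Joint {word.lower()}" if len(group) > 1 else word
    return ScoreTable(
        contributions={},
        totals={alt: scores[alt] for alt in scores},
        ranks=ranks,
        rank_labels=labels,
    )


def score_alternatives(
    matrix: PerformanceMatrix,
    criteria: Sequence[Criterion],
    value_system: ValueSystem | None = None,
    policy: RankingPolicy | None = None,
) -> ScoreTable:
    """Score and rank every alternative in a matrix.

    With a value system the weighted additive model is used and contributions
    are the tabulated level values; without one, the unweighted ordinal model
    is used and contributions are the 1..L codes.
    """
    report = validate_matrix(matrix, criteria)
    if not report.ok:
        raise ValidationError(f"matrix fails validation: {report.to_dict()}")
    contributions: dict[tuple[str, str], Number] = {}
    totals: dict[str, Number] = {}
    for alt in matrix.alternatives:
        if value_system is None:
            for crit in criteria:
                contributions[(alt, crit.id)] = crit.level(
                    matrix.level_label(alt, crit.id)
                ).ordinal_points
            totals[alt] = unweighted_total(matrix, criteria, alt)
        else:
            assignment = matrix.row(alt, criteria)
            for cid, label in assignment.items():
                contributions[(alt, cid)] = value_system.value(cid, label)
            totals[alt] = weighted_value(value_system, assignment)
    ranked = rank_alternatives(totals, policy)
    ranked.contributions = contributions
    return ranked


def criterion_summary(
    value_system: ValueSystem, criteria: Sequence[Criterion]
) -> list[tuple[str, float]]:
    """Criteria sorted by weight descending (criterion id breaks ties).

    This is the data behind the polar chart of criterion weights.
    """
    weights = [(c.id, float(value_system.weight(c.id))) for c in criteria]
    return sorted(weights, key=lambda kv: (-kv[1], kv[0]))


def score_report(
    matrix: PerformanceMatrix,
    criteria: Sequence[Criterion],
    value_system: ValueSystem,
    policy: RankingPolicy | None = None,
) -> dict:
    """Composite report: unweighted and weighted score tables plus the
    weight-ranked criterion summary."""
    unweighted = score_alternatives(matrix, criteria, None, policy)
    weighted = score_alternatives(matrix, criteria, value_system, policy)
    return {
        "unweighted": unweighted,
        "weighted": weighted,
        "criterion_summary": criterion_summary(value_system, criteria),
    }


def polar_chart_csv(value_system: ValueSystem, criteria: Sequence[Criterion]) -> str:
    """CSV of (criterion, weight) rows in weight-descending order."""
    lines = ["criterion_id,weight_percent"]
    for cid, w in criterion_summary(value_system, criteria):
        lines.append(f"{cid},{w}")
    return "\n".join(lines) + "\n"
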