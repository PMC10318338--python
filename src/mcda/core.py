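"""Core domain types for multi-criteria decision analysis.

A decision problem is described by a set of :class:`Criterion` objects, each
carrying an ordered ladder of qualitative performance levels (worst first), a
:class:`PerformanceMatrix` assigning every alternative a level on every
criterion, and a :class:`ValueSystem` holding the part-worth value (in percent)
of each level on each criterion.  In a normalised value system the worst level
of every criterion is worth 0 and the best level is worth the criterion's
weight, so the weights sum to 100 and the best possible alternative scores 100.

Tabular fixtures are read and written as plain CSV or an equivalent JSON
mirror; numeric values are carried as :class:`decimal.Decimal` so that totals
printed to one decimal place are reproduced exactly, without binary-float
drift.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

Number = Union[int, float, Decimal]

RAG_COLOURS = ("red", "amber", "green")


class MCDAError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(MCDAError):
    """An input object violates a structural invariant."""


class ConfigurationError(MCDAError):
    """Inputs are individually valid but mutually inconsistent."""


@dataclass(frozen=True)
class PerformanceLevel:
    """One rung of a criterion's quality ladder.

    ``rank`` is the quality index (0 = worst); ``ordinal_points`` is the
    1-based coding used by the unweighted scoring model.
    """

    label: str
    rank: int

    @property
    def ordinal_points(self) -> int:
        return self.rank + 1


@dataclass(frozen=True)
class Criterion:
    """A named decision criterion with an ordered set of performance levels."""

    id: str
    name: str
    domain_tag: str
    levels: tuple[PerformanceLevel, ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValidationError(
                f"criterion {self.id!r} has {len(self.levels)} level(s); at least 2 required"
            )
        labels = [lv.label for lv in self.levels]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"criterion {self.id!r} has duplicate level labels")
        if [lv.rank for lv in self.levels] != list(range(len(self.levels))):
            raise ValidationError(
                f"criterion {self.id!r}: level ranks must be exactly 0..{len(self.levels) - 1}"
            )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def worst(self) -> PerformanceLevel:
        return self.levels[0]

    @property
    def best(self) -> PerformanceLevel:
        return self.levels[-1]

    def level(self, label: str) -> PerformanceLevel:
        for lv in self.levels:
            if lv.label == label:
                return lv
        raise KeyError(f"criterion {self.id!r} has no level labelled {label!r}")

    def has_level(self, label: str) -> bool:
        return any(lv.label == label for lv in self.levels)


@dataclass
class PerformanceMatrix:
    """Alternatives x criteria grid of qualitative level assignments."""

    alternatives: list[str]
    assignments: dict[tuple[str, str], str]  # (alternative, criterion id) -> level label

    def level_label(self, alternative: str, criterion_id: str) -> str:
        try:
            return self.assignments[(alternative, criterion_id)]
        except KeyError:
            raise KeyError(
                f"no assignment for alternative {alternative!r} on criterion {criterion_id!r}"
            ) from None

    def row(self, alternative: str, criteria: Sequence[Criterion]) -> dict[str, str]:
        """The level assignment of one alternative as a criterion id -> label map."""
        if alternative not in self.alternatives:
            raise KeyError(f"unknown alternative {alternative!r}")
        return {c.id: self.level_label(alternative, c.id) for c in criteria}


@dataclass
class ValidationReport:
    """Problems found when checking a matrix against its criteria."""

    missing_cells: list[tuple[str, str]] = field(default_factory=list)
    unknown_labels: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.missing_cells and not self.unknown_labels

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "missing_cells": [list(c) for c in self.missing_cells],
            "unknown_labels": [list(c) for c in self.unknown_labels],
            "warnings": list(self.warnings),
        }


@dataclass
class ValueSystem:
    """Per-criterion level values (part-worths) in percent.

    ``level_values`` maps ``(criterion id, level label)`` to the value that
    level contributes to an alternative's total.  ``criterion_weights`` is
    derived as the best-level value of each criterion unless given explicitly
    (tabulated weights may differ from the best-level value by rounding).
    """

    level_values: dict[tuple[str, str], Number]
    explicit_weights: dict[str, Number] | None = None

    def value(self, criterion_id: str, label: str) -> Number:
        try:
            return self.level_values[(criterion_id, label)]
        except KeyError:
            raise ConfigurationError(
                f"no value for level {label!r} of criterion {criterion_id!r}"
            ) from None

    def criterion_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for cid, _ in self.level_values:
            seen.setdefault(cid)
        return list(seen)

    def weight(self, criterion_id: str) -> Number:
        if self.explicit_weights is not None and criterion_id in self.explicit_weights:
            return self.explicit_weights[criterion_id]
        vals = [v for (cid, _), v in self.level_values.items() if cid == criterion_id]
        if not vals:
            raise ConfigurationError(f"criterion {criterion_id!r} not in value system")
        return max(vals)

    @property
    def criterion_weights(self) -> dict[str, Number]:
        return {cid: self.weight(cid) for cid in self.criterion_ids()}

    def weight_total(self) -> Number:
        return sum(self.criterion_weights.values())

    def validate(
        self,
        criteria: Sequence[Criterion],
        *,
        weight_tolerance: float = 0.15,
        sum_tolerance: float = 0.5,
    ) -> None:
        """Check the normalisation invariants against a criteria set.

        Raises :class:`ValidationError` if any criterion's worst level is not
        worth 0, values decrease with level rank, a best-level value strays
        from the tabulated weight by more than ``weight_tolerance``, or the
        weights do not sum to 100 within ``sum_tolerance``.
        """
        for crit in criteria:
            values = [float(self.value(crit.id, lv.label)) for lv in crit.levels]
            if values[0] != 0:
                raise ValidationError(
                    f"criterion {crit.id!r}: worst level {crit.worst.label!r} "
                    f"has value {values[0]}, expected 0"
                )
            for lo, hi in zip(values, values[1:]):
                if hi < lo:
                    raise ValidationError(
                        f"criterion {crit.id!r}: level values decrease ({lo} -> {hi})"
                    )
            w = float(self.weight(crit.id))
            if abs(values[-1] - w) > weight_tolerance:
                raise ValidationError(
                    f"criterion {crit.id!r}: best-level value {values[-1]} differs "
                    f"from weight {w} by more than {weight_tolerance}"
                )
        total = float(sum(float(self.weight(c.id)) for c in criteria))
        if abs(total - 100.0) > sum_tolerance:
            raise ValidationError(
                f"criterion weights sum to {total}, expected 100 +/- {sum_tolerance}"
            )


def validate_matrix(
    matrix: PerformanceMatrix, criteria: Sequence[Criterion]
) -> ValidationReport:
    """Report missing cells and unknown labels; empty report iff consistent."""
    report = ValidationReport()
    by_id = {c.id: c for c in criteria}
    for alt in matrix.alternatives:
        for crit in criteria:
            key = (alt, crit.id)
            if key not in matrix.assignments:
                report.missing_cells.append(key)
                continue
            label = matrix.assignments[key]
            if not crit.has_level(label):
                report.unknown_labels.append((alt, crit.id, label))
    for (alt, cid), _ in matrix.assignments.items():
        if cid not in by_id:
            report.unknown_labels.append((alt, cid, matrix.assignments[(alt, cid)]))
    return report


def rag_render(
    matrix: PerformanceMatrix, criteria: Sequence[Criterion]
) -> dict[tuple[str, str], str]:
    """Red/amber/green tag per cell: rank 0 -> red, 1 -> amber, 2 -> green.

    Only defined for three-level criteria (the qualitative traffic-light
    convention); any other ladder length raises :class:`ValidationError`.
    """
    for crit in criteria:
        if crit.n_levels != 3:
            raise ValidationError(
                f"RAG rendering needs exactly 3 levels; criterion {crit.id!r} "
                f"has {crit.n_levels}"
            )
    out: dict[tuple[str, str], str] = {}
    for alt in matrix.alternatives:
        for crit in criteria:
            rank = crit.level(matrix.level_label(alt, crit.id)).rank
            out[(alt, crit.id)] = RAG_COLOURS[rank]
    return out


# ---------------------------------------------------------------------------
# (De)serialisation.  Every reader accepts a path, raw CSV text, or raw JSON
# text (sniffed by a leading '{' / '[').


def _read_source(source: Union[str, Path]) -> str:
    if isinstance(source, Path):
        return source.read_text(encoding="utf-8")
    text = str(source)
    stripped = text.lstrip()
    if "\n" not in text and not stripped.startswith(("{", "[")):
        p = Path(text)
        if p.exists():
            return p.read_text(encoding="utf-8")
    return text


def _is_json(text: str) -> bool:
    return text.lstrip()[:1] in ("{", "[")


def _csv_rows(text: str, required: Sequence[str], what: str) -> list[dict[str, str]]:
    reader = csv.DictReader(io.StringIO(text))
    fields = reader.fieldnames or []
    missing = [c for c in required if c not in fields]
    if missing:
        raise ValidationError(f"{what}: missing column(s) {', '.join(missing)}")
    return [row for row in reader if any((v or "").strip() for v in row.values())]


def load_criteria(source: Union[str, Path]) -> list[Criterion]:
    """Parse criteria from CSV (criterion_id,name,domain_tag,level_rank,level_label)
    or the JSON mirror; levels are returned sorted by rank."""
    text = _read_source(source)
    if _is_json(text):
        docs = json.loads(text)
        out = []
        for doc in docs:
            levels = tuple(
                PerformanceLevel(label=lv["label"], rank=int(lv["rank"]))
                for lv in sorted(doc["levels"], key=lambda lv: int(lv["rank"]))
            )
            out.append(
                Criterion(
                    id=doc["id"],
                    name=doc.get("name", doc["id"]),
                    domain_tag=doc.get("domain_tag", ""),
                    levels=levels,
                )
            )
        return out
    rows = _csv_rows(
        text, ["criterion_id", "name", "domain_tag", "level_rank", "level_label"], "criteria"
    )
    grouped: dict[str, dict] = {}
    for row in rows:
        cid = row["criterion_id"].strip()
        g = grouped.setdefault(
            cid, {"name": row["name"], "domain_tag": row["domain_tag"], "levels": {}}
        )
        rank = int(row["level_rank"])
        if rank in g["levels"]:
            raise ValidationError(f"criterion {cid!r}: duplicate level rank {rank}")
        g["levels"][rank] = row["level_label"]
    out = []
    for cid, g in grouped.items():
        levels = tuple(
            PerformanceLevel(label=g["levels"][r], rank=r) for r in sorted(g["levels"])
        )
        out.append(Criterion(id=cid, name=g["name"], domain_tag=g["domain_tag"], levels=levels))
    return out


def dump_criteria(criteria: Sequence[Criterion], fmt: str = "csv") -> str:
    if fmt == "json":
        return json.dumps(
            [
                {
                    "id": c.id,
                    "name": c.name,
                    "domain_tag": c.domain_tag,
                    "levels": [{"label": lv.label, "rank": lv.rank} for lv in c.levels],
                }
                for c in criteria
            ],
            indent=2,
        )
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["criterion_id", "name", "domain_tag", "level_rank", "level_label"])
    for c in criteria:
        for lv in c.levels:
            w.writerow([c.id, c.name, c.domain_tag, lv.rank, lv.label])
    return buf.getvalue()


def load_matrix(source: Union[str, Path]) -> PerformanceMatrix:
    """Parse a performance matrix from CSV (alternative,criterion_id,level_label)
    or the JSON mirror. Alternative order follows first appearance."""
    text = _read_source(source)
    alternatives: list[str] = []
    assignments: dict[tuple[str, str], str] = {}

    def put(alt: str, cid: str, label: str) -> None:
        if alt not in alternatives:
            alternatives.append(alt)
        key = (alt, cid)
        if key in assignments:
            raise ValidationError(
                f"matrix: duplicate assignment for {alt!r} on {cid!r}"
            )
        assignments[key] = label

    if _is_json(text):
        doc = json.loads(text)
        for alt in doc["alternatives"]:
            for cid, label in doc["assignments"][alt].items():
                put(alt, cid, label)
    else:
        for row in _csv_rows(text, ["alternative", "criterion_id", "level_label"], "matrix"):
            put(row["alternative"].strip(), row["criterion_id"].strip(), row["level_label"])
    return PerformanceMatrix(alternatives=alternatives, assignments=assignments)


def dump_matrix(matrix: PerformanceMatrix, fmt: str = "csv") -> str:
    if fmt == "json":
        return json.dumps(
            {
                "alternatives": matrix.alternatives,
                "assignments": {
                    alt: {
                        cid: label
                        for (a, cid), label in matrix.assignments.items()
                        if a == alt
                    }
                    for alt in matrix.alternatives
                },
            },
            indent=2,
        )
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["alternative", "criterion_id", "level_label"])
    for (alt, cid), label in matrix.assignments.items():
        w.writerow([alt, cid, label])
    return buf.getvalue()


def load_values(source: Union[str, Path]) -> ValueSystem:
    """Parse level values from CSV (criterion_id,level_label,value_percent) or
    the JSON mirror; values become exact :class:`~decimal.Decimal`."""
    text = _read_source(source)
    level_values: dict[tuple[str, str], Number] = {}
    if _is_json(text):
        doc = json.loads(text)
        for cid, levels in doc["level_values"].items():
            for label, value in levels.items():
                level_values[(cid, label)] = Decimal(str(value))
    else:
        for row in _csv_rows(text, ["criterion_id", "level_label", "value_percent"], "values"):
            key = (row["criterion_id"].strip(), row["level_label"])
            if key in level_values:
                raise ValidationError(f"values: duplicate entry for {key}")
            level_values[key] = Decimal(row["value_percent"])
    return ValueSystem(level_values=level_values)


def dump_values(values: ValueSystem, fmt: str = "csv") -> str:
    if fmt == "json":
        by_crit: dict[str, dict[str, str]] = {}
        for (cid, label), v in values.level_values.items():
            by_crit.setdefault(cid, {})[label] = str(v)
        return json.dumps({"level_values": by_crit}, indent=2)
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["criterion_id", "level_label", "value_percent"])
    for (cid, label), v in values.level_values.items():
        w.writerow([cid, label, v])
    return buf.getvalue()
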