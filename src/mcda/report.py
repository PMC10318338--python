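"""Replication report and file validation.

:func:`replicate` re-derives the packaged study's headline numbers from the
shipped fixtures — unweighted totals 25/24/22/22 with ranks First / Second /
Joint third / Joint third, weighted totals 83.8/79.6/71.6/67.8 with ranks
First..Fourth, the weight ranking (patient needs 17.6 at the top, planning
7.8 at the bottom) and, optionally, the three-scenario PSA rank-stability
check — and compares them against the published values, flagging any
mismatch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Sequence

from . import fixtures
from .aggregation import RankingPolicy, criterion_summary, score_alternatives
from .core import load_criteria, load_matrix, load_values, validate_matrix
from .psa import PSAConfig, run_psa

EXPECTED_UNWEIGHTED = {
    "Computerised Interface": 25,
    "Built Environment": 24,
    "Written Communication": 22,
    "Face-to-Face": 22,
}
EXPECTED_WEIGHTED = {
    "Computerised Interface": Decimal("83.8"),
    "Built Environment": Decimal("79.6"),
    "Written Communication": Decimal("71.6"),
    "Face-to-Face": Decimal("67.8"),
}
EXPECTED_UNWEIGHTED_LABELS = {
    "Computerised Interface": "First",
    "Built Environment": "Second",
    "Written Communication": "Joint third",
    "Face-to-Face": "Joint third",
}
EXPECTED_WEIGHTED_LABELS = {
    "Computerised Interface": "First",
    "Built Environment": "Second",
    "Written Communication": "Third",
    "Face-to-Face": "Fourth",
}
EXPECTED_TOP_CRITERION = ("patient_needs", 17.6)
EXPECTED_BOTTOM_CRITERION = ("planning", 7.8)


@dataclass
class ReplicationReport:
    unweighted: dict
    weighted: dict
    criterion_summary: list[tuple[str, float]]
    mismatches: list[str] = field(default_factory=list)
    psa: dict | None = None

    @property
    def ok(self) -> bool:
        return not self.mismatches

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "unweighted": self.unweighted,
            "weighted": self.weighted,
            "criterion_summary": [list(kv) for kv in self.criterion_summary],
            "mismatches": self.mismatches,
            "psa": self.psa,
        }


def replicate(with_psa: bool = False, psa_seed: int = 42) -> ReplicationReport:
    """Recompute the packaged study's scores and ranks and check them
    against the published values.

    Raises :class:`~mcda.fixtures.FixtureIntegrityError` if the packaged
    fixtures were altered.  With ``with_psa`` the three uncertainty
    scenarios (1000 iterations, kappa=100, cv=0.1) are run and checked for
    preservation of the deterministic rank order.
    """
    fixtures.verify_checksums()
    criteria = fixtures.study_criteria()
    values = fixtures.study_values()
    mismatches: list[str] = []

    unw = score_alternatives(fixtures.study_matrix("unweighted"), criteria)
    wtd = score_alternatives(fixtures.study_matrix("weighted"), criteria, values)
    for alt, expected in EXPECTED_UNWEIGHTED.items():
        if unw.totals[alt] != expected:
            mismatches.append(
                f"unweighted total for {alt}: got {unw.totals[alt]}, expected {expected}"
            )
        if unw.rank_labels[alt] != EXPECTED_UNWEIGHTED_LABELS[alt]:
            mismatches.append(
                f"unweighted rank for {alt}: got {unw.rank_labels[alt]!r}, "
                f"expected {EXPECTED_UNWEIGHTED_LABELS[alt]!r}"
            )
    for alt, expected in EXPECTED_WEIGHTED.items():
        if wtd.totals[alt] != expected:
            mismatches.append(
                f"weighted total for {alt}: got {wtd.totals[alt]}, expected {expected}"
            )
        if wtd.rank_labels[alt] != EXPECTED_WEIGHTED_LABELS[alt]:
            mismatches.append(
                f"weighted rank for {alt}: got {wtd.rank_labels[alt]!r}, "
                f"expected {EXPECTED_WEIGHTED_LABELS[alt]!r}"
            )

    summary = criterion_summary(values, criteria)
    if summary[0] != EXPECTED_TOP_CRITERION:
        mismatches.append(f"top criterion: got {summary[0]}, expected {EXPECTED_TOP_CRITERION}")
    if summary[-1] != EXPECTED_BOTTOM_CRITERION:
        mismatches.append(
            f"bottom criterion: got {summary[-1]}, expected {EXPECTED_BOTTOM_CRITERION}"
        )

    psa_block = None
    if with_psa:
        base_order = sorted(wtd.totals, key=lambda a: -float(wtd.totals[a]))
        psa_block = {"base_rank_order": base_order, "scenarios": {}}
        matrix_w = fixtures.study_matrix("weighted")
        for scenario in ("scores", "weights", "both"):
            result = run_psa(
                matrix_w, criteria, values,
                PSAConfig(scenario=scenario, seed=psa_seed),
            )
            order = result.mean_rank_order()
            psa_block["scenarios"][scenario] = {
                "mean_rank_order": order,
                "mean": result.mean,
                "first_rank_prob": result.first_rank_probability,
            }
            if order != base_order:
                mismatches.append(
                    f"PSA scenario {scenario!r} changed the rank order: {order}"
                )

    return ReplicationReport(
        unweighted=unw.to_dict(),
        weighted=wtd.to_dict(),
        criterion_summary=summary,
        mismatches=mismatches,
        psa=psa_block,
    )


def validate_files(
    criteria_path: str | Path,
    matrix_path: str | Path | None = None,
    values_path: str | Path | None = None,
) -> dict:
    """Run all structural validators over user files; returns a
    machine-readable report (never raises for content problems)."""
    report: dict = {"ok": True, "errors": [], "warnings": []}
    try:
        criteria = load_criteria(Path(criteria_path))
    except Exception as err:
        return {"ok": False, "errors": [f"criteria: {err}"], "warnings": []}
    report["criteria"] = {"count": len(criteria)}
    if matrix_path is not None:
        matrix = load_matrix(Path(matrix_path))
        vr = validate_matrix(matrix, criteria)
        report["matrix"] = vr.to_dict()
        if not vr.ok:
            report["ok"] = False
            report["errors"].extend(
                [f"matrix: missing cell {c}" for c in vr.missing_cells]
                + [f"matrix: unknown label {c}" for c in vr.unknown_labels]
            )
    if values_path is not None:
        values = load_values(Path(values_path))
        try:
            values.validate(criteria)
            report["values"] = {"ok": True, "weight_total": float(values.weight_total())}
        except Exception as err:
            report["ok"] = False
            report["errors"].append(f"values: {err}")
    return report


def validate_study_fixtures() -> dict:
    """Cross-check the packaged fixtures; passes with the two documented
    discrepancy warnings between the qualitative matrix and the score table."""
    criteria = fixtures.study_criteria()
    values = fixtures.study_values()
    report: dict = {"ok": True, "errors": [], "warnings": fixtures.fixture_discrepancies()}
    for name in ("unweighted", "weighted"):
        vr = validate_matrix(fixtures.study_matrix(name), criteria)
        if not vr.ok:
            report["ok"] = False
            report["errors"].append(f"matrix_{name}: {vr.to_dict()}")
    values.validate(criteria)
    report["weight_total"] = float(values.weight_total())
    return report
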