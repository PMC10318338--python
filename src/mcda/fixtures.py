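"""Packaged study fixtures: the NHS medication-optimisation MCDA.

The package ships the published decision problem — ten implementation
criteria on three-point quality ladders, four nudge-intervention types
(Computerised Interface, Built Environment, Written Communication,
Face-to-Face), the group preference weights elicited from 356 NHS quality
improvers, and the researchers' performance assessments — as plain CSV
fixtures so the whole pipeline is reproducible offline.

Two reconciliation quirks in the published tables are preserved rather than
silently repaired (see :func:`fixture_discrepancies`):

* The published score table and the qualitative performance matrix disagree
  on Built Environment / available resources (middle vs top level).  The
  replication matrices follow the score table, whose columns sum exactly to
  the published totals; the qualitative matrix is kept verbatim as
  ``table2`` for reference.
* The published score table assigns the patient-needs criterion the middle
  level in its unweighted half but credits the top-level value in its
  weighted half.  No single level assignment reproduces both halves, so the
  package ships ``matrix_unweighted`` and ``matrix_weighted`` which differ
  only on that row.

The packaged level-value table likewise follows the score table where the
published weight table drifts by a rounding step (Moderately available:
4.4 vs 4.5).
"""

from __future__ import annotations

import hashlib
from importlib import resources

from .core import Criterion, PerformanceMatrix, ValueSystem, load_criteria, load_matrix, load_values

ALTERNATIVES = (
    "Computerised Interface",
    "Built Environment",
    "Written Communication",
    "Face-to-Face",
)

_FILES = {
    "criteria": "criteria.csv",
    "values": "values.csv",
    "matrix_unweighted": "matrix_unweighted.csv",
    "matrix_weighted": "matrix_weighted.csv",
    "table2": "table2_matrix.csv",
}

# sha256 of each packaged fixture; replicate() refuses to run on altered data
CHECKSUMS = {
    "criteria": "97ff1c3803642509554d5ada186daff6f74aa0cae33c0be32fbe2ffbc8b9b47d",
    "values": "e022ef66a1836930f2a317343c52edbd6a6f36b2a30b849f1fd6b6a475f95911",
    "matrix_unweighted": "7cf9fc1d285c795e9c9c7bc4d65c2264489a9698f2f3c22ad8284da8de0367a4",
    "matrix_weighted": "fdc3c8f2cff1c5ad033cd6247fa00c10a321d3da0372a222d878cc7459e43248",
    "table2": "09e164fb63a8b4dcf150264848b71ab365547ef6afdf1a5e59909c998912ae4c",
}


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture does not match its recorded checksum."""


def fixture_text(name: str) -> str:
    """Raw CSV text of a packaged fixture (see ``_FILES`` for names)."""
    path = resources.files("mcda").joinpath("data", _FILES[name])
    return path.read_text(encoding="utf-8")


def verify_checksums() -> None:
    for name in _FILES:
        digest = hashlib.sha256(fixture_text(name).encode("utf-8")).hexdigest()
        if digest != CHECKSUMS[name]:
            raise FixtureIntegrityError(
                f"fixture {name!r} checksum mismatch: {digest} != {CHECKSUMS[name]}"
            )


def study_criteria() -> list[Criterion]:
    """The ten implementation criteria, each with a three-level ladder."""
    return load_criteria(fixture_text("criteria"))


def study_values() -> ValueSystem:
    """Group preference values: worst level 0, best level = criterion weight."""
    return load_values(fixture_text("values"))


def study_matrix(model: str = "weighted") -> PerformanceMatrix:
    """Replication performance matrix for the requested scoring model.

    ``model`` is ``"weighted"`` or ``"unweighted"``; the two differ only on
    the patient-needs row (see module docstring).
    """
    if model not in ("weighted", "unweighted"):
        raise ValueError(f"model must be 'weighted' or 'unweighted', got {model!r}")
    return load_matrix(fixture_text(f"matrix_{model}"))


def table2_matrix() -> PerformanceMatrix:
    """The qualitative performance matrix exactly as published."""
    return load_matrix(fixture_text("table2"))


def fixture_discrepancies() -> list[str]:
    """Human-readable list of the known disagreements between the published
    qualitative matrix and the published score table (computed, not frozen)."""
    crits = study_criteria()
    by_id = {c.id: c for c in crits}
    out = []
    t2, unw, wtd = table2_matrix(), study_matrix("unweighted"), study_matrix("weighted")
    for alt in ALTERNATIVES:
        for c in crits:
            a, b = t2.level_label(alt, c.id), unw.level_label(alt, c.id)
            if a != b:
                out.append(
                    f"{alt} / {c.id}: qualitative matrix says {a!r} but the "
                    f"score table implies {b!r}"
                )
    rows = set()
    for alt in ALTERNATIVES:
        for c in crits:
            a, b = unw.level_label(alt, c.id), wtd.level_label(alt, c.id)
            if a != b:
                rows.add(c.id)
    for cid in sorted(rows):
        out.append(
            f"{cid}: the score table's unweighted half uses rank "
            f"{by_id[cid].level(unw.level_label(ALTERNATIVES[0], cid)).rank} but its "
            f"weighted half credits the value of rank "
            f"{by_id[cid].level(wtd.level_label(ALTERNATIVES[0], cid)).rank}"
        )
    return out
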