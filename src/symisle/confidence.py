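"""Gene-model confidence classification from database-evidence rules.

Predicted proteins are compared against three databases — UniMag
(validated Magnoliophyta proteins), Fab (annotated legume proteins) and
PTREP (hypothetical transposon-associated proteins) — and classified from
completeness (start and stop codon present) plus which databases yield a
significant hit:

    REPEAT  significant hit in PTREP only
    HC1     complete, UniMag hit with subject AND query coverage above threshold
    HC2     complete, no UniMag hit, Fab hit, no PTREP hit
    LC1     incomplete, UniMag or Fab hit, no PTREP hit
    LC2     complete, no hit in any database
    UNCLASSIFIED  anything else

A hit is significant when its E-value is below the threshold (default
1e-10; the published protocol's "10e-10" is ambiguous between 1e-9 and
1e-10, so the threshold is configurable) and its subject coverage is
strictly above the coverage threshold (default 0.80).  The rules are
checked in the order listed, so evidence combinations the prose does not
cover resolve deterministically; PTREP-only evidence is claimed by REPEAT
before LC2 can see it.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from symisle.errors import FormatError, SymisleError


class ConfidenceClass(str, enum.Enum):
    HC1 = "HC1"
    HC2 = "HC2"
    LC1 = "LC1"
    LC2 = "LC2"
    REPEAT = "REPEAT"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class DatabaseHit:
    """Best hit of a protein in one database."""

    evalue: float
    subject_coverage: float
    query_coverage: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.subject_coverage <= 1.0:
            raise SymisleError("subject_coverage must be in [0, 1]")
        if self.query_coverage is not None and not 0.0 <= self.query_coverage <= 1.0:
            raise SymisleError("query_coverage must be in [0, 1]")


@dataclass(frozen=True)
class ProteinEvidence:
    protein_id: str
    is_complete: bool
    unimag: Optional[DatabaseHit] = None
    fab: Optional[DatabaseHit] = None
    ptrep: Optional[DatabaseHit] = None


@dataclass(frozen=True)
class Thresholds:
    evalue: float = 1e-10
    coverage: float = 0.80


def significant_hit(
    hit: Optional[DatabaseHit],
    evalue_threshold: float = 1e-10,
    coverage_threshold: float = 0.80,
) -> bool:
    """True iff the hit exists, evalue < threshold and subject coverage > threshold."""
    return (
        hit is not None
        and hit.evalue < evalue_threshold
        and hit.subject_coverage > coverage_threshold
    )


def classify(
    evidence: ProteinEvidence, thresholds: Thresholds = Thresholds()
) -> ConfidenceClass:
    """Assign exactly one confidence class to a protein."""
    t_e, t_c = thresholds.evalue, thresholds.coverage
    u = significant_hit(evidence.unimag, t_e, t_c)
    f = significant_hit(evidence.fab, t_e, t_c)
    p = significant_hit(evidence.ptrep, t_e, t_c)
    complete = evidence.is_complete

    if p and not u and not f:
        return ConfidenceClass.REPEAT
    if (
        complete
        and u
        and evidence.unimag.query_coverage is not None
        and evidence.unimag.query_coverage > t_c
    ):
        return ConfidenceClass.HC1
    if complete and not u and f and not p:
        return ConfidenceClass.HC2
    if not complete and (u or f) and not p:
        return ConfidenceClass.LC1
    if complete and not u and not f and not p:
        return ConfidenceClass.LC2
    return ConfidenceClass.UNCLASSIFIED


def classify_batch(
    evidence: Iterable[ProteinEvidence], thresholds: Thresholds = Thresholds()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify many proteins; returns the class table and per-class counts."""
    rows = []
    seen: set[str] = set()
    for ev in evidence:
        if ev.protein_id in seen:
            raise SymisleError(f"duplicate protein_id: {ev.protein_id!r}")
        seen.add(ev.protein_id)
        rows.append(
            {"protein_id": ev.protein_id, "confidence_class": classify(ev, thresholds).value}
        )
    table = pd.DataFrame(rows, columns=["protein_id", "confidence_class"])
    counts = Counter(table["confidence_class"]) if len(table) else Counter()
    return table, {c.value: counts.get(c.value, 0) for c in ConfidenceClass}


# ---------------------------------------------------------------------------
# evidence TSV I/O: protein_id, complete, then evalue/scov/qcov per database
# (empty field = no hit in that database)
# ---------------------------------------------------------------------------

_DBS = ("unimag", "fab", "ptrep")


def read_evidence_table(path) -> list[ProteinEvidence]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["protein_id", "complete"] + [
        f"{db}_{col}" for db in _DBS for col in ("evalue", "scov", "qcov")
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"evidence table missing columns: {missing}")
    out = []
    for i, row in df.iterrows():
        hits = {}
        for db in _DBS:
            ev = row[f"{db}_evalue"]
            if ev == "":
                hits[db] = None
                continue
            qcov = row[f"{db}_qcov"]
            hits[db] = DatabaseHit(
                evalue=float(ev),
                subject_coverage=float(row[f"{db}_scov"]),
                query_coverage=float(qcov) if qcov != "" else None,
            )
        out.append(
            ProteinEvidence(
                protein_id=row["protein_id"],
                is_complete=str(row["complete"]).strip().lower() in {"1", "true", "yes"},
                unimag=hits["unimag"],
                fab=hits["fab"],
                ptrep=hits["ptrep"],
            )
        )
    return out


def write_class_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
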