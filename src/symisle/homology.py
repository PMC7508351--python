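"""Tabular similarity-search parsing and best-hit selection.

Reads BLAST outfmt-6-style TSV (12 standard columns, optionally two extra
coverage columns) and extracts the single best target-species hit per
query: maximum bitscore, ties broken by lower E-value, then by
lexicographically smallest subject id, so the result is independent of the
input row order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from symisle.errors import FormatError

#: query_id -> (subject_id, bitscore, evalue)
BestHitMap = dict[str, tuple[str, float, float]]


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float
    query_coverage: Optional[float] = None
    subject_coverage: Optional[float] = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise FormatError(f"negative evalue for query {self.query_id!r}")
        if not math.isfinite(self.bitscore):
            raise FormatError(f"non-finite bitscore for query {self.query_id!r}")

    def to_row(self) -> list[str]:
        row = [
            self.query_id,
            self.subject_id,
            f"{self.percent_identity:g}",
            str(self.align_length),
            str(self.mismatches),
            str(self.gap_opens),
            str(self.query_start),
            str(self.query_end),
            str(self.subject_start),
            str(self.subject_end),
            f"{self.evalue:g}",
            f"{self.bitscore:g}",
        ]
        if self.query_coverage is not None and self.subject_coverage is not None:
            row += [f"{self.query_coverage:g}", f"{self.subject_coverage:g}"]
        return row


def parse_similarity_table(path, has_coverage_columns: bool = True) -> list[SimilarityHit]:
    """Parse an outfmt-6 TSV; errors name the offending line number.

    Accepts 12 columns, or 14 (qcov, scov appended) when
    ``has_coverage_columns`` is true.
    """
    expected = 14 if has_coverage_columns else 12
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != expected:
                raise FormatError(
                    f"line {lineno}: expected {expected} tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                hit = SimilarityHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    percent_identity=float(parts[2]),
                    align_length=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    query_start=int(parts[6]),
                    query_end=int(parts[7]),
                    subject_start=int(parts[8]),
                    subject_end=int(parts[9]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                    query_coverage=float(parts[12]) if expected == 14 else None,
                    subject_coverage=float(parts[13]) if expected == 14 else None,
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_similarity_hits(hits: Iterable[SimilarityHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(h.to_row()) + "\n")


def select_best_hits(
    hits: Iterable[SimilarityHit],
    max_evalue: Optional[float] = None,
    reciprocal: bool = False,
) -> BestHitMap:
    """One best hit per query: max bitscore, then min evalue, then min subject id.

    ``max_evalue`` optionally drops hits with evalue above the threshold
    before selection.  With ``reciprocal`` only pairs that are also each
    other's best in the reverse direction are kept (off by default; the
    analysis uses one-way best hits).
    """
    best: BestHitMap = {}
    for h in hits:
        if max_evalue is not None and h.evalue > max_evalue:
            continue
        cur = best.get(h.query_id)
        cand = (h.subject_id, h.bitscore, h.evalue)
        if cur is None or _better(cand, cur):
            best[h.query_id] = cand
    if reciprocal:
        reverse: BestHitMap = {}
        for h in hits:
            if max_evalue is not None and h.evalue > max_evalue:
                continue
            cur = reverse.get(h.subject_id)
            cand = (h.query_id, h.bitscore, h.evalue)
            if cur is None or _better(cand, cur):
                reverse[h.subject_id] = cand
        best = {
            q: v
            for q, v in best.items()
            if reverse.get(v[0], ("",))[0] == q
        }
    return best


def _better(cand: tuple[str, float, float], cur: tuple[str, float, float]) -> bool:
    """Is ``cand`` preferred over ``cur``?  (bitscore desc, evalue asc, id asc)."""
    cs, cb, ce = cand
    us, ub, ue = cur
    if cb != ub:
        return cb > ub
    if ce != ue:
        return ce < ue
    return cs < us


def write_best_hits(best: Mapping[str, tuple[str, float, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tsubject_id\tbitscore\tevalue\n")
        for q in sorted(best):
            s, b, e = best[q]
            fh.write(f"{q}\t{s}\t{b:g}\t{e:g}\n")


def read_best_hits(path) -> BestHitMap:
    best: BestHitMap = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("query_id"):
            raise FormatError("line 1: expected header 'query_id\\tsubject_id\\t...'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise FormatError(f"line {lineno}: expected 4 columns, got {len(parts)}")
            best[parts[0]] = (parts[1], float(parts[2]), float(parts[3]))
    return best
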