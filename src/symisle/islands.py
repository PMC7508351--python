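"""Per-category island conservation counters and derived rates.

For each island category the module counts query-species (A) genes, those
with any best hit, the distinct target-species (B) genes they hit, the
distinct B genes inside microsyntenic regions, the matching lncRNA-only
counters, and islands where more than half of the members have a hit.
From the counters it derives the four headline rates:

    conservation rate (%)  = 100 * A genes with hit / A genes
    duplication rate       = A genes with hit / distinct B genes
    microsynteny ratio (%) = 100 * syntenic B genes / distinct B genes
    majority-hit (%)       = 100 * islands with hits in > half of members / islands

A duplication rate above 1 means several A genes map onto one B gene —
the many-to-one signature of local tandem amplification in the query
species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from symisle.errors import SymisleError
from symisle.microsynteny import MicrosyntenyCall


@dataclass
class IslandSummary:
    """Raw counters for one island category."""

    category: str
    n_islands: int = 0
    n_A_genes: int = 0
    n_A_genes_with_hit: int = 0
    n_distinct_B_genes: int = 0
    n_B_genes_with_synteny: int = 0
    n_A_lncRNAs: int = 0
    n_A_lncRNAs_with_hit: int = 0
    n_A_lncRNAs_with_syntenic_hit: int = 0
    n_islands_majority_hit: int = 0

    def check_nesting(self) -> None:
        ok = (
            self.n_A_genes_with_hit <= self.n_A_genes
            and self.n_distinct_B_genes <= self.n_A_genes_with_hit
            and self.n_B_genes_with_synteny <= self.n_distinct_B_genes
            and self.n_A_lncRNAs <= self.n_A_genes
            and self.n_A_lncRNAs_with_hit <= self.n_A_lncRNAs
            and self.n_A_lncRNAs_with_syntenic_hit <= self.n_A_lncRNAs_with_hit
            and self.n_islands_majority_hit <= self.n_islands
        )
        if not ok:
            raise SymisleError(f"counter nesting violated for {self.category}")


@dataclass
class DerivedRates:
    """Rates derived from an :class:`IslandSummary`; None where undefined."""

    category: str
    conservation_rate_pct: Optional[float]
    duplication_rate: Optional[float]
    microsynteny_ratio_pct: Optional[float]
    majority_hit_pct: Optional[float]


def tabulate(
    islands: pd.DataFrame,
    members: Mapping[str, Sequence[str]],
    biotypes: Mapping[str, str],
    best_hits: Mapping[str, tuple[str, float, float]],
    synteny_calls: Mapping[str, MicrosyntenyCall],
) -> dict[str, IslandSummary]:
    """Count the conservation statistics per category.

    ``islands`` needs columns island_id and category; ``members`` maps
    island_id to its A gene ids; ``biotypes`` maps A gene id to
    "coding"/"lncRNA".  Distinct-B counting is per category.
    """
    summaries: dict[str, IslandSummary] = {}
    distinct_b: dict[str, set[str]] = {}
    syntenic_b: dict[str, set[str]] = {}

    for row in islands.itertuples(index=False):
        island_id = row.island_id
        category = getattr(row, "category", None)
        if category is None or (isinstance(category, float) and pd.isna(category)) or category == "":
            raise SymisleError(f"island {island_id!r} has no category")
        s = summaries.setdefault(category, IslandSummary(category=category))
        distinct_b.setdefault(category, set())
        syntenic_b.setdefault(category, set())

        island_members = list(members.get(island_id, []))
        call = synteny_calls.get(island_id)
        flags = call.member_flags if call is not None else {}

        s.n_islands += 1
        n_with_hit_here = 0
        for g in island_members:
            is_lnc = biotypes.get(g, "coding") == "lncRNA"
            s.n_A_genes += 1
            if is_lnc:
                s.n_A_lncRNAs += 1
            hit = best_hits.get(g)
            if hit is None:
                continue
            n_with_hit_here += 1
            s.n_A_genes_with_hit += 1
            distinct_b[category].add(hit[0])
            syntenic = bool(flags.get(g, False))
            if syntenic:
                syntenic_b[category].add(hit[0])
            if is_lnc:
                s.n_A_lncRNAs_with_hit += 1
                if syntenic:
                    s.n_A_lncRNAs_with_syntenic_hit += 1
        if island_members and n_with_hit_here * 2 > len(island_members):
            s.n_islands_majority_hit += 1

    for category, s in summaries.items():
        s.n_distinct_B_genes = len(distinct_b[category])
        s.n_B_genes_with_synteny = len(syntenic_b[category])
        s.check_nesting()
    return summaries


def derive_rates(summary: IslandSummary) -> DerivedRates:
    """Derive the four rates, with the display rounding of the analysis:

    conservation and microsynteny ratios to 1 decimal, duplication rate to
    2 decimals, majority-hit percentage to the nearest integer.  A zero
    denominator yields None rather than an exception.
    """

    def _ratio(num: int, den: int, scale: float, digits: int) -> Optional[float]:
        if den == 0:
            return None
        return round(scale * num / den, digits)

    majority = _ratio(summary.n_islands_majority_hit, summary.n_islands, 100.0, 0)
    return DerivedRates(
        category=summary.category,
        conservation_rate_pct=_ratio(
            summary.n_A_genes_with_hit, summary.n_A_genes, 100.0, 1
        ),
        duplication_rate=_ratio(
            summary.n_A_genes_with_hit, summary.n_distinct_B_genes, 1.0, 2
        ),
        microsynteny_ratio_pct=_ratio(
            summary.n_B_genes_with_synteny, summary.n_distinct_B_genes, 100.0, 1
        ),
        majority_hit_pct=None if majority is None else float(int(majority)),
    )


def category_totals(
    island_counts: Mapping[str, int], categories: Optional[Iterable[str]] = None
) -> int:
    """Total island count over a subset of categories (all when None)."""
    if categories is None:
        categories = island_counts.keys()
    return sum(int(island_counts[c]) for c in categories if c in island_counts)


def summary_table(
    summaries: Mapping[str, IslandSummary],
    order: Sequence[str] = ("NRU", "NRD", "NRN", "NDA", "NDD", "NDN"),
) -> pd.DataFrame:
    """Categories as columns, counters and derived rates as rows."""
    rows = [
        "Islands",
        "A genes",
        "A genes with B hits",
        "Corresponding B genes",
        "B genes with microsynteny",
        "A lncRNAs",
        "A lncRNAs with B hit",
        "A lncRNAs with syntenic B hit",
        "Conservation rate (%)",
        "Duplication rate",
        "Microsynteny ratio (%)",
        "Islands with hits in more than half of genes (%)",
    ]
    data: dict[str, list] = {}
    for cat in order:
        if cat not in summaries:
            continue
        s = summaries[cat]
        r = derive_rates(s)
        data[cat] = [
            s.n_islands,
            s.n_A_genes,
            s.n_A_genes_with_hit,
            s.n_distinct_B_genes,
            s.n_B_genes_with_synteny,
            s.n_A_lncRNAs,
            s.n_A_lncRNAs_with_hit,
            s.n_A_lncRNAs_with_syntenic_hit,
            r.conservation_rate_pct,
            r.duplication_rate,
            r.microsynteny_ratio_pct,
            None if r.majority_hit_pct is None else int(r.majority_hit_pct),
        ]
    return pd.DataFrame(data, index=rows, dtype=object)
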