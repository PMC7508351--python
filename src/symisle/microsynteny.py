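"""Microsynteny calling: do an island's best hits cluster in the target genome?

The criterion is positional, not collinear: best-hit target genes are
grouped per target chromosome, sorted by start coordinate, and split into
single-linkage clusters wherever the gap between consecutive gene starts
exceeds ``max_gap_bp``.  The cluster containing the most distinct target
genes is the island's microsyntenic region if it holds at least
``min_cluster`` distinct genes; members whose best hit lies inside it are
flagged microsyntenic.  Ties between equally large clusters go to the
smallest chromosome label, then the leftmost start, so the call is
deterministic and invariant to member order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from symisle.errors import SymisleError


@dataclass
class MicrosyntenyCall:
    island_id: str
    target_chromosome: str | None
    member_flags: dict[str, bool] = field(default_factory=dict)
    n_distinct_syntenic_targets: int = 0
    n_members_with_hit: int = 0

    def __post_init__(self) -> None:
        if self.target_chromosome is None and any(self.member_flags.values()):
            raise SymisleError("flags set but no target chromosome")


def call_microsynteny(
    island_id: str,
    island_members: Sequence[str],
    best_hits: Mapping[str, tuple[str, float, float]],
    target_genes: pd.DataFrame,
    max_gap_bp: int = 500_000,
    min_cluster: int = 2,
) -> MicrosyntenyCall:
    """Call the microsyntenic region of one island.

    ``target_genes`` must provide ``gene_id``, ``seqid`` and ``start`` for
    every subject that appears as a best hit; a missing subject raises an
    error naming the gene.
    """
    if max_gap_bp <= 0:
        raise SymisleError("max_gap_bp must be > 0")
    if min_cluster < 2:
        raise SymisleError("min_cluster must be >= 2")

    coords = target_genes.set_index("gene_id")[["seqid", "start"]]
    flags = {m: False for m in island_members}

    # distinct B genes hit by this island, with coordinates
    targets: dict[str, tuple[str, int]] = {}
    hit_of_member: dict[str, str] = {}
    for m in island_members:
        if m not in best_hits:
            continue
        b = best_hits[m][0]
        hit_of_member[m] = b
        if b not in targets:
            if b not in coords.index:
                raise SymisleError(f"no coordinates for target gene {b!r}")
            row = coords.loc[b]
            targets[b] = (str(row["seqid"]), int(row["start"]))

    if not targets:
        return MicrosyntenyCall(island_id, None, flags, 0, 0)

    # single-linkage gap clustering per chromosome
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for b, (chrom, start) in targets.items():
        by_chrom.setdefault(chrom, []).append((start, b))

    best_cluster: set[str] | None = None
    best_key: tuple[int, str, int] | None = None  # (-size, chrom, leftmost)
    best_chrom: str | None = None
    for chrom in sorted(by_chrom):
        positions = sorted(by_chrom[chrom])
        cluster: list[tuple[int, str]] = [positions[0]]
        chunks: list[list[tuple[int, str]]] = [cluster]
        for prev, cur in zip(positions, positions[1:]):
            if cur[0] - prev[0] <= max_gap_bp:
                cluster.append(cur)
            else:
                cluster = [cur]
                chunks.append(cluster)
        for chunk in chunks:
            key = (-len(chunk), chrom, chunk[0][0])
            if best_key is None or key < best_key:
                best_key = key
                best_cluster = {b for _pos, b in chunk}
                best_chrom = chrom

    assert best_cluster is not None
    if len(best_cluster) < min_cluster:
        return MicrosyntenyCall(island_id, None, flags, 0, len(hit_of_member))

    for m, b in hit_of_member.items():
        flags[m] = b in best_cluster
    return MicrosyntenyCall(
        island_id, best_chrom, flags, len(best_cluster), len(hit_of_member)
    )


def count_islands_with_min_syntenic_hits(
    calls: Iterable[MicrosyntenyCall], min_hits: int = 3
) -> int:
    """Number of islands with at least ``min_hits`` distinct syntenic targets."""
    return sum(1 for c in calls if c.n_distinct_syntenic_targets >= min_hits)


def write_synteny_calls(
    calls: Iterable[MicrosyntenyCall],
    categories: Mapping[str, str],
    path,
) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "island_id": c.island_id,
                "category": categories.get(c.island_id, ""),
                "chromosome": c.target_chromosome or "",
                "n_members": len(c.member_flags),
                "n_hits": c.n_members_with_hit,
                "n_distinct_syntenic_targets": c.n_distinct_syntenic_targets,
                "syntenic_members": ",".join(
                    sorted(m for m, f in c.member_flags.items() if f)
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
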