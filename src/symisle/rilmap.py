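"""RIL variant filtering, consensus genotyping and marker-coverage summaries.

Recombinant inbred lines (RILs) from a biparental cross are genotyped per
contig: variant sites are filtered on site quality (>= 30), depth (>= 50),
biallelism, absence of missing genotypes and parental contrast (both
parents homozygous for different alleles), each surviving site's per-line
genotype is translated to parental origin (A = first-parent allele,
B = second parent, H = heterozygous), and the modal call across a contig's
sites becomes the contig's consensus genotype for that line (ties and
empty contigs yield missing).  Marker-coverage summaries partition contigs
by which population(s) retained at least one SNP on them and report
counts, base pairs, percentages and N50/L50 per subset.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from symisle.errors import SymisleError

MISSING = "missing"


@dataclass(frozen=True)
class VariantRecord:
    """One variant site with per-sample diploid genotypes.

    Genotypes are strings "0/0", "1/1", "0/1", "./." (phased separators are
    normalized to '/'); ``depth`` is the site-level total depth.
    """

    contig: str
    position: int
    quality: float
    depth: int
    alleles: tuple[str, ...]
    genotypes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise SymisleError("position must be >= 1")
        if self.depth < 0:
            raise SymisleError("depth must be >= 0")


def _is_missing(gt: str) -> bool:
    return "." in gt


def _is_hom(gt: str) -> bool:
    a = gt.replace("|", "/").split("/")
    return len(a) == 2 and a[0] == a[1] and a[0] != "."


def filter_variants(
    records: Sequence[VariantRecord],
    gifu_sample: str,
    other_parent_sample: str,
    min_qual: float = 30.0,
    min_depth: int = 50,
) -> list[VariantRecord]:
    """Keep sites passing all five criteria, preserving input order.

    (1) quality >= min_qual, (2) depth >= min_depth, (3) biallelic,
    (4) no missing genotype in any sample, (5) parental contrast — both
    parents homozygous, for different alleles.
    """
    if records:
        samples = records[0].genotypes
        for parent in (gifu_sample, other_parent_sample):
            if parent not in samples:
                raise SymisleError(f"parent sample {parent!r} absent from records")
    kept = []
    for r in records:
        if r.quality < min_qual or r.depth < min_depth:
            continue
        if len(r.alleles) != 2:
            continue
        if any(_is_missing(gt) for gt in r.genotypes.values()):
            continue
        g1 = r.genotypes[gifu_sample]
        g2 = r.genotypes[other_parent_sample]
        if not (_is_hom(g1) and _is_hom(g2) and g1 != g2):
            continue
        kept.append(r)
    return kept


def _parental_origin(gt: str, gifu_gt: str, parent2_gt: str) -> str:
    gt = gt.replace("|", "/")
    if _is_missing(gt):
        return MISSING
    if gt == gifu_gt:
        return "A"
    if gt == parent2_gt:
        return "B"
    if not _is_hom(gt):
        return "H"
    return MISSING


def consensus_genotype(
    records: Sequence[VariantRecord],
    line: str,
    gifu_sample: str,
    other_parent_sample: str,
    include_het: bool = True,
) -> str:
    """Modal parental-origin call of one line across one contig's records.

    Ties between the most common calls, or no non-missing call at all,
    yield ``missing``.  Heterozygous calls compete in the mode by default
    (residual heterozygosity is real in RILs); ``include_het=False`` drops
    them before voting.
    """
    contigs = {r.contig for r in records}
    if len(contigs) > 1:
        raise SymisleError(f"records span multiple contigs: {sorted(contigs)}")
    calls = []
    for r in records:
        call = _parental_origin(
            r.genotypes.get(line, "./."),
            r.genotypes[gifu_sample].replace("|", "/"),
            r.genotypes[other_parent_sample].replace("|", "/"),
        )
        if call == MISSING:
            continue
        if call == "H" and not include_het:
            continue
        calls.append(call)
    if not calls:
        return MISSING
    counts = Counter(calls).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return MISSING
    return counts[0][0]


def consensus_matrix(
    records: Sequence[VariantRecord],
    lines: Sequence[str],
    gifu_sample: str,
    other_parent_sample: str,
    include_het: bool = True,
) -> pd.DataFrame:
    """Contig x line consensus calls over already-filtered records."""
    by_contig: dict[str, list[VariantRecord]] = {}
    for r in records:
        by_contig.setdefault(r.contig, []).append(r)
    data = {
        line: [
            consensus_genotype(by_contig[c], line, gifu_sample, other_parent_sample, include_het)
            for c in sorted(by_contig)
        ]
        for line in lines
    }
    return pd.DataFrame(data, index=sorted(by_contig))


def n50_l50(lengths: Sequence[int]) -> tuple[int, int]:
    """Smallest L50 such that the L50 longest contigs cover >= half the total;
    N50 is the length of the L50-th longest contig."""
    if not len(lengths):
        raise SymisleError("empty length list")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if (arr <= 0).any():
        raise SymisleError("contig lengths must be positive")
    half = arr.sum() / 2.0
    csum = np.cumsum(arr)
    l50 = int(np.searchsorted(csum, half) + 1)
    return int(arr[l50 - 1]), l50


def marker_coverage_summary(
    contig_lengths: Mapping[str, int],
    records_per_population: Mapping[str, Sequence[VariantRecord]],
) -> pd.DataFrame:
    """Table-1-style marker coverage: contigs partitioned by SNP content.

    ``records_per_population`` maps population name to its *kept* variant
    records (two populations expected).  Rows: the whole assembly, contigs
    with >= 1 SNP in any population, exclusively-population subsets, both,
    and none.  Percentages (1 decimal) are relative to the whole assembly.
    """
    pops = list(records_per_population)
    if len(pops) != 2:
        raise SymisleError("expected exactly two populations")
    contigs_with: dict[str, set[str]] = {
        p: {r.contig for r in records_per_population[p]} for p in pops
    }
    unknown = (contigs_with[pops[0]] | contigs_with[pops[1]]) - set(contig_lengths)
    if unknown:
        raise SymisleError(f"records on contigs without lengths: {sorted(unknown)}")

    all_contigs = set(contig_lengths)
    both = contigs_with[pops[0]] & contigs_with[pops[1]]
    only1 = contigs_with[pops[0]] - contigs_with[pops[1]]
    only2 = contigs_with[pops[1]] - contigs_with[pops[0]]
    any_snp = contigs_with[pops[0]] | contigs_with[pops[1]]
    none = all_contigs - any_snp

    total_n = len(all_contigs)
    total_bp = sum(contig_lengths.values())

    def _row(name: str, subset: set[str]) -> dict:
        bp = sum(contig_lengths[c] for c in subset)
        if subset:
            n50, l50 = n50_l50([contig_lengths[c] for c in subset])
        else:
            n50, l50 = 0, 0
        return {
            "dataset": name,
            "contig_count": len(subset),
            "contig_pct": round(100.0 * len(subset) / total_n, 1) if total_n else None,
            "total_bp": bp,
            "bp_pct": round(100.0 * bp / total_bp, 1) if total_bp else None,
            "N50": n50,
            "L50": l50,
        }

    rows = [
        _row("Assembly", all_contigs),
        _row("Containing >=1 SNP", any_snp),
        _row(f"Exclusively {pops[0]}", only1),
        _row(f"Exclusively {pops[1]}", only2),
        _row("Contains SNPs from both", both),
        _row("Does not contain any SNPs", none),
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path) -> tuple[list[VariantRecord], list[str], dict[str, int]]:
    """Read a (plain-text or bgzipped) VCF into VariantRecords.

    Returns (records, sample names, contig lengths from the header).
    Site depth is taken from INFO/DP, falling back to the sum of per-sample
    FORMAT/DP values.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        contig_lengths = {
            name: int(c.length) for name, c in vf.header.contigs.items() if c.length
        }
        for rec in vf:
            gts = {}
            dp_sum = 0
            for s in samples:
                sample = rec.samples[s]
                alleles = sample.get("GT")
                if alleles is None or any(a is None for a in alleles):
                    gts[s] = "./."
                else:
                    gts[s] = "/".join(str(a) for a in alleles)
                dp_sum += int(sample.get("DP") or 0)
            depth = int(rec.info.get("DP", dp_sum) or dp_sum)
            records.append(
                VariantRecord(
                    contig=rec.chrom,
                    position=rec.pos,
                    quality=float(rec.qual if rec.qual is not None else 0.0),
                    depth=depth,
                    alleles=tuple(rec.alleles),
                    genotypes=gts,
                )
            )
    return records, samples, contig_lengths


def records_from_frame(
    frame: pd.DataFrame, sample_names: Iterable[str]
) -> list[VariantRecord]:
    """Build records from the simulator's tabular form (see simulate module)."""
    names = list(sample_names)
    out = []
    for r in frame.itertuples(index=False):
        row = r._asdict()
        out.append(
            VariantRecord(
                contig=row["contig"],
                position=int(row["pos"]),
                quality=float(row["qual"]),
                depth=int(row["depth"]),
                alleles=tuple([row["ref"], *str(row["alt"]).split(",")]),
                genotypes={s: row[s] for s in names},
            )
        )
    return out


def write_consensus_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="contig")


def write_marker_summary(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, sep="\t", index=False)
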