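"""Count normalization, log nodule/root ratios and island co-expression.

Implements the expression half of the island-conservation analysis:
median-of-ratios size factors (the DESeq2 estimator, written out as a
formula), library-depth scaling, per-gene log2 nodule/root ratios, the
cross-species Pearson correlation of those ratios over best-hit pairs, and
the per-island mean pairwise expression correlation in two modes —
"redundant" (every query gene with a hit; a target gene matched by k query
genes appears k times) and "unique" (tandem duplicates collapsed to one
query gene per distinct microsyntenic target gene, islands with fewer than
three distinct target genes excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from symisle.errors import NormalizationError, SymisleError


@dataclass
class ExpressionMatrix:
    """Gene x sample counts plus sample metadata.

    ``counts`` is indexed by gene id with sample ids as columns; ``samples``
    has columns sample_id, species, condition, replicate.  Raw counts must
    be non-negative.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise SymisleError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples["sample_id"])
        if missing:
            raise SymisleError(f"samples missing metadata: {sorted(missing)}")

    def samples_for(self, condition: str) -> list[str]:
        sel = self.samples.loc[self.samples["condition"] == condition, "sample_id"]
        return [s for s in self.counts.columns if s in set(sel)]

    def write(self, counts_path, metadata_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        self.samples.to_csv(metadata_path, sep="\t", index=False)

    @classmethod
    def read(cls, counts_path, metadata_path) -> "ExpressionMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
        samples = pd.read_csv(metadata_path, sep="\t")
        return cls(counts=counts, samples=samples)


def size_factors_median_ratio(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For genes with nonzero counts in every sample, factor_j is the median
    over those genes of counts[g, j] / geometric_mean_g(counts[g, :]).
    """
    values = counts.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError("no gene has nonzero counts in all samples")
    sub = values[positive]
    log_gm = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_gm)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, method: str = "median_ratio") -> pd.DataFrame:
    """Scale columns by size factors (``median_ratio``) or by library depth.

    ``library_depth`` divides each column by its total and rescales by the
    mean column total, so column sums become equal.
    """
    if method == "median_ratio":
        factors = size_factors_median_ratio(counts)
        return counts / factors
    if method == "library_depth":
        totals = counts.sum(axis=0)
        if (totals == 0).any():
            bad = list(totals.index[totals == 0])
            raise NormalizationError(f"zero-total column(s): {bad}")
        return counts / totals * totals.mean()
    raise SymisleError(f"unknown normalization method: {method!r}")


def log_ratio(
    normalized: pd.DataFrame,
    nodule_samples: Sequence[str],
    root_samples: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2((mean nodule + pc) / (mean root + pc))."""
    if not len(nodule_samples) or not len(root_samples):
        raise SymisleError("both sample sets must be non-empty")
    for s in [*nodule_samples, *root_samples]:
        if s not in normalized.columns:
            raise SymisleError(f"unknown sample id: {s!r}")
    if pseudocount <= 0:
        raise SymisleError("pseudocount must be > 0")
    nod = normalized[list(nodule_samples)].mean(axis=1)
    root = normalized[list(root_samples)].mean(axis=1)
    out = np.log2((nod + pseudocount) / (root + pseudocount))
    out.name = "log2_nodule_root"
    return out


def cross_species_ratio_correlation(
    ratios_a: pd.Series,
    ratios_b: pd.Series,
    pairs: Sequence[tuple[str, str]],
) -> tuple[float, int]:
    """Pearson r of paired log ratios across species.

    ``pairs`` is a list of (A gene, B gene); a B gene matched by k A genes
    contributes k pairs (redundant mode).  Returns (nan, n) when fewer than
    three pairs have both ratios defined.
    """
    xs, ys = [], []
    for a, b in pairs:
        if a in ratios_a.index and b in ratios_b.index:
            x, y = ratios_a[a], ratios_b[b]
            if np.isfinite(x) and np.isfinite(y):
                xs.append(float(x))
                ys.append(float(y))
    n = len(xs)
    if n < 3:
        return float("nan"), n
    r = stats.pearsonr(xs, ys).statistic
    return float(r), n


@dataclass
class IslandCorrelation:
    """Mean pairwise expression correlation of one island's genes."""

    island_id: str
    mode: str  # "redundant" | "unique"
    mean_pairwise_r: Optional[float]
    n_genes_used: int
    n_pairs: int
    n_zero_variance: int = 0

    @property
    def defined(self) -> bool:
        return self.mean_pairwise_r is not None


def island_mean_pairwise_correlation(
    island_genes: Sequence[str],
    matrix: pd.DataFrame,
    samples_used: Sequence[str],
    island_id: str = "",
    mode: str = "redundant",
    log_transform: bool = True,
) -> IslandCorrelation:
    """Mean Pearson r over all unordered gene pairs of an island.

    Profiles are log2(normalized + 1) across ``samples_used``.  Repeated
    gene ids are legal (redundant mode duplicates a target gene matched by
    several query genes; such pairs contribute r = 1).  Genes with
    zero-variance profiles are excluded from pairing and counted; the mean
    is undefined when fewer than two usable profiles remain.
    """
    genes = [g for g in island_genes if g in matrix.index]
    profiles = matrix.loc[genes, list(samples_used)].to_numpy(dtype=float)
    if log_transform:
        profiles = np.log2(profiles + 1.0)
    variances = profiles.var(axis=1)
    usable = [i for i in range(len(genes)) if variances[i] > 0]
    n_zero = len(genes) - len(usable)
    n = len(usable)
    if n < 2:
        return IslandCorrelation(island_id, mode, None, n, 0, n_zero)
    sub = profiles[usable]
    corr = np.corrcoef(sub)
    iu = np.triu_indices(n, k=1)
    mean_r = float(np.mean(corr[iu]))
    return IslandCorrelation(island_id, mode, mean_r, n, n * (n - 1) // 2, n_zero)


@dataclass
class DeduplicatedIsland:
    """Unique-mode A<->B pairs for one island."""

    island_id: str
    pairs: list[tuple[str, str]] = field(default_factory=list)  # (A gene, B gene)
    excluded: bool = True  # fewer than min_distinct distinct syntenic B genes

    @property
    def a_genes(self) -> list[str]:
        return [a for a, _ in self.pairs]

    @property
    def b_genes(self) -> list[str]:
        return [b for _, b in self.pairs]


def deduplicate_island(
    island_members: Sequence[str],
    best_hits: Mapping[str, tuple[str, float, float]],
    synteny_call,
    min_distinct: int = 3,
) -> DeduplicatedIsland:
    """Collapse many-to-one hits to unique A<->B pairs within the synteny call.

    Only members whose best hit is flagged microsyntenic participate.  For
    each distinct B gene the A gene with the highest bitscore is retained
    (ties: smallest A gene id).  Islands with fewer than ``min_distinct``
    distinct B genes are marked excluded.
    """
    by_b: dict[str, tuple[float, str]] = {}  # B gene -> (bitscore, A gene)
    for a in island_members:
        if a not in best_hits or not synteny_call.member_flags.get(a, False):
            continue
        b, bitscore, _ev = best_hits[a]
        cur = by_b.get(b)
        if cur is None or bitscore > cur[0] or (bitscore == cur[0] and a < cur[1]):
            by_b[b] = (float(bitscore), a)
    pairs = sorted((a, b) for b, (_score, a) in by_b.items())
    return DeduplicatedIsland(
        island_id=synteny_call.island_id,
        pairs=pairs,
        excluded=len(by_b) < min_distinct,
    )


def high_correlation_fraction(
    correlations: Sequence[IslandCorrelation],
    threshold: float = 0.8,
    min_genes: int = 2,
) -> tuple[int, int]:
    """(number of defined islands with mean r > threshold, number defined).

    ``min_genes`` restricts to islands with at least that many usable
    profiles.  When comparing redundant against unique mode use
    ``min_genes=3`` so both modes are measured on the same island-size
    support (unique mode intrinsically requires three distinct target
    genes, while redundant mode would otherwise also count two-gene
    islands whose single pair crosses the threshold by sampling noise).
    """
    defined = [c for c in correlations if c.defined and c.n_genes_used >= min_genes]
    high = sum(1 for c in defined if c.mean_pairwise_r > threshold)
    return high, len(defined)


def proportion_excess_test(
    k1: int, n1: int, k2: int, n2: int
) -> tuple[float, float]:
    """One-sided two-proportion z-test for p1 > p2; returns (z, p-value)."""
    if min(n1, n2) == 0:
        return float("nan"), float("nan")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return float("nan"), 1.0
    z = (p1 - p2) / se
    return float(z), float(stats.norm.sf(z))


def write_island_correlations(correlations, categories: Mapping[str, str], path) -> None:
    rows = [
        {
            "island_id": c.island_id,
            "category": categories.get(c.island_id, ""),
            "mode": c.mode,
            "mean_r": "" if c.mean_pairwise_r is None else f"{c.mean_pairwise_r:.6f}",
            "n_genes": c.n_genes_used,
            "n_pairs": c.n_pairs,
            "n_zero_variance": c.n_zero_variance,
        }
        for c in correlations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def pairs_redundant(
    island_members: Sequence[str],
    best_hits: Mapping[str, tuple[str, float, float]],
) -> list[tuple[str, str]]:
    """All (A gene, best B hit) pairs of an island; duplicates B genes freely."""
    return [(a, best_hits[a][0]) for a in island_members if a in best_hits]
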