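"""Synthetic paired-genome, similarity, expression and RIL genotype generator.

The generator emulates the data regime of the cross-species island analysis:
a query species "A" (Medicago-like) whose symbiotic islands are contiguous
runs of genes containing tandemly duplicated coding genes and poorly
conserved lncRNAs, and a target species "B" (Lotus-like) in which each
conserved ancestral gene has exactly one counterpart that either stays in
the region syntenic to its island or is relocated elsewhere.  Expression
counts are negative binomial with island-level nodule/root regulation
shared between species at the ancestral-gene level, so tandem duplication
inflates within-island co-expression exactly as the analysis assumes.

All four simulation entry points are deterministic functions of
``(config, config.seed)``; each draws from an independent child stream of
the seed so the operations can be re-run in any order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from symisle.errors import ConfigurationError
from symisle.expression import ExpressionMatrix

#: Island regulation categories: nodule-vs-root up / down / non-regulated,
#: and nodule-development apical / differentiation / non-regulated zones.
CATEGORIES = ("NRU", "NRD", "NRN", "NDA", "NDD", "NDN")

# child-stream indices, one per simulation operation
_STREAM_GENOME = 0
_STREAM_SIMILARITY = 1
_STREAM_EXPRESSION = 2
_STREAM_RIL = 3


def _default_islands_per_category() -> dict[str, int]:
    # category sizes of the published Medicago island set
    return {"NRU": 270, "NRD": 89, "NRN": 84, "NDA": 49, "NDD": 211, "NDN": 57}


def _default_effects() -> dict[str, float]:
    # log2 nodule/root shifts of *regulated* genes; magnitudes are free
    # parameters set to realistic symbiosis-gene inductions (16-64 fold for
    # nodule-induced families), with NRD weaker than NRU so the
    # strong/weaker/null ordering of cross-species correlation is emergent
    return {"NRU": 4.0, "NRD": -2.0, "NRN": 0.0, "NDA": 3.0, "NDD": -2.0, "NDN": 0.0}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generator.

    Defaults are the study conditions the pipeline is meant to emulate:
    island counts per category match the published island set, the tandem
    duplication factor matches the NRU duplication rate (1.35), and
    conservation/synteny probabilities sit in the range of the published
    per-category rates.
    """

    seed: int = 0
    n_islands_per_category: Mapping[str, int] = field(
        default_factory=_default_islands_per_category
    )
    genes_per_island: tuple[int, int] = (2, 12)  # inclusive range of ancestral genes
    duplication_factor: float = 1.35  # expected tandem copies per ancestral coding gene
    # amplification is island-clustered and category-dependent: nodule-regulated
    # islands are built around tandemly amplified symbiosis families (NCR-like
    # clusters) far more often than non-regulated ones
    island_amp_prob: Mapping[str, float] = field(
        default_factory=lambda: {
            "NRU": 0.4, "NRD": 0.5, "NRN": 0.02, "NDA": 0.05, "NDD": 0.3, "NDN": 0.1
        }
    )
    amp_gene_prob: float = 0.35  # within an amplified island, chance an ancestor founds a family
    lnc_fraction_amp: float = 0.5  # lncRNA share among non-family genes of amplified islands
    lnc_fraction: float = 0.12
    conservation_prob: float = 0.4  # coding genes
    lnc_conservation_prob: float = 0.15
    synteny_retention_prob: float = 0.65
    spurious_hit_rate: float = 0.02  # chance an unconserved gene gets a junk hit
    intergenic_gap_bp: int = 2000
    island_gap_bp: int = 1_000_000
    gene_length_bp: int = 3000
    n_chromosomes: int = 6
    # expression
    n_root_samples: int = 3
    n_nodule_samples: int = 3
    nb_dispersion: float = 0.3  # NB alpha: var = mu + alpha * mu^2
    island_log2_effect: Mapping[str, float] = field(default_factory=_default_effects)
    effect_sd_scale: float = 0.25  # per-gene effect sd = scale * |category effect|
    # regulation is concentrated in the amplified tandem families: island
    # membership marks a region, but only some members respond to nodulation
    amp_regulated_prob: float = 0.95
    single_regulated_prob: float = 0.5
    # probability that a conserved gene keeps its nodule/root regulation in
    # species B; amplified symbiosis families retain it far more often than
    # single-copy genes, which is what makes island co-regulation poorly
    # conserved after deduplication
    b_effect_retention_amp: float = 0.85
    b_effect_retention_single: float = 0.2
    baseline_mean: float = 100.0
    baseline_log_sd: float = 1.0
    # RIL genotyping
    n_ril_lines: int = 20
    n_ril_contigs: int = 40
    snps_per_contig: int = 15
    contig_length_range: tuple[int, int] = (50_000, 1_000_000)
    qual_fail_fraction: float = 0.1
    depth_fail_fraction: float = 0.1
    multiallelic_fraction: float = 0.05
    missing_fraction: float = 0.05
    noncontrast_fraction: float = 0.1
    genotype_error_fraction: float = 0.0  # per record x line flip of the true call
    residual_het_fraction: float = 0.02  # contigs genuinely heterozygous in a line

    def validate(self) -> None:
        for cat in self.n_islands_per_category:
            if cat not in CATEGORIES:
                raise ConfigurationError(f"unknown island category: {cat!r}")
        for cat in self.island_log2_effect:
            if cat not in CATEGORIES:
                raise ConfigurationError(f"unknown island category: {cat!r}")
        for cat, p in self.island_amp_prob.items():
            if cat not in CATEGORIES:
                raise ConfigurationError(f"unknown island category: {cat!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"island_amp_prob[{cat}] must be in [0, 1]")
        probs = {
            "lnc_fraction": self.lnc_fraction,
            "conservation_prob": self.conservation_prob,
            "lnc_conservation_prob": self.lnc_conservation_prob,
            "synteny_retention_prob": self.synteny_retention_prob,
            "spurious_hit_rate": self.spurious_hit_rate,
            "amp_gene_prob": self.amp_gene_prob,
            "lnc_fraction_amp": self.lnc_fraction_amp,
            "amp_regulated_prob": self.amp_regulated_prob,
            "single_regulated_prob": self.single_regulated_prob,
            "b_effect_retention_amp": self.b_effect_retention_amp,
            "b_effect_retention_single": self.b_effect_retention_single,
            "qual_fail_fraction": self.qual_fail_fraction,
            "depth_fail_fraction": self.depth_fail_fraction,
            "multiallelic_fraction": self.multiallelic_fraction,
            "missing_fraction": self.missing_fraction,
            "noncontrast_fraction": self.noncontrast_fraction,
            "genotype_error_fraction": self.genotype_error_fraction,
            "residual_het_fraction": self.residual_het_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if self.duplication_factor < 1.0:
            raise ConfigurationError("duplication_factor must be >= 1")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.baseline_mean <= 0:
            raise ConfigurationError("baseline_mean must be > 0")
        if self.intergenic_gap_bp <= 0:
            raise ConfigurationError("intergenic_gap_bp must be > 0")
        lo, hi = self.genes_per_island
        if not (1 <= lo <= hi):
            raise ConfigurationError("genes_per_island range must satisfy 1 <= lo <= hi")
        if self.n_root_samples < 2 or self.n_nodule_samples < 2:
            raise ConfigurationError("need >= 2 samples per condition")
        if self.n_ril_lines < 2 or self.n_ril_contigs < 1:
            raise ConfigurationError("need >= 2 RIL lines and >= 1 contig")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class TruthMap:
    """Ground truth linking species-A genes to ancestors and B counterparts."""

    a_copies: dict[str, list[str]]  # ancestral gene -> tandem copies in A
    b_gene: dict[str, Optional[str]]  # ancestral gene -> B counterpart or None
    anc_of_a: dict[str, str]  # A gene -> ancestral gene
    island_of_anc: dict[str, str]
    category_of_island: dict[str, str]
    biotype_of_anc: dict[str, str]  # "coding" | "lncRNA"
    effect_of_anc: dict[str, float]  # true log2 nodule/root shift in species A
    b_effect_of_anc: dict[str, float]  # shift of the B counterpart (0 if lost)
    syntenic_b: set[str]  # B genes retained in their island's syntenic region

    def conserved_ancestors(self) -> list[str]:
        return [a for a, b in self.b_gene.items() if b is not None]

    def mean_copies(self, biotype: str = "coding") -> float:
        ns = [
            len(copies)
            for anc, copies in self.a_copies.items()
            if self.biotype_of_anc[anc] == biotype
        ]
        return float(np.mean(ns)) if ns else float("nan")


def _mean_island_amp_prob(config: SimulationConfig) -> float:
    """Island-count-weighted mean amplification probability."""
    weights = {c: int(n) for c, n in config.n_islands_per_category.items() if n > 0}
    total = sum(weights.values())
    if total == 0:
        return 0.0
    return (
        sum(config.island_amp_prob.get(c, 0.0) * n for c, n in weights.items()) / total
    )


def _family_prob_given_coding(config: SimulationConfig) -> float:
    """P(ancestral coding gene founds a tandem family).

    Amplified islands hold the families; their non-family genes are
    lncRNA-rich, so the coding margin has to be computed over both island
    kinds for the family-size calibration to keep the mean copy number of
    coding ancestors at exactly ``duplication_factor``.  Island sizes are
    iid across categories, so the category mixture enters only through the
    island-count-weighted mean amplification probability.
    """
    p_amp = _mean_island_amp_prob(config)
    p_fam_and_coding = p_amp * config.amp_gene_prob
    p_coding = (
        p_amp * (config.amp_gene_prob + (1 - config.amp_gene_prob) * (1 - config.lnc_fraction_amp))
        + (1 - p_amp) * (1 - config.lnc_fraction)
    )
    return p_fam_and_coding / p_coding if p_coding > 0 else 0.0


def _draw_copy_number(
    rng: np.random.Generator, config: SimulationConfig, is_family: bool
) -> int:
    """Tandem copy number of one ancestral coding gene.

    Amplification is clustered, not uniform: only family founders inside
    amplified islands are duplicated, with family size ``1 + A`` where
    ``A = 1 + Poisson(extra - 1)`` and ``extra`` calibrated so the mean
    copy number over all ancestral coding genes is exactly
    ``duplication_factor``.  This is the regime where a handful of tandem
    families (NCR-peptide-like) carry most of the many-to-one best-hit
    signal.
    """
    excess = config.duplication_factor - 1.0
    if excess <= 0 or not is_family:
        return 1
    q = _family_prob_given_coding(config)
    q = min(q, excess) if q > 0 else excess
    extra_mean = max(excess / q, 1.0)
    return 1 + 1 + int(rng.poisson(extra_mean - 1.0))


def simulate_genome_pair(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthMap]:
    """Generate gene tables for species A and B, the island table and truth.

    Species-A islands are contiguous runs of genes; tandem copies of an
    ancestral gene are adjacent.  Each conserved ancestral gene has exactly
    one B counterpart which, with probability ``synteny_retention_prob``,
    stays in the B region syntenic to its island and is otherwise relocated
    to a random position on another chromosome.
    """
    config.validate()
    rng = config.rng(_STREAM_GENOME)

    a_rows: list[dict] = []
    b_rows: list[dict] = []
    island_rows: list[dict] = []
    a_copies: dict[str, list[str]] = {}
    b_gene: dict[str, Optional[str]] = {}
    anc_of_a: dict[str, str] = {}
    island_of_anc: dict[str, str] = {}
    category_of_island: dict[str, str] = {}
    biotype_of_anc: dict[str, str] = {}
    effect_of_anc: dict[str, float] = {}
    b_effect_of_anc: dict[str, float] = {}
    syntenic_b: set[str] = set()

    a_cursor = np.full(config.n_chromosomes, 1, dtype=np.int64)
    b_cursor = np.full(config.n_chromosomes, 1, dtype=np.int64)
    glen = config.gene_length_bp
    gap = config.intergenic_gap_bp

    anc_counter = 0
    a_counter = 0
    b_counter = 0
    island_index = 0
    lo, hi = config.genes_per_island

    relocated: list[tuple[str, int]] = []  # (B gene id, home chromosome idx)

    for cat in CATEGORIES:
        n_islands = int(config.n_islands_per_category.get(cat, 0))
        eff_mean = float(config.island_log2_effect.get(cat, 0.0))
        eff_sd = config.effect_sd_scale * abs(eff_mean)
        for k in range(n_islands):
            island_index += 1
            island_id = f"{cat}_{k + 1:04d}"
            category_of_island[island_id] = cat
            amp_island = rng.random() < config.island_amp_prob.get(cat, 0.0)
            chrom_idx = (island_index - 1) % config.n_chromosomes
            a_chrom = f"A_chr{chrom_idx + 1}"
            b_chrom = f"B_chr{chrom_idx + 1}"
            n_anc = int(rng.integers(lo, hi + 1))
            island_start = int(a_cursor[chrom_idx])
            n_a_in_island = 0
            for _ in range(n_anc):
                anc_counter += 1
                anc = f"anc{anc_counter:06d}"
                island_of_anc[anc] = island_id
                is_family = amp_island and rng.random() < config.amp_gene_prob
                lnc_p = (
                    0.0
                    if is_family
                    else (config.lnc_fraction_amp if amp_island else config.lnc_fraction)
                )
                is_lnc = rng.random() < lnc_p
                biotype = "lncRNA" if is_lnc else "coding"
                biotype_of_anc[anc] = biotype
                if is_lnc:
                    n_copies = 1
                    conserved = rng.random() < config.lnc_conservation_prob
                else:
                    n_copies = _draw_copy_number(rng, config, is_family)
                    conserved = rng.random() < config.conservation_prob
                p_reg = (
                    config.amp_regulated_prob
                    if is_family
                    else config.single_regulated_prob
                )
                if eff_mean != 0.0 and rng.random() < p_reg:
                    effect_of_anc[anc] = (
                        float(rng.normal(eff_mean, eff_sd)) if eff_sd > 0 else eff_mean
                    )
                else:
                    effect_of_anc[anc] = 0.0
                p_keep = (
                    config.b_effect_retention_amp
                    if is_family
                    else config.b_effect_retention_single
                )
                b_effect_of_anc[anc] = (
                    effect_of_anc[anc] if rng.random() < p_keep else 0.0
                )

                copies = []
                for _c in range(n_copies):
                    a_counter += 1
                    gid = f"geneA{a_counter:06d}"
                    copies.append(gid)
                    anc_of_a[gid] = anc
                    start = int(a_cursor[chrom_idx])
                    a_rows.append(
                        {
                            "gene_id": gid,
                            "seqid": a_chrom,
                            "start": start,
                            "end": start + glen - 1,
                            "strand": "+" if rng.random() < 0.5 else "-",
                            "biotype": biotype,
                            "island_id": island_id,
                        }
                    )
                    a_cursor[chrom_idx] += glen + gap
                    n_a_in_island += 1
                a_copies[anc] = copies

                if conserved:
                    b_counter += 1
                    bid = f"geneB{b_counter:06d}"
                    b_gene[anc] = bid
                    if rng.random() < config.synteny_retention_prob:
                        start = int(b_cursor[chrom_idx])
                        b_rows.append(
                            {
                                "gene_id": bid,
                                "seqid": b_chrom,
                                "start": start,
                                "end": start + glen - 1,
                                "strand": "+" if rng.random() < 0.5 else "-",
                                "biotype": biotype,
                                "island_id": "",
                            }
                        )
                        b_cursor[chrom_idx] += glen + gap
                        syntenic_b.add(bid)
                    else:
                        relocated.append((bid, chrom_idx))
                        b_rows.append(
                            {
                                "gene_id": bid,
                                "seqid": "",  # placed below
                                "start": 0,
                                "end": 0,
                                "strand": "+" if rng.random() < 0.5 else "-",
                                "biotype": biotype,
                                "island_id": "",
                            }
                        )
                else:
                    b_gene[anc] = None

            island_rows.append(
                {
                    "island_id": island_id,
                    "category": cat,
                    "seqid": a_chrom,
                    "start": island_start,
                    "end": int(a_cursor[chrom_idx]) - gap - 1,
                    "n_genes": n_a_in_island,
                }
            )
            a_cursor[chrom_idx] += config.island_gap_bp
            b_cursor[chrom_idx] += config.island_gap_bp

    # relocate unsynteny B genes far from the syntenic blocks, off their home
    # chromosome, at scattered positions so they do not form spurious clusters
    by_id = {r["gene_id"]: r for r in b_rows}
    relocation_base = int(b_cursor.max()) + 10_000_000
    for bid, home in relocated:
        if config.n_chromosomes > 1:
            other = int(rng.integers(config.n_chromosomes - 1))
            if other >= home:
                other += 1
        else:
            other = home
        start = relocation_base + int(rng.integers(0, 500_000_000))
        row = by_id[bid]
        row["seqid"] = f"B_chr{other + 1}"
        row["start"] = start
        row["end"] = start + glen - 1

    genes_a = pd.DataFrame(
        a_rows,
        columns=["gene_id", "seqid", "start", "end", "strand", "biotype", "island_id"],
    )
    genes_b = pd.DataFrame(
        b_rows,
        columns=["gene_id", "seqid", "start", "end", "strand", "biotype", "island_id"],
    )
    islands = pd.DataFrame(
        island_rows,
        columns=["island_id", "category", "seqid", "start", "end", "n_genes"],
    )
    truth = TruthMap(
        a_copies=a_copies,
        b_gene=b_gene,
        anc_of_a=anc_of_a,
        island_of_anc=island_of_anc,
        category_of_island=category_of_island,
        biotype_of_anc=biotype_of_anc,
        effect_of_anc=effect_of_anc,
        b_effect_of_anc=b_effect_of_anc,
        syntenic_b=syntenic_b,
    )
    return genes_a, genes_b, islands, truth


def simulate_similarity(truth: TruthMap, config: SimulationConfig) -> pd.DataFrame:
    """Emit an outfmt-6-style similarity table consistent with the truth map.

    Every A-copy of a conserved ancestral gene gets its B counterpart as the
    strictly top-scoring row; additional lower-scoring rows to other conserved
    B genes of the same island mimic paralogous cross-hits.  Unconserved genes
    get no rows, or a single spurious low-score row with probability
    ``spurious_hit_rate``.  Output is sorted by query then descending bitscore.
    """
    config.validate()
    rng = config.rng(_STREAM_SIMILARITY)
    all_b = [b for b in truth.b_gene.values() if b is not None]
    # conserved B genes per island, for paralogous secondary hits
    b_by_island: dict[str, list[str]] = {}
    for anc, b in truth.b_gene.items():
        if b is not None:
            b_by_island.setdefault(truth.island_of_anc[anc], []).append(b)

    rows: list[tuple] = []

    def _row(q: str, s: str, bitscore: float, pident: float) -> tuple:
        evalue = float(10.0 ** -(bitscore / 10.0))
        alen = int(rng.integers(150, 600))
        qcov = float(rng.uniform(0.6, 1.0))
        scov = float(rng.uniform(0.6, 1.0))
        return (
            q,
            s,
            round(pident, 2),
            alen,
            int(rng.integers(0, 40)),
            int(rng.integers(0, 5)),
            1,
            alen,
            1,
            alen,
            evalue,
            round(bitscore, 1),
            round(qcov, 3),
            round(scov, 3),
        )

    for anc in sorted(truth.a_copies):
        b = truth.b_gene[anc]
        island = truth.island_of_anc[anc]
        for gid in truth.a_copies[anc]:
            if b is not None:
                top = float(rng.uniform(300.0, 600.0))
                rows.append(_row(gid, b, top, rng.uniform(70.0, 98.0)))
                others = [x for x in b_by_island.get(island, []) if x != b]
                if others:
                    n_sec = int(rng.integers(0, min(2, len(others)) + 1))
                    if n_sec:
                        picks = rng.choice(len(others), size=n_sec, replace=False)
                        for i in picks:
                            sec = top * float(rng.uniform(0.3, 0.8))
                            rows.append(_row(gid, others[int(i)], sec, rng.uniform(40.0, 70.0)))
            else:
                if all_b and rng.random() < config.spurious_hit_rate:
                    junk = float(rng.uniform(40.0, 60.0))
                    sbj = all_b[int(rng.integers(len(all_b)))]
                    rows.append(_row(gid, sbj, junk, rng.uniform(25.0, 40.0)))

    cols = [
        "qseqid",
        "sseqid",
        "pident",
        "length",
        "mismatch",
        "gapopen",
        "qstart",
        "qend",
        "sstart",
        "send",
        "evalue",
        "bitscore",
        "qcov",
        "scov",
    ]
    df = pd.DataFrame(rows, columns=cols)
    df = df.sort_values(
        ["qseqid", "bitscore"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
    return df


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma–Poisson draw: var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_expression(
    truth: TruthMap,
    genes_a: pd.DataFrame,
    genes_b: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Negative-binomial root/nodule counts for both species.

    Baseline means are lognormal per ancestral gene; the true log2
    nodule/root shift of an ancestral gene (category effect plus per-gene
    heterogeneity) is shared by all its tandem copies in A and its conserved
    counterpart in B, so regulation is inherited at the ancestral level.
    """
    config.validate()
    rng = config.rng(_STREAM_EXPRESSION)

    baselines = {
        anc: config.baseline_mean * float(np.exp(rng.normal(0.0, config.baseline_log_sd)))
        for anc in sorted(truth.a_copies)
    }

    b_to_anc = {b: anc for anc, b in truth.b_gene.items() if b is not None}

    def _matrix(
        gene_ids: Sequence[str], species: str, anc_lookup, effects
    ) -> ExpressionMatrix:
        n_r, n_n = config.n_root_samples, config.n_nodule_samples
        samples = [f"{species}_root_{i + 1}" for i in range(n_r)] + [
            f"{species}_nodule_{i + 1}" for i in range(n_n)
        ]
        conditions = ["root"] * n_r + ["nodule"] * n_n
        mu = np.empty((len(gene_ids), n_r + n_n))
        for i, gid in enumerate(gene_ids):
            anc = anc_lookup(gid)
            base = baselines[anc]
            eff = effects[anc]
            mu[i, :n_r] = base
            mu[i, n_r:] = base * (2.0**eff)
        counts = _nb_counts(rng, mu, config.nb_dispersion)
        meta = pd.DataFrame(
            {
                "sample_id": samples,
                "species": species,
                "condition": conditions,
                "replicate": list(range(1, n_r + 1)) + list(range(1, n_n + 1)),
            }
        )
        frame = pd.DataFrame(counts, index=list(gene_ids), columns=samples)
        return ExpressionMatrix(counts=frame, samples=meta)

    mat_a = _matrix(
        list(genes_a["gene_id"]), "A", lambda g: truth.anc_of_a[g], truth.effect_of_anc
    )
    mat_b = _matrix(
        list(genes_b["gene_id"]), "B", lambda g: b_to_anc[g], truth.b_effect_of_anc
    )
    return mat_a, mat_b


@dataclass
class RILSimulation:
    """Output bundle of :func:`simulate_ril_variants`."""

    records: pd.DataFrame  # one row per site, per-sample GT columns
    contig_lengths: dict[str, int]
    true_pattern: pd.DataFrame  # contigs x RIL lines, calls in {A, B, H}
    gifu_sample: str
    parent2_sample: str
    line_samples: list[str]


def simulate_ril_variants(config: SimulationConfig) -> RILSimulation:
    """RIL variant table with injected filter-failure modes and known truth.

    Each contig carries a true parental-origin pattern per line (A = Gifu
    allele, B = other parent, rare residual H).  Sites independently fail
    quality/depth, become multiallelic, lose a genotype, or lose parental
    contrast at the configured fractions; per-line calls are flipped with
    ``genotype_error_fraction``.
    """
    config.validate()
    rng = config.rng(_STREAM_RIL)

    lines = [f"RIL{i + 1:03d}" for i in range(config.n_ril_lines)]
    gifu, parent2 = "Gifu", "Parent2"
    contigs = [f"contig{i + 1:04d}" for i in range(config.n_ril_contigs)]
    lo, hi = config.contig_length_range
    lengths = {c: int(rng.integers(lo, hi + 1)) for c in contigs}

    pattern = pd.DataFrame(index=contigs, columns=lines, dtype=object)
    for c in contigs:
        for ln in lines:
            if rng.random() < config.residual_het_fraction:
                pattern.loc[c, ln] = "H"
            else:
                pattern.loc[c, ln] = "A" if rng.random() < 0.5 else "B"

    gt_of = {"A": "0/0", "B": "1/1", "H": "0/1"}
    rows = []
    for c in contigs:
        n_sites = max(1, int(rng.poisson(config.snps_per_contig)))
        positions = np.sort(
            rng.choice(np.arange(1, lengths[c] + 1), size=min(n_sites, lengths[c]), replace=False)
        )
        for pos in positions:
            qual_fail = rng.random() < config.qual_fail_fraction
            depth_fail = rng.random() < config.depth_fail_fraction
            multi = rng.random() < config.multiallelic_fraction
            missing = rng.random() < config.missing_fraction
            noncontrast = rng.random() < config.noncontrast_fraction

            qual = float(rng.uniform(5.0, 29.5)) if qual_fail else float(rng.uniform(30.0, 60.0))
            depth = int(rng.integers(5, 50)) if depth_fail else int(rng.integers(50, 200))
            alleles = ("A", "C", "T") if multi else ("A", "C")

            gts = {gifu: "0/0", parent2: "0/0" if noncontrast else "1/1"}
            for ln in lines:
                call = pattern.loc[c, ln]
                if rng.random() < config.genotype_error_fraction:
                    call = {"A": "B", "B": "A", "H": "A"}[call]
                gts[ln] = gt_of[call]
            if missing:
                victim = [gifu, parent2, *lines][int(rng.integers(len(lines) + 2))]
                gts[victim] = "./."

            rows.append(
                {
                    "contig": c,
                    "pos": int(pos),
                    "qual": round(qual, 1),
                    "depth": depth,
                    "ref": alleles[0],
                    "alt": ",".join(alleles[1:]),
                    **gts,
                }
            )

    records = pd.DataFrame(rows)
    return RILSimulation(
        records=records,
        contig_lengths=lengths,
        true_pattern=pattern,
        gifu_sample=gifu,
        parent2_sample=parent2,
        line_samples=lines,
    )


# ---------------------------------------------------------------------------
# writers for the on-disk formats
# ---------------------------------------------------------------------------

def write_gene_table(genes: pd.DataFrame, path) -> None:
    """GFF3-like TSV: seqid, source, type, start, end, score, strand, phase, attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genes.itertuples(index=False):
            attrs = f"ID={r.gene_id};biotype={r.biotype}"
            if r.island_id:
                attrs += f";island_id={r.island_id}"
            fh.write(
                f"{r.seqid}\tsymisle\tgene\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n"
            )


def read_gene_table(path) -> pd.DataFrame:
    """Inverse of :func:`write_gene_table`."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "gene_id": attrs.get("ID", ""),
                    "seqid": parts[0],
                    "start": int(parts[3]),
                    "end": int(parts[4]),
                    "strand": parts[6],
                    "biotype": attrs.get("biotype", "coding"),
                    "island_id": attrs.get("island_id", ""),
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "seqid", "start", "end", "strand", "biotype", "island_id"]
    )


def write_similarity_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def write_island_table(islands: pd.DataFrame, path) -> None:
    islands.to_csv(path, sep="\t", index=False)


def read_island_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_vcf(sim: RILSimulation, path) -> None:
    """Minimal VCF v4.2 with QUAL, INFO DP and per-sample GT:DP."""
    samples = [sim.gifu_sample, sim.parent2_sample, *sim.line_samples]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for c, ln in sim.contig_lengths.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        n = len(samples)
        for r in sim.records.itertuples(index=False):
            per_sample_dp = max(1, r.depth // n)
            fields = [
                r.contig,
                str(r.pos),
                ".",
                r.ref,
                r.alt,
                f"{r.qual:.1f}",
                "PASS",
                f"DP={r.depth}",
                "GT:DP",
            ]
            row = getattr(r, "_asdict")()
            for s in samples:
                fields.append(f"{row[s]}:{per_sample_dp}")
            fh.write("\t".join(fields) + "\n")


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=int(seed))
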