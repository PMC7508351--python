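"""End-to-end orchestration: simulate -> best hits -> synteny -> expression -> islands.

The pipeline chains the per-module operations in dependency order, writes
every intermediate as a plain-text table, and finishes with a JSON
manifest listing each output with its SHA-256 checksum; re-running with
the same configuration and seed reproduces identical checksums.  Stage
failures are wrapped in :class:`~symisle.errors.StageError` naming the
stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from symisle import expression as ex
from symisle import homology, islands as isl, microsynteny as ms, rilmap, simulate as sim
from symisle.errors import StageError


@dataclass
class PipelineConfig:
    """All pipeline knobs; numeric defaults mirror the per-module defaults."""

    simulation: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    max_evalue: Optional[float] = None  # best-hit pre-filter; off by default
    max_gap_bp: int = 500_000
    min_cluster: int = 2
    min_distinct_targets: int = 3  # unique-mode island inclusion rule
    normalization: str = "median_ratio"
    pseudocount: float = 1.0
    corr_conditions: tuple[str, ...] = ("root", "nodule")
    run_rilmap: bool = True

    @property
    def seed(self) -> int:
        return self.simulation.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        if "n_islands_per_category" in sim_raw:
            sim_raw["n_islands_per_category"] = dict(sim_raw["n_islands_per_category"])
        if "genes_per_island" in sim_raw:
            sim_raw["genes_per_island"] = tuple(sim_raw["genes_per_island"])
        if "island_log2_effect" in sim_raw:
            sim_raw["island_log2_effect"] = dict(sim_raw["island_log2_effect"])
        if "contig_length_range" in sim_raw:
            sim_raw["contig_length_range"] = tuple(sim_raw["contig_length_range"])
        if "corr_conditions" in raw:
            raw["corr_conditions"] = tuple(raw["corr_conditions"])
        cfg = cls(simulation=sim.SimulationConfig(**sim_raw), **raw)
        cfg.simulation.validate()
        return cfg

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["simulation"]["n_islands_per_category"] = dict(
            raw["simulation"]["n_islands_per_category"]
        )
        raw["corr_conditions"] = list(self.corr_conditions)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# reusable analysis drivers (also used by the examples and acceptance script)
# ---------------------------------------------------------------------------

def island_members_from_gene_table(genes: pd.DataFrame) -> dict[str, list[str]]:
    members: dict[str, list[str]] = {}
    for r in genes.itertuples(index=False):
        if r.island_id:
            members.setdefault(r.island_id, []).append(r.gene_id)
    return members


def call_all_islands(
    members: Mapping[str, Sequence[str]],
    best_hits: homology.BestHitMap,
    target_genes: pd.DataFrame,
    max_gap_bp: int = 500_000,
    min_cluster: int = 2,
) -> dict[str, ms.MicrosyntenyCall]:
    return {
        island_id: ms.call_microsynteny(
            island_id, members[island_id], best_hits, target_genes, max_gap_bp, min_cluster
        )
        for island_id in sorted(members)
    }


def condition_samples(mat: ex.ExpressionMatrix, conditions: Sequence[str]) -> list[str]:
    out: list[str] = []
    for cond in conditions:
        out.extend(mat.samples_for(cond))
    return out


def island_correlation_analysis(
    members: Mapping[str, Sequence[str]],
    best_hits: homology.BestHitMap,
    synteny_calls: Mapping[str, ms.MicrosyntenyCall],
    normalized_a: pd.DataFrame,
    normalized_b: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    min_distinct: int = 3,
) -> dict[tuple[str, str], list[ex.IslandCorrelation]]:
    """Mean pairwise island correlations for both species and both modes.

    Redundant mode uses every island member with a best hit (species A) and
    the multiset of their best-hit targets (species B, duplicates kept);
    unique mode uses the deduplicated microsyntenic pairs and skips islands
    excluded by the distinct-target rule.  Keys are (mode, species).
    """
    out: dict[tuple[str, str], list[ex.IslandCorrelation]] = {
        ("redundant", "A"): [],
        ("redundant", "B"): [],
        ("unique", "A"): [],
        ("unique", "B"): [],
    }
    for island_id in sorted(members):
        pairs = ex.pairs_redundant(members[island_id], best_hits)
        if pairs:
            a_genes = [a for a, _ in pairs]
            b_genes = [b for _, b in pairs]
            out[("redundant", "A")].append(
                ex.island_mean_pairwise_correlation(
                    a_genes, normalized_a, samples_a, island_id, "redundant"
                )
            )
            out[("redundant", "B")].append(
                ex.island_mean_pairwise_correlation(
                    b_genes, normalized_b, samples_b, island_id, "redundant"
                )
            )
        call = synteny_calls.get(island_id)
        if call is None:
            continue
        dedup = ex.deduplicate_island(members[island_id], best_hits, call, min_distinct)
        if dedup.excluded:
            continue
        out[("unique", "A")].append(
            ex.island_mean_pairwise_correlation(
                dedup.a_genes, normalized_a, samples_a, island_id, "unique"
            )
        )
        out[("unique", "B")].append(
            ex.island_mean_pairwise_correlation(
                dedup.b_genes, normalized_b, samples_b, island_id, "unique"
            )
        )
    return out


def category_ratio_correlations(
    categories: Mapping[str, str],
    members: Mapping[str, Sequence[str]],
    best_hits: homology.BestHitMap,
    ratios_a: pd.Series,
    ratios_b: pd.Series,
) -> pd.DataFrame:
    """Cross-species Pearson r of log nodule/root ratios per island category."""
    pairs_by_cat: dict[str, list[tuple[str, str]]] = {}
    for island_id, cat in categories.items():
        pairs_by_cat.setdefault(cat, []).extend(
            ex.pairs_redundant(members.get(island_id, []), best_hits)
        )
    rows = []
    for cat in sorted(pairs_by_cat):
        r, n = ex.cross_species_ratio_correlation(ratios_a, ratios_b, pairs_by_cat[cat])
        rows.append({"category": cat, "pearson_r": r, "n_pairs": n})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the pipeline itself
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and return (and write) the output manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    stages_run: list[str] = []

    def _stage(name: str):
        def deco(fn):
            try:
                fn()
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
            stages_run.append(name)

        return deco

    paths = {
        "genes_a": outdir / "genes_a.gff",
        "genes_b": outdir / "genes_b.gff",
        "islands": outdir / "islands.tsv",
        "similarity": outdir / "similarity.tsv",
        "counts_a": outdir / "counts_a.tsv",
        "samples_a": outdir / "samples_a.tsv",
        "counts_b": outdir / "counts_b.tsv",
        "samples_b": outdir / "samples_b.tsv",
        "vcf1": outdir / "ril_pop1.vcf",
        "vcf2": outdir / "ril_pop2.vcf",
        "besthits": outdir / "besthits.tsv",
        "synteny": outdir / "synteny.tsv",
        "ratios_a": outdir / "log_ratios_a.tsv",
        "ratios_b": outdir / "log_ratios_b.tsv",
        "ratio_corr": outdir / "category_ratio_correlation.tsv",
        "summary": outdir / "island_summary.tsv",
        "consensus1": outdir / "consensus_pop1.tsv",
        "consensus2": outdir / "consensus_pop2.tsv",
        "marker_summary": outdir / "marker_summary.tsv",
    }
    for mode in ("redundant", "unique"):
        for species in ("A", "B"):
            paths[f"corr_{mode}_{species}"] = outdir / f"island_corr_{mode}_{species}.tsv"

    state: dict = {}

    @_stage("simulate")
    def _simulate():
        cfg = config.simulation
        genes_a, genes_b, islands_df, truth = sim.simulate_genome_pair(cfg)
        similarity = sim.simulate_similarity(truth, cfg)
        mat_a, mat_b = sim.simulate_expression(truth, genes_a, genes_b, cfg)
        sim.write_gene_table(genes_a, paths["genes_a"])
        sim.write_gene_table(genes_b, paths["genes_b"])
        sim.write_island_table(islands_df, paths["islands"])
        sim.write_similarity_table(similarity, paths["similarity"])
        mat_a.write(paths["counts_a"], paths["samples_a"])
        mat_b.write(paths["counts_b"], paths["samples_b"])
        if config.run_rilmap:
            ril1 = sim.simulate_ril_variants(cfg)
            ril2 = sim.simulate_ril_variants(sim.with_seed(cfg, cfg.seed + 1_000_003))
            sim.write_vcf(ril1, paths["vcf1"])
            sim.write_vcf(ril2, paths["vcf2"])
        files.extend(
            paths[k]
            for k in (
                "genes_a",
                "genes_b",
                "islands",
                "similarity",
                "counts_a",
                "samples_a",
                "counts_b",
                "samples_b",
            )
        )
        if config.run_rilmap:
            files.extend([paths["vcf1"], paths["vcf2"]])
        state["truth"] = truth

    @_stage("besthits")
    def _besthits():
        hits = homology.parse_similarity_table(paths["similarity"], has_coverage_columns=True)
        best = homology.select_best_hits(hits, max_evalue=config.max_evalue)
        homology.write_best_hits(best, paths["besthits"])
        files.append(paths["besthits"])
        state["best"] = best

    @_stage("synteny")
    def _synteny():
        if not paths["islands"].exists():
            raise FileNotFoundError(f"islands file not found: {paths['islands']}")
        genes_a = sim.read_gene_table(paths["genes_a"])
        genes_b = sim.read_gene_table(paths["genes_b"])
        islands_df = sim.read_island_table(paths["islands"])
        members = island_members_from_gene_table(genes_a)
        calls = call_all_islands(
            members, state["best"], genes_b, config.max_gap_bp, config.min_cluster
        )
        categories = dict(zip(islands_df["island_id"], islands_df["category"]))
        ms.write_synteny_calls(calls.values(), categories, paths["synteny"])
        files.append(paths["synteny"])
        state.update(
            genes_a=genes_a,
            genes_b=genes_b,
            islands_df=islands_df,
            members=members,
            calls=calls,
            categories=categories,
        )

    @_stage("expression")
    def _expression():
        mat_a = ex.ExpressionMatrix.read(paths["counts_a"], paths["samples_a"])
        mat_b = ex.ExpressionMatrix.read(paths["counts_b"], paths["samples_b"])
        norm_a = ex.normalize(mat_a.counts, config.normalization)
        norm_b = ex.normalize(mat_b.counts, config.normalization)
        ratios = {}
        for label, mat, norm in (("a", mat_a, norm_a), ("b", mat_b, norm_b)):
            r = ex.log_ratio(
                norm, mat.samples_for("nodule"), mat.samples_for("root"), config.pseudocount
            )
            r.to_csv(paths[f"ratios_{label}"], sep="\t", index_label="gene_id")
            files.append(paths[f"ratios_{label}"])
            ratios[label] = r
        corr_table = category_ratio_correlations(
            state["categories"], state["members"], state["best"], ratios["a"], ratios["b"]
        )
        corr_table.to_csv(paths["ratio_corr"], sep="\t", index=False)
        files.append(paths["ratio_corr"])
        corrs = island_correlation_analysis(
            state["members"],
            state["best"],
            state["calls"],
            norm_a,
            norm_b,
            condition_samples(mat_a, config.corr_conditions),
            condition_samples(mat_b, config.corr_conditions),
            config.min_distinct_targets,
        )
        for (mode, species), lst in corrs.items():
            p = paths[f"corr_{mode}_{species}"]
            ex.write_island_correlations(lst, state["categories"], p)
            files.append(p)

    @_stage("islands")
    def _islands():
        biotypes = dict(zip(state["genes_a"]["gene_id"], state["genes_a"]["biotype"]))
        summaries = isl.tabulate(
            state["islands_df"], state["members"], biotypes, state["best"], state["calls"]
        )
        table = isl.summary_table(summaries)
        table.to_csv(paths["summary"], sep="\t", index_label="statistic")
        files.append(paths["summary"])

    if config.run_rilmap:

        @_stage("rilmap")
        def _rilmap():
            kept_per_pop = {}
            for pop, vcf_key, out_key in (
                ("pop1", "vcf1", "consensus1"),
                ("pop2", "vcf2", "consensus2"),
            ):
                records, samples, lengths = rilmap.read_vcf(paths[vcf_key])
                gifu, parent2 = samples[0], samples[1]
                lines = samples[2:]
                kept = rilmap.filter_variants(records, gifu, parent2)
                kept_per_pop[pop] = kept
                matrix = rilmap.consensus_matrix(kept, lines, gifu, parent2)
                rilmap.write_consensus_matrix(matrix, paths[out_key])
                files.append(paths[out_key])
                state.setdefault("contig_lengths", lengths)
            summary = rilmap.marker_coverage_summary(state["contig_lengths"], kept_per_pop)
            rilmap.write_marker_summary(summary, paths["marker_summary"])
            files.append(paths["marker_summary"])

    manifest = {
        "seed": config.seed,
        "stages": stages_run,
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(files))},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
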