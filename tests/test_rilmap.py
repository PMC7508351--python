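"""RIL variant filtering, consensus genotyping and assembly summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from symisle.errors import SymisleError
from symisle.rilmap import (
    VariantRecord,
    consensus_genotype,
    consensus_matrix,
    filter_variants,
    marker_coverage_summary,
    n50_l50,
    read_vcf,
    records_from_frame,
)
from symisle.simulate import SimulationConfig, simulate_ril_variants, write_vcf


def record(qual=40.0, depth=100, alleles=("A", "C"), contig="c1", pos=100, **gts):
    genotypes = {"Gifu": "0/0", "P2": "1/1", "L1": "0/0", "L2": "1/1"}
    genotypes.update(gts)
    return VariantRecord(contig, pos, qual, depth, tuple(alleles), genotypes)


class TestFilter:
    def test_quality_just_below_threshold_dropped(self):
        assert filter_variants([record(qual=29.9)], "Gifu", "P2") == []
        assert len(filter_variants([record(qual=30.0)], "Gifu", "P2")) == 1

    def test_depth_below_threshold_dropped(self):
        assert filter_variants([record(depth=49)], "Gifu", "P2") == []

    def test_triallelic_dropped(self):
        assert filter_variants([record(alleles=("A", "C", "T"))], "Gifu", "P2") == []

    def test_missing_genotype_dropped(self):
        assert filter_variants([record(L1="./.")], "Gifu", "P2") == []

    def test_parental_contrast_required(self):
        same = record(P2="0/0")
        het_parent = record(Gifu="0/1")
        good = record()
        kept = filter_variants([same, het_parent, good], "Gifu", "P2")
        assert kept == [good]

    def test_order_preserved(self):
        recs = [record(pos=p) for p in (5, 3, 9)]
        kept = filter_variants(recs, "Gifu", "P2")
        assert [r.position for r in kept] == [5, 3, 9]

    def test_absent_parent_raises(self):
        with pytest.raises(SymisleError, match="nope"):
            filter_variants([record()], "nope", "P2")

    def test_relaxing_thresholds_is_monotone(self):
        recs = [
            record(qual=q, depth=d, pos=i + 1)
            for i, (q, d) in enumerate(itertools.product((10, 25, 35, 60), (20, 55, 150)))
        ]
        kept_strict = {r.position for r in filter_variants(recs, "Gifu", "P2", 30, 50)}
        kept_loose_q = {r.position for r in filter_variants(recs, "Gifu", "P2", 20, 50)}
        kept_loose_d = {r.position for r in filter_variants(recs, "Gifu", "P2", 30, 10)}
        assert kept_strict <= kept_loose_q
        assert kept_strict <= kept_loose_d


class TestConsensus:
    def test_modal_call(self):
        recs = [record(pos=p, L1=gt) for p, gt in ((1, "0/0"), (2, "0/0"), (3, "1/1"))]
        assert consensus_genotype(recs, "L1", "Gifu", "P2") == "A"

    def test_two_call_tie_enumeration(self):
        """All two-record call combinations: equal calls win, differing tie."""
        call_of = {"0/0": "A", "1/1": "B", "0/1": "H"}
        for g1, g2 in itertools.product(call_of, repeat=2):
            recs = [record(pos=1, L1=g1), record(pos=2, L1=g2)]
            got = consensus_genotype(recs, "L1", "Gifu", "P2")
            expected = call_of[g1] if g1 == g2 else "missing"
            assert got == expected, (g1, g2)

    def test_no_records_missing(self):
        assert consensus_genotype([], "L1", "Gifu", "P2") == "missing"

    def test_all_missing_calls_give_missing(self):
        recs = [record(pos=p, L1="./.") for p in (1, 2)]
        assert consensus_genotype(recs, "L1", "Gifu", "P2") == "missing"

    def test_het_exclusion_flag(self):
        recs = [record(pos=1, L1="0/1"), record(pos=2, L1="0/1"), record(pos=3, L1="0/0")]
        assert consensus_genotype(recs, "L1", "Gifu", "P2") == "H"
        assert consensus_genotype(recs, "L1", "Gifu", "P2", include_het=False) == "A"

    def test_multiple_contigs_rejected(self):
        with pytest.raises(SymisleError):
            consensus_genotype([record(contig="c1"), record(contig="c2", pos=5)], "L1", "Gifu", "P2")

    def test_record_order_invariance(self, rng):
        gts = ["0/0", "1/1", "0/1", "0/0", "0/0"]
        recs = [record(pos=i + 1, L1=g) for i, g in enumerate(gts)]
        base = consensus_genotype(recs, "L1", "Gifu", "P2")
        for _ in range(10):
            shuffled = list(rng.permutation(recs))
            assert consensus_genotype(shuffled, "L1", "Gifu", "P2") == base

    def test_matches_brute_force_on_random_instances(self, rng):
        """Oracle: explicit counting with Python dicts."""
        from collections import Counter

        gt_pool = ["0/0", "1/1", "0/1", "./."]
        call_of = {"0/0": "A", "1/1": "B", "0/1": "H"}
        for _ in range(250):
            gts = [gt_pool[i] for i in rng.integers(0, 4, size=rng.integers(1, 9))]
            recs = [record(pos=i + 1, L1=g) for i, g in enumerate(gts)]
            calls = [call_of[g] for g in gts if g != "./."]
            if not calls:
                expected = "missing"
            else:
                ranked = Counter(calls).most_common()
                if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
                    expected = "missing"
                else:
                    expected = ranked[0][0]
            assert consensus_genotype(recs, "L1", "Gifu", "P2") == expected


class TestN50:
    @pytest.mark.parametrize(
        "lengths,expected",
        [([8, 5, 4, 3], (5, 2)), ([10], (10, 1)), ([4, 4, 4, 4], (4, 2))],
    )
    def test_worked_examples(self, lengths, expected):
        assert n50_l50(lengths) == expected

    def test_empty_raises(self):
        with pytest.raises(SymisleError):
            n50_l50([])

    @settings(max_examples=250, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 10_000), min_size=1, max_size=30))
    def test_matches_cumulative_sum_oracle(self, lengths):
        n50, l50 = n50_l50(lengths)
        ordered = sorted(lengths, reverse=True)
        total = sum(ordered)
        running, count = 0, 0
        for length in ordered:
            running += length
            count += 1
            if running * 2 >= total:
                break
        assert (n50, l50) == (ordered[count - 1], count)


class TestMarkerCoverage:
    def test_published_percentage_arithmetic(self):
        """1,538 of 1,686 contigs with a SNP is 91.2%; 551,215,263 of
        554,078,227 bp is 99.5% (display rounding to one decimal)."""
        assert round(100 * 1538 / 1686, 1) == 91.2
        lengths = {f"c{i}": 1 for i in range(1686)}
        # make the with-SNP contigs carry the published bp split
        for i in range(1538):
            lengths[f"c{i}"] = 551_215_263 // 1538 + (1 if i < 551_215_263 % 1538 else 0)
        rest = 554_078_227 - 551_215_263
        for i in range(1538, 1686):
            lengths[f"c{i}"] = rest // 148 + (1 if i - 1538 < rest % 148 else 0)
        pop1 = [record(contig=f"c{i}", pos=1) for i in range(1200)]
        pop2 = [record(contig=f"c{i}", pos=1) for i in range(900, 1538)]
        table = marker_coverage_summary(lengths, {"pop1": pop1, "pop2": pop2}).set_index("dataset")
        snp_row = table.loc["Containing >=1 SNP"]
        assert snp_row["contig_count"] == 1538
        assert snp_row["contig_pct"] == 91.2
        assert snp_row["total_bp"] == 551_215_263
        assert snp_row["bp_pct"] == 99.5

    def test_subsets_partition_all_contigs(self):
        lengths = {f"c{i}": 100 * (i + 1) for i in range(10)}
        pop1 = [record(contig=c, pos=1) for c in ("c0", "c1", "c2")]
        pop2 = [record(contig=c, pos=1) for c in ("c2", "c3")]
        table = marker_coverage_summary(lengths, {"p1": pop1, "p2": pop2}).set_index("dataset")
        parts = ["Exclusively p1", "Exclusively p2", "Contains SNPs from both", "Does not contain any SNPs"]
        assert table.loc[parts, "contig_count"].sum() == table.loc["Assembly", "contig_count"]
        assert table.loc[parts, "total_bp"].sum() == table.loc["Assembly", "total_bp"]
        assert table.loc["Exclusively p1", "contig_count"] == 2
        assert table.loc["Contains SNPs from both", "contig_count"] == 1

    def test_all_markerless(self):
        lengths = {"c1": 10, "c2": 20}
        table = marker_coverage_summary(lengths, {"p1": [], "p2": []}).set_index("dataset")
        assert table.loc["Does not contain any SNPs", "contig_pct"] == 100.0
        assert table.loc["Containing >=1 SNP", "contig_count"] == 0


class TestSimulationRoundTrip:
    def test_consensus_recovers_true_pattern_via_vcf(self, tmp_path):
        """Error-free simulation -> VCF -> pysam -> filter -> consensus
        reproduces the generator's per-contig truth exactly."""
        cfg = SimulationConfig(
            seed=61,
            n_ril_contigs=12,
            n_ril_lines=8,
            qual_fail_fraction=0.0,
            depth_fail_fraction=0.0,
            multiallelic_fraction=0.0,
            missing_fraction=0.0,
            noncontrast_fraction=0.0,
            genotype_error_fraction=0.0,
        )
        sim = simulate_ril_variants(cfg)
        path = tmp_path / "ril.vcf"
        write_vcf(sim, path)
        records, samples, lengths = read_vcf(path)
        assert samples[:2] == [sim.gifu_sample, sim.parent2_sample]
        assert lengths == sim.contig_lengths
        kept = filter_variants(records, sim.gifu_sample, sim.parent2_sample)
        assert len(kept) == len(sim.records)
        matrix = consensus_matrix(kept, sim.line_samples, sim.gifu_sample, sim.parent2_sample)
        truth = sim.true_pattern.loc[matrix.index, matrix.columns]
        pd.testing.assert_frame_equal(matrix, truth)

    def test_records_from_frame_matches_vcf_reader(self, tmp_path):
        cfg = SimulationConfig(seed=67, n_ril_contigs=5, n_ril_lines=4)
        sim = simulate_ril_variants(cfg)
        direct = records_from_frame(
            sim.records, [sim.gifu_sample, sim.parent2_sample, *sim.line_samples]
        )
        path = tmp_path / "ril.vcf"
        write_vcf(sim, path)
        via_vcf, _samples, _lengths = read_vcf(path)
        assert len(direct) == len(via_vcf)
        for d, v in zip(direct, via_vcf):
            assert (d.contig, d.position, d.alleles) == (v.contig, v.position, v.alleles)
            assert d.genotypes == v.genotypes
            assert abs(d.quality - v.quality) < 0.05
            assert d.depth == v.depth
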