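"""Filter RIL variants and call per-contig consensus genotypes.

Sites must have QUAL >= 30, depth >= 50, be biallelic, carry no missing
genotypes, and contrast the two parents (both homozygous, different
alleles).  Each contig then gets the modal parental-origin call per line
(A = Gifu allele, B = other parent, H = heterozygous; ties -> missing).
"""

from symisle import SimulationConfig, simulate_ril_variants
from symisle.rilmap import (
    consensus_matrix,
    filter_variants,
    marker_coverage_summary,
    n50_l50,
    records_from_frame,
)
from symisle.simulate import with_seed

config = SimulationConfig(seed=3, n_ril_contigs=20, n_ril_lines=6)
# both populations are mapped against the same assembly; each covers a
# different (overlapping) subset of its contigs with markers
pops = {
    "gifu_x_burttii": simulate_ril_variants(config),
    "gifu_x_mg20": simulate_ril_variants(with_seed(config, 1003)),
}
coverage = {"gifu_x_burttii": range(0, 14), "gifu_x_mg20": range(8, 18)}

kept = {}
for name, sim in pops.items():
    samples = [sim.gifu_sample, sim.parent2_sample, *sim.line_samples]
    records = records_from_frame(sim.records, samples)
    contigs = {f"contig{i + 1:04d}" for i in coverage[name]}
    records = [r for r in records if r.contig in contigs]
    kept[name] = filter_variants(records, sim.gifu_sample, sim.parent2_sample)
    print(f"{name}: kept {len(kept[name])}/{len(records)} sites after filtering")

sim = pops["gifu_x_burttii"]
matrix = consensus_matrix(kept["gifu_x_burttii"], sim.line_samples, sim.gifu_sample, sim.parent2_sample)
print("\nconsensus genotypes (first 5 contigs):")
print(matrix.head().to_string())

summary = marker_coverage_summary(sim.contig_lengths, kept)
print("\nmarker coverage partition:")
print(summary.to_string(index=False))
n50, l50 = n50_l50(list(sim.contig_lengths.values()))
print(f"\nassembly N50 = {n50} bp at L50 = {l50} contigs")
# Contigs fall into four disjoint marker classes (exclusively either
# population, both, none); counts and bp sum to the assembly totals.
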