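# symisle

Cross-species conservation analysis of *symbiotic islands* — positional
clusters of co-regulated, symbiosis-related genes — between a query legume
genome rich in tandem duplications (Medicago-like, "species A") and a
target genome (Lotus-like, "species B").  The package is a tested,
offline-reproducible reimplementation of the comparative pipeline used to
ask whether such islands are a general feature of legume genomes: best-hit
homology, microsynteny calling, island co-expression statistics in
redundant and deduplicated modes, per-category conservation tables, plus
two companion procedures from the same genome project — gene-model
confidence classification and RIL (recombinant inbred line) consensus
genotyping.  A synthetic-data generator with known ground truth drives
every stage, so nothing needs to be downloaded.

## The statistics at the core

For each island category (NRU/NRD/NRN for nodule-vs-root up/down/non-
regulated; NDA/NDD/NDN for nodule developmental zones) the pipeline
tabulates counters and derives:

* **conservation rate** `= 100 · |A genes with a best hit| / |A genes|`
* **duplication rate** `= |A genes with hits| / |distinct B genes hit|` —
  values above 1 are the many-to-one signature of local tandem
  amplification in the query species;
* **microsynteny ratio** `= 100 · |B genes inside the island's microsyntenic
  region| / |distinct B genes|`, where the microsyntenic region is the
  densest positional cluster of the island's best hits (single-linkage,
  gaps ≤ 500 kb, ≥ 2 distinct genes);
* **majority-hit fraction**: islands where hits cover more than half of the
  members.

Expression conservation is measured two ways: the Pearson correlation of
per-gene `log2(nodule/root)` ratios across species over best-hit pairs, and
the per-island mean pairwise Pearson correlation of `log2(normalized+1)`
root/nodule profiles.  The latter is computed in **redundant** mode (a B
gene matched by k A genes enters k times) and **unique** mode (one A gene
per distinct microsyntenic B gene; islands with fewer than three distinct B
genes excluded).  The contrast between the two modes quantifies how much of
the apparent island co-regulation is an artifact of tandem duplication.

Counts are normalized with median-of-ratios size factors
(`factor_j = median_g counts[g,j] / geomean_g`) or per-library depth.

## Worked example

`examples/03_island_coexpression.py` simulates 150 nodule-upregulated (NRU)
and 150 non-regulated (NRN) islands at duplication factor 1.35, runs
best-hit selection, microsynteny calling and both correlation analyses, and
prints:

```
fraction of islands with mean pairwise r > 0.8 (target-species profiles):
  NRU:  redundant: 8/65   unique: 0/25
  NRN:  redundant: 0/76   unique: 0/30

cross-species Pearson r of log2(nodule/root) ratios over best-hit pairs:
category  pearson_r  n_pairs
     NRN   0.017152      398
     NRU   0.555515      552
```

Reading: NRU islands show a positive cross-species ratio correlation
(r ≈ 0.56) and an excess of highly co-expressed islands that exists *only*
while duplicated target genes are counted redundantly — after
deduplication the excess vanishes, which is precisely the signature that
island co-regulation is driven by local gene amplification rather than by
conserved regulatory neighborhoods.  NRN islands show neither signal.

The other scripts in `examples/` each demonstrate one capability
(simulation, best hits + microsynteny, conservation tables, confidence
classification, RIL consensus genotyping).  A thin CLI wraps the same
functions: `symisle run --out DIR --seed 7` executes the whole pipeline and
writes a checksummed manifest; per-stage subcommands (`simulate`,
`besthits`, `synteny`, `express-ratios`, `islands-summarize`, `classify`,
`ril consensus`, `ril summary`) operate on the plain-text interchange
formats (GFF-like gene tables, outfmt-6 similarity TSV, count matrices,
minimal VCF).

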