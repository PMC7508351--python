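# Methods

## Scope and model

`symisle` analyses the conservation of symbiotic islands — positional
clusters of co-regulated genes — between a query species A whose islands
contain tandemly duplicated coding families and poorly conserved lncRNAs,
and a target species B.  The pipeline is: similarity table → one best hit
per query (max bitscore; ties by lower E-value, then lexicographic subject
id, so selection is order-invariant) → per-island microsynteny call →
expression normalization, log nodule/root ratios, island co-expression in
redundant and unique modes → per-category counters and derived rates.
Companion modules classify predicted proteins into confidence classes and
build RIL consensus genotypes.

## Microsynteny

The call is positional, not collinear: distinct best-hit target genes are
grouped per chromosome, sorted by start, and split where consecutive gaps
exceed `max_gap_bp` (default 500 kb).  The largest cluster (ties: smallest
chromosome label, then leftmost start) is the island's microsyntenic
region when it holds at least `min_cluster` (default 2) distinct genes.
Gap-clustering is the weakest reasonable criterion and both knobs are
exposed; no gene-order or strand requirement is imposed.  The stricter
"≥ 3 distinct syntenic targets" rule is applied downstream as the
unique-mode island filter, not inside the synteny definition.
Distinctness is counted on target gene ids because tandem duplication
makes best-hit maps many-to-one.

## Expression statistics

Median-of-ratios size factors follow the standard estimator over genes
with nonzero counts in every sample; `library_depth` rescales columns to
the mean library size.  Log ratios are `log2((mean nodule + c)/(mean root
+ c))` with pseudocount `c = 1` by default (log base and pseudocount are
conventions, both configurable).  Island co-expression uses Pearson
correlation of `log2(normalized + 1)` profiles over root and nodule
samples; the log stabilizes negative-binomial variance.  Genes with
zero-variance profiles have no defined correlation; they are excluded from
pairing and reported, and an island's mean is undefined with fewer than
two usable profiles.  In redundant mode repeated target genes contribute
identical profiles (pairs with r = 1) by construction — that is the
phenomenon under study, not an artifact of the implementation.  Unique
mode keeps, per distinct microsyntenic target gene, the query gene with
the highest bitscore (ties: smallest gene id) and excludes islands with
fewer than three distinct target genes.

When the redundant- and unique-mode high-correlation fractions are
compared (`high_correlation_fraction`, threshold r > 0.8), both modes are
restricted to islands with at least three usable profiles: unique mode
requires three distinct targets intrinsically, and without the matching
restriction the redundant arm also counts two-gene islands whose single
pair crosses the threshold by sampling noise — an island-size composition
effect, not a duplication effect.  The excess is tested with a one-sided
two-proportion z-test.

## Derived rates and their rounding

conservation = 100·hits/genes (1 decimal), duplication = hits/distinct
targets (2 decimals), microsynteny ratio = 100·syntenic/distinct
(1 decimal), majority-hit = 100·(islands with hits in strictly more than
half of members)/islands (nearest integer).  Exactly half does not count
as a majority.  Distinct target genes are pooled per category.  Zero
denominators yield flagged undefined values rather than exceptions.

## Synthetic data

The generator emulates the data regime the analysis assumes; its defaults
are the study conditions.  Key structure:

* **Islands** are contiguous runs of 2–16 ancestral genes (uniform), laid
  out with 2 kb intergenic gaps and 1 Mb between islands on six
  chromosomes; category counts default to the published island set
  (270/89/84/49/211/57 for NRU/NRD/NRN/NDA/NDD/NDN).
* **Tandem amplification is clustered.**  A category-dependent fraction of
  islands (`island_amp_prob`; 0.40 for NRU, 0.50 for NRD, 0.02 for NRN,
  0.05/0.30/0.10 for NDA/NDD/NDN) are amplified-family islands; inside
  them each ancestor founds a family with probability `amp_gene_prob`
  (0.35), with `1 + 1 + Poisson(extra − 1)` copies.  `extra` is calibrated
  against the coding-gene margin so the mean copy number over all
  ancestral coding genes is exactly `duplication_factor` (default 1.35).
  A flat per-gene Poisson was rejected: it spreads the duplication budget
  so thinly that the redundant-mode co-expression excess the analysis is
  about carries no statistical signal.  Amplified islands are lncRNA-rich
  among their non-family genes (`lnc_fraction_amp` = 0.5, versus 0.12
  elsewhere), mirroring clusters of lineage-specific peptide genes
  annotated as lncRNAs.
* **Conservation** is Bernoulli per ancestral gene: 0.40 for coding, 0.15
  for lncRNA.  Conserved genes have exactly one B counterpart which stays
  in the island's syntenic block with probability 0.65 and is otherwise
  relocated to a scattered position on another chromosome.  Tandem copies
  are adjacent; every A coding gene descends from exactly one ancestor.
* **Similarity rows**: each copy of a conserved ancestor gets its true
  counterpart as the strictly top-scoring row plus lower-scoring rows to
  other conserved genes of the island; unconserved genes get a junk row
  with probability `spurious_hit_rate` (0.02).
* **Expression** is negative binomial (gamma–Poisson, variance
  `μ + αμ²`, dispersion α = 0.3) with lognormal per-ancestor baselines
  around 100 counts.  Regulation is assigned at the ancestral level:
  family founders respond to nodulation with probability 0.95,
  single-copy genes 0.5; regulated genes draw a log2 shift from
  `N(m, (0.25·|m|)²)` with category means +4 (NRU), −2 (NRD), 0 (NRN),
  +3/−2/0 (NDA/NDD/NDN) — magnitudes chosen once as realistic symbiosis-
  gene inductions, with down-regulation weaker than up-regulation so the
  strong/weaker/null ordering of cross-species correlation across
  NRU/NRD/NRN is emergent rather than asserted.  A conserved gene keeps
  its regulation in species B with probability 0.85 if it belongs to an
  amplified family and 0.2 otherwise; this encodes the central premise
  that island co-regulation is largely not conserved outside the
  amplified symbiosis families.  Tandem copies share their ancestor's
  baseline and effect exactly.
* **RIL data**: per contig, a true parental-origin pattern per line
  (A/B 50:50, residual heterozygosity 2%); sites independently fail
  quality (QUAL < 30), depth (< 50), become triallelic, lose one
  genotype, or lose parental contrast at configured fractions; per-line
  calls may be flipped with a configurable error rate (0 by default).

All four entry points are deterministic functions of `(config, seed)`;
each draws from an independent child stream so the operations may run in
any order.

What the generator does **not** emulate: sequence content (only scores and
coordinates), per-gene dispersion trends, read-level noise, genome
rearrangements beyond single-gene relocation, and linkage structure along
chromosomes.  Passing tests therefore show the pipeline's statistics are
correct and recover known ground truth under the assumed regime; they say
nothing about alignment quality or annotation error in real data.

## Confidence classification

Significance: E-value strictly below 1e-10 and subject coverage strictly
above 0.80.  The threshold is configurable because the protocol's printed
"10e-10" is ambiguous between 1e-9 and 1e-10; 1e-10 is used.  HC1
additionally requires query coverage above the same threshold (no second
number is stated, so one threshold serves both coverages).  Decision
order: PTREP-only evidence → REPEAT; complete + UniMag (both coverages) →
HC1; complete + Fab only → HC2; incomplete + (UniMag or Fab) without
PTREP → LC1; complete with no hits → LC2; everything else UNCLASSIFIED.
The order resolves combinations the prose leaves open (e.g. UniMag + PTREP
→ HC1: curated-protein evidence outranks repeat evidence) and makes the
classifier total over the evidence lattice.

## RIL consensus

Filters are conjunctive: site QUAL ≥ 30 (site-level quality, since the
genotype-level alternative is not specified), depth ≥ 50, biallelic, no
missing genotype in any sample, both parents homozygous for different
alleles.  The per-contig consensus is the modal parental-origin call;
ties yield `missing` rather than an arbitrary pick, avoiding systematic
map distortion.  Heterozygous calls compete in the mode by default
(residual heterozygosity is real in RILs) and can be excluded.  N50/L50
follow the usual cumulative-sum definition; marker-coverage summaries
partition contigs into exclusively-population-1, exclusively-population-2,
both, and none, with percentages shown to one decimal.

## Problem sizes

The default test and acceptance runs use up to 800 islands per category
(~15k genes, 6 samples per condition per species) for the co-expression
experiment and 150/80/80 islands for parameter recovery; both finish in
seconds.  Recovery runs exclude lncRNAs so that `conservation_prob` and
`duplication_factor` — both defined over coding genes — are estimated
without dilution by the separately-parameterized lncRNA conservation.

## Known limitations

Single global NB dispersion and conservation probability (no per-gene or
per-category trends beyond amplification); no collinearity requirement in
the microsynteny call; the redundant/unique contrast is sensitive to the
amplified-island composition, which is parameterized but fixed by default;
VCF support is minimal (GT/DP/QUAL as written by the simulator, read via
pysam).
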