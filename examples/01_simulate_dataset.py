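"""Generate a synthetic paired-species dataset and look at its ground truth.

The generator produces a Medicago-like query species A whose symbiotic
islands contain tandemly duplicated coding families and poorly conserved
lncRNAs, and a Lotus-like target species B holding one counterpart per
conserved ancestral gene.
"""

import numpy as np

from symisle import SimulationConfig, simulate_genome_pair

config = SimulationConfig(seed=42, n_islands_per_category={"NRU": 40, "NRD": 20, "NRN": 20})
genes_a, genes_b, islands, truth = simulate_genome_pair(config)

copies = np.array(
    [len(c) for a, c in truth.a_copies.items() if truth.biotype_of_anc[a] == "coding"]
)
conserved = sum(b is not None for b in truth.b_gene.values())

print(f"species A genes:        {len(genes_a)} ({(genes_a.biotype == 'lncRNA').sum()} lncRNA)")
print(f"species B genes:        {len(genes_b)}")
print(f"islands:                {len(islands)}")
print(f"ancestral genes:        {len(truth.a_copies)} ({conserved} conserved in B)")
print(f"mean copies (coding):   {copies.mean():.2f}  <- the tandem duplication factor")
print(f"largest tandem family:  {copies.max()} copies")

# Mean copies tracks config.duplication_factor (1.35 by default); families
# are clustered in a minority of amplified islands, so the maximum is large
# while most ancestors stay single copy.
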