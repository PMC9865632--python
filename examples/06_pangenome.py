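"""Gene presence/absence, mating-type calls and core/pan accounting.

A gene is present in a strain when enough of its bases are covered;
genes absent somewhere are dispensable, novel genes enter via a ledger,
and core + dispensable = reference, pan = reference + novel.
"""

import pandas as pd

from haplopop import (
    core_pan_accounting,
    gene_presence,
    mat_typing,
    simulate_depth,
    simulate_reference,
)
from haplopop.simulate import PopulationModel

model = PopulationModel(
    seed=5,
    chrom_length=100_000,
    strains_per_clade=(2, 2),
    n_genes=40,
    depth_noise="none",
    gene_deletions={
        "c1s1": ["g0001", "g0002"],  # planted losses (MATB markers below)
        "c1s2": ["g0001", "g0002", "g0007"],
    },
)
reference, genes = simulate_reference(model)
tracks = simulate_depth(model, reference, genes)

pa = gene_presence(tracks, genes, min_breadth=0.2, min_depth=1)
ledger = pd.DataFrame({"gene": ["novelA"], "strain": ["c2s1"], "length": [900]})
summary = core_pan_accounting(pa, ledger)
print(
    f"reference genes: {summary.n_reference_genes}, dispensable: {summary.n_dispensable}, "
    f"core: {summary.n_core}, novel: {summary.n_novel}, pan: {summary.n_pan}"
)

mats = mat_typing(pa, ("g0001", "g0002"))
print("mating types:", dict(mats))
# Strains missing both marker genes type as MATA, strains carrying both
# as MATB — the two idiomorphs of this heterothallic haploid yeast.
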