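# Demo pipeline config: simulate a small population and run every stage.
seed = 7

[simulate]
enabled = true
chrom_length = 200000
n_clades = 2
strains_per_clade = [5, 5]
clade_divergence = 4000
within_clade_divergence = 1000
singleton_rate = 10.0
n_genes = 30

[variants]
max_missing_fraction = 0.10
min_maf = 0.03

[popgen]
window = 10000
ld_max_dist = 10000

[distances]
clonemate_threshold = 725

[cnv]
window = 5000
step = 500
min_ratio = 1.25
min_len = 10000

[pangenome]
min_breadth = 0.2
min_depth = 1.0
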