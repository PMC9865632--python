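"""Estimate transposable-element copy numbers from coverage.

Mean depth over a TE divided by the genome-wide mean depth estimates its
copy number; summing length x copies over elements gives the TE fraction
of the genome.
"""

from haplopop import TELibrary, simulate_te_coverage, te_abundance, te_summary
from haplopop.simulate import PopulationModel

library = TELibrary(
    {
        "Ylt1": (8000, "LTR-retrotransposon"),
        "Tyl5_solo": (300, "solo-LTR"),
        "Ylli": (6000, "LINE"),
    }
)
model = PopulationModel(
    seed=2,
    chrom_length=1_000_000,
    strains_per_clade=(1, 1),
    te_loads={
        "c1s1": {"Ylt1": 47, "Tyl5_solo": 12, "Ylli": 5},  # a TE-rich outlier
        "c2s1": {"Tyl5_solo": 30, "Ylli": 10},
    },
    mean_depth=30.0,
)
coverage = simulate_te_coverage(model, library)

GENOME_LENGTH = 20_500_000  # fraction denominator: the 20.5-Mb reference
abundances = []
for strain, grp in coverage.groupby("strain"):
    ab = te_abundance(
        str(strain),
        dict(zip(grp["te"], grp["mean_depth"])),
        genome_mean_depth=model.mean_depth,
        library=library,
        genome_length=GENOME_LENGTH,
    )
    abundances.append(ab)
    print(f"{strain}: TE fraction {ab.genome_fraction_pct:.2f}% of the genome")

per_element, per_strain = te_summary(abundances, outlier_fraction_pct=1.5)
print("flagged as TE-rich (> 1.5% of genome):", list(per_strain.index[per_strain["flagged"]]))
# Fractional copy numbers are expected: solo LTRs and degenerate copies
# cover only part of the reference element.
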