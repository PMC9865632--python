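# Methods

This note documents the models, estimators and numerical choices behind
haplopop, and what the synthetic-data validation does and does not show
about real resequencing data.

## Genotype model

All statistics operate on a sites × strains matrix of haploid calls
{0 = reference, 1 = alternate, missing}. Strains are haploid, so a
diploid-style heterozygous GT in the input VCF cannot be a genotype; it
typically marks reads from collapsed duplicated copies. Such calls are
converted to missing (with a warning) rather than guessed — duplications
are detected from depth, not from genotypes. Multiallelic records are
split into one biallelic row per alternate; calls to the other
alternates become missing for that row.

Missing data are handled pairwise/complete-case at every site: allele
frequencies, pairwise differences and correlations use only the strains
called at the sites involved, with no rescaling. Sites reduced to fewer
than two calls contribute zero and are counted.

## Filtering

The SNP-panel filter keeps biallelic SNPs with missing fraction
≤ `max_missing_fraction` (default 0.10) and minor-allele frequency
≥ `min_maf` (default 0.03). Two conventions had to be fixed where the
source workflow is ambiguous:

* the MAF denominator is the number of **non-missing** calls (the PLINK
  behaviour); and
* both thresholds are inclusive keeps — "above 0.10" and "below 0.03"
  are read as exclusive removals.

Both are visible in `FilterConfig` and changeable.

## Diversity statistics

Per site with alternate count *a* among *n* called strains:

* π_site = a(n−a) / C(n,2), the fraction of differing pairs;
* d_site = p̂_A(1−p̂_B) + p̂_B(1−p̂_A) for Dxy;
* Hudson Fst per window: 1 − ΣH_w / ΣH_b (ratio of sums, not mean of
  ratios), with H_w = [2p̂_A(1−p̂_A)·n_A/(n_A−1) +
  2p̂_B(1−p̂_B)·n_B/(n_B−1)]/2 and H_b = p̂_A(1−p̂_B) + p̂_B(1−p̂_A).
  The n/(n−1) factor makes H_w the unbiased probability that two genomes
  drawn from the same population differ; the estimator is 0 for
  identical allele frequencies and 1 for a fixed difference. This is the
  standard haploid ratio-of-averages form; a variant sometimes written
  without the factor 2 in H_w is not mean-zero under panmixia and is
  deliberately not used.

Windows are fixed 10-kb physical intervals; the denominator is the
window's physical length (monomorphic positions dilute diversity), and
the terminal window uses its true length. Dividing by callable sites
instead would raise estimates on low-coverage data; physical length is
the convention matched here and genome-wide values are length-weighted
window means.

## LD decay

For every same-chromosome SNP pair within `max_dist` (default 10 kb),
r² is the squared Pearson correlation of the two 0/1 vectors over
pairwise-complete strains; zero-variance vectors are skipped. Means are
grouped by exact integer distance. LD₁/₂ is the smallest distance whose
mean r² is at or below half of the **maximum of the per-distance
means** — not half of r² at distance 1, which is noisier.

## Distances and clonemates

Distances are raw counts of differing pairwise-complete sites. They are
deliberately not rescaled for missingness; the per-pair complete-site
count is reported alongside so that missingness bias is visible rather
than hidden.

The clonemate threshold (default 725 differences) is strict
(d < threshold) and grouping is single linkage: any chain of
sub-threshold edges joins strains into one group; groups of size 1 are
not reported. `distance_gap` searches the largest empty interval between
consecutive distinct pairwise values, restricted to values at or below a
quantile of the distribution (default the median) so the clade-level
mode cannot mask the clonemate break. The returned interval is a
data-driven threshold suggestion, not a test.

## Depth, smoothing and duplication calling

Depth ratios follow log-then-average: per-position depth / genome-wide
mean, log2 (zero depth floored at −5 and counted), then a shifted
average — windows of 5000 bp at step 500, fully inside the chromosome.

Calling proceeds in three steps:

1. **Baseline.** The copy-1 level is the genome-wide median of the
   smoothed values. Dividing by the genome-wide mean alone leaves the
   baseline below zero whenever duplications inflate the mean — on a
   short chromosome carrying a 47-kb duplication the shift is ~0.2 in
   log2 — so both thresholding and copy-number estimation are
   baseline-relative. This assumes copy-1 sequence fills the majority of
   windows; a genome more than half duplicated defeats the calibration.
2. **Runs.** Windows whose baseline-relative ratio is ≥ `min_ratio`
   (default 1.25) are merged into maximal runs, bridging up to
   `merge_gap` sub-threshold windows. The threshold is an artifact
   decision — the source workflow states the transform and smoothing but
   no calling rule — chosen to retain sub-clonal events at ratio 1.4
   while clearing Poisson noise at 30× (smoothed-window noise SD is
   ~0.004 in log2, orders of magnitude below log2 1.25 ≈ 0.32).
3. **Boundary refinement.** Each run's plateau is the median in-run
   smoothed value; the segment's edges are placed where the smoothed
   profile crosses the level halfway between baseline and plateau,
   linearly interpolated between window midpoints. For an ideal step
   convolved with a boxcar window, this half-amplitude crossing falls
   exactly on the true edge, so noiseless planted boundaries are
   recovered to the base pair and Poisson-noise boundaries to well
   within one step. Taking the raw first-window-start to last-window-end
   span instead would pad every segment by up to a window width on each
   side (~6 kb here).

Segments shorter than `min_len` (default 10 kb) are dropped. Copy
number is 2^(plateau − baseline) against the haploid baseline of 1,
reported unrounded (sub-clonal events are fractional by nature: a
copy-2 event in a cell fraction f sits at 1 + f) and rounded. Deletions
use the same machinery mirrored at `max_ratio` (default 0.75).

## TE quantification

Copy number is mean depth over the element divided by genome-wide mean
depth; fractional values are meaningful (solo LTRs, degenerate copies).
The genome fraction is Σ length·CN over the reference genome length;
with copies exceeding the reference count the fraction can pass 100 %
and is flagged rather than clamped. Multi-mapping ambiguity between
near-identical elements is a property of the upstream alignment and is
taken as given: the coverage table is the interface.

## Presence/absence and pan-genome accounting

A gene is present when ≥ `min_breadth` (default 0.2) of its bases have
depth ≥ `min_depth` (default 1). The breadth rule is an operational
stand-in — the outcome ("missing in a strain") is published but the
criterion is not — and it is validated by exact recovery of planted
deletions on noiseless synthetic tracks. Novel genes enter through a
ledger (id, strain of origin, length ≥ 500 bp, matching the assembly
contig cutoff) because de-novo assembly is outside this package's
scope; the accounting identities core = reference − dispensable and
pan = reference + novel are asserted on every run. MAT typing calls
MATB when both MATB marker genes are present, MATA when both are
absent, and flags discordant strains as ambiguous.

## Synthetic populations

The generator plants structure directly in the quantity downstream
stages consume — the pairwise-difference matrix — rather than running a
coalescent:

* clade-diagnostic variants, (clade_divergence −
  within_clade_divergence)/2 per clade, carried by every clade member;
* lineage-private variants, within_clade_divergence/2 − singleton_rate
  per lineage (a clonemate group is one lineage; every other strain is
  its own), carried by all lineage members;
* per-strain singletons, Poisson(singleton_rate);
* clonemate extra mutations, uniform on [max_diff/4, max_diff/2] per
  member (the distribution of within-group differences is not published;
  a uniform range is exposed rather than guessing a mechanism), capped
  so singleton draws cannot push a within-group pair past max_diff.

Expected pairwise differences are then within_clade_divergence inside a
clade and clade_divergence across clades, and expected π follows from
the realized allele counts (the TruthRecord stores it exactly). The
canonical `diversity_benchmark` configuration — 1 Mb, four clades of
five strains, divergences 600/2082 — has mean pairwise difference
(40·600 + 150·2082)/190 = 1770 over 1 Mb, i.e. π = 0.00177, the
diversity scale of the motivating survey. Note that lineage-private
variants of non-clonemate strains are singletons under classification;
configurations that test singleton counts set within_clade_divergence =
2·singleton_rate so the Poisson draws are the only private variants.

Depth tracks are flat at mean_depth (default 30×), multiplied by
1 + (copy_number − 1)·cell_fraction inside planted duplications, zeroed
across planted gene deletions, with Poisson or no noise. TE coverage is
genome mean × planted copies, with optional Poisson averaging over the
element length. Indels are drawn at `indel_fraction` with geometric
lengths 1–10. All randomness flows from `numpy.random.default_rng`
seeded with (model seed, stream offset) pairs; identical models produce
byte-identical FASTA/BED/VCF/bedGraph outputs.

What the generator does **not** emulate: sequencing error, mapping
bias, GC-dependent coverage, linkage structure within clades (variants
are placed independently, so LD tests build Markov haplotypes
separately), recombination graphs, and read-level artifacts. Passing
the recovery tests therefore demonstrates estimator correctness on the
intended signal, not robustness to alignment pathologies.

## Problem sizes

The validation suite runs at desk scale by design: oracle-equivalence
checks use ≤ 10 strains × 50 sites where brute-force enumeration is
exact and fast; parameter-recovery runs use 0.5–2-Mb genomes with 20
strains at 30× depth, large enough that Poisson noise and window
quantization are exercised while a full run of the suite stays in the
tens of seconds. The 56-strain, 196,619-record composition fixture is
generated and round-tripped through VCF at full published scale.

## Known limitations

* The Fst implementation is the Hudson estimator; the survey's own
  numbers came from a package whose exact estimator choice is not
  stated, so parity with its printed genome-wide range is not claimed.
* Effect annotation covers single-interval CDS models only (no introns,
  no splice/UTR classes — those collapse to intergenic/modifier); it
  targets low/moderate/high accounting, not full annotator parity.
* Duplication calling reports depth evidence only; breakpoint
  resolution and insertion-site mapping need split reads or assembly.
* The presence/absence rule is coverage-based; paralog collapse can
  mask true losses in duplicated families.
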