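"""Synthetic haploid populations with known truth.

Generates everything the downstream stages consume — reference FASTA,
gene BED, haploid VCF, per-strain depth bedGraphs, TE coverage tables —
from a single seeded model, so diversity estimation, clonemate
detection, duplication calling, TE quantification and presence/absence
accounting can all be validated against planted ground truth without any
sequencing data.

The mutation model is a star-within-clades construction, which controls
exactly the quantity downstream statistics consume (the pairwise
difference structure) without simulating a coalescent:

* clade-diagnostic variants carried by every member of one clade
  (``(clade_divergence - within_clade_divergence) / 2`` per clade);
* lineage-private variants carried by all members of a lineage, where a
  lineage is a clonemate group or a single non-clonemate strain
  (``within_clade_divergence / 2 - singleton_rate`` per lineage);
* per-strain singletons, Poisson with mean ``singleton_rate``;
* clonemate extra mutations, one uniform draw per group member on
  ``[max_diff/4, max_diff/2]`` (capped so that realized singleton counts
  cannot push a within-group pair past ``max_diff``).

Expected pairwise differences are then ``within_clade_divergence`` for
two same-clade lineages and ``clade_divergence`` across clades, and the
expected nucleotide diversity follows from the realized allele counts.

Depth tracks are flat at ``mean_depth`` except inside planted
duplications, where the expectation is
``mean_depth * (1 + (copy_number - 1) * cell_fraction)`` — a sub-clonal
copy-2 event in 40% of cells sits at ratio 1.4 — and zero across planted
gene deletions. Noise is Poisson or none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .depth_cnv import DepthTrack
from .genotypes import GenotypeMatrix, write_vcf
from .io import GeneModel
from .te_quant import TELibrary

BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class DuplicationEvent:
    """A planted segmental duplication (0-based half-open coordinates)."""

    strain: str
    chrom: str
    start: int
    end: int
    copy_number: int
    cell_fraction: float = 1.0

    def __post_init__(self):
        if self.end <= self.start or self.start < 0:
            raise ValueError("invalid event coordinates")
        if self.copy_number < 2:
            raise ValueError("duplication copy_number must be >= 2")
        if not 0 < self.cell_fraction <= 1:
            raise ValueError("cell_fraction must lie in (0, 1]")

    @property
    def depth_factor(self) -> float:
        return 1.0 + (self.copy_number - 1) * self.cell_fraction


@dataclass(frozen=True)
class ClonemateGroup:
    clade: int  # 0-based clade index
    size: int
    max_pairwise_diff: int


@dataclass
class PopulationModel:
    """Full specification of one synthetic study population."""

    seed: int
    n_chromosomes: int = 1
    chrom_length: int = 200_000
    n_clades: int = 2
    strains_per_clade: tuple = (5, 5)
    clade_divergence: int = 4000
    within_clade_divergence: int = 1000
    clonemate_groups: tuple = ()
    singleton_rate: float = 10.0
    indel_fraction: float = 0.0
    duplication_events: tuple = ()
    te_loads: dict = field(default_factory=dict)
    gene_deletions: dict = field(default_factory=dict)
    mean_depth: float = 30.0
    depth_noise: str = "poisson"
    n_genes: int = 50
    gene_length: int = 999
    gene_min_gap: int = 50

    def __post_init__(self):
        if self.n_chromosomes <= 0 or self.chrom_length <= 0:
            raise ValueError("chromosome counts and lengths must be positive")
        if len(self.strains_per_clade) != self.n_clades:
            raise ValueError("strains_per_clade must have n_clades entries")
        if self.within_clade_divergence > self.clade_divergence:
            raise ValueError("within-clade divergence cannot exceed between-clade divergence")
        if self.singleton_rate > self.within_clade_divergence / 2:
            raise ValueError("singleton_rate cannot exceed within_clade_divergence / 2")
        if not 0 <= self.indel_fraction <= 1:
            raise ValueError("indel_fraction must lie in [0, 1]")
        if self.depth_noise not in ("poisson", "none"):
            raise ValueError("depth_noise must be 'poisson' or 'none'")
        groups = [g if isinstance(g, ClonemateGroup) else ClonemateGroup(*g) for g in self.clonemate_groups]
        used: dict[int, int] = {}
        for g in groups:
            if not 0 <= g.clade < self.n_clades:
                raise ValueError("clonemate group references unknown clade")
            if g.max_pairwise_diff >= self.clade_divergence:
                raise ValueError("clonemate max_pairwise_diff must be below clade_divergence")
            used[g.clade] = used.get(g.clade, 0) + g.size
        for clade, n in used.items():
            if n > self.strains_per_clade[clade]:
                raise ValueError("clonemate groups larger than their clade")
        self.clonemate_groups = tuple(groups)
        self.duplication_events = tuple(
            e if isinstance(e, DuplicationEvent) else DuplicationEvent(*e)
            for e in self.duplication_events
        )

    # ---- derived layout -------------------------------------------------
    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def genome_length(self) -> int:
        return self.n_chromosomes * self.chrom_length

    def strain_names(self) -> list[str]:
        return [
            f"c{k + 1}s{i + 1}"
            for k in range(self.n_clades)
            for i in range(self.strains_per_clade[k])
        ]

    def clade_of(self) -> dict[str, int]:
        out = {}
        for k in range(self.n_clades):
            for i in range(self.strains_per_clade[k]):
                out[f"c{k + 1}s{i + 1}"] = k
        return out

    def lineages(self) -> tuple[list[list[str]], list[list[str]]]:
        """Partition strains into lineages.

        Returns ``(lineages, clonemate_lineages)`` where each lineage is a
        list of strain names; clonemate groups occupy the first strains of
        their clade, every other strain is its own lineage.
        """
        lineages: list[list[str]] = []
        clone_lineages: list[list[str]] = []
        for k in range(self.n_clades):
            members = [f"c{k + 1}s{i + 1}" for i in range(self.strains_per_clade[k])]
            cursor = 0
            for g in self.clonemate_groups:
                if g.clade == k:
                    grp = members[cursor : cursor + g.size]
                    cursor += g.size
                    lineages.append(grp)
                    clone_lineages.append(grp)
            for s in members[cursor:]:
                lineages.append([s])
        return lineages, clone_lineages

    # ---- canonical configurations --------------------------------------
    @classmethod
    def diversity_benchmark(cls, seed: int) -> "PopulationModel":
        """1-Mb, 20-strain population whose expected pi is 0.00177.

        Four clades of five strains; mean pairwise difference
        (40*600 + 150*2082)/190 = 1770 over 1 Mb.
        """
        return cls(
            seed=seed,
            n_chromosomes=1,
            chrom_length=1_000_000,
            n_clades=4,
            strains_per_clade=(5, 5, 5, 5),
            clade_divergence=2082,
            within_clade_divergence=600,
            singleton_rate=10.0,
            n_genes=100,
        )

    @classmethod
    def clonemate_benchmark(cls, seed: int) -> "PopulationModel":
        """Population with planted clonemate groups separated from the
        clade-level mode (within-group < 725, everything else > 2533)."""
        return cls(
            seed=seed,
            n_chromosomes=1,
            chrom_length=500_000,
            n_clades=2,
            strains_per_clade=(10, 10),
            clade_divergence=5000,
            within_clade_divergence=4000,
            clonemate_groups=(ClonemateGroup(0, 3, 300), ClonemateGroup(1, 4, 500)),
            singleton_rate=10.0,
        )

    @property
    def expected_pi(self) -> float:
        """Expected nucleotide diversity of the model (no clonemate terms)."""
        sizes = np.asarray(self.strains_per_clade)
        n = sizes.sum()
        total_pairs = n * (n - 1) / 2
        within_pairs = (sizes * (sizes - 1) / 2).sum()
        between_pairs = total_pairs - within_pairs
        mean_d = (
            within_pairs * self.within_clade_divergence
            + between_pairs * self.clade_divergence
        ) / total_pairs
        return mean_d / self.genome_length


@dataclass
class TruthRecord:
    """Ground truth emitted alongside each simulated population."""

    strain_variant_counts: pd.Series
    pairwise_diff: pd.DataFrame
    expected_pi: float
    site_pi: pd.DataFrame  # chrom, pos, pi_site of the emitted matrix
    clonemate_groups: list[list[str]]
    planted_segments: tuple
    planted_te: dict
    deleted_genes: dict
    n_singletons: int

    def expected_pi_windows(self, window: int, chrom_lengths: dict[str, int]) -> pd.DataFrame:
        rows = []
        for chrom, length in chrom_lengths.items():
            sub = self.site_pi[self.site_pi["chrom"] == chrom]
            pos0 = sub["pos"].to_numpy() - 1
            starts = np.arange(0, length, window)
            ends = np.minimum(starts + window, length)
            idx = np.searchsorted(starts, pos0, side="right") - 1
            sums = np.bincount(idx, weights=sub["pi_site"].to_numpy(), minlength=len(starts))
            for k in range(len(starts)):
                rows.append((chrom, int(starts[k]), int(ends[k]), sums[k] / (ends[k] - starts[k])))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "pi"])


def _rng(model: PopulationModel, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(model.seed), stream])


def simulate_reference(model: PopulationModel):
    """Random reference genome and non-overlapping gene models.

    Returns ``(reference, genes)``: one uppercase A/C/G/T sequence per
    chromosome and a list of :class:`GeneModel`. Deterministic given the
    model seed.
    """
    rng = _rng(model, 0)
    reference = {
        name: "".join(BASES[rng.integers(0, 4, size=model.chrom_length)])
        for name in model.chrom_names
    }
    genes: list[GeneModel] = []
    per_chrom = [model.n_genes // model.n_chromosomes] * model.n_chromosomes
    for i in range(model.n_genes % model.n_chromosomes):
        per_chrom[i] += 1
    gid = 0
    for chrom, count in zip(model.chrom_names, per_chrom):
        footprint = count * (model.gene_length + model.gene_min_gap)
        if footprint > model.chrom_length:
            raise ValueError(
                f"cannot place {count} genes of {model.gene_length} bp on a "
                f"{model.chrom_length} bp chromosome"
            )
        slack = model.chrom_length - footprint
        offsets = np.sort(rng.integers(0, slack + 1, size=count))
        for k in range(count):
            start = int(offsets[k] + k * (model.gene_length + model.gene_min_gap))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(chrom, start, start + model.gene_length, f"g{gid:04d}", strand))
            gid += 1
    return reference, genes


def _alt_allele(rng, reference, chrom, pos0, is_indel):
    ref_base = reference[chrom][pos0]
    if not is_indel:
        alt = str(rng.choice(BASES[BASES != ref_base]))
        return ref_base, alt
    length = int(min(rng.geometric(0.5), 10))
    if rng.random() < 0.5:  # insertion
        ins = "".join(rng.choice(BASES, size=length))
        return ref_base, ref_base + ins
    ref = reference[chrom][pos0 : pos0 + 1 + length]
    return ref, ref_base


def simulate_population(model: PopulationModel, reference: dict[str, str], vcf_path=None):
    """Plant the star-within-clades variant structure.

    Returns ``(GenotypeMatrix, TruthRecord)`` and optionally writes the
    haploid VCF. Raises when the requested divergences need more variant
    sites than the genome has positions.
    """
    rng = _rng(model, 1)
    strains = model.strain_names()
    n_strains = len(strains)
    col = {s: j for j, s in enumerate(strains)}
    lineages, clone_lineages = model.lineages()

    n_clade_var = max(0, round((model.clade_divergence - model.within_clade_divergence) / 2))
    n_lineage_var = max(0, round(model.within_clade_divergence / 2 - model.singleton_rate))

    carriers: list[list[int]] = []
    category: list[str] = []
    clade_members = {
        k: [col[s] for s, c in model.clade_of().items() if c == k] for k in range(model.n_clades)
    }
    for k in range(model.n_clades):
        for _ in range(n_clade_var):
            carriers.append(clade_members[k])
            category.append("clade")
    for lin in lineages:
        for _ in range(n_lineage_var):
            carriers.append([col[s] for s in lin])
            category.append("lineage")
    singleton_counts = {}
    for s in strains:
        k = int(rng.poisson(model.singleton_rate))
        singleton_counts[s] = k
        for _ in range(k):
            carriers.append([col[s]])
            category.append("singleton")
    for g, members in zip(model.clonemate_groups, clone_lineages):
        cap = g.max_pairwise_diff // 2
        lo = max(0, g.max_pairwise_diff // 4)
        for s in members:
            n_extra = int(rng.integers(lo, cap + 1))
            n_extra = max(0, min(n_extra, cap - singleton_counts[s]))
            for _ in range(n_extra):
                carriers.append([col[s]])
                category.append("clonemate_extra")

    n_var = len(carriers)
    # keep indel REF spans inside the chromosome
    usable = model.chrom_length - 12
    if n_var > usable * model.n_chromosomes:
        raise ValueError(
            f"requested divergences need {n_var} variant sites but only "
            f"{usable * model.n_chromosomes} positions are available"
        )
    flat = rng.choice(usable * model.n_chromosomes, size=n_var, replace=False)
    chrom_idx = flat // usable
    pos0 = flat % usable

    order = np.lexsort((pos0, chrom_idx))
    calls = np.zeros((n_var, n_strains), dtype=np.int8)
    refs, alts, chroms, poss = [], [], [], []
    is_indel = rng.random(n_var) < model.indel_fraction
    for row, k in enumerate(order):
        chrom = model.chrom_names[chrom_idx[k]]
        ref, alt = _alt_allele(rng, reference, chrom, int(pos0[k]), bool(is_indel[k]))
        chroms.append(chrom)
        poss.append(int(pos0[k]) + 1)
        refs.append(ref)
        alts.append(alt)
        calls[row, carriers[k]] = 1

    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    m = GenotypeMatrix(sites=sites, calls=calls, strains=strains)

    x = calls.astype(np.int64)
    diff = x.T @ (1 - x) + (1 - x).T @ x
    a = x.sum(axis=1)
    site_pi = 2 * a * (n_strains - a) / (n_strains * (n_strains - 1))
    truth = TruthRecord(
        strain_variant_counts=pd.Series(x.sum(axis=0), index=strains),
        pairwise_diff=pd.DataFrame(diff, index=strains, columns=strains),
        expected_pi=float(site_pi.sum() / model.genome_length),
        site_pi=pd.DataFrame({"chrom": chroms, "pos": poss, "pi_site": site_pi}),
        clonemate_groups=[list(g) for g in clone_lineages],
        planted_segments=model.duplication_events,
        planted_te=dict(model.te_loads),
        deleted_genes=dict(model.gene_deletions),
        n_singletons=int((a == 1).sum()),
    )
    if vcf_path is not None:
        write_vcf(m, vcf_path, contigs={c: model.chrom_length for c in model.chrom_names})
    return m, truth


def simulate_depth(
    model: PopulationModel, reference: dict[str, str], genes: list[GeneModel] | None = None
) -> dict[str, DepthTrack]:
    """Per-strain depth tracks with planted duplications and gene deletions.

    Expected depth inside a duplication is
    ``mean_depth * (1 + (copy_number - 1) * cell_fraction)``; planted
    gene deletions are zero-depth. Overlapping events in one strain are
    rejected.
    """
    by_strain: dict[str, list[DuplicationEvent]] = {}
    for e in model.duplication_events:
        if e.chrom not in reference or e.end > len(reference[e.chrom]):
            raise ValueError(f"duplication event outside chromosome: {e}")
        by_strain.setdefault(e.strain, []).append(e)
    for strain, events in by_strain.items():
        by_chrom: dict[str, list[DuplicationEvent]] = {}
        for e in events:
            by_chrom.setdefault(e.chrom, []).append(e)
        for chrom_events in by_chrom.values():
            chrom_events.sort(key=lambda e: e.start)
            for prev, nxt in zip(chrom_events, chrom_events[1:]):
                if nxt.start < prev.end:
                    raise ValueError(f"overlapping duplication events in strain {strain}")
    gene_by_name = {g.name: g for g in (genes or [])}
    tracks = {}
    for j, strain in enumerate(model.strain_names()):
        rng = _rng(model, 1000 + j)
        depths = {}
        for chrom, seq in reference.items():
            expected = np.full(len(seq), float(model.mean_depth))
            for e in by_strain.get(strain, []):
                if e.chrom == chrom:
                    expected[e.start : e.end] *= e.depth_factor
            for gname in model.gene_deletions.get(strain, []):
                g = gene_by_name.get(gname)
                if g is None:
                    raise KeyError(f"gene deletion references unknown gene {gname}")
                if g.chrom == chrom:
                    expected[g.start : g.end] = 0.0
            if model.depth_noise == "poisson":
                depths[chrom] = rng.poisson(expected).astype(np.float64)
            else:
                depths[chrom] = expected
        tracks[strain] = DepthTrack(depths)
    return tracks


def simulate_te_coverage(model: PopulationModel, library: TELibrary) -> pd.DataFrame:
    """Per-strain per-TE mean depth: genome mean depth times planted copies.

    With Poisson noise the per-base coverage over the element is drawn and
    averaged; noiseless gives the expectation exactly. Unknown TE names
    raise.
    """
    rows = []
    for j, strain in enumerate(model.strain_names()):
        rng = _rng(model, 2000 + j)
        loads = model.te_loads.get(strain, {})
        unknown = set(loads) - set(library.entries)
        if unknown:
            raise KeyError(f"te_loads references TEs not in library: {sorted(unknown)}")
        for te in library.entries:
            copies = float(loads.get(te, 0.0))
            expected = model.mean_depth * copies
            if model.depth_noise == "poisson" and expected > 0:
                length = library.length(te)
                depth = rng.poisson(expected, size=length).mean()
            else:
                depth = expected
            rows.append((strain, te, float(depth)))
    return pd.DataFrame(rows, columns=["strain", "te", "mean_depth"])


@dataclass(frozen=True)
class CompositionCounts:
    """Requested per-class variant totals for a composition fixture."""

    n_snp: int
    n_insertion: int
    n_deletion: int
    n_snp_singleton: int = 0
    n_insertion_singleton: int = 0
    n_deletion_singleton: int = 0

    def __post_init__(self):
        for tot, single, name in (
            (self.n_snp, self.n_snp_singleton, "SNP"),
            (self.n_insertion, self.n_insertion_singleton, "insertion"),
            (self.n_deletion, self.n_deletion_singleton, "deletion"),
        ):
            if tot < 0 or single < 0:
                raise ValueError(f"{name} counts must be non-negative")
            if single > tot:
                raise ValueError(f"{name} singleton sub-count exceeds class total")

    @property
    def n_total(self) -> int:
        return self.n_snp + self.n_insertion + self.n_deletion


def make_composition_vcf(counts: CompositionCounts, path, n_strains: int = 4, seed: int = 0):
    """Emit a multi-sample haploid VCF whose classification reproduces the
    requested per-class and singleton totals exactly.

    Positions are synthetic (sorted, unique, step 12 on one chromosome);
    non-singleton records carry the alternate allele in two strains.
    Byte-identical output for identical arguments.
    """
    if n_strains < 3:
        raise ValueError("need at least 3 strains so non-singletons stay minority-free")
    rng = np.random.default_rng([int(seed), 42])
    n = counts.n_total
    strains = [f"s{i + 1}" for i in range(n_strains)]
    specs = (
        ("snp", counts.n_snp, counts.n_snp_singleton),
        ("ins", counts.n_insertion, counts.n_insertion_singleton),
        ("del", counts.n_deletion, counts.n_deletion_singleton),
    )
    kinds = np.concatenate(
        [np.full(tot, k) for k, tot, _ in specs] or [np.empty(0, dtype="U3")]
    )
    single = np.concatenate(
        [np.r_[np.ones(s, bool), np.zeros(tot - s, bool)] for _, tot, s in specs]
        or [np.empty(0, bool)]
    )
    order = rng.permutation(n)
    kinds, single = kinds[order], single[order]

    calls = np.zeros((n, n_strains), dtype=np.int8)
    if n:
        first = rng.integers(0, n_strains, size=n)
        calls[np.arange(n), first] = 1
        second = (first + 1 + rng.integers(0, n_strains - 1, size=n)) % n_strains
        rows = np.flatnonzero(~single)
        calls[rows, second[rows]] = 1

    pos = 10 + 12 * np.arange(n)
    refs, alts = [], []
    for k in kinds:
        base, other = rng.choice(BASES, size=2, replace=False)
        if k == "snp":
            refs.append(base)
            alts.append(other)
        elif k == "ins":
            refs.append(base)
            alts.append(base + "".join(rng.choice(BASES, size=int(rng.integers(1, 6)))))
        else:
            refs.append(base + "".join(rng.choice(BASES, size=int(rng.integers(1, 6)))))
            alts.append(base)
    sites = pd.DataFrame({"chrom": "chr1", "pos": pos, "ref": refs, "alt": alts})
    m = GenotypeMatrix(sites=sites, calls=calls, strains=strains)
    length = int(pos[-1] + 20) if n else 100
    write_vcf(m, path, contigs={"chr1": length})
    return m


def simulate_all(model: PopulationModel, outdir, te_library: TELibrary | None = None):
    """Write the complete fixture set for one model into ``outdir``.

    reference.fa, genes.bed, population.vcf, clades.tsv, depth/<strain>.bedgraph,
    te_coverage.tsv and truth tables. Returns the TruthRecord.
    """
    from pathlib import Path

    from .io import write_bed, write_bedgraph, write_fasta

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    reference, genes = simulate_reference(model)
    write_fasta(reference, out / "reference.fa")
    write_bed(genes, out / "genes.bed")
    m, truth = simulate_population(model, reference, vcf_path=out / "population.vcf")
    clade_of = model.clade_of()
    pd.DataFrame(
        {"strain": list(clade_of), "clade": [f"clade{k + 1}" for k in clade_of.values()]}
    ).to_csv(out / "clades.tsv", sep="\t", index=False)
    (out / "depth").mkdir(exist_ok=True)
    for strain, track in simulate_depth(model, reference, genes).items():
        write_bedgraph(track.depths, out / "depth" / f"{strain}.bedgraph")
    if te_library is not None:
        simulate_te_coverage(model, te_library).to_csv(
            out / "te_coverage.tsv", sep="\t", index=False
        )
    truth.pairwise_diff.to_csv(out / "truth_pairwise.tsv", sep="\t")
    truth.strain_variant_counts.rename("n_variants").to_csv(out / "truth_counts.tsv", sep="\t")
    return truth
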