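"""Variant accounting: class totals, singleton counts, Ts/Tv, SNP
filtering, and a simplified codon-aware effect/impact classifier.

The filter mirrors the conventional PLINK-style SNP panel preparation for
a haploid population survey: biallelic SNPs with a missing-genotype
fraction at or below ``max_missing_fraction`` and a minor-allele
frequency at or above ``min_maf``, the frequency computed over
non-missing calls only.

Effect classification is deliberately coarse: synonymous / missense /
stop_gained / stop_lost for coding SNPs, frameshift vs in-frame for
coding indels (|len(ref) - len(alt)| mod 3), everything else intergenic.
Impacts follow the usual low / moderate / high / modifier buckets.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .genotypes import MISSING, GenotypeMatrix
from .io import GeneModel

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

IMPACT_OF_EFFECT = {
    "synonymous": "low",
    "missense": "moderate",
    "inframe_indel": "moderate",
    "stop_gained": "high",
    "stop_lost": "high",
    "frameshift": "high",
    "intergenic": "modifier",
}


@dataclass(frozen=True)
class FilterConfig:
    """SNP panel filter thresholds (boundary-inclusive keeps)."""

    max_missing_fraction: float = 0.10
    min_maf: float = 0.03
    snps_only: bool = True

    def __post_init__(self):
        if not (0 <= self.max_missing_fraction <= 1 and 0 <= self.min_maf <= 1):
            raise ValueError("filter fractions must lie in [0, 1]")


@dataclass
class VariantClassSummary:
    n_total: int = 0
    n_snp: int = 0
    n_insertion: int = 0
    n_deletion: int = 0
    n_singleton: int = 0
    n_snp_singleton: int = 0
    n_insertion_singleton: int = 0
    n_deletion_singleton: int = 0
    n_transition: int = 0
    n_transversion: int = 0

    @property
    def n_indel(self) -> int:
        return self.n_insertion + self.n_deletion

    @property
    def n_indel_singleton(self) -> int:
        return self.n_insertion_singleton + self.n_deletion_singleton

    @property
    def ts_tv_ratio(self) -> float:
        return self.n_transition / self.n_transversion if self.n_transversion else float("nan")


@dataclass(frozen=True)
class EffectCall:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str | None
    effect: str
    impact: str = field(default="")

    def __post_init__(self):
        if not self.impact:
            object.__setattr__(self, "impact", IMPACT_OF_EFFECT[self.effect])


def _class_masks(m: GenotypeMatrix):
    ref_len = m.sites["ref"].str.len().to_numpy()
    alt_len = m.sites["alt"].str.len().to_numpy()
    snp = (ref_len == 1) & (alt_len == 1)
    ins = alt_len > ref_len
    dele = ~snp & ~ins
    return snp, ins, dele


def classify_variants(m: GenotypeMatrix) -> VariantClassSummary:
    """Per-class totals, singletons and the Ts/Tv ratio.

    A singleton is a variant whose alternate allele is carried by exactly
    one strain (the study's "variants observed in only one genome").
    """
    if m.n_sites == 0:
        return VariantClassSummary()
    snp, ins, dele = _class_masks(m)
    alt_count = (m.calls == 1).sum(axis=1)
    singleton = alt_count == 1

    ref = m.sites["ref"].to_numpy()
    alt = m.sites["alt"].to_numpy()
    ts = np.zeros(m.n_sites, dtype=bool)
    snp_idx = np.flatnonzero(snp)
    for i in snp_idx:
        ts[i] = (ref[i], alt[i]) in TRANSITIONS

    return VariantClassSummary(
        n_total=m.n_sites,
        n_snp=int(snp.sum()),
        n_insertion=int(ins.sum()),
        n_deletion=int(dele.sum()),
        n_singleton=int(singleton.sum()),
        n_snp_singleton=int((snp & singleton).sum()),
        n_insertion_singleton=int((ins & singleton).sum()),
        n_deletion_singleton=int((dele & singleton).sum()),
        n_transition=int(ts.sum()),
        n_transversion=int((snp & ~ts).sum()),
    )


def filter_snps(m: GenotypeMatrix, cfg: FilterConfig = FilterConfig()) -> GenotypeMatrix:
    """Keep sites passing missingness and MAF thresholds (order preserved)."""
    missing = (m.calls == MISSING).sum(axis=1)
    n_called = m.n_strains - missing
    with np.errstate(invalid="ignore", divide="ignore"):
        missing_frac = missing / m.n_strains
        alt_freq = np.where(n_called > 0, (m.calls == 1).sum(axis=1) / np.maximum(n_called, 1), 0.0)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    keep = (missing_frac <= cfg.max_missing_fraction) & (maf >= cfg.min_maf) & (n_called > 0)
    if cfg.snps_only:
        keep &= m.is_snp()
    return m.take_sites(keep)


def _coding_sequence(gene: GeneModel, reference: dict[str, str]) -> str:
    seq = reference[gene.chrom][gene.start : gene.end]
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _coding_offset(gene: GeneModel, pos0: int) -> int:
    """0-based offset of genomic position ``pos0`` within the coding sequence."""
    return pos0 - gene.start if gene.strand == "+" else gene.end - 1 - pos0


def _classify_coding_snp(gene: GeneModel, reference: dict[str, str], pos0: int, alt: str) -> str:
    cds = _coding_sequence(gene, reference)
    offset = _coding_offset(gene, pos0)
    alt_base = alt if gene.strand == "+" else str(Seq(alt).complement())
    ci = offset // 3
    codon = cds[3 * ci : 3 * ci + 3]
    if len(codon) < 3:  # trailing partial codon of a non-multiple-of-3 model
        return "missense"
    mutated = codon[: offset % 3] + alt_base + codon[offset % 3 + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mutated).translate())
    if alt_aa == ref_aa:
        return "synonymous"
    if alt_aa == "*":
        return "stop_gained"
    if ref_aa == "*":
        return "stop_lost"
    return "missense"


def annotate_effects(
    m: GenotypeMatrix, genes: list[GeneModel], reference: dict[str, str]
) -> list[EffectCall]:
    """Map each variant to a gene (or intergenic) and classify its effect.

    The variant's anchor base (its VCF POS) decides gene membership.
    Raises ValueError when a REF allele disagrees with the reference
    sequence at its position.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    starts = {c: [g.start for g in sorted(gs, key=lambda g: g.start)] for c, gs in by_chrom.items()}
    sorted_genes = {c: sorted(gs, key=lambda g: g.start) for c, gs in by_chrom.items()}

    calls = []
    for chrom, pos, ref, alt in m.sites.itertuples(index=False):
        pos0 = int(pos) - 1
        if chrom in reference:
            expect = reference[chrom][pos0 : pos0 + len(ref)]
            if expect != ref:
                raise ValueError(
                    f"REF allele {ref!r} at {chrom}:{pos} disagrees with reference {expect!r}"
                )
        gene = None
        if chrom in sorted_genes:
            k = bisect_right(starts[chrom], pos0) - 1
            if k >= 0 and sorted_genes[chrom][k].end > pos0:
                gene = sorted_genes[chrom][k]
        if gene is None:
            effect = "intergenic"
        elif len(ref) == 1 == len(alt):
            effect = _classify_coding_snp(gene, reference, pos0, alt)
        else:
            effect = "frameshift" if abs(len(ref) - len(alt)) % 3 else "inframe_indel"
        calls.append(
            EffectCall(chrom, int(pos), ref, alt, gene.name if gene else None, effect)
        )
    return calls


def impact_counts(effects: list[EffectCall]) -> dict[str, int]:
    """Tally effect calls by impact bucket (low/moderate/high/modifier)."""
    out = {"low": 0, "moderate": 0, "high": 0, "modifier": 0}
    for e in effects:
        out[e.impact] += 1
    return out
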