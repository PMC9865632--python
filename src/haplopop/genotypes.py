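"""Haploid genotype matrix container and VCF input/output.

The central substrate for every population-genetic statistic in this
package is a sites x strains matrix of haploid calls: 0 for the reference
allele, 1 for the alternate allele, -1 for a missing genotype. Sites carry
their VCF metadata (chromosome, 1-based position, ref and alt allele
strings) in a pandas DataFrame so records can be filtered and written back
out without loss.

Strains are haploid; diploid-style GT fields occasionally emitted by
joint callers are collapsed (``0/0`` -> 0, ``1/1`` -> 1) and residual
heterozygous calls — which in a haploid genome signal collapsed duplicated
copies rather than true genotypes — are converted to missing with a
warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

MISSING = -1

SITE_COLUMNS = ("chrom", "pos", "ref", "alt")


class VCFParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


@dataclass
class GenotypeMatrix:
    """Sites x strains haploid call matrix with per-site VCF metadata.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom, pos, ref, alt``; ``pos`` is the
        1-based VCF coordinate. Positions must be strictly increasing
        within each chromosome.
    calls
        int8 array of shape ``(n_sites, n_strains)`` with values in
        {0, 1, MISSING}.
    strains
        Sample names, one per matrix column.
    """

    sites: pd.DataFrame
    calls: np.ndarray
    strains: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D sites x strains array")
        if len(self.sites) != self.calls.shape[0]:
            raise ValueError("sites and calls row counts differ")
        if len(self.strains) != self.calls.shape[1]:
            raise ValueError("strain names and calls column counts differ")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return self.calls.shape[0]

    @property
    def n_strains(self) -> int:
        return self.calls.shape[1]

    def is_snp(self) -> np.ndarray:
        """Boolean mask of sites where ref and alt are both single bases."""
        ref_len = self.sites["ref"].str.len().to_numpy()
        alt_len = self.sites["alt"].str.len().to_numpy()
        return (ref_len == 1) & (alt_len == 1)

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        """Return a new matrix restricted to the selected sites (order kept)."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            calls=self.calls[idx],
            strains=list(self.strains),
        )

    def take_strains(self, names) -> "GenotypeMatrix":
        pos = [self.strains.index(n) for n in names]
        return GenotypeMatrix(self.sites.copy(), self.calls[:, pos], list(names))

    def validate(self) -> None:
        """Check container invariants; raise ValueError on violation."""
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise ValueError("calls contain values outside {0, 1, missing}")
        for _, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions not strictly increasing within chromosome")
        if self.n_sites and (self.calls == MISSING).all(axis=1).any():
            raise ValueError("site with no non-missing call")


def _collapse_allele_indices(indices: tuple, chrom: str, pos: int) -> int:
    """Map a pysam allele-index tuple to a haploid call."""
    alleles = [a for a in indices if a is not None]
    if not alleles:
        return MISSING
    if len(set(alleles)) > 1:  # heterozygous in a haploid strain
        warnings.warn(
            f"heterozygous genotype at {chrom}:{pos} in haploid sample; set to missing",
            stacklevel=3,
        )
        return MISSING
    return int(alleles[0])


def read_vcf(path, multiallelic: str = "split") -> GenotypeMatrix:
    """Read a VCF into a haploid :class:`GenotypeMatrix`.

    Diploid homozygous genotypes are collapsed to haploid; heterozygous
    genotypes become missing (with a warning). Multiallelic records are
    split into one biallelic row per alternate allele when
    ``multiallelic="split"`` (calls to other alternates become missing),
    or rejected with ``multiallelic="error"``.
    """
    if multiallelic not in ("split", "error"):
        raise ValueError("multiallelic must be 'split' or 'error'")
    chroms, poss, refs, alts, rows = [], [], [], [], []
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VCFParseError(f"cannot open VCF {path}: {exc}") from exc
    with vf:
        strains = list(vf.header.samples)
        for i, rec in enumerate(vf, 1):
            if rec.alts is None:
                continue
            if len(rec.alts) > 1 and multiallelic == "error":
                raise VCFParseError(f"multiallelic record at line-record {i} ({rec.chrom}:{rec.pos})")
            base = np.empty(len(strains), dtype=np.int8)
            for j, sample in enumerate(rec.samples.values()):
                base[j] = _collapse_allele_indices(sample.allele_indices, rec.chrom, rec.pos)
            for alt_index, alt in enumerate(rec.alts, start=1):
                calls = base.copy()
                other = (calls != MISSING) & (calls != 0) & (calls != alt_index)
                calls[other] = MISSING
                calls[calls == alt_index] = 1
                chroms.append(rec.chrom)
                poss.append(rec.pos)
                refs.append(rec.ref)
                alts.append(alt)
                rows.append(calls)
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": np.asarray(poss, dtype=np.int64), "ref": refs, "alt": alts}
    )
    calls = np.vstack(rows) if rows else np.empty((0, len(strains)), dtype=np.int8)
    return GenotypeMatrix(sites=sites, calls=calls, strains=strains)


def write_vcf(m: GenotypeMatrix, path, contigs: dict | None = None) -> None:
    """Write a haploid VCF v4.2 ("." for missing calls).

    ``contigs`` maps chromosome name to length for the header; omitted
    chromosomes get a contig line without a length.
    """
    contigs = dict(contigs or {})
    seen = []
    for c in m.sites["chrom"]:
        if c not in seen:
            seen.append(c)
    for c in seen:
        contigs.setdefault(c, None)
    gt_map = {0: "0", 1: "1", MISSING: "."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haplopop\n")
        for name, length in contigs.items():
            if length is None:
                fh.write(f"##contig=<ID={name}>\n")
            else:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.strains)
            + "\n"
        )
        chrom_arr = m.sites["chrom"].to_numpy()
        pos_arr = m.sites["pos"].to_numpy()
        ref_arr = m.sites["ref"].to_numpy()
        alt_arr = m.sites["alt"].to_numpy()
        for i in range(m.n_sites):
            gts = "\t".join(gt_map[int(v)] for v in m.calls[i])
            fh.write(
                f"{chrom_arr[i]}\t{pos_arr[i]}\t.\t{ref_arr[i]}\t{alt_arr[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )
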