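"""Readers and writers for the flat-file formats the pipeline exchanges.

BED (genes), bedGraph (per-position depth), FASTA (reference and TE
library) and assorted TSV tables. Coordinates follow each format's own
convention: BED and bedGraph are 0-based half-open, VCF positions are
1-based (converted at the genotype layer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class GeneModel:
    """A single-CDS gene: BED interval plus strand.

    ``start``/``end`` are 0-based half-open; translation frame starts at
    ``start`` on '+' genes and at ``end`` on '-' genes.
    """

    chrom: str
    start: int
    end: int
    name: str
    strand: str = "+"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"gene {self.name}: end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_bed(path) -> list[GeneModel]:
    """Read BED4/BED6 gene intervals (name required, strand optional)."""
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: BED gene records need at least 4 columns")
            strand = parts[5] if len(parts) >= 6 else "+"
            genes.append(GeneModel(parts[0], int(parts[1]), int(parts[2]), parts[3], strand))
    return genes


def write_bed(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> ordered {name: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_bedgraph(path) -> dict[str, np.ndarray]:
    """bedGraph -> {chrom: per-position value array}.

    Intervals must be sorted, non-overlapping and cover each chromosome
    from 0 to its last interval end.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    out: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        vals = grp["value"].to_numpy(dtype=np.float64)
        if starts[0] != 0 or np.any(starts[1:] != ends[:-1]):
            raise ValueError(f"bedGraph intervals for {chrom} must tile the chromosome")
        arr = np.repeat(vals, ends - starts)
        out[str(chrom)] = arr
    return out


def write_bedgraph(tracks: dict[str, np.ndarray], path, bin_size: int = 1) -> None:
    """Write per-position arrays as run-length-merged bedGraph intervals.

    ``bin_size`` > 1 first coarsens the track by block means, emitting one
    interval per block (the last, possibly short, block keeps its true
    span).
    """
    with open(path, "w") as fh:
        for chrom, arr in tracks.items():
            arr = np.asarray(arr, dtype=float)
            if bin_size > 1:
                edges = np.arange(0, arr.size, bin_size)
                vals = np.array([arr[s : s + bin_size].mean() for s in edges])
                starts = edges
                ends = np.minimum(edges + bin_size, arr.size)
            else:
                # run-length encode consecutive equal values
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [arr.size]))
                vals = arr[starts]
            for s, e, v in zip(starts, ends, vals):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_te_coverage(path) -> pd.DataFrame:
    """TSV of per-strain per-TE mean depth: columns strain, te, mean_depth."""
    df = pd.read_csv(path, sep="\t", dtype={"strain": str, "te": str})
    required = {"strain", "te", "mean_depth"}
    if not required.issubset(df.columns):
        raise ValueError(f"TE coverage table needs columns {sorted(required)}")
    return df


def read_clade_map(path) -> dict[str, str]:
    """TSV with columns strain, clade -> {strain: clade}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"strain", "clade"}.issubset(df.columns):
        raise ValueError("clade map needs columns strain, clade")
    return dict(zip(df["strain"], df["clade"]))
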