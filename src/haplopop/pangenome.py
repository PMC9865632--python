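"""Gene presence/absence, mating-type locus typing and core/pan-genome
accounting.

A reference gene is called present in a strain when at least
``min_breadth`` of its bases are covered at depth >= ``min_depth`` (the
breadth rule is this package's operational stand-in for "missing in a
strain"; validated against planted deletions in synthetic data). Genes
absent from at least one strain are dispensable; the core genome is the
complement. Novel genes — discovered by assembling unmapped reads, a
step outside this package — enter through a ledger table and extend the
pan-genome:

    core = reference - dispensable        pan = reference + novel

Mating type of this heterothallic haploid yeast is diagnosed from the
presence of the two MATB-specific genes: both present -> MATB, both
absent -> MATA, discordant -> ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .depth_cnv import DepthTrack
from .io import GeneModel


@dataclass
class PresenceAbsenceMatrix:
    """genes x strains booleans, plus the coverage breadth behind each call."""

    presence: pd.DataFrame  # bool, index=gene, columns=strain
    breadth: pd.DataFrame | None = None

    def __post_init__(self):
        if self.presence.index.has_duplicates:
            raise ValueError("gene ids must be unique")

    @property
    def genes(self) -> list[str]:
        return list(self.presence.index)

    @property
    def strains(self) -> list[str]:
        return list(self.presence.columns)

    def dispensable_genes(self) -> list[str]:
        missing_somewhere = ~self.presence.all(axis=1)
        return list(self.presence.index[missing_somewhere])


@dataclass
class PanGenomeSummary:
    n_reference_genes: int
    n_dispensable: int
    n_novel: int

    @property
    def n_core(self) -> int:
        return self.n_reference_genes - self.n_dispensable

    @property
    def n_pan(self) -> int:
        return self.n_reference_genes + self.n_novel


def gene_presence(
    depth_tracks: dict[str, DepthTrack],
    genes: list[GeneModel],
    min_breadth: float = 0.2,
    min_depth: float = 1.0,
) -> PresenceAbsenceMatrix:
    """Call gene presence per strain from coverage breadth."""
    strains = list(depth_tracks)
    names = [g.name for g in genes]
    breadth = np.zeros((len(genes), len(strains)))
    for j, strain in enumerate(strains):
        track = depth_tracks[strain]
        for i, g in enumerate(genes):
            if g.chrom not in track.depths or g.end > track.depths[g.chrom].size:
                raise ValueError(f"gene {g.name} outside depth track of {strain}")
            seg = track.depths[g.chrom][g.start : g.end]
            breadth[i, j] = np.mean(seg >= min_depth)
    breadth_df = pd.DataFrame(breadth, index=names, columns=strains)
    return PresenceAbsenceMatrix(presence=breadth_df >= min_breadth, breadth=breadth_df)


def read_novel_gene_ledger(path, min_length: int = 500) -> pd.DataFrame:
    """TSV ledger of novel genes: columns gene, strain, length.

    Entries shorter than ``min_length`` (the assembly contig cutoff) are
    dropped; duplicate gene ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "strain": str})
    if not {"gene", "strain", "length"}.issubset(df.columns):
        raise ValueError("novel-gene ledger needs columns gene, strain, length")
    df = df[df["length"] >= min_length].reset_index(drop=True)
    if df["gene"].duplicated().any():
        raise ValueError("duplicate gene ids in novel-gene ledger")
    return df


def core_pan_accounting(
    pa: PresenceAbsenceMatrix, novel_ledger: pd.DataFrame | None = None
) -> PanGenomeSummary:
    """Core / dispensable / pan counts from a PA matrix and a novel-gene ledger."""
    n_novel = 0
    if novel_ledger is not None and len(novel_ledger):
        if novel_ledger["gene"].duplicated().any():
            raise ValueError("duplicate gene ids in novel-gene ledger")
        n_novel = len(novel_ledger)
    return PanGenomeSummary(
        n_reference_genes=len(pa.genes),
        n_dispensable=len(pa.dispensable_genes()),
        n_novel=n_novel,
    )


def mat_typing(pa: PresenceAbsenceMatrix, matb_gene_ids: tuple[str, str]) -> pd.Series:
    """Per-strain mating type from the two MATB marker genes."""
    g1, g2 = matb_gene_ids
    for g in (g1, g2):
        if g not in pa.presence.index:
            raise KeyError(f"MATB marker gene {g} not in presence/absence matrix")
    p1 = pa.presence.loc[g1]
    p2 = pa.presence.loc[g2]
    out = pd.Series("ambiguous", index=pa.presence.columns, name="mat_type")
    out[p1 & p2] = "MATB"
    out[~p1 & ~p2] = "MATA"
    return out
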