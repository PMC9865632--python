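"""Pairwise SNP distances, clonemate detection and SNP-alignment export.

Near-identical strains ("clonemates" — clonal propagation of one
lineage) show up as a low-distance mode in the distribution of pairwise
SNP differences, separated from the clade-level mode by an empty gap.
``distance_gap`` locates that gap; ``clonal_groups`` clusters strains by
single linkage below a threshold (default 725 differences, the lower
edge of the break observed in the 56-strain survey this package was
built around).

Distances are raw counts of differing pairwise-complete sites — no
rescaling for missing data — with the per-pair complete-site count
reported alongside so missingness bias stays visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    strains: list[str]
    counts: np.ndarray  # integer SNP-difference counts, symmetric, zero diagonal
    complete_sites: np.ndarray  # per-pair pairwise-complete site counts

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.complete_sites = np.asarray(self.complete_sites)
        n = len(self.strains)
        if self.counts.shape != (n, n) or self.complete_sites.shape != (n, n):
            raise ValueError("matrix shapes must be n_strains x n_strains")

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances as a flat vector."""
        iu = np.triu_indices(len(self.strains), k=1)
        return self.counts[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.strains, columns=self.strains)


@dataclass
class ClonalGroups:
    threshold: int
    groups: list[set[str]]  # disjoint strain sets of size >= 2

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_clonemate_strains(self) -> int:
        return sum(len(g) for g in self.groups)


def pairwise_distances(m: GenotypeMatrix) -> DistanceMatrix:
    """Count differing sites for every strain pair.

    Only sites where both strains have a call enter the comparison
    ("pairwise-complete"); d(i,j) = #{sites: calls differ}.
    """
    calls = m.calls
    present = (calls != MISSING).astype(np.float64)
    alt = (calls == 1).astype(np.float64)
    ref = (calls == 0).astype(np.float64)
    # differing complete sites = (alt_i & ref_j) + (ref_i & alt_j)
    diff = alt.T @ ref + ref.T @ alt
    complete = present.T @ present
    np.fill_diagonal(diff, 0)
    return DistanceMatrix(list(m.strains), diff.astype(np.int64), complete.astype(np.int64))


def distance_gap(d: DistanceMatrix, quantile: float = 0.5):
    """Largest empty interval between consecutive distinct pairwise values.

    Only values at or below the given quantile of the pairwise
    distribution are searched, so the clade-level mode does not mask the
    clonemate break. Returns ``(gap_low, gap_high)`` or ``None`` when
    fewer than two distinct values remain.
    """
    if len(d.strains) < 2:
        raise ValueError("need at least 2 strains")
    values = np.sort(d.condensed())
    cutoff = np.quantile(values, quantile)
    values = np.unique(values[values <= cutoff])
    if len(values) < 2:
        return None
    gaps = np.diff(values)
    k = int(np.argmax(gaps))
    return int(values[k]), int(values[k + 1])


def clonal_groups(d: DistanceMatrix, threshold: int = 725) -> ClonalGroups:
    """Single-linkage clusters of strains connected by sub-threshold edges.

    An edge joins strains with fewer than ``threshold`` differences;
    connected components of size >= 2 are reported as clonal groups.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = len(d.strains)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    adj = d.counts < threshold
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                parent[find(i)] = find(j)
    comps: dict[int, set[str]] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(d.strains[i])
    groups = sorted((g for g in comps.values() if len(g) >= 2), key=lambda g: sorted(g)[0])
    return ClonalGroups(threshold=threshold, groups=groups)


def snp_alignment_fasta(m: GenotypeMatrix) -> dict[str, str]:
    """Concatenate SNP alleles into one equal-length sequence per strain.

    Position k of each sequence carries the REF base for call 0, the ALT
    base for call 1, and ``N`` for missing — the usual input for external
    tree builders. Non-SNP records are rejected.
    """
    if not bool(m.is_snp().all()):
        raise ValueError("alignment export requires a SNP-only matrix")
    order = m.sites.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    ref = m.sites["ref"].to_numpy()[order]
    alt = m.sites["alt"].to_numpy()[order]
    calls = m.calls[order]
    out = {}
    for j, strain in enumerate(m.strains):
        col = calls[:, j]
        bases = np.where(col == 0, ref, np.where(col == 1, alt, "N"))
        out[strain] = "".join(bases)
    return out
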