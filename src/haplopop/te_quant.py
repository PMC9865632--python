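"""Transposable-element abundance from coverage over a TE library.

Reads mapped to a set of reference TE sequences give a mean depth per
element; dividing by the strain's genome-wide mean depth yields a
copy-number estimate (fractional values are meaningful — degenerate or
partial copies, solo LTRs of a full element). The genome fraction
attributed to TEs is ``sum(length_t * CN_t) / genome_length``.

Multi-mapping ambiguity between near-identical elements is a property of
the upstream alignment and is taken as given here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

TE_CLASSES = ("LTR-retrotransposon", "solo-LTR", "LINE", "DNA-transposon")


@dataclass(frozen=True)
class TELibrary:
    """TE name -> (sequence length in bp, class label)."""

    entries: dict[str, tuple[int, str]]

    def __post_init__(self):
        for name, (length, klass) in self.entries.items():
            if length <= 0:
                raise ValueError(f"TE {name}: length must be positive")
            if klass not in TE_CLASSES:
                raise ValueError(f"TE {name}: unknown class {klass!r}")

    def length(self, name: str) -> int:
        return self.entries[name][0]

    @classmethod
    def from_sequences(cls, seqs: dict[str, str], classes: dict[str, str] | None = None):
        classes = classes or {}
        return cls({n: (len(s), classes.get(n, "LTR-retrotransposon")) for n, s in seqs.items()})


@dataclass
class TEAbundance:
    """Per-strain TE quantification."""

    strain: str
    table: pd.DataFrame  # index: te; columns: mean_depth, copy_number, attributed_bp
    genome_fraction_pct: float = field(default=float("nan"))


def te_copy_number(te_mean_depths: dict[str, float], genome_mean_depth: float) -> dict[str, float]:
    """CN(t) = mean depth over element t / genome-wide mean depth."""
    if genome_mean_depth <= 0:
        raise ValueError("genome mean depth must be positive")
    out = {}
    for te, depth in te_mean_depths.items():
        if depth < 0:
            raise ValueError(f"negative depth for TE {te}")
        out[te] = depth / genome_mean_depth
    return out


def te_genome_fraction(
    copy_numbers: dict[str, float], library: TELibrary, genome_length: int
) -> float:
    """Percent of the genome attributed to TE copies.

    Can mathematically exceed 100% when copies far outnumber the
    reference; callers flag such strains downstream.
    """
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    attributed = sum(library.length(te) * cn for te, cn in copy_numbers.items())
    return 100.0 * attributed / genome_length


def te_abundance(
    strain: str,
    te_mean_depths: dict[str, float],
    genome_mean_depth: float,
    library: TELibrary,
    genome_length: int,
) -> TEAbundance:
    """Full per-strain quantification: CN, attributed bp, genome fraction."""
    unknown = set(te_mean_depths) - set(library.entries)
    if unknown:
        raise KeyError(f"TEs not in library: {sorted(unknown)}")
    cn = te_copy_number(te_mean_depths, genome_mean_depth)
    table = pd.DataFrame(
        {
            "mean_depth": pd.Series(te_mean_depths, dtype=float),
            "copy_number": pd.Series(cn, dtype=float),
            "attributed_bp": pd.Series(
                {te: library.length(te) * c for te, c in cn.items()}, dtype=float
            ),
        }
    )
    frac = te_genome_fraction(cn, library, genome_length)
    return TEAbundance(strain=strain, table=table, genome_fraction_pct=frac)


def te_summary(abundances: list[TEAbundance], outlier_fraction_pct: float = 2.0):
    """Rank elements and strains by abundance.

    Returns ``(per_element, per_strain)`` DataFrames; ``per_strain`` has a
    boolean ``flagged`` column for strains whose TE genome fraction
    exceeds ``outlier_fraction_pct``.
    """
    if not abundances:
        return (
            pd.DataFrame(columns=["total_attributed_bp", "total_copies"]),
            pd.DataFrame(columns=["genome_fraction_pct", "flagged"]),
        )
    per_strain = pd.DataFrame(
        {
            "genome_fraction_pct": {a.strain: a.genome_fraction_pct for a in abundances},
        }
    ).sort_values("genome_fraction_pct", ascending=False)
    per_strain["flagged"] = per_strain["genome_fraction_pct"] > outlier_fraction_pct

    acc: dict[str, dict[str, float]] = {}
    for a in abundances:
        for te, row in a.table.iterrows():
            d = acc.setdefault(te, {"total_attributed_bp": 0.0, "total_copies": 0.0})
            d["total_attributed_bp"] += row["attributed_bp"]
            d["total_copies"] += row["copy_number"]
    per_element = pd.DataFrame(acc).T.sort_values("total_attributed_bp", ascending=False)
    return per_element, per_strain
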