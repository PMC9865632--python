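"""Windowed population-genetic statistics for haploid genotype matrices.

Implements the classic per-site estimators, accumulated in fixed physical
windows (default 10 kb) and divided by the window's physical length, so
monomorphic positions dilute diversity as they should:

* pi (nucleotide diversity): per site the fraction of non-missing strain
  pairs that differ, ``a(n-a) / C(n,2)`` for alt count ``a`` among ``n``
  called strains.
* Dxy (absolute divergence): per site ``pA(1-pB) + pB(1-pA)`` with allele
  frequencies taken over non-missing calls in each population.
* Fst: the Hudson estimator as a ratio of window sums,
  ``1 - sum(Hw) / sum(Hb)``, where per site
  ``Hw = [2 pA (1-pA) nA/(nA-1) + 2 pB (1-pB) nB/(nB-1)] / 2`` (the
  unbiased probability that two genomes drawn from the same population
  differ, averaged over the two populations) and
  ``Hb = pA (1-pB) + pB (1-pA)``; zero for identical frequencies and
  one for a fixed difference.
* LD decay: squared Pearson correlation of the haploid 0/1 vectors for
  every same-chromosome SNP pair up to ``max_dist``, averaged per exact
  base-pair distance; the half-decay distance is the smallest distance at
  which the per-distance mean falls to half the maximum of those means.

Missing data are handled pairwise/complete-case per site; sites left with
fewer than two calls contribute zero and are counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


def _chrom_lengths(m: GenotypeMatrix, chrom_lengths: dict[str, int] | None) -> dict[str, int]:
    if chrom_lengths is not None:
        return dict(chrom_lengths)
    return {c: int(g["pos"].max()) for c, g in m.sites.groupby("chrom", sort=False)}


def _windows(length: int, window: int):
    starts = np.arange(0, length, window)
    ends = np.minimum(starts + window, length)
    return starts, ends


def _site_pi(calls: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-site pairwise-difference fraction and the count of sites with <2 calls."""
    called = calls != MISSING
    n = called.sum(axis=1)
    a = (calls == 1).sum(axis=1)
    pairs = n * (n - 1) / 2
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(pairs > 0, a * (n - a) / np.where(pairs > 0, pairs, 1), 0.0)
    return pi, int((n < 2).sum())


def _window_table(m, per_site, window, chrom_lengths, value_name):
    lengths = _chrom_lengths(m, chrom_lengths)
    rows = []
    chrom_arr = m.sites["chrom"].to_numpy()
    pos0 = m.sites["pos"].to_numpy() - 1
    poly = per_site != 0
    for chrom, length in lengths.items():
        in_chrom = chrom_arr == chrom
        starts, ends = _windows(length, window)
        idx = np.searchsorted(starts, pos0[in_chrom], side="right") - 1
        sums = np.bincount(idx, weights=per_site[in_chrom], minlength=len(starts))
        nvar = np.bincount(idx, weights=poly[in_chrom].astype(float), minlength=len(starts))
        for k in range(len(starts)):
            span = ends[k] - starts[k]
            rows.append((chrom, int(starts[k]), int(ends[k]), sums[k] / span, int(nvar[k])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", value_name, "n_variant_sites"])


def nucleotide_diversity(
    m: GenotypeMatrix, window: int = 10_000, chrom_lengths: dict[str, int] | None = None
):
    """Windowed and genome-wide pi.

    Returns ``(window_table, genome_pi, n_low_call_sites)`` where
    ``genome_pi`` is the length-weighted mean over windows (equivalently
    the per-site sum over the whole genome length).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    per_site, n_low = _site_pi(m.calls)
    table = _window_table(m, per_site, window, chrom_lengths, "pi")
    total_len = sum(_chrom_lengths(m, chrom_lengths).values())
    genome_pi = float(per_site.sum() / total_len) if total_len else float("nan")
    return table, genome_pi, n_low


def _pop_freqs(calls: np.ndarray, cols: np.ndarray):
    sub = calls[:, cols]
    called = sub != MISSING
    n = called.sum(axis=1)
    a = (sub == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, a / np.maximum(n, 1), np.nan)
    return p, n


def _strain_cols(m: GenotypeMatrix, pop) -> np.ndarray:
    return np.asarray([m.strains.index(s) for s in pop], dtype=int)


def dxy(
    m: GenotypeMatrix,
    pop_a,
    pop_b,
    window: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
):
    """Windowed and genome-wide absolute divergence between two populations.

    Sites where either population has no call are skipped (and counted in
    the third return value).
    """
    if set(pop_a) & set(pop_b):
        raise ValueError("populations must be disjoint")
    if not pop_a or not pop_b:
        raise ValueError("both populations need at least one strain")
    pa, na = _pop_freqs(m.calls, _strain_cols(m, pop_a))
    pb, nb = _pop_freqs(m.calls, _strain_cols(m, pop_b))
    valid = (na > 0) & (nb > 0)
    d = np.where(valid, pa * (1 - pb) + pb * (1 - pa), 0.0)
    table = _window_table(m, d, window, chrom_lengths, "dxy")
    total_len = sum(_chrom_lengths(m, chrom_lengths).values())
    genome_dxy = float(np.nansum(d) / total_len) if total_len else float("nan")
    return table, genome_dxy, int((~valid).sum())


def fst(
    m: GenotypeMatrix,
    pop_a,
    pop_b,
    window: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
):
    """Hudson Fst per window (ratio of sums) and genome-wide.

    Windows with zero between-population heterozygosity are undefined and
    reported as NaN. Each population must contain at least two strains.
    """
    if len(pop_a) < 2 or len(pop_b) < 2:
        raise ValueError("each population needs at least 2 strains")
    if set(pop_a) & set(pop_b):
        raise ValueError("populations must be disjoint")
    pa, na = _pop_freqs(m.calls, _strain_cols(m, pop_a))
    pb, nb = _pop_freqs(m.calls, _strain_cols(m, pop_b))
    valid = (na > 1) & (nb > 1)
    # within: average over pops of the unbiased probability that two
    # haploid genomes from the same pop differ, 2p(1-p) * n/(n-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        hw = (
            pa * (1 - pa) * na / np.maximum(na - 1, 1)
            + pb * (1 - pb) * nb / np.maximum(nb - 1, 1)
        )
        hb = pa * (1 - pb) + pb * (1 - pa)
    hw = np.where(valid, hw, 0.0)
    hb = np.where(valid, hb, 0.0)

    tw = _window_table(m, hw, window, chrom_lengths, "hw_sum")
    tb = _window_table(m, hb, window, chrom_lengths, "hb_sum")
    table = tw.drop(columns="n_variant_sites").merge(
        tb.drop(columns="n_variant_sites"), on=["chrom", "start", "end"]
    )
    # window sums are per-bp densities times span; undo the span division
    span = table["end"] - table["start"]
    hw_sum = table["hw_sum"] * span
    hb_sum = table["hb_sum"] * span
    with np.errstate(invalid="ignore", divide="ignore"):
        table["fst"] = np.where(hb_sum > 0, 1.0 - hw_sum / hb_sum, np.nan)
    genome = float(1.0 - hw.sum() / hb.sum()) if hb.sum() > 0 else float("nan")
    return table[["chrom", "start", "end", "fst"]], genome


@dataclass
class LDDecay:
    """Mean r-squared per exact pair distance, and the half-decay distance."""

    table: pd.DataFrame  # columns: distance, mean_r2, n_pairs
    ld_half: int | None

    @property
    def max_mean_r2(self) -> float:
        return float(self.table["mean_r2"].max()) if len(self.table) else float("nan")


def ld_decay(m: GenotypeMatrix, max_dist: int = 10_000) -> LDDecay:
    """LD decay from all same-chromosome SNP pairs within ``max_dist``.

    r-squared is the squared Pearson correlation of the two haploid 0/1
    vectors over pairwise-complete strains; pairs where either vector is
    constant are skipped. Means are grouped by exact distance.
    """
    calls = m.calls.astype(float)
    calls[m.calls == MISSING] = np.nan
    dists: list[np.ndarray] = []
    r2s: list[np.ndarray] = []
    chrom_arr = m.sites["chrom"].to_numpy()
    pos_arr = m.sites["pos"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        rows = np.flatnonzero(chrom_arr == chrom)
        pos = pos_arr[rows]
        sub = calls[rows]
        valid = ~np.isnan(sub)
        j_hi = np.searchsorted(pos, pos + max_dist, side="right")
        for i in range(len(rows) - 1):
            j = np.arange(i + 1, j_hi[i])
            j = j[pos[j] > pos[i]]
            if j.size == 0:
                continue
            x = sub[i]
            y = sub[j]
            both = valid[i] & valid[j]
            n = both.sum(axis=1)
            xs = np.where(both, x, 0.0)
            ys = np.where(both, y, 0.0)
            sx = xs.sum(axis=1)
            sy = ys.sum(axis=1)
            sxx = (xs * xs).sum(axis=1)
            syy = (ys * ys).sum(axis=1)
            sxy = (xs * ys).sum(axis=1)
            var_x = n * sxx - sx * sx
            var_y = n * syy - sy * sy
            ok = (n >= 2) & (var_x > 0) & (var_y > 0)
            if not ok.any():
                continue
            cov = (n * sxy - sx * sy)[ok]
            r2 = cov * cov / (var_x[ok] * var_y[ok])
            dists.append(pos[j[ok]] - pos[i])
            r2s.append(r2)
    if not dists:
        return LDDecay(pd.DataFrame(columns=["distance", "mean_r2", "n_pairs"]), None)
    dist = np.concatenate(dists)
    r2 = np.concatenate(r2s)
    grouped = pd.DataFrame({"distance": dist, "r2": r2}).groupby("distance", sort=True)
    table = grouped.agg(mean_r2=("r2", "mean"), n_pairs=("r2", "size")).reset_index()
    half = table["mean_r2"].max() / 2
    below = table[table["mean_r2"] <= half]
    ld_half = int(below["distance"].iloc[0]) if len(below) else None
    return LDDecay(table, ld_half)


def maf_spectrum(m: GenotypeMatrix, thresholds=(0.05,)) -> pd.Series:
    """Fraction of variants with minor-allele frequency <= each threshold."""
    if m.n_sites == 0:
        return pd.Series(dtype=float)
    called = m.calls != MISSING
    n = called.sum(axis=1)
    a = (m.calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, a / np.maximum(n, 1), np.nan)
    maf = np.minimum(p, 1 - p)
    return pd.Series(
        {t: float(np.mean(maf <= t)) for t in thresholds}, name="fraction"
    )


def site_density_per_kb(n_sites: int, span_bp: int) -> float:
    """Variant sites per kilobase over a physical span (e.g. divergence of
    a duplicated region from its heterozygous-position count)."""
    if span_bp <= 0:
        raise ValueError("span must be positive")
    return 1000.0 * n_sites / span_bp
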