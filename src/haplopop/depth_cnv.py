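"""Read-depth copy-number analysis: normalization, smoothing, and
segmental duplication / deletion calling.

The pipeline follows the standard depth-ratio recipe for haploid
genomes: divide each position's depth by the genome-wide mean, take
log2, then smooth with a shifted-average (moving window, default
window 5000 bp at step 500 bp). A single-copy region sits at log2 = 0, a
full clonal duplication at +1; sub-clonal events (a duplication present
in only a fraction of the sequenced cells) sit in between — a ratio of
1.4 corresponds to a copy-2 event in ~40% of cells.

Segment calling first self-calibrates a copy-1 baseline as the
genome-wide median of the smoothed values — dividing by the genome-wide
mean alone leaves the baseline below zero whenever duplications inflate
the mean, and on a short test chromosome the shift is substantial. It
then thresholds the baseline-relative ratio (default 1.25, low enough to
retain sub-clonal events at ratio 1.4 while clearing Poisson noise at
typical depth), merges qualifying windows into runs, and refines each
run's boundaries by linear interpolation of the smoothed profile at the
level halfway between baseline and the run's plateau. For an ideal step
convolved with a boxcar, that half-amplitude crossing falls exactly on
the true edge, so planted boundaries are recovered to sub-window
precision. The calibration assumes copy-1 sequence occupies the majority
of windows; a genome more than half duplicated would defeat it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import GeneModel

LOG2_FLOOR = -5.0


@dataclass
class DepthTrack:
    """Per-position sequencing depth for one strain, one array per chromosome."""

    depths: dict[str, np.ndarray]

    def __post_init__(self):
        self.depths = {c: np.asarray(a, dtype=np.float64) for c, a in self.depths.items()}
        for c, a in self.depths.items():
            if (a < 0).any():
                raise ValueError(f"negative depth on {c}")

    @property
    def mean_depth(self) -> float:
        total = sum(a.sum() for a in self.depths.values())
        n = sum(a.size for a in self.depths.values())
        return total / n if n else float("nan")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: a.size for c, a in self.depths.items()}


@dataclass
class SmoothedTrack:
    """Moving-window means of the per-position log2 depth ratio.

    Windows lie fully inside the chromosome:
    ``floor((L - window) / step) + 1`` windows per chromosome of length
    ``L >= window``, none otherwise.
    """

    window: int
    step: int
    starts: dict[str, np.ndarray]
    values: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]
    short_chroms: list[str] = field(default_factory=list)

    def midpoints(self, chrom: str) -> np.ndarray:
        return self.starts[chrom] + self.window / 2


@dataclass
class DuplicationSegment:
    chrom: str
    start: int  # 0-based half-open
    end: int
    log2_ratio: float  # baseline-relative plateau (median in-run smoothed value)
    kind: str = "duplication"
    genes: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def copy_number(self) -> float:
        """Copy-number estimate against the haploid baseline of 1."""
        return float(2.0 ** self.log2_ratio)

    @property
    def copy_number_rounded(self) -> int:
        return round(self.copy_number)


def normalize_log2(track: DepthTrack, floor: float = LOG2_FLOOR):
    """Per-position ``log2(depth / genome-wide mean)``.

    Zero-depth positions are floored at ``floor`` and counted. Raises on
    an all-zero track.
    """
    mean = track.mean_depth
    if not mean > 0:
        raise ValueError("genome-wide mean depth must be positive")
    out: dict[str, np.ndarray] = {}
    n_floored = 0
    for chrom, depth in track.depths.items():
        with np.errstate(divide="ignore"):
            val = np.log2(depth / mean)
        zero = depth == 0
        n_floored += int(zero.sum())
        val[zero] = floor
        out[chrom] = val
    return out, n_floored


def smooth(
    log2_tracks: dict[str, np.ndarray], window: int = 5000, step: int = 500
) -> SmoothedTrack:
    """Shifted-average smoothing of per-position values."""
    if not (window >= step > 0):
        raise ValueError("need window >= step > 0")
    starts: dict[str, np.ndarray] = {}
    values: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    short = []
    for chrom, arr in log2_tracks.items():
        arr = np.asarray(arr, dtype=np.float64)
        lengths[chrom] = arr.size
        if arr.size < window:
            starts[chrom] = np.empty(0, dtype=np.int64)
            values[chrom] = np.empty(0)
            short.append(chrom)
            continue
        s = np.arange(0, arr.size - window + 1, step, dtype=np.int64)
        csum = np.concatenate(([0.0], np.cumsum(arr)))
        values[chrom] = (csum[s + window] - csum[s]) / window
        starts[chrom] = s
    return SmoothedTrack(window, step, starts, values, lengths, short)


def _runs(qualify: np.ndarray, merge_gap: int):
    """Maximal runs of True indices, bridging gaps of <= merge_gap False."""
    idx = np.flatnonzero(qualify)
    if idx.size == 0:
        return []
    runs = []
    lo = hi = idx[0]
    for k in idx[1:]:
        if k - hi <= merge_gap + 1:
            hi = k
        else:
            runs.append((lo, hi))
            lo = hi = k
    runs.append((lo, hi))
    return runs


def _half_crossing(mids, v, half, sign, i0, i1, reach, chrom_len, window):
    """Interpolated half-plateau crossings flanking run [i0, i1]."""
    lo = max(0, i0 - reach)
    hi = min(len(v) - 1, i1 + reach)
    above = sign * v >= sign * half

    # left edge: first above-half index at/after lo
    k = i0
    while k > lo and above[k - 1]:
        k -= 1
    if k == 0:
        left = 0.0
    elif above[k - 1] or v[k] == v[k - 1]:
        left = float(mids[k] - window / 2)  # no clean crossing; window start
    else:
        frac = (half - v[k - 1]) / (v[k] - v[k - 1])
        left = float(mids[k - 1] + frac * (mids[k] - mids[k - 1]))

    k = i1
    while k < hi and above[k + 1]:
        k += 1
    if k == len(v) - 1:
        right = float(chrom_len)
    elif above[k + 1] or v[k] == v[k + 1]:
        right = float(mids[k] + window / 2)
    else:
        frac = (v[k] - half) / (v[k] - v[k + 1])
        right = float(mids[k] + frac * (mids[k + 1] - mids[k]))
    return left, right


def genome_baseline(s: SmoothedTrack) -> float:
    """Copy-1 baseline: the genome-wide median smoothed log2 value."""
    allv = np.concatenate([v for v in s.values.values() if v.size]) if s.values else np.empty(0)
    if allv.size == 0:
        raise ValueError("smoothed track has no windows")
    return float(np.median(allv))


def _call_segments(
    s: SmoothedTrack, log2_threshold: float, sign: int, min_len: int, merge_gap: int, kind: str
) -> list[DuplicationSegment]:
    segments = []
    reach = math.ceil(s.window / s.step)
    baseline = genome_baseline(s)
    for chrom, v in s.values.items():
        if v.size == 0:
            continue
        mids = s.midpoints(chrom)
        qualify = sign * (v - baseline) >= sign * log2_threshold
        for i0, i1 in _runs(qualify, merge_gap):
            run_vals = v[i0 : i1 + 1]
            plateau = float(np.median(run_vals[qualify[i0 : i1 + 1]]))
            left, right = _half_crossing(
                mids, v, (plateau + baseline) / 2, sign, i0, i1, reach,
                s.chrom_lengths[chrom], s.window,
            )
            start = max(0, int(round(left)))
            end = min(s.chrom_lengths[chrom], int(round(right)))
            if end - start < min_len:
                continue
            segments.append(
                DuplicationSegment(chrom, start, end, plateau - baseline, kind=kind)
            )
    return segments


def call_duplications(
    s: SmoothedTrack, min_ratio: float = 1.25, min_len: int = 10_000, merge_gap: int = 1
) -> list[DuplicationSegment]:
    """Segments whose smoothed depth ratio is elevated above ``min_ratio``.

    Qualifying windows (``2**value >= min_ratio``) are merged into
    maximal runs, bridging up to ``merge_gap`` sub-threshold windows;
    boundaries are refined at half the run's plateau and segments shorter
    than ``min_len`` are dropped.
    """
    if min_ratio <= 1 or min_len <= 0:
        raise ValueError("min_ratio must exceed 1 and min_len be positive")
    return _call_segments(s, math.log2(min_ratio), +1, min_len, merge_gap, "duplication")


def call_deletions(
    s: SmoothedTrack, max_ratio: float = 0.75, min_len: int = 10_000, merge_gap: int = 1
) -> list[DuplicationSegment]:
    """Depressed-depth segments (``2**value <= max_ratio``), symmetric to
    :func:`call_duplications`."""
    if not 0 < max_ratio < 1 or min_len <= 0:
        raise ValueError("max_ratio must lie in (0, 1) and min_len be positive")
    return _call_segments(s, math.log2(max_ratio), -1, min_len, merge_gap, "deletion")


def genes_in_segments(
    segments: list[DuplicationSegment], genes: list[GeneModel]
) -> tuple[list[int], int]:
    """Count genes overlapping each segment by >= 1 bp.

    Fills each segment's ``genes`` list in place and returns the
    per-segment counts plus the de-duplicated total across segments.
    """
    seen: set[str] = set()
    counts = []
    for seg in segments:
        hits = [
            g.name
            for g in genes
            if g.chrom == seg.chrom and g.start < seg.end and g.end > seg.start
        ]
        seg.genes = hits
        counts.append(len(hits))
        seen.update(hits)
    return counts, len(seen)
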