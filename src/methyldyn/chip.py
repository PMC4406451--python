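"""ChIP-seq read-density enrichment with random-window z-score
normalization.

The enrichment of a histone mark in a region is its read density
normalized against the mean and standard deviation of densities in a
large panel (default 100,000) of 100-bp windows drawn uniformly at random
across the genome, so scores are comparable across marks and libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dmr import AnalysisConfig, ConDMR


@dataclass
class ChipTrack:
    """Read intervals per chromosome; intervals are (n, 2) half-open
    arrays sorted by start."""

    intervals: dict[str, np.ndarray]
    _starts: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _ends: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        norm = {}
        for chrom, iv in self.intervals.items():
            iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
            iv = iv[np.argsort(iv[:, 0], kind="stable")]
            norm[chrom] = iv
            self._starts[chrom] = iv[:, 0]
            self._ends[chrom] = np.sort(iv[:, 1])
        self.intervals = norm

    @property
    def total_reads(self) -> int:
        return sum(len(iv) for iv in self.intervals.values())

    def overlap_counts(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Number of reads overlapping each half-open query interval.

        A read [a, b) overlaps [s, e) iff a < e and b > s; counted as
        (#starts < e) - (#ends <= s), exact for any interval set.
        """
        if chrom not in self.intervals:
            return np.zeros(len(starts), dtype=np.int64)
        n_start_lt = np.searchsorted(self._starts[chrom], ends, side="left")
        n_end_le = np.searchsorted(self._ends[chrom], starts, side="right")
        return n_start_lt - n_end_le


@dataclass
class Baseline:
    n: int
    window_bp: int
    mean: float
    sd: float
    seed: Optional[int]
    rpm: bool = False


def interval_density(
    track: ChipTrack, chrom: str, start: int, end: int, rpm: bool = False
) -> float:
    """Overlapping-read count per bp; ``rpm=True`` scales to reads per
    million mapped reads."""
    if end <= start:
        raise ValueError("zero-width interval")
    count = int(track.overlap_counts(chrom, np.array([start]), np.array([end]))[0])
    d = count / (end - start)
    if rpm:
        total = track.total_reads
        d = d * 1e6 / total if total else 0.0
    return d


def random_baseline(
    track: ChipTrack,
    genome: dict[str, int],
    config: Optional[AnalysisConfig] = None,
    window_bp: int = 100,
    rpm: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> Baseline:
    """Density mean/sd over n random windows, positions uniform over the
    concatenated genome. Windows may overlap each other."""
    config = config or AnalysisConfig()
    if rng is None:
        if config.rng_seed is None:
            raise ValueError("random_baseline needs config.rng_seed or an rng")
        rng = np.random.default_rng(config.rng_seed)
    chroms = list(genome)
    lengths = np.array([max(genome[c] - window_bp, 1) for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    n = config.n_random_windows
    which = rng.choice(len(chroms), size=n, p=probs)
    densities = np.empty(n, dtype=float)
    scale = 1e6 / track.total_reads if (rpm and track.total_reads) else 1.0
    for i, chrom in enumerate(chroms):
        sel = which == i
        m = int(sel.sum())
        if m == 0:
            continue
        starts = rng.integers(0, max(genome[chrom] - window_bp, 1), size=m)
        counts = track.overlap_counts(chrom, starts, starts + window_bp)
        densities[sel] = counts / window_bp * scale
    return Baseline(
        n=n, window_bp=window_bp, mean=float(densities.mean()),
        sd=float(densities.std(ddof=0)), seed=config.rng_seed, rpm=rpm,
    )


def zscore(density: float, baseline: Baseline) -> float:
    """(density - baseline mean) / baseline sd; NaN when sd is 0."""
    if baseline.sd == 0:
        return float("nan")
    return (density - baseline.mean) / baseline.sd


def region_zscores(
    regions: Sequence, track: ChipTrack, baseline: Baseline
) -> np.ndarray:
    """z-score of the read density of each region (DMR or ConDMR)."""
    out = np.empty(len(regions))
    for i, r in enumerate(regions):
        d = interval_density(track, r.chrom, r.start, r.end, rpm=baseline.rpm)
        out[i] = zscore(d, baseline)
    return out


def profile_around(
    regions: Sequence[ConDMR],
    track: ChipTrack,
    baseline: Baseline,
    flank_bp: int = 2000,
    bins: int = 40,
) -> np.ndarray:
    """Mean z-score per bin across regions extended by ``flank_bp`` on
    each side, oriented 5'->3' along each region's gene.

    Regions without an orientation are skipped.
    """
    acc = np.zeros(bins)
    cnt = np.zeros(bins)
    for r in regions:
        if r.orientation not in ("+", "-"):
            continue
        lo, hi = r.start - flank_bp, r.end + flank_bp
        edges = np.linspace(lo, hi, bins + 1)
        starts = np.floor(edges[:-1]).astype(np.int64)
        ends = np.ceil(edges[1:]).astype(np.int64)
        ends = np.maximum(ends, starts + 1)
        counts = track.overlap_counts(r.chrom, starts, ends)
        dens = counts / (ends - starts)
        if baseline.rpm and track.total_reads:
            dens = dens * 1e6 / track.total_reads
        z = (dens - baseline.mean) / baseline.sd if baseline.sd else np.full(bins, np.nan)
        if r.orientation == "-":
            z = z[::-1]
        ok = np.isfinite(z)
        acc[ok] += z[ok]
        cnt[ok] += 1
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
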