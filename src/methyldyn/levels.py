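"""Weighted methylation levels over intervals, features, metagenes and
chromosome-scale tracks.

The weighted level of a region is the total number of methylated read
calls divided by the total number of read calls over all cytosines of one
context in the region (both strands pooled) — not the mean of per-site
ratios. A region with zero calls has an *undefined* level (NaN), never a
level of 0 by fiat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import CONTEXT_CODE, FeatureAnnotation, MethylomeSample


@dataclass(frozen=True)
class LevelResult:
    chrom: str
    start: int
    end: int
    context: str
    meth_obs: int
    total_obs: int

    @property
    def level(self) -> float:
        return self.meth_obs / self.total_obs if self.total_obs > 0 else float("nan")

    @property
    def defined(self) -> bool:
        return self.total_obs > 0


@dataclass
class MetageneProfile:
    context: str
    upstream: np.ndarray  # per-bin level, 5' flank
    body: np.ndarray
    downstream: np.ndarray
    n_features: int
    flank_bp: int

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.upstream, self.body, self.downstream])


def _slice(sample: MethylomeSample, chrom: str, start: int, end: int, context: str):
    """(meth, total, pos) arrays for one context within [start, end)."""
    arr = sample.chrom_arrays(chrom)
    pos = arr["pos"]
    lo, hi = np.searchsorted(pos, [start, end])
    mask = arr["context"][lo:hi] == CONTEXT_CODE[context]
    return arr["meth"][lo:hi][mask], arr["total"][lo:hi][mask], pos[lo:hi][mask]


def weighted_level(
    sample: MethylomeSample, chrom: str, start: int, end: int, context: str
) -> LevelResult:
    """Weighted methylation level of ``context`` over [start, end)."""
    if context not in CONTEXT_CODE:
        raise ValueError(f"unknown context {context!r}")
    meth, total, _ = _slice(sample, chrom, start, end, context)
    return LevelResult(chrom, start, end, context, int(meth.sum()), int(total.sum()))


def feature_levels(
    samples: Sequence[MethylomeSample],
    features: Iterable[FeatureAnnotation],
    context: str,
) -> pd.DataFrame:
    """feature x sample table of weighted levels (NaN where uncovered)."""
    features = list(features)
    ids = [f.feature_id for f in features]
    cols = {}
    for i, s in enumerate(samples):
        name = s.sample_id or f"sample{i}"
        cols[name] = [
            weighted_level(s, f.chrom, f.start, f.end, context).level
            for f in features
        ]
    return pd.DataFrame(cols, index=pd.Index(ids, name="feature_id"))


def metagene_profile(
    sample: MethylomeSample,
    features: Iterable[FeatureAnnotation],
    context: str,
    body_bins: int = 20,
    flank_bp: int = 2000,
    flank_bins: int = 20,
    mode: str = "pooled",
) -> MetageneProfile:
    """Average methylation over aligned gene bodies plus flanks.

    Every feature is oriented 5'->3'; the body is length-scaled into
    ``body_bins`` bins, each flank of ``flank_bp`` bp into ``flank_bins``.
    ``mode="pooled"`` sums read calls over all features per bin (the
    weighted-level convention); ``mode="mean"`` averages per-feature bin
    levels instead, as a sensitivity check.
    """
    if mode not in ("pooled", "mean"):
        raise ValueError(f"unknown mode {mode!r}")
    nbins = 2 * flank_bins + body_bins
    meth_acc = np.zeros(nbins)
    total_acc = np.zeros(nbins)
    mean_acc = np.zeros(nbins)
    mean_n = np.zeros(nbins)
    n_feat = 0
    for f in features:
        n_feat += 1
        lo = f.start - flank_bp
        hi = f.end + flank_bp
        meth, total, pos = _slice(sample, f.chrom, max(lo, 0), hi, context)
        if len(pos) == 0:
            continue
        # bin index in gene orientation: [0, flank_bins) upstream,
        # [flank_bins, flank_bins+body_bins) body, rest downstream
        binned = np.empty(len(pos), dtype=np.int64)
        if f.strand == "+":
            rel_up = (pos - lo) / flank_bp
            rel_body = (pos - f.start) / f.length
            rel_dn = (pos - f.end) / flank_bp
        else:
            rel_up = (hi - 1 - pos) / flank_bp
            rel_body = (f.end - 1 - pos) / f.length
            rel_dn = (f.start - 1 - pos + flank_bp) / flank_bp
        in_body = (pos >= f.start) & (pos < f.end)
        if f.strand == "+":
            in_up = pos < f.start
            in_dn = pos >= f.end
        else:
            in_up = pos >= f.end
            in_dn = pos < f.start
        binned[in_up] = np.clip(
            (rel_up[in_up] * flank_bins).astype(np.int64), 0, flank_bins - 1
        )
        binned[in_body] = flank_bins + np.clip(
            (rel_body[in_body] * body_bins).astype(np.int64), 0, body_bins - 1
        )
        binned[in_dn] = flank_bins + body_bins + np.clip(
            (rel_dn[in_dn] * flank_bins).astype(np.int64), 0, flank_bins - 1
        )
        np.add.at(meth_acc, binned, meth)
        np.add.at(total_acc, binned, total)
        if mode == "mean":
            fm = np.bincount(binned, weights=meth, minlength=nbins)
            ft = np.bincount(binned, weights=total, minlength=nbins)
            ok = ft > 0
            mean_acc[ok] += fm[ok] / ft[ok]
            mean_n += ok
    if mode == "pooled":
        with np.errstate(invalid="ignore"):
            values = np.where(total_acc > 0, meth_acc / np.maximum(total_acc, 1), np.nan)
    else:
        with np.errstate(invalid="ignore"):
            values = np.where(mean_n > 0, mean_acc / np.maximum(mean_n, 1), np.nan)
    return MetageneProfile(
        context=context,
        upstream=values[:flank_bins],
        body=values[flank_bins:flank_bins + body_bins],
        downstream=values[flank_bins + body_bins:],
        n_features=n_feat,
        flank_bp=flank_bp,
    )


def chromosome_track(
    sample: MethylomeSample,
    context: str,
    chrom_sizes: dict[str, int],
    window_bp: int = 1_000_000,
    step_bp: Optional[int] = None,
) -> pd.DataFrame:
    """Sliding-window weighted levels along each chromosome.

    Returns a DataFrame chrom, start, end, meth_obs, total_obs, level.
    """
    step = step_bp if step_bp is not None else window_bp
    if step > window_bp:
        raise ValueError("step_bp must be <= window_bp")
    rows = []
    for chrom, size in chrom_sizes.items():
        starts = range(0, max(size - 1, 1), step)
        for s in starts:
            e = min(s + window_bp, size)
            res = weighted_level(sample, chrom, s, e, context)
            rows.append((chrom, s, e, res.meth_obs, res.total_obs, res.level))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "meth_obs", "total_obs", "level"]
    )
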