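"""Centroid-of-methylation statistic for detecting 3'->5' spreading.

Within a conDMR oriented along its overlapping gene, each cytosine i of
the context has a per-site level m_i = meth_i/total_i and a relative
position x_i in [0, 1] measured 5'->3'. The centroid is the level-weighted
mean position sum(x_i m_i)/sum(m_i). Across several plants of the same
generation, a negative correlation between the mean level in the conDMR
and the centroid position means that plants with more methylation carry it
further toward the 5' end — the signature of methylation spreading in
from a 3' heterochromatic seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .dmr import ConDMR
from .levels import _slice, weighted_level
from .types import MethylomeSample


@dataclass
class SpreadResult:
    condmr: ConDMR
    levels: list[float]  # mean context level per sample
    centroids: list[float]  # relative centroid per sample
    r: Optional[float]  # None when undefined


def centroid(
    sample: MethylomeSample,
    condmr: ConDMR,
    context: str = "CHG",
    orientation: Optional[str] = None,
) -> Optional[float]:
    """Level-weighted mean relative position of methylation, 5'->3' along
    the gene orientation; None when no cytosine carries methylation."""
    orient = orientation or condmr.orientation
    if orient not in ("+", "-"):
        raise ValueError("conDMR needs an orientation (overlapping-gene strand)")
    meth, total, pos = _slice(sample, condmr.chrom, condmr.start, condmr.end, context)
    covered = total > 0
    if not covered.any():
        return None
    m = meth[covered] / total[covered]
    x = (pos[covered] - condmr.start + 0.5) / condmr.length
    if orient == "-":
        x = 1.0 - x
    s = m.sum()
    if s == 0:
        return None
    return float((x * m).sum() / s)


def spread_correlation(
    samples: Sequence[MethylomeSample],
    condmr: ConDMR,
    context: str = "CHG",
    method: str = "pearson",
) -> SpreadResult:
    """Correlation across plants between mean level and centroid position.

    Undefined (r = None) when fewer than 3 plants have a defined centroid
    or either variable has zero variance.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    levels, cents = [], []
    for s in samples:
        c = centroid(s, condmr, context=context)
        if c is None:
            continue
        lv = weighted_level(s, condmr.chrom, condmr.start, condmr.end, context)
        if not lv.defined:
            continue
        levels.append(lv.level)
        cents.append(c)
    r: Optional[float] = None
    if len(levels) >= 3:
        lv = np.asarray(levels)
        ce = np.asarray(cents)
        # spread below float noise counts as zero variance
        if np.ptp(lv) > 1e-9 and np.ptp(ce) > 1e-9:
            if method == "pearson":
                r = float(stats.pearsonr(lv, ce).statistic)
            else:
                r = float(stats.spearmanr(lv, ce).statistic)
    return SpreadResult(condmr, levels, cents, r)


def spread_histogram(
    results: Sequence[SpreadResult], bins: int = 20
) -> tuple[np.ndarray, np.ndarray, int]:
    """Histogram of defined r values over [-1, 1].

    Returns (counts, bin_edges, n_excluded).
    """
    rs = [res.r for res in results if res.r is not None]
    counts, edges = np.histogram(rs, bins=bins, range=(-1.0, 1.0))
    return counts, edges, len(results) - len(rs)
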