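"""epiRIL analyses: global hypomethylation index from MeDIP-chip HMM
states, haplotype mosaic inference from parental-state markers, and the
local-vs-global correlation that separates cis from trans effects.

epiRILs are inbred lines from a ddm1 x wild-type cross; each chromosome is
a mosaic of WT-derived (methylated) and ddm1-derived (hypomethylated)
segments. The global hypomethylation index of a line is the mean of HMM
probe states (M=0, I=0.5, U=1) over "target" probes — those methylated in
the WT parent and unmethylated in the ddm1 parent — so the WT parent
scores 0 and the ddm1 parent scores 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import FeatureAnnotation, MarkerTable, ProbeStatusTable

STATUS_VALUE = {"M": 0.0, "I": 0.5, "U": 1.0}


@dataclass
class IndexResult:
    line: str
    n_target_probes: int
    index: float


@dataclass
class HaplotypeMap:
    """Per chromosome, ordered (start, end, label) segments with label in
    {WT, ddm1, unknown}; coordinates span the marker-covered range."""

    segments: dict[str, list[tuple[int, int, str]]]

    def label_at(self, chrom: str, pos: int) -> str:
        for s, e, lab in self.segments.get(chrom, []):
            if s <= pos < e:
                return lab
        return "unknown"


def select_target_probes(
    table: ProbeStatusTable, wt_line: str, ddm1_line: str
) -> np.ndarray:
    """Indices of probes with status M in the WT parent and U in the ddm1
    parent — the probes informative about ddm1-disrupted methylation."""
    for line in (wt_line, ddm1_line):
        if line not in table.status.columns:
            raise KeyError(f"parental line {line!r} absent from probe table")
    wt = table.status[wt_line].to_numpy()
    dd = table.status[ddm1_line].to_numpy()
    return np.flatnonzero((wt == "M") & (dd == "U"))


def hypomethylation_index(
    table: ProbeStatusTable, targets: np.ndarray, line: str
) -> IndexResult:
    """Mean of {M->0, I->0.5, U->1} over target probes for one line."""
    if len(targets) == 0:
        raise ValueError("empty target probe set")
    vals = table.status[line].to_numpy()[targets]
    idx = float(np.mean([STATUS_VALUE[v] for v in vals]))
    return IndexResult(line=line, n_target_probes=len(targets), index=idx)


def local_global_correlation(
    local_change: pd.Series, indices: pd.Series
) -> tuple[float, float]:
    """Pearson r (and two-sided p, t-distribution with n-2 df) between a
    per-line local methylation change and the global index.

    Returns (nan, nan) when fewer than 3 lines overlap or either variable
    has zero variance.
    """
    df = pd.DataFrame({"local": local_change, "index": indices}).dropna()
    if len(df) < 3:
        return (float("nan"), float("nan"))
    x = df["local"].to_numpy()
    y = df["index"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    res = stats.pearsonr(x, y)
    return (float(res.statistic), float(res.pvalue))


def infer_haplotypes(markers: MarkerTable, line: str) -> HaplotypeMap:
    """Segment chromosomes by parental state of consecutive markers.

    The interval between two concordant markers takes their shared label;
    between discordant markers (a crossover lies somewhere within) it is
    labelled unknown. Regions beyond the terminal markers are not covered.
    """
    segs: dict[str, list[tuple[int, int, str]]] = {}
    data = markers.for_line(line)
    for chrom, sub in data.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        state = sub["state"].to_numpy()
        chrom_segs: list[tuple[int, int, str]] = []
        for i in range(len(pos) - 1):
            label = state[i] if state[i] == state[i + 1] else "unknown"
            chrom_segs.append((int(pos[i]), int(pos[i + 1]), label))
        # merge runs of equal labels
        merged: list[tuple[int, int, str]] = []
        for s, e, lab in chrom_segs:
            if merged and merged[-1][2] == lab and merged[-1][1] == s:
                merged[-1] = (merged[-1][0], e, lab)
            else:
                merged.append((s, e, lab))
        segs[str(chrom)] = merged
    return HaplotypeMap(segs)


def assign_features(
    features: Iterable[FeatureAnnotation], haplotype: HaplotypeMap
) -> dict[str, str]:
    """Label each feature WT/ddm1 when fully contained in a segment of
    that label; unknown otherwise (straddling a breakpoint or uncovered)."""
    out = {}
    for f in features:
        label = "unknown"
        for s, e, lab in haplotype.segments.get(f.chrom, []):
            if s <= f.start and f.end <= e:
                label = lab
                break
        out[f.feature_id] = label
    return out


def index_table(
    table: ProbeStatusTable, wt_line: str, ddm1_line: str,
    lines: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Hypomethylation index for every line (or a subset) in one call."""
    targets = select_target_probes(table, wt_line, ddm1_line)
    lines = list(lines) if lines is not None else list(table.status.columns)
    rows = [
        (ln, hypomethylation_index(table, targets, ln).index) for ln in lines
    ]
    return pd.DataFrame(rows, columns=["line", "index"]).set_index("line")
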