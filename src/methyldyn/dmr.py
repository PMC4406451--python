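"""100-bp-window DMR calling between two genotypes and conDMR merging.

A window is eligible when both samples have at least ``min_obs`` sequenced
cytosine observations of the tested context in it; it is a DMR when the
absolute difference of weighted levels meets the context threshold
(0.5 for CG, 0.3 for CHG — both inclusive; CHH has no canonical threshold
and must be set explicitly). Contiguous DMRs (conDMRs) merge runs of DMR
windows that are adjacent or separated by exactly one non-DMR window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import CONTEXT_CODE, FeatureAnnotation, MethylomeSample

# guard against float representation noise at the inclusive threshold
_EPS = 1e-9


@dataclass
class AnalysisConfig:
    """Constants of the windowed analyses; defaults follow the study design."""

    window_bp: int = 100
    min_obs: int = 20
    min_obs_mode: str = "observations"  # or "positions"
    delta_cg: float = 0.5
    delta_chg: float = 0.3
    delta_chh: Optional[float] = None
    condmr_min_bp: int = 500
    gain_low: float = 0.1
    gain_high: float = 0.1
    top_n: int = 1000
    n_random_windows: int = 100_000
    extrapolation_factor: int = 7
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("delta_cg", "delta_chg", "gain_low", "gain_high"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.delta_chh is not None and not 0 <= self.delta_chh <= 1:
            raise ValueError("delta_chh outside [0, 1]")
        for name in ("window_bp", "min_obs", "top_n", "n_random_windows"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_obs_mode not in ("observations", "positions"):
            raise ValueError("min_obs_mode must be 'observations' or 'positions'")

    def delta_for(self, context: str) -> float:
        if context == "CG":
            return self.delta_cg
        if context == "CHG":
            return self.delta_chg
        if context == "CHH":
            if self.delta_chh is None:
                raise ValueError(
                    "CHH DMR calling requires an explicit delta_chh threshold"
                )
            return self.delta_chh
        raise ValueError(f"unknown context {context!r}")


@dataclass(frozen=True)
class DMR:
    chrom: str
    start: int
    end: int
    context: str
    level_a: float
    level_b: float

    @property
    def delta(self) -> float:
        return self.level_b - self.level_a

    @property
    def direction(self) -> str:
        """hyper/hypo in B relative to A."""
        return "hyper" if self.delta > 0 else "hypo"

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.start)


@dataclass
class ConDMR:
    chrom: str
    start: int
    end: int
    members: list[int]  # member window starts, sorted
    feature_id: Optional[str] = None
    orientation: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start


def window_levels(
    sample: MethylomeSample, context: str, config: Optional[AnalysisConfig] = None
) -> pd.DataFrame:
    """Per-window (meth_obs, total_obs, n_sites, level) on the fixed
    0-anchored non-overlapping window grid."""
    config = config or AnalysisConfig()
    w = config.window_bp
    code = CONTEXT_CODE[context]
    frames = []
    for chrom in sample.chroms:
        arr = sample.chrom_arrays(chrom)
        mask = arr["context"] == code
        if not mask.any():
            continue
        win = arr["pos"][mask] // w
        df = pd.DataFrame(
            {
                "win": win,
                "meth": arr["meth"][mask],
                "total": arr["total"][mask],
            }
        )
        g = df.groupby("win", sort=True).agg(
            meth_obs=("meth", "sum"),
            total_obs=("total", "sum"),
            n_sites=("total", "size"),
        )
        g = g.reset_index()
        g.insert(0, "chrom", chrom)
        g["start"] = g.pop("win") * w
        frames.append(g)
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "start", "meth_obs", "total_obs", "n_sites", "level"]
        )
    out = pd.concat(frames, ignore_index=True)
    out["level"] = np.where(
        out["total_obs"] > 0, out["meth_obs"] / out["total_obs"].clip(lower=1), np.nan
    )
    return out[["chrom", "start", "meth_obs", "total_obs", "n_sites", "level"]]


def call_dmrs(
    sample_a: MethylomeSample,
    sample_b: MethylomeSample,
    context: str,
    config: Optional[AnalysisConfig] = None,
) -> list[DMR]:
    """Windows eligible in both samples whose level difference meets the
    context threshold (inclusive). Direction: hyper/hypo in B vs A."""
    config = config or AnalysisConfig()
    thr = config.delta_for(context)
    wa = window_levels(sample_a, context, config)
    wb = window_levels(sample_b, context, config)
    m = wa.merge(wb, on=["chrom", "start"], suffixes=("_a", "_b"))
    if config.min_obs_mode == "observations":
        eligible = (m["total_obs_a"] >= config.min_obs) & (
            m["total_obs_b"] >= config.min_obs
        )
    else:
        eligible = (m["n_sites_a"] >= config.min_obs) & (
            m["n_sites_b"] >= config.min_obs
        )
    m = m[eligible]
    delta = m["level_b"] - m["level_a"]
    m = m[np.abs(delta) >= thr - _EPS]
    w = config.window_bp
    return [
        DMR(r.chrom, int(r.start), int(r.start) + w, context,
            float(r.level_a), float(r.level_b))
        for r in m.itertuples(index=False)
    ]


def subtract_dmrs(set_a: Sequence[DMR], set_b: Sequence[DMR]) -> list[DMR]:
    """Windows of set_a whose (chrom, start) is absent from set_b."""
    keys_b = {d.key for d in set_b}
    return [d for d in set_a if d.key not in keys_b]


def _best_overlap_feature(
    chrom: str, start: int, end: int, features: Sequence[FeatureAnnotation]
) -> Optional[FeatureAnnotation]:
    best = None
    best_ov = 0
    for f in features:
        if f.chrom != chrom:
            continue
        ov = min(end, f.end) - max(start, f.start)
        if ov <= 0:
            continue
        if ov > best_ov or (ov == best_ov and best and f.feature_id < best.feature_id):
            best, best_ov = f, ov
    return best


def merge_condmrs(
    dmrs: Sequence[DMR],
    features: Optional[Iterable[FeatureAnnotation]] = None,
    config: Optional[AnalysisConfig] = None,
    min_bp: Optional[int] = None,
    require_feature: bool = False,
) -> list[ConDMR]:
    """Merge DMR windows that are adjacent or separated by exactly one
    window; the span covers gap windows.

    With ``min_bp`` (or ``require_feature``), conDMRs shorter than the
    minimum (or not overlapping any feature) are dropped — the filter used
    for spreading analyses. The overlapping feature with the largest
    overlap supplies the conDMR's id and orientation; ties go to the
    lexicographically smallest feature id.
    """
    config = config or AnalysisConfig()
    w = config.window_bp
    feats = list(features) if features is not None else []
    out: list[ConDMR] = []
    by_chrom: dict[str, list[int]] = {}
    for d in dmrs:
        by_chrom.setdefault(d.chrom, []).append(d.start)
    for chrom in sorted(by_chrom):
        starts = sorted(set(by_chrom[chrom]))
        run = [starts[0]]
        for s in starts[1:]:
            if s - run[-1] <= 2 * w:  # adjacent or one-window gap
                run.append(s)
            else:
                out.append(ConDMR(chrom, run[0], run[-1] + w, run))
                run = [s]
        out.append(ConDMR(chrom, run[0], run[-1] + w, run))
    kept = []
    for c in out:
        if min_bp is not None and c.length < min_bp:
            continue
        f = _best_overlap_feature(c.chrom, c.start, c.end, feats) if feats else None
        if require_feature and f is None:
            continue
        if f is not None:
            c.feature_id = f.feature_id
            c.orientation = f.strand
        kept.append(c)
    return kept
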