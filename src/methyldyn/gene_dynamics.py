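"""Gene-level hypermethylation-gain calls, cross-line association against
a binomial null, and the linear-extrapolation acceleration test.

A gene "gains" methylation when its level is below ``gain_low`` in the
reference plant and at or above ``gain_high`` in the alternative plant
(both default 0.1). The association test asks whether the top-N genes by
methylation increase in L independently propagated lines overlap more
than expected if each line drew its top-N independently.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import AnalysisConfig


def classify_gains(
    ref_levels: pd.Series,
    alt_levels: pd.Series,
    config: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Per-feature gain calls: gained iff ref < gain_low and alt >= gain_high.

    Features with an undefined level in either sample are excluded.
    Returns a DataFrame indexed by feature_id with columns
    level_ref, level_alt, gained.
    """
    config = config or AnalysisConfig()
    df = pd.DataFrame({"level_ref": ref_levels, "level_alt": alt_levels}).dropna()
    df["gained"] = (df["level_ref"] < config.gain_low) & (
        df["level_alt"] >= config.gain_high
    )
    return df


def topn_overlap_association(
    increase_tables: dict[str, pd.Series],
    config: Optional[AnalysisConfig] = None,
    top_n: Optional[int] = None,
) -> pd.DataFrame:
    """Observed vs expected counts of genes shared by k of L top-N lists.

    Each table maps feature -> methylation increase for one line. The
    universe G is the set of features with a defined increase in every
    line. Per line the top_n features by increase are selected (ties
    broken by feature id). Expected counts assume independent selection:
    expected(k) = G * C(L, k) p^k (1-p)^(L-k) with p = top_n / G.
    """
    config = config or AnalysisConfig()
    n = top_n if top_n is not None else config.top_n
    if len(increase_tables) < 2:
        raise ValueError("need at least two lines")
    common = None
    for s in increase_tables.values():
        idx = s.dropna().index
        common = idx if common is None else common.intersection(idx)
    G = len(common)
    if n > G:
        raise ValueError(f"top_n {n} exceeds shared feature universe {G}")
    L = len(increase_tables)
    shared = pd.Series(0, index=common)
    for s in increase_tables.values():
        s = s.loc[common]
        order = s.sort_values(ascending=False, kind="mergesort")
        # stable sort on value then id makes ties deterministic
        order = order.loc[sorted(order.index)].sort_values(
            ascending=False, kind="mergesort"
        )
        shared.loc[order.index[:n]] += 1
    observed = np.bincount(shared.to_numpy(), minlength=L + 1).astype(float)
    p = n / G
    ks = np.arange(L + 1)
    expected = G * stats.binom.pmf(ks, L, p)
    return pd.DataFrame({"k": ks, "observed": observed, "expected": expected})


def montecarlo_association_null(
    G: int, L: int, top_n: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo expected sharing counts: each draw selects top_n of G
    features independently per line; returns mean counts per k over draws."""
    acc = np.zeros(L + 1)
    for _ in range(n_draws):
        shared = np.zeros(G, dtype=np.int64)
        for _ in range(L):
            shared[rng.choice(G, size=top_n, replace=False)] += 1
        acc += np.bincount(shared, minlength=L + 1)
    return acc / n_draws


def extrapolate_linear(level_1g, level_2g, factor: int = 7):
    """Predicted later-generation level assuming per-generation increments
    stay at the 1G->2G size: B + (B - A) * factor.

    Accepts scalars or arrays; the prediction is reported unclamped (it
    may exceed 1 when the observed increment is large).
    """
    a = np.asarray(level_1g, dtype=float)
    b = np.asarray(level_2g, dtype=float)
    pred = b + (b - a) * factor
    return pred if pred.ndim else float(pred)


def equal_increment_bound(n_steps: int = 8) -> float:
    """Minimum share of a multi-step increase attributable to the first
    step when increments are equal or shrinking (saturation): 1/n_steps.

    With eight self-pollinations between 1G and 9G, an equal-or-saturating
    schedule puts at least 1/8 of the 1G->9G increase into 1G->2G; a
    first-step share below this bound indicates acceleration.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    return 1.0 / n_steps
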