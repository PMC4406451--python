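"""Read-level quality filters for bisulfite data and pileup into counts.

Two bespoke filters precede all downstream analyses:

* clonal-read removal — among reads sharing (chrom, alignment start,
  strand), only the read with the best quality is kept, so PCR duplicates
  do not inflate counts;
* CHH-run removal — a read carrying ``run_length`` (default 3) consecutive
  methylated CHH calls is discarded wholesale, flagging incomplete
  bisulfite conversion (genuine CHH methylation is sparse, conversion
  failure methylates everything).

"Consecutive" defaults to successive CHH calls in read order, skipping
interleaved CG/CHG cytosines; ``adjacency="strict"`` instead requires the
CHH calls to be adjacent among *all* calls of the read.
"""

from __future__ import annotations

from collections import Counter

import pandas as pd

from .types import MethylomeSample, ReadRecord, ReadSet, ValidationError


def remove_clonal(readset: ReadSet) -> ReadSet:
    """Collapse clonal groups to the single best-quality read.

    Ties on quality keep the first read in input order.
    """
    best: dict[tuple[str, int, str], ReadRecord] = {}
    order: list[tuple[str, int, str]] = []
    for read in readset.reads:
        key = (read.chrom, read.start, read.strand)
        if key not in best:
            best[key] = read
            order.append(key)
        elif read.quality > best[key].quality:
            best[key] = read
    return ReadSet([best[k] for k in order], provenance=readset.provenance)


def has_chh_run(
    read: ReadRecord, run_length: int = 3, adjacency: str = "read_order"
) -> bool:
    """True if the read contains ``run_length`` consecutive methylated
    CHH calls under the chosen adjacency convention."""
    if run_length < 1:
        raise ValueError("run_length must be >= 1")
    if adjacency not in ("read_order", "strict"):
        raise ValueError(f"unknown adjacency {adjacency!r}")
    run = 0
    for _, ctx, methylated in read.calls:
        if ctx == "CHH":
            run = run + 1 if methylated else 0
            if run >= run_length:
                return True
        elif adjacency == "strict":
            run = 0  # a non-CHH cytosine interrupts strict adjacency
    return False


def remove_chh_runs(
    readset: ReadSet, run_length: int = 3, adjacency: str = "read_order"
) -> ReadSet:
    """Drop every read with ``run_length`` consecutive methylated CHH calls."""
    kept = [
        r for r in readset.reads
        if not has_chh_run(r, run_length=run_length, adjacency=adjacency)
    ]
    return ReadSet(kept, provenance=readset.provenance)


def pileup(
    readset: ReadSet,
    contexts: dict[tuple[str, int, str], str] | None = None,
    sample_id: str = "",
) -> MethylomeSample:
    """Stack read calls into per-cytosine (meth, total) counts.

    ``contexts`` maps (chrom, pos, strand) to the reference context; when
    given, a call whose context disagrees raises (it signals the reads
    were aligned to a different reference). When omitted the contexts
    carried on the calls are trusted, but two calls at one site with
    different contexts still raise.
    """
    meth: Counter = Counter()
    total: Counter = Counter()
    site_ctx: dict[tuple[str, int, str], str] = {}
    for read in readset.reads:
        for offset, ctx, methylated in read.calls:
            site = (read.chrom, read.start + offset, read.strand)
            if contexts is not None:
                ref = contexts.get(site)
                if ref is None:
                    raise ValidationError(f"call at {site} absent from reference")
                if ref != ctx:
                    raise ValidationError(
                        f"context mismatch at {site}: call {ctx}, reference {ref}"
                    )
            prev = site_ctx.setdefault(site, ctx)
            if prev != ctx:
                raise ValidationError(
                    f"conflicting call contexts at {site}: {prev} vs {ctx}"
                )
            total[site] += 1
            if methylated:
                meth[site] += 1
    rows = [
        (chrom, pos, strand, site_ctx[(chrom, pos, strand)],
         meth[(chrom, pos, strand)], n)
        for (chrom, pos, strand), n in total.items()
    ]
    df = pd.DataFrame(rows, columns=list(MethylomeSample.COLUMNS))
    return MethylomeSample(df, sample_id=sample_id or readset.provenance)


def filter_reads(
    readset: ReadSet, chh_run_length: int = 3, adjacency: str = "read_order"
) -> ReadSet:
    """Full filter chain: clonal removal, then CHH-run removal."""
    return remove_chh_runs(
        remove_clonal(readset), run_length=chh_run_length, adjacency=adjacency
    )
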