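"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; file
dialects that use other conventions are converted at the I/O boundary.
Methylation contexts follow the plant convention: CG, CHG, CHH (H = A/T/C).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
CONTEXT_CODE = {c: i for i, c in enumerate(CONTEXTS)}
STRANDS = ("+", "-")


class ValidationError(ValueError):
    """Raised when an input file or structure violates its contract."""


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine's read counts in one sample."""

    chrom: str
    pos: int  # 0-based
    strand: str
    context: str
    meth_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError(f"negative position {self.pos}")
        if self.strand not in STRANDS:
            raise ValidationError(f"bad strand {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValidationError(f"unknown context {self.context!r}")
        if not (0 <= self.meth_reads <= self.total_reads):
            raise ValidationError(
                f"meth_reads {self.meth_reads} > total_reads {self.total_reads}"
            )


class MethylomeSample:
    """Per-cytosine methylation counts for one plant.

    Backed by a DataFrame with columns ``chrom, pos, strand, context,
    meth, total`` sorted by (chrom, pos, strand) with no duplicate
    (chrom, pos, strand) key. ``context`` is stored as the string code.
    """

    COLUMNS = ("chrom", "pos", "strand", "context", "meth", "total")

    def __init__(
        self,
        data: pd.DataFrame,
        sample_id: str = "",
        genotype: str = "",
        generation: str = "",
        validate: bool = True,
    ) -> None:
        if validate:
            data = self._validate(data)
        self.data = data
        self.sample_id = sample_id
        self.genotype = genotype
        self.generation = generation
        self._chrom_cache: dict[str, dict[str, np.ndarray]] = {}

    @staticmethod
    def _validate(data: pd.DataFrame) -> pd.DataFrame:
        missing = set(MethylomeSample.COLUMNS) - set(data.columns)
        if missing:
            raise ValidationError(f"missing columns: {sorted(missing)}")
        data = data.loc[:, list(MethylomeSample.COLUMNS)].copy()
        if len(data) == 0:
            return data.reset_index(drop=True)
        if not data["context"].isin(CONTEXTS).all():
            bad = data.loc[~data["context"].isin(CONTEXTS), "context"].iloc[0]
            raise ValidationError(f"unknown context {bad!r}")
        if not data["strand"].isin(STRANDS).all():
            raise ValidationError("strand must be + or -")
        if (data["pos"] < 0).any():
            raise ValidationError("negative position")
        if (data["meth"] > data["total"]).any():
            raise ValidationError("meth > total")
        data = data.sort_values(["chrom", "pos", "strand"], kind="mergesort")
        dup = data.duplicated(["chrom", "pos", "strand"])
        if dup.any():
            raise ValidationError("duplicate (chrom, pos, strand) records")
        return data.reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records, sample_id: str = "", genotype: str = "", generation: str = ""
    ) -> "MethylomeSample":
        rows = [
            (r.chrom, r.pos, r.strand, r.context, r.meth_reads, r.total_reads)
            for r in records
        ]
        df = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        return cls(df, sample_id, genotype, generation)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.data["chrom"].unique())

    def chrom_arrays(self, chrom: str) -> dict[str, np.ndarray]:
        """Position-sorted numpy views for one chromosome (cached)."""
        if chrom not in self._chrom_cache:
            sub = self.data[self.data["chrom"] == chrom]
            ctx = sub["context"].map(CONTEXT_CODE).to_numpy(dtype=np.int8)
            self._chrom_cache[chrom] = {
                "pos": sub["pos"].to_numpy(dtype=np.int64),
                "context": ctx,
                "meth": sub["meth"].to_numpy(dtype=np.int64),
                "total": sub["total"].to_numpy(dtype=np.int64),
            }
        return self._chrom_cache[chrom]

    def records(self):
        for row in self.data.itertuples(index=False):
            yield CytosineRecord(
                row.chrom, row.pos, row.strand, row.context, row.meth, row.total
            )


@dataclass(frozen=True)
class FeatureAnnotation:
    """A gene or transposable-element gene (TEG) interval."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    kind: str = "gene"  # gene | TEG
    family: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"{self.feature_id}: start {self.start} >= end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReadRecord:
    """One aligned read's per-cytosine methylation calls.

    ``calls`` is an ordered list of (offset_in_read, context, methylated).
    """

    read_id: str
    chrom: str
    start: int
    strand: str
    quality: float
    calls: list[tuple[int, str, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        offsets = [c[0] for c in self.calls]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValidationError(f"{self.read_id}: offsets not strictly increasing")
        for _, ctx, _ in self.calls:
            if ctx not in CONTEXTS:
                raise ValidationError(f"{self.read_id}: unknown context {ctx!r}")


@dataclass
class ReadSet:
    reads: list[ReadRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class ProbeStatusTable:
    """MeDIP-chip HMM methylation states per probe per line.

    ``probes`` is a DataFrame with columns chrom, start, end; ``status``
    a probe x line DataFrame with entries in {M, I, U}.
    """

    probes: pd.DataFrame
    status: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.probes) != len(self.status):
            raise ValidationError("probe list and status matrix length mismatch")
        vals = self.status.to_numpy()
        if len(vals) and not np.isin(vals, ["M", "I", "U"]).all():
            raise ValidationError("status entries must be in {M, I, U}")

    @property
    def samples(self) -> list[str]:
        return list(self.status.columns)


@dataclass
class MarkerTable:
    """Parental-state markers along chromosomes, per line.

    DataFrame columns: line, chrom, pos, state (WT | ddm1), sorted by
    (line, chrom, pos).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"line", "chrom", "pos", "state"}
        if not need.issubset(self.data.columns):
            raise ValidationError(f"marker table needs columns {sorted(need)}")
        if len(self.data) and not self.data["state"].isin(["WT", "ddm1"]).all():
            raise ValidationError("marker state must be WT or ddm1")
        self.data = (
            self.data.sort_values(["line", "chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )

    def for_line(self, line: str) -> pd.DataFrame:
        return self.data[self.data["line"] == line]
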