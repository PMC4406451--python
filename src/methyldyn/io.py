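"""Readers and writers for the pipeline's on-disk dialects.

All dialects are plain TSV/GFF3/BED. Positions in cytosine reports are
1-based on disk (Bismark CX convention) and converted to 0-based on read;
GFF3 1-based closed intervals become 0-based half-open; BED is passed
through unchanged.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .types import (
    CONTEXTS,
    FeatureAnnotation,
    MarkerTable,
    MethylomeSample,
    ProbeStatusTable,
    ReadRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_CX_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "context"]

# GFF3 feature types mapped onto the two feature kinds the analyses use
DEFAULT_KIND_MAP = {"gene": "gene", "transposable_element_gene": "TEG"}


def _looks_like_header(fields: list[str]) -> bool:
    try:
        int(fields[1])
        return False
    except (ValueError, IndexError):
        return True


def read_cytosine_report(
    path: PathLike,
    sample_id: str = "",
    genotype: str = "",
    generation: str = "",
) -> MethylomeSample:
    """Parse a per-cytosine report: chrom, pos(1-based), strand,
    count_methylated, count_unmethylated, context."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) < 6:
                raise ValidationError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, got {len(fields)}"
                )
            chrom, pos_s, strand, meth_s, unmeth_s, context = fields[:6]
            try:
                pos1 = int(pos_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-integer field ({exc})")
            if context not in CONTEXTS:
                raise ValidationError(
                    f"{path}:{lineno}: unknown context {context!r}"
                )
            if pos1 < 1:
                raise ValidationError(f"{path}:{lineno}: position must be >= 1")
            if meth < 0 or unmeth < 0:
                raise ValidationError(f"{path}:{lineno}: negative count")
            rows.append((chrom, pos1 - 1, strand, context, meth, meth + unmeth))
    df = pd.DataFrame(rows, columns=list(MethylomeSample.COLUMNS))
    return MethylomeSample(df, sample_id, genotype, generation)


def write_cytosine_report(sample: MethylomeSample, path: PathLike) -> None:
    df = sample.data
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"] + 1,
            "strand": df["strand"],
            "meth": df["meth"],
            "unmeth": df["total"] - df["meth"],
            "context": df["context"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out = {}
    for piece in attr.strip().split(";"):
        if "=" in piece:
            k, v = piece.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_annotation(
    path: PathLike, kind_map: Optional[dict[str, str]] = None
) -> list[FeatureAnnotation]:
    """Read gene/TEG annotation from GFF3 or BED6.

    Format is sniffed: 9-column lines with a source/type column are GFF3,
    otherwise BED6 with the kind carried in the name field as
    ``id|kind[|family]`` (bare ids default to kind ``gene``).
    """
    kind_map = dict(DEFAULT_KIND_MAP if kind_map is None else kind_map)
    feats: list[FeatureAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 9:  # GFF3
                chrom, _, ftype, start_s, end_s, _, strand, _, attrs = fields[:9]
                if ftype not in kind_map:
                    continue
                start = int(start_s) - 1  # 1-based closed -> 0-based half-open
                end = int(end_s)
                a = _parse_gff_attributes(attrs)
                fid = a.get("ID") or a.get("Name") or f"feat{lineno}"
                family = a.get("family")
                kind = kind_map[ftype]
            elif len(fields) >= 6:  # BED6
                chrom, start_s, end_s, name, _, strand = fields[:6]
                start, end = int(start_s), int(end_s)
                parts = name.split("|")
                fid = parts[0]
                kind = parts[1] if len(parts) > 1 else "gene"
                family = parts[2] if len(parts) > 2 else None
            else:
                raise ValidationError(
                    f"{path}:{lineno}: neither GFF3 (9 cols) nor BED6"
                )
            if end <= start:
                raise ValidationError(
                    f"{path}:{lineno}: empty interval after conversion"
                )
            feats.append(FeatureAnnotation(fid, chrom, start, end, strand, kind, family))
    return feats


def write_annotation_bed(features: Iterable[FeatureAnnotation], path: PathLike) -> None:
    with open(path, "w") as fh:
        for f in features:
            name = f.feature_id + "|" + f.kind + (f"|{f.family}" if f.family else "")
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{name}\t0\t{f.strand}\n")


def read_read_calls(path: PathLike) -> list[ReadRecord]:
    """Read per-read methylation calls:
    read_id, chrom, start(0-based), strand, quality, calls
    with calls = comma-joined ``offset:context:M|U``."""
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValidationError(f"{path}:{lineno}: expected 6 fields")
            rid, chrom, start_s, strand, qual_s, calls_s = fields[:6]
            calls = []
            if calls_s:
                for tok in calls_s.split(","):
                    off_s, ctx, state = tok.split(":")
                    if state not in ("M", "U"):
                        raise ValidationError(
                            f"{path}:{lineno}: call state must be M or U"
                        )
                    calls.append((int(off_s), ctx, state == "M"))
            try:
                reads.append(
                    ReadRecord(rid, chrom, int(start_s), strand, float(qual_s), calls)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}")
    return reads


def write_read_calls(reads: Iterable[ReadRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            calls = ",".join(
                f"{off}:{ctx}:{'M' if m else 'U'}" for off, ctx, m in r.calls
            )
            fh.write(f"{r.read_id}\t{r.chrom}\t{r.start}\t{r.strand}\t{r.quality}\t{calls}\n")


def read_probe_table(path: PathLike) -> ProbeStatusTable:
    """Probe status TSV: header ``chrom start end <line1> <line2> ...``,
    one probe per row, statuses in {M, I, U}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"chrom", "start", "end"}
    if not need.issubset(df.columns):
        raise ValidationError(f"probe table needs columns {sorted(need)}")
    probes = df[["chrom", "start", "end"]].copy()
    probes["start"] = probes["start"].astype(int)
    probes["end"] = probes["end"].astype(int)
    lines = [c for c in df.columns if c not in need]
    status = df[lines]
    return ProbeStatusTable(probes=probes, status=status)


def write_probe_table(table: ProbeStatusTable, path: PathLike) -> None:
    out = pd.concat([table.probes.reset_index(drop=True),
                     table.status.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_marker_table(path: PathLike) -> MarkerTable:
    """Marker TSV: line, chrom, pos, state(WT|ddm1); no header required."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["line", "chrom", "pos", "state"],
        dtype={"line": str, "chrom": str, "pos": int, "state": str},
    )
    if len(df) and df["line"].iloc[0] == "line":  # tolerate a header row
        df = df.iloc[1:].reset_index(drop=True)
        df["pos"] = df["pos"].astype(int)
    sorted_ok = (
        df.groupby(["line", "chrom"], sort=False)["pos"].apply(
            lambda s: s.is_monotonic_increasing
        ).all()
        if len(df)
        else True
    )
    if not sorted_ok:
        logger.warning("marker table %s not position-sorted; sorting", path)
    return MarkerTable(df)


def write_marker_table(markers: MarkerTable, path: PathLike) -> None:
    markers.data.to_csv(path, sep="\t", header=False, index=False)


def read_chip_bed(path: PathLike) -> dict[str, np.ndarray]:
    """ChIP read intervals from BED (first three columns used).

    Returns chrom -> (n, 2) int array of half-open intervals, start-sorted.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValidationError(f"{path}:{lineno}: empty interval")
            by_chrom.setdefault(chrom, []).append((start, end))
    return {
        c: np.array(sorted(iv), dtype=np.int64).reshape(-1, 2)
        for c, iv in by_chrom.items()
    }


def read_genome_sizes(path: PathLike) -> dict[str, int]:
    """Two-column TSV: chrom, length."""
    sizes = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


def write_genome_sizes(sizes: dict[str, int], path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")
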