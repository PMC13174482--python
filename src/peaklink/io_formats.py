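"""Readers and writers for BED, narrowPeak, GTF, bedGraph and TSV summaries.

Everything is converted on read to the single internal convention:
0-based, half-open coordinates (the BED convention). GTF, which is 1-based
inclusive, has 1 subtracted from its start on read and added back on write.
Parsing is order-preserving and never silently drops records: malformed
lines raise with their line number.
"""

from __future__ import annotations

import os
from collections import OrderedDict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import TranscriptModel
from .intervals import GenomicInterval

__all__ = [
    "ChromSizes",
    "PeakRecord",
    "read_chrom_sizes",
    "read_peaks",
    "write_peaks",
    "read_transcripts",
    "write_gtf",
    "read_bedgraph",
    "write_bedgraph",
    "write_table",
    "read_table",
]


class ChromSizes(OrderedDict):
    """Mapping chromosome name -> length in bp."""

    def __init__(self, items: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__()
        pairs = items.items() if isinstance(items, Mapping) else items
        for name, length in pairs:
            self[name] = length

    def __setitem__(self, name: str, length: int) -> None:
        if int(length) < 1:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        super().__setitem__(str(name), int(length))

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "ChromSizes":
        out = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                out[fields[0]] = int(fields[1])
        return out

    def to_file(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for name, length in self.items():
                fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path: str | os.PathLike) -> ChromSizes:
    return ChromSizes.from_file(path)


@dataclass(frozen=True)
class PeakRecord:
    """A called peak; summit_offset is the bp offset of the summit from start.

    narrowPeak column 10 of -1 (summit not reported) maps to
    ``summit_offset=None``.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    signal: float = 0.0
    p_neglog10: float | None = None
    q_neglog10: float | None = None
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"peak {self.chrom}:{self.start}-{self.end}: need 0 <= start < end"
            )
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"peak {self.name}: summit offset {self.summit_offset} outside peak"
            )

    @property
    def summit(self) -> int | None:
        """Absolute summit position, or None when not reported."""
        if self.summit_offset is None:
            return None
        return self.start + self.summit_offset

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


def _check_chrom(chrom: str, end: int, sizes: ChromSizes | None, where: str) -> None:
    if sizes is None:
        return
    if chrom not in sizes:
        raise ValueError(f"{where}: unknown chromosome {chrom!r}")
    if end > sizes[chrom]:
        raise ValueError(f"{where}: end {end} beyond chromosome length {sizes[chrom]}")


def read_peaks(
    path: str | os.PathLike,
    format: str | None = None,
    sizes: ChromSizes | None = None,
) -> list[PeakRecord]:
    """Read a BED (>= 3 columns) or ENCODE narrowPeak (exactly 10) peak file.

    ``format`` is "bed", "narrowPeak" or None to autodetect from the column
    count (10 tab-separated columns -> narrowPeak).
    """
    records: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            where = f"{path}:{lineno}"
            fmt = format
            if fmt is None:
                fmt = "narrowPeak" if len(f) == 10 else "bed"
            try:
                if fmt == "narrowPeak":
                    if len(f) != 10:
                        raise ValueError("narrowPeak requires exactly 10 columns")
                    chrom, start, end = f[0], int(f[1]), int(f[2])
                    offset = int(f[9])
                    rec = PeakRecord(
                        chrom=chrom,
                        start=start,
                        end=end,
                        name=f[3],
                        score=float(f[4]),
                        strand=f[5],
                        signal=float(f[6]),
                        p_neglog10=None if float(f[7]) < 0 else float(f[7]),
                        q_neglog10=None if float(f[8]) < 0 else float(f[8]),
                        summit_offset=None if offset == -1 else offset,
                    )
                elif fmt == "bed":
                    if len(f) < 3:
                        raise ValueError("BED requires >= 3 columns")
                    chrom, start, end = f[0], int(f[1]), int(f[2])
                    rec = PeakRecord(
                        chrom=chrom,
                        start=start,
                        end=end,
                        name=f[3] if len(f) > 3 else ".",
                        score=float(f[4]) if len(f) > 4 else 0.0,
                        strand=f[5] if len(f) > 5 else ".",
                    )
                else:
                    raise ValueError(f"unknown format {fmt!r}")
            except ValueError as exc:
                raise ValueError(f"{where}: malformed line ({exc})") from exc
            _check_chrom(rec.chrom, rec.end, sizes, where)
            records.append(rec)
    return records


def write_peaks(
    records: Sequence[PeakRecord],
    path: str | os.PathLike,
    format: str = "narrowPeak",
) -> None:
    """Write peaks as narrowPeak (10 col), BED6, or summit BED (1 bp)."""
    with open(path, "w") as fh:
        for r in records:
            if format == "narrowPeak":
                off = -1 if r.summit_offset is None else r.summit_offset
                p = -1 if r.p_neglog10 is None else r.p_neglog10
                q = -1 if r.q_neglog10 is None else r.q_neglog10
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score:g}\t"
                    f"{r.strand}\t{r.signal:g}\t{p:g}\t{q:g}\t{off}\n"
                )
            elif format == "bed":
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score:g}\t{r.strand}\n"
                )
            elif format == "summits":
                if r.summit is None:
                    raise ValueError(f"peak {r.name} has no summit")
                fh.write(f"{r.chrom}\t{r.summit}\t{r.summit + 1}\t{r.name}\n")
            else:
                raise ValueError(f"unknown format {format!r}")


# GTF ------------------------------------------------------------------------

_UTR5_TYPES = {"5UTR", "five_prime_utr", "five_prime_UTR"}
_UTR3_TYPES = {"3UTR", "three_prime_utr", "three_prime_UTR"}


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " in chunk:
            key, _, value = chunk.partition(" ")
            out[key] = value.strip().strip('"')
    return out


def read_transcripts(path: str | os.PathLike) -> list[TranscriptModel]:
    """Parse a GTF into TranscriptModels (0-based half-open on read).

    Exon features are required per transcript; CDS and explicit 5UTR/3UTR
    features are used when present, otherwise UTRs derive from the
    exon-minus-CDS difference. Transcripts appear in order of first
    occurrence in the file.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    utr5: dict[str, list[GenomicInterval]] = {}
    utr3: dict[str, list[GenomicInterval]] = {}
    meta: "OrderedDict[str, tuple[str, str, str]]" = OrderedDict()  # tid -> (gene, chrom, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, ftype, start1, end1, _, strand, _, attrs = f
            if ftype not in ("exon", "CDS") and ftype not in _UTR5_TYPES | _UTR3_TYPES:
                continue
            start, end = int(start1) - 1, int(end1)  # 1-based inclusive -> half-open
            a = _parse_gtf_attributes(attrs)
            tid = a.get("transcript_id")
            if tid is None:
                raise ValueError(f"{path}:{lineno}: feature without transcript_id")
            gene = a.get("gene_name", a.get("gene_id", tid))
            if tid in meta:
                if meta[tid][2] != strand:
                    raise ValueError(
                        f"{path}:{lineno}: inconsistent strand within transcript {tid}"
                    )
            else:
                meta[tid] = (gene, chrom, strand)
            if ftype == "exon":
                exons.setdefault(tid, []).append(GenomicInterval(chrom, start, end))
            elif ftype == "CDS":
                cds.setdefault(tid, []).append((start, end))
            elif ftype in _UTR5_TYPES:
                utr5.setdefault(tid, []).append(GenomicInterval(chrom, start, end))
            else:
                utr3.setdefault(tid, []).append(GenomicInterval(chrom, start, end))
    out: list[TranscriptModel] = []
    for tid, (gene, chrom, strand) in meta.items():
        if tid not in exons:
            raise ValueError(f"transcript {tid} has no exon features")
        cds_start = cds_end = None
        if tid in cds:
            cds_start = min(s for s, _ in cds[tid])
            cds_end = max(e for _, e in cds[tid])
        out.append(
            TranscriptModel(
                gene_symbol=gene,
                transcript_id=tid,
                chrom=chrom,
                strand=strand,
                exons=exons[tid],
                cds_start=cds_start,
                cds_end=cds_end,
                utr5=sorted(utr5.get(tid, []), key=lambda iv: iv.start),
                utr3=sorted(utr3.get(tid, []), key=lambda iv: iv.start),
            )
        )
    return out


def write_gtf(transcripts: Sequence[TranscriptModel], path: str | os.PathLike) -> None:
    """Write transcripts as GTF (converting back to 1-based inclusive)."""

    def line(t: TranscriptModel, ftype: str, iv: GenomicInterval) -> str:
        attrs = f'gene_id "{t.gene_symbol}"; transcript_id "{t.transcript_id}";'
        return (
            f"{t.chrom}\tpeaklink\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
            f"{t.strand}\t.\t{attrs}\n"
        )

    with open(path, "w") as fh:
        for t in transcripts:
            for exon in t.exons:
                fh.write(line(t, "exon", exon))
            if t.is_coding:
                for exon in t.exons:
                    lo = max(exon.start, t.cds_start)
                    hi = min(exon.end, t.cds_end)
                    if lo < hi:
                        fh.write(line(t, "CDS", GenomicInterval(t.chrom, lo, hi)))
            u5, u3 = t.utr_intervals()
            for iv in u5:
                fh.write(line(t, "5UTR", iv))
            for iv in u3:
                fh.write(line(t, "3UTR", iv))


# bedGraph -------------------------------------------------------------------

def read_bedgraph(path: str | os.PathLike) -> list[tuple[str, int, int, float]]:
    """Read a 4-column bedGraph (0-based half-open) into (chrom, start, end, value)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) != 4:
                raise ValueError(f"{path}:{lineno}: bedGraph requires 4 columns")
            start, end = int(f[1]), int(f[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            out.append((f[0], start, end, float(f[3])))
    return out


def write_bedgraph(
    runs: Iterable[tuple[str, int, int, float]], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in runs:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# TSV summaries --------------------------------------------------------------

_SORT_PRIORITY = ["chrom", "start", "end", "label", "name", "gene"]


def write_table(records, path: str | os.PathLike, sort: bool = True) -> None:
    """Write records (DataFrame or list of mappings/dataclasses) as TSV.

    Deterministic: column order preserved from input, rows sorted by the
    coordinate/label columns present. Writing the same input twice yields
    byte-identical files.
    """
    if records is None:
        raise ValueError("records must not be None")
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = []
        for r in records:
            if hasattr(r, "__dataclass_fields__"):
                rows.append({k: getattr(r, k) for k in r.__dataclass_fields__})
            else:
                rows.append(dict(r))
        df = pd.DataFrame(rows)
    if sort and len(df):
        keys = [c for c in _SORT_PRIORITY if c in df.columns]
        if keys:
            df = df.sort_values(keys, kind="stable")
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
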