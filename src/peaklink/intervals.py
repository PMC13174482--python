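"""Genomic interval algebra: merging, summit windows, overlaps, nearest TSS.

All coordinates are 0-based, half-open (BED convention). Strand is carried
but ignored by merging and overlap detection; it only matters for
transcription-relative distance signs.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "AnalysisParameters",
    "merge_intervals",
    "summit_window",
    "overlap_pairs",
    "nearest_tss",
    "TssIndex",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic region ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class AnalysisParameters:
    """Tunable distances and thresholds of the integration pipeline.

    merge_gap
        Peak intervals closer than or equal to this many bp are merged
        into one accessible region (default 100 bp).
    summit_flank
        Half-width of the fixed summit-centered window; 100 bp gives the
        200 bp windows used for condition-overlap classification.
    tss_range
        Maximum |anchor - TSS| distance for peak-to-gene assignment
        (default 100 kb).
    promoter_flank
        Promoter half-width around the TSS (default 2 kb).
    profile_flank
        Half-width of signal metaprofiles around anchors (default 2 kb).
    downsample_n
        Read-level normalization target; the full-scale study value is
        100 million reads per sample.
    cut_width
        Number of bp at the 5' end of each read kept as the accessibility
        "cut site" (default 9).
    dar_adj_p, dar_abs_log2fc
        Differential-accessibility call thresholds (BH-adjusted p and
        absolute log2 fold change).
    """

    merge_gap: int = 100
    summit_flank: int = 100
    tss_range: int = 100_000
    promoter_flank: int = 2_000
    profile_flank: int = 2_000
    downsample_n: int = 100_000_000
    cut_width: int = 9
    dar_adj_p: float = 0.05
    dar_abs_log2fc: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "merge_gap",
            "summit_flank",
            "tss_range",
            "promoter_flank",
            "profile_flank",
            "downsample_n",
            "cut_width",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.dar_adj_p <= 1:
            raise ValueError("dar_adj_p must be in (0, 1]")
        if self.dar_abs_log2fc <= 0:
            raise ValueError("dar_abs_log2fc must be > 0")


def merge_intervals(
    intervals: Iterable[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap (next.start - prev.end) is <= ``max_gap``.

    Input may be unsorted, overlapping and multi-chromosome. Output is
    sorted by (chrom, start); strand is dropped. Touching intervals and
    intervals exactly ``max_gap`` apart both merge.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def summit_window(
    summit_pos: int, chrom: str, flank: int, sizes: "ChromSizesLike"
) -> GenomicInterval:
    """Fixed window ``[summit - flank, summit + flank)`` clipped to the chromosome."""
    length = sizes[chrom]
    if not 0 <= summit_pos < length:
        raise ValueError(
            f"summit {chrom}:{summit_pos} outside chromosome of length {length}"
        )
    return GenomicInterval(chrom, max(0, summit_pos - flank), min(length, summit_pos + flank))


def _subject_trees(subject: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for j, iv in enumerate(subject):
        trees[iv.chrom][iv.start : iv.end] = j
    return trees


def overlap_pairs(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """All (query index, subject index) pairs sharing >= 1 bp, sorted."""
    trees = _subject_trees(subject)
    pairs: list[tuple[int, int]] = []
    for i, iv in enumerate(query):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            pairs.append((i, hit.data))
    pairs.sort()
    return pairs


class TssIndex:
    """Sorted per-chromosome TSS arrays for fast nearest-TSS queries.

    Tie-breaking at equal |distance| is deterministic: smaller |distance|
    first, then lexicographic gene symbol, then transcript id.
    """

    def __init__(self, transcripts: Sequence["TranscriptLike"]):
        per_chrom: dict[str, list[tuple[int, str, str, str]]] = defaultdict(list)
        for t in transcripts:
            per_chrom[t.chrom].append((t.tss, t.gene_symbol, t.transcript_id, t.strand))
        self._pos: dict[str, np.ndarray] = {}
        self._meta: dict[str, list[tuple[int, str, str, str]]] = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            self._pos[chrom] = np.array([r[0] for r in rows], dtype=np.int64)
            self._meta[chrom] = rows

    def query(
        self, chrom: str, anchor: int, max_dist: int
    ) -> tuple[str, str, int] | None:
        """Nearest TSS to ``anchor`` within ``max_dist``.

        Returns (gene_symbol, transcript_id, signed distance) where the
        sign is transcription-relative: positive means the anchor lies
        downstream of the TSS, negative upstream.
        """
        pos = self._pos.get(chrom)
        if pos is None or len(pos) == 0:
            return None
        k = int(np.searchsorted(pos, anchor))
        best_abs: int | None = None
        for idx in (k - 1, k):
            if 0 <= idx < len(pos):
                d = abs(int(pos[idx]) - anchor)
                if best_abs is None or d < best_abs:
                    best_abs = d
        if best_abs is None or best_abs > max_dist:
            return None
        # every TSS achieving the winning |distance| (duplicated positions,
        # and the symmetric left/right tie), then deterministic tie-break
        lo = bisect.bisect_left(pos, anchor - best_abs)
        hi = bisect.bisect_right(pos, anchor + best_abs)
        best: tuple[str, str, int, str] | None = None  # (gene, tx, tss, strand)
        for tss, gene, tx, strand in self._meta[chrom][lo:hi]:
            if abs(tss - anchor) != best_abs:
                continue
            if best is None or (gene, tx) < (best[0], best[1]):
                best = (gene, tx, tss, strand)
        assert best is not None
        gene, tx, tss, strand = best
        raw = anchor - tss
        signed = raw if strand == "+" else -raw
        return gene, tx, signed


def nearest_tss(
    region: GenomicInterval,
    transcripts: Sequence["TranscriptLike"],
    tss_range: int = 100_000,
    index: TssIndex | None = None,
) -> tuple[str, str, int] | None:
    """Nearest transcript TSS to the region midpoint, within ``tss_range``.

    The anchor is the region midpoint ``floor((start + end) / 2)``. The
    returned distance is signed in the transcription direction of the
    winning transcript: positive = anchor downstream of the TSS.
    Returns None when no TSS lies within range.
    """
    idx = index if index is not None else TssIndex(transcripts)
    return idx.query(region.chrom, region.midpoint, tss_range)


# typing helpers -------------------------------------------------------------

class ChromSizesLike:  # pragma: no cover - structural typing aid only
    def __getitem__(self, chrom: str) -> int: ...


class TranscriptLike:  # pragma: no cover - structural typing aid only
    chrom: str
    tss: int
    gene_symbol: str
    transcript_id: str
    strand: str
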