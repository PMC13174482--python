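"""Prioritized genomic-feature annotation and nearest-gene assignment.

Each peak is classified by where its midpoint falls relative to transcript
features, with priority promoter > 5'UTR > 3'UTR > exon > intron and
intergenic as the fallback. Independently of the feature class, the peak is
assigned its nearest gene by TSS distance within a configurable range
(default 100 kb); both a feature-attributed gene and a nearest-TSS gene are
reported because overlapping transcripts can make them differ.

The promoter is symmetric, TSS +/- promoter_flank (default 2 kb). The
classification anchor is the peak midpoint, which makes the six classes
mutually exclusive.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .intervals import AnalysisParameters, GenomicInterval, TssIndex

__all__ = [
    "FEATURE_CLASSES",
    "TranscriptModel",
    "FeatureAnnotation",
    "FeatureIndex",
    "build_feature_models",
    "annotate_peak",
    "annotate_peaks",
    "feature_distribution",
]

#: feature classes in priority order; intergenic is the fallback class
FEATURE_CLASSES = ("promoter", "utr5", "utr3", "exon", "intron", "intergenic")
_PRIORITY = {c: i for i, c in enumerate(FEATURE_CLASSES)}


@dataclass
class TranscriptModel:
    """Strand-aware gene structure in 0-based half-open coordinates.

    ``tss`` is the 5'-most transcribed position: the start of the first
    exon on the + strand, the (half-open) end of the last exon on the
    - strand. ``utr5``/``utr3`` may be given explicitly (e.g. parsed from
    a UTR-aware GTF); otherwise they are derived as the exon-minus-CDS
    set difference oriented by strand.
    """

    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds_start: int | None = None
    cds_end: int | None = None
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.transcript_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must be given together")
        if self.cds_start is not None:
            if not (self.span.start <= self.cds_start < self.cds_end <= self.span.end):
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS outside exon span"
                )

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end)

    @property
    def tss(self) -> int:
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start))
        return out

    def utr_intervals(self) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
        """(5'UTR, 3'UTR) intervals: explicit if provided, else exon \\ CDS."""
        if self.utr5 or self.utr3:
            return list(self.utr5), list(self.utr3)
        if not self.is_coding:
            return [], []
        left, right = [], []  # upstream / downstream of CDS in genome order
        for exon in self.exons:
            if exon.start < self.cds_start:
                left.append(
                    GenomicInterval(self.chrom, exon.start, min(exon.end, self.cds_start))
                )
            if exon.end > self.cds_end:
                right.append(
                    GenomicInterval(self.chrom, max(exon.start, self.cds_end), exon.end)
                )
        return (left, right) if self.strand == "+" else (right, left)


@dataclass
class FeatureAnnotation:
    """One peak's feature class and gene assignment."""

    peak: object  # PeakRecord or GenomicInterval-like
    feature_class: str
    gene_symbol: str | None = None
    transcript_id: str | None = None
    tss_distance: int | None = None
    feature_gene_symbol: str | None = None
    feature_transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")


class FeatureIndex:
    """Point-queryable index of derived feature intervals over all transcripts."""

    def __init__(
        self,
        transcripts: Sequence[TranscriptModel],
        promoter_flank: int,
        sizes: Mapping[str, int] | None = None,
    ):
        self.transcripts = list(transcripts)
        self.promoter_flank = promoter_flank
        self.tss_index = TssIndex(self.transcripts)
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for t in sorted(self.transcripts, key=lambda t: (t.gene_symbol, t.transcript_id)):
            length = sizes[t.chrom] if sizes is not None else None
            p_lo = max(0, t.tss - promoter_flank)
            p_hi = t.tss + promoter_flank
            if length is not None:
                p_hi = min(length, p_hi)
            if p_lo < p_hi:
                self._add(t.chrom, p_lo, p_hi, "promoter", t)
            u5, u3 = t.utr_intervals()
            for iv in u5:
                self._add(t.chrom, iv.start, iv.end, "utr5", t)
            for iv in u3:
                self._add(t.chrom, iv.start, iv.end, "utr3", t)
            for iv in t.exons:
                self._add(t.chrom, iv.start, iv.end, "exon", t)
            for iv in t.introns():
                self._add(t.chrom, iv.start, iv.end, "intron", t)

    def _add(self, chrom: str, start: int, end: int, cls: str, t: TranscriptModel) -> None:
        self._trees[chrom][start:end] = (cls, t.gene_symbol, t.transcript_id)

    def classify_point(self, chrom: str, pos: int) -> tuple[str, str | None, str | None]:
        """(feature class, attributed gene, attributed transcript) at a bp.

        The highest-priority class across every transcript whose derived
        features contain the point wins; among equal-priority hits the
        lexicographically smallest (gene, transcript) is attributed.
        """
        tree = self._trees.get(chrom)
        hits = tree.at(pos) if tree is not None else ()
        best: tuple[int, str, str] | None = None
        for hit in hits:
            cls, gene, tx = hit.data
            key = (_PRIORITY[cls], gene, tx)
            if best is None or key < best:
                best = key
        if best is None:
            return "intergenic", None, None
        return FEATURE_CLASSES[best[0]], best[1], best[2]


def build_feature_models(
    transcripts: Sequence[TranscriptModel],
    promoter_flank: int = 2_000,
    sizes: Mapping[str, int] | None = None,
) -> FeatureIndex:
    """Derive promoter/UTR/exon/intron intervals and index them for queries."""
    return FeatureIndex(transcripts, promoter_flank, sizes)


def _anchor(peak) -> tuple[str, int]:
    if hasattr(peak, "midpoint"):
        return peak.chrom, peak.midpoint
    return peak.chrom, (peak.start + peak.end) // 2


def annotate_peak(
    peak,
    index: FeatureIndex,
    params: AnalysisParameters | None = None,
) -> FeatureAnnotation:
    """Classify one peak by midpoint and assign its nearest-TSS gene."""
    params = params or AnalysisParameters()
    chrom, mid = _anchor(peak)
    cls, fgene, ftx = index.classify_point(chrom, mid)
    hit = index.tss_index.query(chrom, mid, params.tss_range)
    gene, tx, dist = hit if hit is not None else (None, None, None)
    return FeatureAnnotation(
        peak=peak,
        feature_class=cls,
        gene_symbol=gene,
        transcript_id=tx,
        tss_distance=dist,
        feature_gene_symbol=fgene,
        feature_transcript_id=ftx,
    )


def annotate_peaks(
    peaks: Iterable,
    index: FeatureIndex,
    params: AnalysisParameters | None = None,
) -> list[FeatureAnnotation]:
    params = params or AnalysisParameters()
    return [annotate_peak(p, index, params) for p in peaks]


def annotations_to_frame(annotations: Sequence[FeatureAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        p = a.peak
        rows.append(
            {
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "feature_class": a.feature_class,
                "gene": a.gene_symbol,
                "transcript": a.transcript_id,
                "tss_distance": a.tss_distance,
                "feature_gene": a.feature_gene_symbol,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "feature_class",
            "gene",
            "transcript",
            "tss_distance",
            "feature_gene",
        ],
    )


def feature_distribution(
    annotations: Sequence[FeatureAnnotation],
) -> tuple[dict[str, int], dict[str, float]]:
    """Counts and fractions of peaks per feature class (fractions sum to 1)."""
    if not annotations:
        raise ValueError("feature_distribution requires at least one annotation")
    counts = {c: 0 for c in FEATURE_CLASSES}
    for a in annotations:
        counts[a.feature_class] += 1
    n = len(annotations)
    fractions = {c: counts[c] / n for c in FEATURE_CLASSES}
    return counts, fractions
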