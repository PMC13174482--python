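"""Set-level bookkeeping: condition overlap, cistrome overlap, gene collapse.

These operations produce the headline counts and proportions of a
two-condition accessibility comparison: which summit windows are shared
between vehicle and ligand, how many cistrome (CUT&RUN) peaks fall in open
chromatin, and how differentially expressed genes partition across the two
conditions' open-chromatin gene repertoires. Overlap here means genomic
colocalization, not direct evidence of regulatory interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._util import fmt_pct, pct
from .intervals import GenomicInterval, overlap_pairs, summit_window

__all__ = [
    "IntegrationSummary",
    "ConditionOverlapResult",
    "DegAssociation",
    "classify_condition_overlap",
    "summarize_cistrome_overlap",
    "peaks_to_unique_genes",
    "compare_gene_sets",
    "classify_deg_association",
]


@dataclass(frozen=True)
class IntegrationSummary:
    """Counts and proportions of an asymmetric two-set overlap."""

    n_query: int
    n_subject: int
    n_query_overlapping: int
    n_subject_overlapping: int
    n_pairs: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_query_overlapping <= self.n_query:
            raise ValueError("n_query_overlapping out of range")
        if not 0 <= self.n_subject_overlapping <= self.n_subject:
            raise ValueError("n_subject_overlapping out of range")
        if self.n_pairs < max(self.n_query_overlapping, self.n_subject_overlapping):
            raise ValueError("n_pairs cannot be below either overlapping count")

    @property
    def prop_query(self) -> float:
        return self.n_query_overlapping / self.n_query if self.n_query else 0.0

    @property
    def prop_subject(self) -> float:
        return self.n_subject_overlapping / self.n_subject if self.n_subject else 0.0

    @property
    def pct_query(self) -> float:
        return pct(self.n_query_overlapping, self.n_query)

    @property
    def pct_subject(self) -> float:
        return pct(self.n_subject_overlapping, self.n_subject)

    def report(self) -> str:
        return (
            f"query: {self.n_query_overlapping}/{self.n_query} overlapping "
            f"({fmt_pct(self.n_query_overlapping, self.n_query)}); "
            f"subject: {self.n_subject_overlapping}/{self.n_subject} overlapping "
            f"({fmt_pct(self.n_subject_overlapping, self.n_subject)}); "
            f"pairs: {self.n_pairs}"
        )


@dataclass(frozen=True)
class ConditionOverlapResult:
    """Shared / condition-specific summit classification for both conditions.

    Shared counts are computed per condition: a summit of A is shared when
    its window overlaps at least one window of B, and vice versa. With
    asymmetric sets shared_a and shared_b need not be equal, so both are
    reported, each as a percentage of its own condition's total.
    """

    labels_a: tuple[bool, ...]  # True = shared
    labels_b: tuple[bool, ...]
    n_pairs: int

    @property
    def n_a(self) -> int:
        return len(self.labels_a)

    @property
    def n_b(self) -> int:
        return len(self.labels_b)

    @property
    def shared_a(self) -> int:
        return sum(self.labels_a)

    @property
    def shared_b(self) -> int:
        return sum(self.labels_b)

    @property
    def specific_a(self) -> int:
        return self.n_a - self.shared_a

    @property
    def specific_b(self) -> int:
        return self.n_b - self.shared_b

    @property
    def pct_shared_a(self) -> float:
        return pct(self.shared_a, self.n_a)

    @property
    def pct_shared_b(self) -> float:
        return pct(self.shared_b, self.n_b)

    @classmethod
    def from_counts(
        cls, shared_a: int, specific_a: int, shared_b: int, specific_b: int
    ) -> "ConditionOverlapResult":
        """Build the bookkeeping object from already-tabulated counts."""
        return cls(
            labels_a=(True,) * shared_a + (False,) * specific_a,
            labels_b=(True,) * shared_b + (False,) * specific_b,
            n_pairs=max(shared_a, shared_b),
        )

    def report(self) -> str:
        return (
            f"A: {self.shared_a} shared + {self.specific_a} specific of {self.n_a} "
            f"({fmt_pct(self.shared_a, self.n_a)} shared); "
            f"B: {self.shared_b} shared + {self.specific_b} specific of {self.n_b} "
            f"({fmt_pct(self.shared_b, self.n_b)} shared)"
        )


def classify_condition_overlap(
    summits_a: Sequence[tuple[str, int]],
    summits_b: Sequence[tuple[str, int]],
    flank: int,
    sizes: Mapping[str, int],
) -> ConditionOverlapResult:
    """Label each summit shared/specific by summit-window intersection.

    Summits are (chrom, position) pairs; each is extended to a fixed
    ``[pos - flank, pos + flank)`` window (200 bp at the default flank of
    100) and a summit is shared when its window overlaps >= 1 bp of any
    window from the other condition.
    """
    win_a = [summit_window(pos, chrom, flank, sizes) for chrom, pos in summits_a]
    win_b = [summit_window(pos, chrom, flank, sizes) for chrom, pos in summits_b]
    pairs = overlap_pairs(win_a, win_b)
    hit_a = {i for i, _ in pairs}
    hit_b = {j for _, j in pairs}
    return ConditionOverlapResult(
        labels_a=tuple(i in hit_a for i in range(len(win_a))),
        labels_b=tuple(j in hit_b for j in range(len(win_b))),
        n_pairs=len(pairs),
    )


def summarize_cistrome_overlap(
    atac_windows: Sequence[GenomicInterval],
    cistrome_peaks: Sequence[GenomicInterval],
) -> tuple[IntegrationSummary, list[GenomicInterval]]:
    """Intersect ATAC summit windows (query) with cistrome peaks (subject).

    Returns the two-directional overlap summary and the overlapping
    cistrome subset (input order preserved) for downstream gene annotation.
    """
    pairs = overlap_pairs(atac_windows, cistrome_peaks)
    hit_q = {i for i, _ in pairs}
    hit_s = sorted({j for _, j in pairs})
    summary = IntegrationSummary(
        n_query=len(atac_windows),
        n_subject=len(cistrome_peaks),
        n_query_overlapping=len(hit_q),
        n_subject_overlapping=len(hit_s),
        n_pairs=len(pairs),
    )
    return summary, [cistrome_peaks[j] for j in hit_s]


def peaks_to_unique_genes(annotations: Iterable) -> list[str]:
    """Collapse peak annotations to a sorted unique gene-symbol list.

    Annotations without an assigned gene (no TSS within range) are
    excluded.
    """
    genes = {a.gene_symbol for a in annotations if a.gene_symbol is not None}
    return sorted(genes)


def compare_gene_sets(genes_a: Iterable[str], genes_b: Iterable[str]) -> IntegrationSummary:
    """Two-condition gene-repertoire overlap (the gene-level Venn counts)."""
    sa, sb = set(genes_a), set(genes_b)
    inter = len(sa & sb)
    return IntegrationSummary(
        n_query=len(sa),
        n_subject=len(sb),
        n_query_overlapping=inter,
        n_subject_overlapping=inter,
        n_pairs=inter,
    )


@dataclass(frozen=True)
class DegAssociation:
    """One differentially expressed gene's chromatin-association class."""

    gene: str
    direction: str  # up | down | .
    in_condition_a: bool
    in_condition_b: bool

    @property
    def assoc_class(self) -> str:
        if self.in_condition_a and self.in_condition_b:
            return "shared"
        if self.in_condition_a:
            return "a_specific"
        if self.in_condition_b:
            return "b_specific"
        return "neither"


def classify_deg_association(
    degs: Sequence[str | tuple[str, str]],
    genes_a: Iterable[str],
    genes_b: Iterable[str],
    case_insensitive: bool = False,
) -> tuple[list[DegAssociation], dict[str, int]]:
    """Class each DEG by membership in the two open-chromatin gene sets.

    ``degs`` entries are gene symbols or (symbol, direction) pairs.
    Duplicate symbols are deduplicated with a warning. Matching is exact
    and case-sensitive unless ``case_insensitive``.
    """
    norm = (lambda g: g.casefold()) if case_insensitive else (lambda g: g)
    set_a = {norm(g) for g in genes_a}
    set_b = {norm(g) for g in genes_b}
    seen: dict[str, str] = {}
    order: list[tuple[str, str]] = []
    n_dup = 0
    for entry in degs:
        gene, direction = entry if isinstance(entry, tuple) else (entry, ".")
        key = norm(gene)
        if key in seen:
            n_dup += 1
            continue
        seen[key] = gene
        order.append((gene, direction))
    if n_dup:
        warnings.warn(f"{n_dup} duplicate DEG symbol(s) removed", stacklevel=2)
    out = [
        DegAssociation(
            gene=gene,
            direction=direction,
            in_condition_a=norm(gene) in set_a,
            in_condition_b=norm(gene) in set_b,
        )
        for gene, direction in order
    ]
    counts = {"shared": 0, "a_specific": 0, "b_specific": 0, "neither": 0}
    for a in out:
        counts[a.assoc_class] += 1
    return out, counts
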