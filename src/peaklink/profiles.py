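"""Aggregate signal metaprofiles: coverage tracks and anchor-centered matrices.

A coverage track counts, at every bp, how many cut-site intervals contain
it. Profile matrices average that coverage in fixed-size bins around a set
of anchors (peak centers or TSSs, +/- 2 kb by default); the column-wise
mean is the metaprofile drawn over heatmaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval

__all__ = [
    "CoverageTrack",
    "ProfileMatrix",
    "coverage_track",
    "profile_matrix",
    "mean_profile_compare",
]


class CoverageTrack:
    """Dense per-chromosome per-bp coverage with run-length bedGraph export."""

    def __init__(self, sizes: Mapping[str, int]):
        self.sizes = dict(sizes)
        self._arrays = {c: np.zeros(l, dtype=np.int32) for c, l in self.sizes.items()}

    def add_intervals(self, intervals) -> None:
        """Add coverage from intervals (iterable or array-backed CutSites)."""
        # difference-array increments, one cumsum per chromosome at the end
        diffs = {c: np.zeros(l + 1, dtype=np.int32) for c, l in self.sizes.items()}
        touched = set()
        per_chrom = getattr(intervals, "per_chrom", None)
        if per_chrom is not None:
            for chrom, (s, e) in per_chrom.items():
                if chrom not in diffs:
                    raise KeyError(f"interval on unknown chromosome {chrom!r}")
                if len(s) == 0:
                    continue
                lo = np.clip(s, 0, self.sizes[chrom])
                hi = np.clip(e, 0, self.sizes[chrom])
                np.add.at(diffs[chrom], lo, 1)
                np.add.at(diffs[chrom], hi, -1)
                touched.add(chrom)
        else:
            for iv in intervals:
                d = diffs.get(iv.chrom)
                if d is None:
                    raise KeyError(f"interval on unknown chromosome {iv.chrom!r}")
                lo = max(0, iv.start)
                hi = min(self.sizes[iv.chrom], iv.end)
                if lo < hi:
                    d[lo] += 1
                    d[hi] -= 1
                    touched.add(iv.chrom)
        for chrom in touched:
            self._arrays[chrom] += np.cumsum(diffs[chrom][:-1])

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self._arrays[chrom]

    @property
    def total_mass(self) -> int:
        return int(sum(a.sum() for a in self._arrays.values()))

    def to_runs(self) -> list[tuple[str, int, int, float]]:
        """Run-length (chrom, start, end, value) encoding, zero runs omitted."""
        runs = []
        for chrom in self.sizes:
            a = self._arrays[chrom]
            if len(a) == 0:
                continue
            change = np.flatnonzero(np.diff(a)) + 1
            bounds = np.concatenate(([0], change, [len(a)]))
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                v = int(a[lo])
                if v != 0:
                    runs.append((chrom, int(lo), int(hi), float(v)))
        return runs

    @classmethod
    def from_runs(
        cls, runs: Iterable[tuple[str, int, int, float]], sizes: Mapping[str, int]
    ) -> "CoverageTrack":
        track = cls(sizes)
        for chrom, start, end, value in runs:
            track._arrays[chrom][start:end] += int(value)
        return track


def coverage_track(
    cut_sites: Iterable[GenomicInterval], sizes: Mapping[str, int]
) -> CoverageTrack:
    """Per-bp coverage: coverage[x] = number of intervals containing x."""
    track = CoverageTrack(sizes)
    track.add_intervals(cut_sites)
    return track


@dataclass
class ProfileMatrix:
    """Anchors x bins matrix of mean per-bp coverage around each anchor."""

    anchors: list[tuple[str, int, str]]  # (chrom, position, strand)
    flank: int
    bin_size: int
    matrix: np.ndarray

    @property
    def n_bins(self) -> int:
        return 2 * self.flank // self.bin_size

    @property
    def mean_profile(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            return np.nanmean(self.matrix, axis=0)

    def sorted_by_row_mean(self) -> "ProfileMatrix":
        """Stable descending sort by row mean, for heatmap export."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(self.matrix, axis=1)
        means = np.where(np.isnan(means), -np.inf, means)
        order = np.argsort(-means, kind="stable")
        return ProfileMatrix(
            anchors=[self.anchors[i] for i in order],
            flank=self.flank,
            bin_size=self.bin_size,
            matrix=self.matrix[order],
        )

    def plot(self, ax=None, label: str | None = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(self.n_bins) * self.bin_size - self.flank + self.bin_size / 2
        ax.plot(x, self.mean_profile, label=label)
        ax.set_xlabel("distance from anchor (bp)")
        ax.set_ylabel("mean coverage")
        if label:
            ax.legend(frameon=False)
        return ax


def _normalize_anchor(anchor) -> tuple[str, int, str]:
    if isinstance(anchor, tuple):
        if len(anchor) == 2:
            return anchor[0], anchor[1], "."
        return anchor[0], anchor[1], anchor[2]
    return anchor.chrom, anchor.midpoint, getattr(anchor, "strand", ".")


def profile_matrix(
    coverage: CoverageTrack,
    anchors: Sequence,
    flank: int = 2_000,
    bin_size: int = 10,
    strand_aware: bool = False,
    pad_edges: bool = False,
) -> ProfileMatrix:
    """Bin coverage in ``[anchor - flank, anchor + flank)`` around each anchor.

    Anchors are (chrom, position[, strand]) tuples or interval-like objects
    (anchored at their midpoint). Bins truncated by a chromosome edge are
    averaged over the available bp unless ``pad_edges``, which zero-pads
    instead. With ``strand_aware``, rows of minus-strand anchors are
    reversed so transcription direction reads left to right. Anchors on
    unknown chromosomes or outside them give all-NaN rows with a warning.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    norm = [_normalize_anchor(a) for a in anchors]
    n_bins = 2 * flank // bin_size
    matrix = np.full((len(norm), n_bins), np.nan)
    n_bad = 0
    for i, (chrom, pos, strand) in enumerate(norm):
        length = coverage.sizes.get(chrom)
        if length is None or not 0 <= pos < length:
            n_bad += 1
            continue
        lo, hi = pos - flank, pos + flank
        arr = coverage[chrom]
        if lo >= 0 and hi <= length:
            row = arr[lo:hi].reshape(n_bins, bin_size).mean(axis=1)
        else:
            row = np.empty(n_bins)
            for j in range(n_bins):
                b_lo, b_hi = max(0, lo + j * bin_size), min(length, lo + (j + 1) * bin_size)
                if b_hi <= b_lo:
                    row[j] = 0.0 if pad_edges else np.nan
                elif pad_edges:
                    row[j] = arr[b_lo:b_hi].sum() / bin_size
                else:
                    row[j] = arr[b_lo:b_hi].mean()
        if strand_aware and strand == "-":
            row = row[::-1]
        matrix[i] = row
    if n_bad:
        warnings.warn(f"{n_bad} anchor(s) outside chromosomes: NaN rows", stacklevel=2)
    return ProfileMatrix(anchors=norm, flank=flank, bin_size=bin_size, matrix=matrix)


@dataclass
class ProfileComparison:
    """Elementwise and summary comparison of two equal-shape profile matrices."""

    diff_matrix: np.ndarray
    mean_diff: np.ndarray  # per-bin difference of mean profiles (b - a)
    center_mean_a: float
    center_mean_b: float
    auc_a: float
    auc_b: float

    @property
    def center_ratio(self) -> float:
        return self.center_mean_b / self.center_mean_a if self.center_mean_a else np.inf


def mean_profile_compare(a: ProfileMatrix, b: ProfileMatrix) -> ProfileComparison:
    """Compare two matrices (b relative to a): per-bin difference + summaries.

    The "center" summary averages the two central bins (the bp around the
    anchor); AUC is the bin-width-weighted sum of the mean profile.
    """
    if a.matrix.shape != b.matrix.shape or a.bin_size != b.bin_size:
        raise ValueError("profile matrices must have identical shape and binning")
    pa, pb = a.mean_profile, b.mean_profile
    mid = a.n_bins // 2
    center = slice(mid - 1, mid + 1)
    return ProfileComparison(
        diff_matrix=b.matrix - a.matrix,
        mean_diff=pb - pa,
        center_mean_a=float(np.nanmean(pa[center])),
        center_mean_b=float(np.nanmean(pb[center])),
        auc_a=float(np.nansum(pa) * a.bin_size),
        auc_b=float(np.nansum(pb) * b.bin_size),
    )
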