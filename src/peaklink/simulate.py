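"""Synthetic study generator: every pipeline input, with recorded ground truth.

The generator emulates the design of a two-condition (vehicle vs ligand)
chromatin-accessibility study with three replicates per condition: a small
multi-chromosome genome with gene models, two condition peak sets with a
controlled shared fraction, per-replicate cut-site data with background vs
in-peak enrichment and planted differential regions, a DEG list with a
controlled chromatin-linked fraction, and a cistrome peak set with a
controlled overlap fraction.

Placement is construction-guaranteed rather than probabilistic wherever a
downstream stage is supposed to recover a planted quantity exactly:

* summit slots are laid on a grid spaced well beyond twice the summit
  flank, so within-condition windows never collide and the planted shared
  fraction is recovered exactly by window-overlap classification;
* each chromosome reserves a trailing peak-free zone where "guaranteed
  unlinked" genes and non-overlapping cistrome peaks live.

Every generator is a pure function of its config: identical outputs for
identical (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .annotation import TranscriptModel
from .differential import CutSites, RegionSignal
from .intervals import AnalysisParameters, GenomicInterval, TssIndex, merge_intervals, summit_window
from .io_formats import ChromSizes, PeakRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedStudy",
    "generate_annotation",
    "generate_condition_peaks",
    "generate_fragments",
    "generate_deg_list",
    "generate_cistrome",
    "simulate_region_counts",
    "simulate_study",
]

VEHICLE = "vehicle"
LIGAND = "ligand"

# substream ids so stages draw from independent, reproducible streams
_STREAM_ANNOTATION = 1
_STREAM_PEAKS = 2
_STREAM_FRAGMENTS = 3
_STREAM_DEGS = 4
_STREAM_CISTROME = 5
_STREAM_DAR = 6


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic two-condition experiment.

    Defaults are the desk-scale study conditions: 2 chromosomes x 5 Mb,
    300 genes, 2,000 peaks per condition with 80% of summits shared
    between conditions, 3 replicates per condition at 500k cut sites each
    with 5-fold in-peak enrichment, 100 planted 8-fold differential
    regions, 200 DEGs of which 80% are chromatin-linked, and 600 cistrome
    peaks of which 60% overlap accessible windows.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 300
    exons_per_gene: int = 3
    n_peaks_per_condition: int = 2_000
    shared_fraction: float = 0.80
    n_replicates: int = 3
    depth: int = 500_000
    peak_enrichment: float = 5.0
    n_dar: int = 100
    dar_log2fc: float = 3.0
    deg_count: int = 200
    deg_linked_fraction: float = 0.80
    cistrome_count: int = 600
    cistrome_overlap_fraction: float = 0.60
    summit_flank: int = 100
    cut_width: int = 9
    peak_spacing: int = 1_000
    peak_free_zone: int = 1_000_000
    edge_margin: int = 2_000

    def __post_init__(self) -> None:
        for name in ("shared_fraction", "deg_linked_fraction", "cistrome_overlap_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in (
            "n_chroms",
            "chrom_length",
            "exons_per_gene",
            "n_peaks_per_condition",
            "n_replicates",
            "summit_flank",
            "cut_width",
            "peak_spacing",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_genes", "depth", "n_dar", "deg_count", "cistrome_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.peak_enrichment < 1:
            raise ValueError("peak_enrichment must be >= 1")
        if self.peak_spacing <= 2 * self.summit_flank:
            raise ValueError("peak_spacing must exceed the summit window width")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    def chrom_sizes(self) -> ChromSizes:
        return ChromSizes(
            (f"chr{i + 1}", self.chrom_length) for i in range(self.n_chroms)
        )


@dataclass
class GroundTruth:
    """Planted quantities, aligned with the emitted records."""

    shared_summits: set[tuple[str, int]] = field(default_factory=set)
    labels_a: list[bool] = field(default_factory=list)  # per peaks_a record
    labels_b: list[bool] = field(default_factory=list)
    dar_flags: np.ndarray | None = None  # per merged region, True = planted
    deg_linked: dict[str, bool] = field(default_factory=dict)
    cistrome_overlap: list[bool] = field(default_factory=list)


def generate_annotation(
    config: SimulationConfig,
) -> tuple[list[TranscriptModel], ChromSizes]:
    """Gene models placed without overlap on the synthetic genome.

    Genes alternate strand, each with ``exons_per_gene`` exons and a CDS
    leaving non-empty UTRs at both ends. One transcript per gene.
    """
    sizes = config.chrom_sizes()
    transcripts: list[TranscriptModel] = []
    if config.n_genes == 0:
        return transcripts, sizes
    rng = config.rng(_STREAM_ANNOTATION)
    chroms = list(sizes)
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    min_exon, min_intron = 200, 100
    min_gene = config.exons_per_gene * min_exon + (config.exons_per_gene - 1) * min_intron
    gene_idx = 0
    for chrom, n_here in zip(chroms, per_chrom):
        if n_here == 0:
            continue
        slot = config.chrom_length // n_here
        if slot < min_gene + 400:
            raise ValueError(
                f"genes do not fit: need chrom_length >= {n_here * (min_gene + 400)}"
            )
        for j in range(n_here):
            gene_len = int(rng.integers(min_gene, min(3 * min_gene, slot - 200) + 1))
            offset = int(rng.integers(0, slot - gene_len - 100))
            gstart = j * slot + offset
            # partition the gene span into alternating exon/intron segments
            k = config.exons_per_gene
            n_seg = 2 * k - 1
            mins = np.array([min_exon if s % 2 == 0 else min_intron for s in range(n_seg)])
            spare = gene_len - mins.sum()
            extra = rng.multinomial(spare, np.full(n_seg, 1 / n_seg))
            seg_lens = mins + extra
            bounds = gstart + np.concatenate(([0], np.cumsum(seg_lens)))
            exons = [
                GenomicInterval(chrom, int(bounds[2 * s]), int(bounds[2 * s + 1]))
                for s in range(k)
            ]
            first, last = exons[0], exons[-1]
            u5 = int(rng.integers(50, min(150, first.width - 50) + 1))
            u3 = int(rng.integers(50, min(150, last.width - 50) + 1))
            transcripts.append(
                TranscriptModel(
                    gene_symbol=f"GENE{gene_idx + 1:04d}",
                    transcript_id=f"TX{gene_idx + 1:04d}",
                    chrom=chrom,
                    strand="+" if gene_idx % 2 == 0 else "-",
                    exons=exons,
                    cds_start=first.start + u5,
                    cds_end=last.end - u3,
                )
            )
            gene_idx += 1
    return transcripts, sizes


def _summit_slots(config: SimulationConfig) -> list[tuple[str, int]]:
    """Grid positions where summits may be planted (outside the free zone)."""
    slots = []
    lo = config.edge_margin
    hi = config.chrom_length - config.peak_free_zone - config.edge_margin
    for i in range(config.n_chroms):
        chrom = f"chr{i + 1}"
        slots.extend((chrom, int(p)) for p in range(lo, hi, config.peak_spacing))
    return slots


def generate_condition_peaks(
    config: SimulationConfig,
) -> tuple[list[PeakRecord], list[PeakRecord], GroundTruth]:
    """Two condition peak sets whose summit windows plant the shared fraction.

    Exactly round(shared_fraction * n) summit positions are identical
    between conditions; every other summit sits on its own grid slot, so
    no unintended window overlap is possible and window-overlap
    classification recovers the planted counts exactly.
    """
    rng = config.rng(_STREAM_PEAKS)
    n = config.n_peaks_per_condition
    n_shared = round(config.shared_fraction * n)
    n_spec = n - n_shared
    slots = _summit_slots(config)
    need = n_shared + 2 * n_spec
    if need > len(slots):
        raise ValueError(
            f"infeasible peak density: need {need} summit slots, have {len(slots)}"
        )
    chosen = rng.choice(len(slots), size=need, replace=False)
    shared = [slots[i] for i in chosen[:n_shared]]
    spec_a = [slots[i] for i in chosen[n_shared : n_shared + n_spec]]
    spec_b = [slots[i] for i in chosen[n_shared + n_spec :]]

    def build(summits: list[tuple[str, int]], labels: list[bool], prefix: str):
        recs = []
        for (chrom, pos), shared_flag in zip(summits, labels):
            left = int(rng.integers(100, 251))
            right = int(rng.integers(100, 251))
            recs.append(
                (
                    PeakRecord(
                        chrom=chrom,
                        start=pos - left,
                        end=pos + right,
                        name="",  # renamed after sorting
                        score=float(rng.integers(100, 1000)),
                        strand=".",
                        signal=float(np.round(rng.uniform(2, 10), 3)),
                        summit_offset=left,
                    ),
                    shared_flag,
                )
            )
        recs.sort(key=lambda t: (t[0].chrom, t[0].start))
        out_recs, out_labels = [], []
        for k, (r, flag) in enumerate(recs):
            out_recs.append(replace(r, name=f"{prefix}_{k + 1:05d}"))
            out_labels.append(flag)
        return out_recs, out_labels

    peaks_a, labels_a = build(shared + spec_a, [True] * n_shared + [False] * n_spec, "veh")
    peaks_b, labels_b = build(shared + spec_b, [True] * n_shared + [False] * n_spec, "lig")
    truth = GroundTruth(
        shared_summits=set(shared), labels_a=labels_a, labels_b=labels_b
    )
    return peaks_a, peaks_b, truth


def _region_probs(
    regions: Sequence[GenomicInterval],
    dar_flags: np.ndarray,
    config: SimulationConfig,
    condition: str,
) -> tuple[np.ndarray, float]:
    """(per-region extra-mass probabilities, background probability).

    Per-bp rate is 1 outside regions and E inside, where E is
    ``peak_enrichment`` scaled by 2**dar_log2fc in the treated condition
    at planted regions. The background category is uniform over the whole
    genome, so the total per-bp rate inside region i is exactly E_i.
    """
    genome = config.n_chroms * config.chrom_length
    widths = np.array([r.width for r in regions], dtype=float)
    enrich = np.full(len(regions), config.peak_enrichment)
    if condition == LIGAND and dar_flags is not None:
        enrich[dar_flags] *= 2.0 ** config.dar_log2fc
    extra = widths * (enrich - 1.0)
    total = genome + extra.sum()
    return extra / total, genome / total


def generate_fragments(
    config: SimulationConfig,
    regions: Sequence[GenomicInterval],
    dar_flags: np.ndarray | None = None,
) -> tuple[dict[str, CutSites], dict[str, str]]:
    """Per-sample cut sites: multinomial background + in-region enrichment.

    Each sample draws ``depth`` cut-site start positions; region category
    counts are multinomial, hence marginally binomial, which is the
    analytic oracle for calibration checks. Returns (cut sites by sample,
    condition by sample).
    """
    rng = config.rng(_STREAM_FRAGMENTS)
    sizes = config.chrom_sizes()
    chroms = list(sizes)
    genome = config.n_chroms * config.chrom_length
    if dar_flags is None:
        dar_flags = np.zeros(len(regions), dtype=bool)
    cuts: dict[str, CutSites] = {}
    conditions: dict[str, str] = {}
    for condition in (VEHICLE, LIGAND):
        extra_p, bg_p = _region_probs(regions, dar_flags, config, condition)
        probs = np.concatenate(([bg_p], extra_p))
        for rep in range(config.n_replicates):
            label = f"{condition}_{rep + 1}"
            conditions[label] = condition
            if config.depth == 0:
                cuts[label] = CutSites({})
                continue
            counts = rng.multinomial(config.depth, probs)
            pos_chunks: dict[str, list[np.ndarray]] = {c: [] for c in chroms}
            # background: uniform over the concatenated genome
            flat = rng.integers(0, genome, size=counts[0])
            for ci, chrom in enumerate(chroms):
                lo, hi = ci * config.chrom_length, (ci + 1) * config.chrom_length
                sel = flat[(flat >= lo) & (flat < hi)]
                pos_chunks[chrom].append(sel - lo)
            # in-region extra mass: uniform within each region
            for ri, region in enumerate(regions):
                k = counts[ri + 1]
                if k:
                    pos_chunks[region.chrom].append(
                        rng.integers(region.start, region.end, size=k)
                    )
            per_chrom = {}
            for chrom in chroms:
                if pos_chunks[chrom]:
                    starts = np.sort(np.concatenate(pos_chunks[chrom]))
                    ends = np.minimum(starts + config.cut_width, sizes[chrom])
                    per_chrom[chrom] = (starts, ends)
            cuts[label] = CutSites(per_chrom)
    return cuts, conditions


def simulate_region_counts(
    n_regions: int,
    n_replicates: int = 3,
    depth: int = 500_000,
    region_width: int = 400,
    peak_enrichment: float = 5.0,
    n_dar: int = 0,
    dar_log2fc: float = 0.0,
    genome_length: int = 10_000_000,
    seed: int = 0,
) -> tuple[RegionSignal, np.ndarray]:
    """Direct multinomial draw of the per-region count matrix.

    Marginally identical to running `generate_fragments` + counting (minus
    boundary spill-in of cut sites starting just upstream of a region);
    used for fast null-calibration and power studies. Regions are laid on
    a synthetic chromosome for coordinate bookkeeping only.
    """
    rng = np.random.default_rng(seed)
    gap = 1_000
    regions = [
        GenomicInterval("chrSim", i * (region_width + gap), i * (region_width + gap) + region_width)
        for i in range(n_regions)
    ]
    dar_flags = np.zeros(n_regions, dtype=bool)
    if n_dar:
        dar_flags[rng.choice(n_regions, size=n_dar, replace=False)] = True
    cfg = SimulationConfig(
        seed=seed,
        chrom_length=max(genome_length, (region_width + gap) * n_regions + 1),
        n_chroms=1,
        peak_enrichment=peak_enrichment,
        dar_log2fc=dar_log2fc,
        depth=depth,
        n_replicates=n_replicates,
    )
    labels, conditions, cols = [], [], []
    for condition in (VEHICLE, LIGAND):
        extra_p, bg_p = _region_probs(regions, dar_flags, cfg, condition)
        widths = np.array([r.width for r in regions], dtype=float)
        genome = cfg.n_chroms * cfg.chrom_length
        # in-region start probability = extra mass + uniform background share
        p_in = extra_p + bg_p * widths / genome
        probs = np.concatenate((p_in, [1.0 - p_in.sum()]))
        for rep in range(n_replicates):
            labels.append(f"{condition}_{rep + 1}")
            conditions.append(condition)
            cols.append(rng.multinomial(depth, probs)[:-1])
    counts = np.column_stack(cols)
    signal = RegionSignal(
        regions=regions,
        counts=counts,
        sample_labels=labels,
        conditions=conditions,
        library_sizes=np.full(len(labels), depth),
    )
    return signal, dar_flags


def generate_deg_list(
    config: SimulationConfig,
    transcripts: Sequence[TranscriptModel],
    peaks_a: Sequence[PeakRecord],
    peaks_b: Sequence[PeakRecord],
    params: AnalysisParameters | None = None,
) -> tuple[list[tuple[str, str]], dict[str, bool]]:
    """DEG list with a controlled chromatin-linked fraction.

    Linked DEGs are drawn from genes that are the nearest-TSS assignment
    of at least one peak in *both* conditions; unlinked DEGs from genes
    with no peak midpoint within ``tss_range`` of their TSS in either
    condition (guaranteed by the peak-free zone). Directions are random.
    """
    params = params or AnalysisParameters()
    rng = config.rng(_STREAM_DEGS)
    index = TssIndex(transcripts)

    def gene_set(peaks: Sequence[PeakRecord]) -> set[str]:
        out = set()
        for p in peaks:
            hit = index.query(p.chrom, p.midpoint, params.tss_range)
            if hit is not None:
                out.add(hit[0])
        return out

    genes_a = gene_set(peaks_a)
    genes_b = gene_set(peaks_b)
    mids: dict[str, np.ndarray] = {}
    for p in list(peaks_a) + list(peaks_b):
        mids.setdefault(p.chrom, [])
    for p in list(peaks_a) + list(peaks_b):
        mids[p.chrom].append(p.midpoint)
    mids = {c: np.sort(np.array(v)) for c, v in mids.items()}

    def has_nearby_peak(t: TranscriptModel) -> bool:
        arr = mids.get(t.chrom)
        if arr is None or len(arr) == 0:
            return False
        k = int(np.searchsorted(arr, t.tss))
        best = min(
            (abs(int(arr[i]) - t.tss) for i in (k - 1, k) if 0 <= i < len(arr)),
            default=None,
        )
        return best is not None and best <= params.tss_range

    linked_pool = sorted(genes_a & genes_b)
    unlinked_pool = sorted(
        t.gene_symbol for t in transcripts if not has_nearby_peak(t)
    )
    n_linked = round(config.deg_linked_fraction * config.deg_count)
    n_unlinked = config.deg_count - n_linked
    if n_linked > len(linked_pool):
        raise ValueError(
            f"cannot satisfy linkage: need {n_linked} linked genes, "
            f"have {len(linked_pool)}"
        )
    if n_unlinked > len(unlinked_pool):
        raise ValueError(
            f"cannot satisfy linkage: need {n_unlinked} unlinked genes, "
            f"have {len(unlinked_pool)} (grow the peak-free zone or gene count)"
        )
    chosen_linked = [linked_pool[i] for i in rng.choice(len(linked_pool), n_linked, replace=False)] if n_linked else []
    chosen_unlinked = [unlinked_pool[i] for i in rng.choice(len(unlinked_pool), n_unlinked, replace=False)] if n_unlinked else []
    degs = [
        (g, str(rng.choice(["up", "down"])))
        for g in sorted(chosen_linked + chosen_unlinked)
    ]
    truth = {g: True for g in chosen_linked}
    truth.update({g: False for g in chosen_unlinked})
    return degs, truth


def generate_cistrome(
    config: SimulationConfig,
    atac_windows: Sequence[GenomicInterval],
) -> tuple[list[GenomicInterval], list[bool]]:
    """Cistrome peaks with a controlled ATAC-window overlap fraction.

    round(fraction * count) peaks are centered on distinct ATAC windows;
    the rest are laid on a grid inside the peak-free zone, clear of every
    window. Returned sorted by coordinate with aligned overlap labels.
    """
    rng = config.rng(_STREAM_CISTROME)
    n_ov = round(config.cistrome_overlap_fraction * config.cistrome_count)
    n_non = config.cistrome_count - n_ov
    if n_ov > len(atac_windows):
        raise ValueError(
            f"infeasible: need {n_ov} overlapping cistrome peaks, "
            f"only {len(atac_windows)} ATAC windows"
        )
    zone_lo = config.chrom_length - config.peak_free_zone + config.edge_margin
    zone_hi = config.chrom_length - config.edge_margin
    zone_slots = [
        (f"chr{i + 1}", int(p))
        for i in range(config.n_chroms)
        for p in range(zone_lo, zone_hi, config.peak_spacing)
    ]
    if n_non > len(zone_slots):
        raise ValueError(
            f"infeasible: need {n_non} non-overlapping cistrome peaks, "
            f"have {len(zone_slots)} free-zone slots"
        )
    records: list[tuple[GenomicInterval, bool]] = []
    if n_ov:
        for wi in rng.choice(len(atac_windows), size=n_ov, replace=False):
            w = atac_windows[int(wi)]
            center = (w.start + w.end) // 2
            half = int(rng.integers(100, 201))
            records.append(
                (GenomicInterval(w.chrom, max(0, center - half), center + half), True)
            )
    if n_non:
        for si in rng.choice(len(zone_slots), size=n_non, replace=False):
            chrom, pos = zone_slots[int(si)]
            half = int(rng.integers(100, 201))
            records.append((GenomicInterval(chrom, pos - half, pos + half), False))
    records.sort(key=lambda t: (t[0].chrom, t[0].start))
    return [r for r, _ in records], [f for _, f in records]


@dataclass
class SimulatedStudy:
    """Everything one pipeline run consumes, plus the ground truth."""

    config: SimulationConfig
    params: AnalysisParameters
    sizes: ChromSizes
    transcripts: list[TranscriptModel]
    peaks_vehicle: list[PeakRecord]
    peaks_ligand: list[PeakRecord]
    merged_regions: list[GenomicInterval]
    cut_sites: dict[str, CutSites]
    conditions: dict[str, str]
    degs: list[tuple[str, str]]
    cistrome: list[GenomicInterval]
    truth: GroundTruth

    def summits(self, condition: str) -> list[tuple[str, int]]:
        peaks = self.peaks_vehicle if condition == VEHICLE else self.peaks_ligand
        return [(p.chrom, p.summit) for p in peaks]

    def summit_windows(self, condition: str) -> list[GenomicInterval]:
        return [
            summit_window(pos, chrom, self.config.summit_flank, self.sizes)
            for chrom, pos in self.summits(condition)
        ]


def simulate_study(
    config: SimulationConfig | None = None,
    params: AnalysisParameters | None = None,
) -> SimulatedStudy:
    """Generate a complete synthetic study from one config."""
    config = config or SimulationConfig()
    params = params or AnalysisParameters(
        summit_flank=config.summit_flank, cut_width=config.cut_width
    )
    transcripts, sizes = generate_annotation(config)
    peaks_a, peaks_b, truth = generate_condition_peaks(config)
    regions = merge_intervals(
        [p.interval() for p in peaks_a + peaks_b], params.merge_gap
    )
    rng = config.rng(_STREAM_DAR)
    dar_flags = np.zeros(len(regions), dtype=bool)
    if config.n_dar:
        if config.n_dar > len(regions):
            raise ValueError("n_dar exceeds the number of merged regions")
        dar_flags[rng.choice(len(regions), size=config.n_dar, replace=False)] = True
    truth.dar_flags = dar_flags
    cut_sites, conditions = generate_fragments(config, regions, dar_flags)
    degs, deg_truth = generate_deg_list(config, transcripts, peaks_a, peaks_b, params)
    truth.deg_linked = deg_truth
    windows_b = [
        summit_window(p.summit, p.chrom, config.summit_flank, sizes) for p in peaks_b
    ]
    cistrome, cist_labels = generate_cistrome(config, windows_b)
    truth.cistrome_overlap = cist_labels
    return SimulatedStudy(
        config=config,
        params=params,
        sizes=sizes,
        transcripts=transcripts,
        peaks_vehicle=peaks_a,
        peaks_ligand=peaks_b,
        merged_regions=regions,
        cut_sites=cut_sites,
        conditions=conditions,
        degs=degs,
        cistrome=cistrome,
        truth=truth,
    )
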