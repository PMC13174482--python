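# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open (the BED convention). GTF
input (1-based inclusive) has 1 subtracted from feature starts on read and
added back on write. The TSS is the 5′-most transcribed position: the
start of the first exon on the + strand and the half-open end coordinate
of the last exon on the − strand. Parsing is strict: malformed lines raise
with their line number, and no record is ever silently dropped.

## Summit-window overlap model

Peak summits (single-bp positions, from narrowPeak column 10 or summit
BED) are extended to fixed windows `[s − f, s + f)` with `f = 100` bp,
clipped at chromosome ends. A summit of condition A is **shared** iff its
window shares ≥ 1 bp with any window of condition B; window intersection
is computed with an interval tree. "Within 100 bp" merging uses the most
permissive reading: two intervals merge when `next.start − prev.end ≤
gap`, so touching intervals and intervals exactly `gap` apart both merge.

Shared counts are computed and reported **per condition**. For asymmetric
peak sets a single shared count is not well defined (several windows of
one condition can hit one window of the other), so each condition's
shared count is shown as a percentage of that condition's own total.
Percentages are rounded half-up to two decimals in reports.

Overlap is colocalization: intersecting a summit window with a cistrome
peak or assigning a nearby gene asserts genomic proximity, not a direct
regulatory interaction.

## Feature annotation

Classification anchors on the **peak midpoint** `floor((start + end)/2)`,
which makes the six classes mutually exclusive. Per transcript the derived
intervals are: promoter = TSS ± `promoter_flank` (2 kb default, symmetric
— "within 2 kb of the TSS" is ambiguous about sidedness and the symmetric
reading matches the common annotator convention); 5′/3′UTRs taken from
explicit UTR features when the annotation provides them, otherwise from
the exon-minus-CDS set difference oriented by strand; exons; introns =
gene span minus exons. The midpoint is tested against every transcript's
intervals and the highest-priority class wins, priority
promoter > 5′UTR > 3′UTR > exon > intron, intergenic as fallback. Among
equal-priority hits from overlapping transcripts the lexicographically
smallest (gene, transcript) is attributed; because the nearest-TSS gene
can differ from the feature-attributed gene, both are reported.

Nearest-gene assignment minimizes |midpoint − TSS| over all transcripts
within `tss_range` (100 kb default). Ties break deterministically by
|distance|, then gene symbol, then transcript id. The reported distance is
signed in the transcription direction of the winning transcript (positive
= downstream of the TSS).

## Differential accessibility

**Signal unit.** The accessibility signal is the Tn5 cut site: the first
`cut_width = 9` bp at each read 5′ end (both ends for an unstranded
fragment). No Tn5 +4/−5 offset is applied by default; the cut-site rule is
purely positional. A `downsample_fragments` operation provides read-level
down-sampling for workflow parity with full-scale studies (where the
normalization target is 100 million reads per sample).

**Counting and normalization.** Cut sites are counted per merged region
(≥ 1 bp overlap) per sample. With the default 100 bp merge gap and 9 bp
cut sites no cut site can straddle two regions; if regions closer than
the cut width are supplied, a straddling cut increments each region it
overlaps and a warning is raised. Desk-scale normalization scales each
sample to a common in-region total (counts per 10 million); this is a
pure library-size scaling, so under strong, asymmetric planted signal it
exhibits the usual compositional shift — regions that do not change in
absolute signal drift slightly negative when a large fraction of in-region
mass moves into up-regulated regions. This is inherent to scaling
normalization (the reason count-model tools use median-of-ratios
factors) and is visible in the test suite's strong-effect scenarios; at
the default study conditions (100 planted regions of 2,400, ≤ 40-fold
local mass) the drift stays well below the |log2FC| ≥ 1 call threshold.

**Test.** Per region, `y = log2(normalized + 1)`; log2FC = mean(y,
treatment) − mean(y, control); two-sided two-sample t-test on y with
pooled variance by default. The pooled choice is deliberate: the design
is balanced (equal replicate numbers) with a common dispersion model, and
at 3 vs 3 the Welch–Satterthwaite degree-of-freedom estimate makes
Welch's test markedly conservative (measured null rejection ≈ 0.034 at
α = 0.05 versus ≈ 0.049 for the pooled test on the null generator);
`equal_var=False` selects Welch for unbalanced or heteroscedastic data.
Degenerate regions: all values identical across both groups → p = 1;
zero variance within both groups but shifted between them → p = 0. NaN
p-values (should not occur) map to 1. Benjamini–Hochberg adjustment is
applied across all tested regions (statsmodels step-up), and regions are
classed increased/decreased when adj p < 0.05 and |log2FC| ≥ 1, both
configurable. Genome-scale differential-region counts from full-scale
studies are not an exact reproduction target: such counts depend on the
exact test, thresholds and raw sequencing data, none of which are inputs
at desk scale.

## Signal profiles

Coverage[x] = number of cut-site intervals containing bp x, stored as
dense per-chromosome arrays with run-length bedGraph export — at the
package's desk-scale genomes (tens of Mb) dense arrays are simpler and
faster than interval bookkeeping. Profile matrices average coverage in
`bin_size` (10 bp) bins over anchor ± `flank` (2 kb); bins truncated by a
chromosome edge average over their available bp (avoiding artificial edge
dips; `pad_edges=True` zero-pads instead), anchors outside the genome
give NaN rows with a warning, and minus-strand rows are reversed under
`strand_aware` so transcription reads left-to-right. Row order follows
anchor order; a stable descending sort by row mean is provided for
heatmap export.

## Comparative Ct

Per measurement ΔCt = Ct(target) − Ct(reference); the group statistic is
ΔΔCt = mean ΔCt(treated) − mean ΔCt(control) and the fold change is
2^−ΔΔCt, so the control group is 1 by construction and each cycle of
advantage doubles the estimate. Replicate ΔCt values are aggregated by
their mean — the conventional reading of the comparative-Ct guideline —
and per-replicate fold changes (each treated replicate against the
control mean) are emitted for dispersion display. Efficiency correction
(Pfaffl-style) is out of scope. Ct values outside 5–40 cycles warn but
are accepted.

## Synthetic study generator

The generator emulates a two-condition (vehicle vs ligand), three-
replicate accessibility study at desk scale. Defaults: 2 chromosomes ×
5 Mb, 300 genes (3 exons each, CDS placed to leave non-empty UTRs,
alternating strands, non-overlapping), 2,000 peaks per condition with
shared fraction 0.80 (the vehicle-side regime of the motivating study),
500k cut sites per sample with 5-fold in-peak enrichment, 100 planted
differential regions at log2FC = 3 (8-fold), 200 DEGs with linked
fraction 0.80, and 600 cistrome peaks with overlap fraction 0.60. The
full default study generates in about one second.

Planted quantities are **construction-guaranteed**, not probabilistic:

- Summits sit on a grid spaced 1,000 bp (≫ the 200 bp window width), so
  within-condition windows never collide, shared summits are placed at
  identical positions in both conditions, and condition-specific summits
  occupy their own slots — window classification recovers the planted
  shared count exactly.
- Each chromosome reserves a trailing 1 Mb peak-free zone. Guaranteed-
  unlinked DEGs are drawn from genes whose TSS is > 100 kb from every
  peak midpoint (they live in the zone), and non-overlapping cistrome
  peaks are laid on a grid inside it; linked DEGs are drawn from genes
  that are the nearest-TSS assignment of peaks in both conditions.
- Cut sites are drawn multinomially: a background category uniform over
  the genome (per-bp rate 1) plus per-region extra-mass categories
  (bringing the in-region per-bp rate to `peak_enrichment`, times
  2^log2FC in the treated condition at planted regions). Per-region
  counts are therefore marginally binomial — the analytic oracle used by
  the calibration tests. `simulate_region_counts` draws that marginal
  directly for fast null and power studies.

Every generator is a pure function of (config, seed), using per-stage
independent substreams, so outputs are record-identical across runs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: fragment-length mixtures and nucleosome
periodicity, GC and mappability bias, chromatin-domain structure,
overlapping genes and multi-isoform loci, irregular peak spacing (real
summits can sit within one window width of each other, where per-condition
shared counts genuinely diverge), and overdispersion beyond multinomial
sampling (real replicate variance exceeds binomial, which is why the
pooled t on log counts, not a count GLM, is the desk-scale default).

## Numerical and edge-case choices

- Merging with `max_gap = 0` merges exactly the touching/overlapping
  intervals; negative gaps are rejected.
- Summit windows clip at chromosome edges (width < 2f only there).
- Empty overlap inputs give zero-count summaries, not errors; an empty
  annotation list is an error for distributions (a fraction over nothing
  is undefined).
- Gene-symbol matching is exact and case-sensitive; a case-insensitive
  switch exists for messy inputs. Duplicate DEG symbols deduplicate with
  a warning.
- Down-sampling keeps input order and is deterministic per seed.
- All report percentages round half-up at two decimals; internal values
  stay full-precision.

## Known limitations

- The differential model is a two-group location test on log-transformed
  scaled counts: no dispersion shrinkage, no GLM, no batch terms. It is
  calibrated and powerful at the generator's conditions; heavily
  overdispersed real data would need count-model tooling.
- Scaling normalization carries the compositional caveat described above.
- Annotation assigns one transcript per class decision and one nearest
  gene; it does not model enhancer–promoter looping or k-nearest
  relations.
- BAM/FASTQ/bigWig are out of scope; inputs are text formats (BED,
  narrowPeak, GTF, bedGraph, TSV).
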