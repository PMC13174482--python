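"""Generator determinism, self-consistency and planted-quantity recovery."""

import numpy as np
import pytest

from peaklink import (
    AnalysisParameters,
    SimulationConfig,
    TssIndex,
    classify_condition_overlap,
    classify_deg_association,
    merge_intervals,
    simulate_region_counts,
    summarize_cistrome_overlap,
)
from peaklink.simulate import (
    generate_annotation,
    generate_cistrome,
    generate_condition_peaks,
    generate_deg_list,
    generate_fragments,
    simulate_study,
)


class TestConfig:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(shared_fraction=1.5)

    def test_spacing_must_exceed_window(self):
        with pytest.raises(ValueError):
            SimulationConfig(peak_spacing=150, summit_flank=100)

    def test_enrichment_floor(self):
        with pytest.raises(ValueError):
            SimulationConfig(peak_enrichment=0.5)


class TestAnnotationGenerator:
    def test_empty(self):
        transcripts, sizes = generate_annotation(SimulationConfig(n_genes=0))
        assert transcripts == [] and len(sizes) == 2

    def test_deterministic(self):
        cfg = SimulationConfig(seed=9, n_genes=30)
        a, _ = generate_annotation(cfg)
        b, _ = generate_annotation(cfg)
        assert a == b

    def test_models_self_validate(self):
        transcripts, sizes = generate_annotation(SimulationConfig(seed=9, n_genes=50))
        assert len(transcripts) == 50
        for t in transcripts:
            assert t.span.end <= sizes[t.chrom]
            u5, u3 = t.utr_intervals()
            assert u5 and u3  # CDS placed to leave both UTRs non-empty
            assert len(t.exons) == 3

    def test_strands_alternate(self):
        transcripts, _ = generate_annotation(SimulationConfig(seed=9, n_genes=10))
        assert {t.strand for t in transcripts} == {"+", "-"}

    def test_genes_must_fit(self):
        with pytest.raises(ValueError, match="fit"):
            generate_annotation(SimulationConfig(n_genes=5_000, chrom_length=1_000_000))


class TestPeakGenerator:
    def test_shared_fraction_extremes(self):
        cfg = SimulationConfig(seed=2, n_peaks_per_condition=50, shared_fraction=1.0)
        a, b, truth = generate_condition_peaks(cfg)
        assert {p.summit for p in a} == {p.summit for p in b}
        cfg0 = SimulationConfig(seed=2, n_peaks_per_condition=50, shared_fraction=0.0)
        a0, b0, _ = generate_condition_peaks(cfg0)
        assert not ({p.summit for p in a0} & {p.summit for p in b0})

    def test_infeasible_density_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_condition_peaks(
                SimulationConfig(n_peaks_per_condition=100_000, chrom_length=2_000_000)
            )

    def test_summits_inside_peaks(self):
        a, b, _ = generate_condition_peaks(SimulationConfig(seed=3, n_peaks_per_condition=100))
        for p in a + b:
            assert p.start <= p.summit < p.end

    def test_deterministic(self):
        cfg = SimulationConfig(seed=4, n_peaks_per_condition=100)
        assert generate_condition_peaks(cfg)[0] == generate_condition_peaks(cfg)[0]


class TestFragmentGenerator:
    def test_depth_zero_empty(self):
        cfg = SimulationConfig(seed=5, depth=0, n_peaks_per_condition=20)
        a, b, _ = generate_condition_peaks(cfg)
        regions = merge_intervals([p.interval() for p in a + b], 100)
        cuts, conditions = generate_fragments(cfg, regions)
        assert all(len(c) == 0 for c in cuts.values())
        assert len(cuts) == 6 and set(conditions.values()) == {"vehicle", "ligand"}

    def test_expected_in_region_mass(self):
        """Mean in-region count matches the analytic multinomial expectation."""
        cfg = SimulationConfig(
            seed=6, n_peaks_per_condition=200, depth=200_000, peak_enrichment=5.0,
            n_dar=0,
        )
        a, b, _ = generate_condition_peaks(cfg)
        regions = merge_intervals([p.interval() for p in a + b], 100)
        cuts, conditions = generate_fragments(cfg, regions)
        genome = cfg.n_chroms * cfg.chrom_length
        widths = np.array([r.width for r in regions], dtype=float)
        extra = widths * (cfg.peak_enrichment - 1)
        total = genome + extra.sum()
        p_in = (extra + widths).sum() / total
        from peaklink import count_in_regions

        sig = count_in_regions(regions, cuts, conditions)
        observed = sig.counts.sum(axis=0) / cfg.depth
        # starts-in-region expectation; cut sites starting just upstream
        # spill in, so allow a small one-sided margin plus sampling noise
        assert np.all(observed > p_in - 0.01)
        assert np.all(observed < p_in + 0.02)


class TestStudyRecovery:
    def test_deterministic_end_to_end(self, small_config):
        s1 = simulate_study(small_config)
        s2 = simulate_study(small_config)
        assert s1.peaks_vehicle == s2.peaks_vehicle
        assert s1.degs == s2.degs
        assert s1.cistrome == s2.cistrome
        for label in s1.cut_sites:
            for chrom, (a, _) in s1.cut_sites[label].per_chrom.items():
                b, _ = s2.cut_sites[label].per_chrom[chrom]
                assert (a == b).all()

    def test_planted_shared_fraction_recovered_exactly(self, small_study):
        cfg = small_study.config
        res = classify_condition_overlap(
            small_study.summits("vehicle"),
            small_study.summits("ligand"),
            cfg.summit_flank,
            small_study.sizes,
        )
        expected = round(cfg.shared_fraction * cfg.n_peaks_per_condition)
        assert res.shared_a == res.shared_b == expected
        assert list(res.labels_a) == small_study.truth.labels_a
        assert list(res.labels_b) == small_study.truth.labels_b

    def test_planted_cistrome_fraction_recovered_exactly(self, small_study):
        cfg = small_study.config
        summary, _ = summarize_cistrome_overlap(
            small_study.summit_windows("ligand"), small_study.cistrome
        )
        assert summary.n_subject_overlapping == round(
            cfg.cistrome_overlap_fraction * cfg.cistrome_count
        )

    def test_planted_deg_linkage_recovered_exactly(self, small_study):
        cfg = small_study.config
        index = TssIndex(small_study.transcripts)
        params = AnalysisParameters()

        def genes(peaks):
            out = set()
            for p in peaks:
                hit = index.query(p.chrom, p.midpoint, params.tss_range)
                if hit is not None:
                    out.add(hit[0])
            return out

        _, counts = classify_deg_association(
            [g for g, _ in small_study.degs],
            genes(small_study.peaks_vehicle),
            genes(small_study.peaks_ligand),
        )
        n_linked = round(cfg.deg_linked_fraction * cfg.deg_count)
        assert counts["shared"] == n_linked
        assert counts["neither"] == cfg.deg_count - n_linked
        assert counts["a_specific"] == counts["b_specific"] == 0

    def test_truth_tables_aligned(self, small_study):
        assert len(small_study.truth.labels_a) == len(small_study.peaks_vehicle)
        assert len(small_study.truth.dar_flags) == len(small_study.merged_regions)
        assert len(small_study.truth.cistrome_overlap) == len(small_study.cistrome)
        assert len(small_study.truth.deg_linked) == len(small_study.degs)


class TestCistromeGenerator:
    def test_extreme_fractions(self, small_study):
        for frac, expect in ((0.0, 0), (1.0, 50)):
            cfg = SimulationConfig(
                seed=8, cistrome_count=50, cistrome_overlap_fraction=frac
            )
            windows = small_study.summit_windows("ligand")
            peaks, labels = generate_cistrome(cfg, windows)
            summary, _ = summarize_cistrome_overlap(windows, peaks)
            assert summary.n_subject_overlapping == expect
            assert sum(labels) == expect


class TestRegionCountSimulator:
    def test_null_matches_binomial_expectation(self):
        sig, flags = simulate_region_counts(
            n_regions=500, depth=100_000, peak_enrichment=5.0, seed=30
        )
        assert not flags.any()
        assert sig.counts.shape == (500, 6)
        # equal-width regions share one analytic expectation:
        # p = (width * enrichment) / (genome + total extra mass)
        genome = 10_000_000
        extra = 500 * 400 * 4.0
        p = 400 * 5.0 / (genome + extra)
        expect = 100_000 * p
        assert sig.counts.mean() == pytest.approx(expect, rel=0.05)
        # dispersion consistent with binomial (variance ~ mean at small p)
        assert sig.counts.var() == pytest.approx(expect, rel=0.25)

    def test_planted_fold_change_in_expectation(self):
        sig, flags = simulate_region_counts(
            n_regions=500, depth=500_000, n_dar=50, dar_log2fc=3.0, seed=31
        )
        veh = sig.counts[:, :3].mean(axis=1)
        lig = sig.counts[:, 3:].mean(axis=1)
        ratio = lig[flags].sum() / veh[flags].sum()
        assert ratio == pytest.approx(8.0, rel=0.15)
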