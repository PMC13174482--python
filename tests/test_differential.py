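"""Cut-site extraction, counting, normalization, t-test, BH adjustment."""

import numpy as np
import pytest

from peaklink import (
    AnalysisParameters,
    CutSites,
    DifferentialAccessibility,
    Fragment,
    GenomicInterval,
    RegionSignal,
    bh_adjust,
    count_in_regions,
    downsample_fragments,
    extract_cut_sites,
    simulate_region_counts,
)
from peaklink import test_differential as run_differential

GI = GenomicInterval


class TestDownsample:
    def test_identity_when_n_large(self):
        frags = [Fragment("chr1", i, i + 50) for i in range(10)]
        assert downsample_fragments(frags, 100, seed=0) == frags

    def test_zero(self):
        assert downsample_fragments([Fragment("chr1", 0, 50)], 0, seed=0) == []

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            downsample_fragments([], -1, seed=0)

    def test_deterministic_and_order_preserving(self):
        frags = [Fragment("chr1", i * 100, i * 100 + 50) for i in range(100)]
        a = downsample_fragments(frags, 30, seed=5)
        b = downsample_fragments(frags, 30, seed=5)
        assert a == b
        starts = [f.start for f in a]
        assert starts == sorted(starts)

    def test_inclusion_frequency_uniform(self):
        """Each record kept with frequency ~ n/total across seeds."""
        frags = [Fragment("chr1", i * 10, i * 10 + 5) for i in range(40)]
        hits = np.zeros(40)
        n_seeds = 500
        for seed in range(n_seeds):
            for f in downsample_fragments(frags, 10, seed=seed):
                hits[f.start // 10] += 1
        freq = hits / n_seeds
        # binomial(500, 0.25): sd ~ 0.019, allow 5 sd
        assert np.all(np.abs(freq - 0.25) < 0.1)


class TestExtractCutSites:
    def test_plus_read(self):
        (cut,) = extract_cut_sites(Fragment("chr1", 1_000, 1_050, "+"))
        assert cut == GI("chr1", 1_000, 1_009)

    def test_minus_read(self):
        (cut,) = extract_cut_sites(Fragment("chr1", 1_950, 2_000, "-"))
        assert cut == GI("chr1", 1_991, 2_000)

    def test_unstranded_fragment_both_ends(self):
        cuts = extract_cut_sites(Fragment("chr1", 1_000, 1_050))
        assert cuts == [GI("chr1", 1_000, 1_009), GI("chr1", 1_041, 1_050)]

    def test_clipped_to_chromosome(self):
        sizes = {"chr1": 1_005}
        cuts = extract_cut_sites(Fragment("chr1", 1_000, 1_005, "+"), sizes=sizes)
        assert cuts == [GI("chr1", 1_000, 1_005)]

    def test_bad_width_rejected(self):
        with pytest.raises(ValueError):
            extract_cut_sites(Fragment("chr1", 0, 50), cut_width=0)


def make_cuts(*positions, chrom="chr1", width=9):
    return [GI(chrom, p, p + width) for p in positions]


class TestCountInRegions:
    def test_hand_counts(self):
        regions = [GI("chr1", 100, 200), GI("chr1", 500, 600)]
        cuts = {"s1": make_cuts(110, 150, 190), "s2": make_cuts(550)}
        sig = count_in_regions(regions, cuts, {"s1": "veh", "s2": "lig"})
        assert sig.counts.tolist() == [[3, 0], [0, 1]]
        assert sig.library_sizes.tolist() == [3, 1]

    def test_no_cuts_zero_matrix(self):
        sig = count_in_regions(
            [GI("chr1", 0, 100)], {"s1": []}, {"s1": "veh"}
        )
        assert sig.counts.sum() == 0

    def test_partial_overlap_counts(self):
        # cut [95,104) overlaps region [100,200) by 4 bp
        sig = count_in_regions(
            [GI("chr1", 100, 200)], {"s1": make_cuts(95)}, {"s1": "veh"}
        )
        assert sig.counts[0, 0] == 1

    def test_straddling_cut_counts_in_both_regions(self):
        regions = [GI("chr1", 0, 100), GI("chr1", 103, 200)]
        with pytest.warns(UserWarning, match="straddling"):
            sig = count_in_regions(regions, {"s1": make_cuts(98)}, {"s1": "veh"})
        assert sig.counts[:, 0].tolist() == [1, 1]

    def test_column_sums_bounded_by_totals(self, small_study):
        sig = count_in_regions(
            small_study.merged_regions, small_study.cut_sites, small_study.conditions
        )
        assert (sig.counts.sum(axis=0) <= sig.library_sizes).all()

    def test_non_disjoint_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            count_in_regions(
                [GI("chr1", 0, 100), GI("chr1", 50, 150)], {"s1": []}, {"s1": "v"}
            )

    def test_accepts_array_backed_cut_sites(self):
        regions = [GI("chr1", 100, 200)]
        cuts = CutSites.from_intervals(make_cuts(110, 150))
        sig = count_in_regions(regions, {"s1": cuts}, {"s1": "veh"})
        assert sig.counts[0, 0] == 2


class TestNormalization:
    def test_common_in_region_total(self):
        sig = RegionSignal(
            regions=[GI("chr1", 0, 100), GI("chr1", 200, 300)],
            counts=np.array([[10, 40], [30, 40]]),
            sample_labels=["a", "b"],
            conditions=["veh", "lig"],
            library_sizes=np.array([100, 100]),
        )
        norm = sig.normalized
        assert norm.sum(axis=0) == pytest.approx([1e7, 1e7])


def reference_bh(p):
    """Hand step-up: sorted p*m/rank, cumulative min from the largest."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestBhAdjust:
    def test_stepup_example(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_reference_random(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 200))
            assert bh_adjust(p) == pytest.approx(reference_bh(p))


def make_signal(counts, conditions=("vehicle", "vehicle", "ligand", "ligand")):
    counts = np.asarray(counts)
    return RegionSignal(
        regions=[GI("chr1", i * 1_000, i * 1_000 + 500) for i in range(counts.shape[0])],
        counts=counts,
        sample_labels=[f"s{i}" for i in range(counts.shape[1])],
        conditions=list(conditions),
        library_sizes=counts.sum(axis=0) + 10,
    )


class TestDifferentialModel:
    def test_identical_groups_unchanged(self):
        sig = make_signal([[5, 5, 5, 5], [9, 9, 9, 9]])
        res = run_differential(sig, "ligand", "vehicle")
        for r in res:
            assert r.log2fc == 0 and r.p == 1.0 and r.dar_class == "unchanged"

    def test_relabeling_flips_sign_and_classes(self):
        sig, _ = simulate_region_counts(
            n_regions=300, depth=50_000, n_dar=30, dar_log2fc=3.0, seed=21
        )
        fwd = DifferentialAccessibility(sig, "ligand", "vehicle").fit()
        rev = DifferentialAccessibility(sig, "vehicle", "ligand").fit()
        assert fwd.frame["log2fc"].to_numpy() == pytest.approx(
            -rev.frame["log2fc"].to_numpy()
        )
        assert fwd.frame["p"].to_numpy() == pytest.approx(rev.frame["p"].to_numpy())
        assert fwd.n_increased == rev.n_decreased
        assert fwd.n_decreased == rev.n_increased

    def test_planted_effect_called_increased(self):
        sig, flags = simulate_region_counts(
            n_regions=500, depth=200_000, n_dar=40, dar_log2fc=3.0, seed=22
        )
        res = DifferentialAccessibility(sig, "ligand", "vehicle").fit()
        called = res.frame["dar_class"].to_numpy() == "increased"
        assert (called & flags).sum() >= 0.9 * flags.sum()
        # no non-planted region is called increased
        assert (called & ~flags).sum() == 0

    def test_requires_two_replicates(self):
        sig = make_signal([[1, 2, 3]], conditions=["vehicle", "vehicle", "ligand"])
        with pytest.raises(ValueError, match="replicates"):
            DifferentialAccessibility(sig, "ligand", "vehicle")

    def test_empty_regions_rejected(self):
        sig = RegionSignal(
            regions=[],
            counts=np.zeros((0, 4), dtype=int),
            sample_labels=["a", "b", "c", "d"],
            conditions=["vehicle"] * 2 + ["ligand"] * 2,
            library_sizes=np.array([1, 1, 1, 1]),
        )
        with pytest.raises(ValueError, match="empty"):
            DifferentialAccessibility(sig, "ligand", "vehicle")

    def test_summary_and_volcano_table(self):
        sig, _ = simulate_region_counts(n_regions=100, depth=20_000, seed=23)
        res = DifferentialAccessibility(sig, "ligand", "vehicle").fit()
        assert "regions tested:        100" in res.summary()
        vt = res.volcano_table()
        assert {"log2fc", "neglog10_adj_p", "dar_class"} <= set(vt.columns)

    def test_welch_option_more_conservative_at_n3(self):
        sig, _ = simulate_region_counts(n_regions=2_000, depth=100_000, seed=24)
        pooled = DifferentialAccessibility(sig, "ligand", "vehicle").fit()
        welch = DifferentialAccessibility(
            sig, "ligand", "vehicle", equal_var=False
        ).fit()
        assert (welch.frame["p"] < 0.05).mean() <= (pooled.frame["p"] < 0.05).mean()

    def test_power_increases_with_depth(self):
        """Planted 4-fold regions: recovery grows monotonically with depth."""
        recovery = []
        for depth in (10_000, 60_000, 400_000):
            rates = []
            for rep in range(3):
                sig, flags = simulate_region_counts(
                    n_regions=400, depth=depth, n_dar=40, dar_log2fc=2.0,
                    seed=1_000 + depth + rep,
                )
                res = DifferentialAccessibility(sig, "ligand", "vehicle").fit()
                called = (res.frame["adj_p"] < 0.05).to_numpy() & (
                    res.frame["log2fc"].to_numpy() > 0
                )
                rates.append((called & flags).sum() / flags.sum())
            recovery.append(np.mean(rates))
        assert recovery[0] <= recovery[1] <= recovery[2]
        assert recovery[2] > recovery[0]
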