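import numpy as np
import pandas as pd
import pytest

from liquidbiopsy.cnv import (
    BinnedCounts,
    DegenerateInputError,
    attenuation_factor,
    compare_profiles,
    compute_logr,
    count_reads,
    instability_score,
    make_bins,
)
from liquidbiopsy.genome import GenomeBuild
from liquidbiopsy.synthetic import (
    CopyNumberTruth,
    simulate_binned_counts,
    simulate_copy_number_truth,
)


def brute_force_counts(reads: pd.DataFrame, binning) -> np.ndarray:
    """Naive per-read loop over all bins (O(reads * bins) oracle)."""
    counts = np.zeros(len(binning), dtype=np.int64)
    for _, read in reads.iterrows():
        for i, (chrom, start, end) in enumerate(binning.bins):
            if read["chrom"] == chrom and start <= read["start"] < end:
                counts[i] += 1
                break
    return counts


class TestMakeBins:
    def test_exact_division(self):
        build = GenomeBuild((("chr1", 100_000),))
        binning = make_bins(build, 50_000)
        assert binning.bins == (("chr1", 0, 50_000), ("chr1", 50_000, 100_000))

    def test_truncated_last_bin(self):
        build = GenomeBuild((("chr1", 120_000),))
        binning = make_bins(build, 50_000)
        assert len(binning) == 3
        assert binning.bins[-1] == ("chr1", 100_000, 120_000)

    def test_total_matches_ceil_arithmetic(self, desk_build):
        binning = make_bins(desk_build, 50_000)
        expected = sum(-(-l // 50_000) for _, l in desk_build.chromosomes)
        assert len(binning) == expected

    def test_bins_partition_each_chromosome(self, toy_binning, toy_build):
        for name, length in toy_build.chromosomes:
            chrom_bins = [b for b in toy_binning.bins if b[0] == name]
            assert chrom_bins[0][1] == 0
            assert chrom_bins[-1][2] == length
            for (_, _, e), (_, s, _) in zip(chrom_bins, chrom_bins[1:]):
                assert e == s  # contiguous, non-overlapping

    def test_bin_index(self, toy_binning):
        assert toy_binning.bin_index("chr1", 0) == 0
        assert toy_binning.bin_index("chr1", 49_999) == 0
        assert toy_binning.bin_index("chr1", 50_000) == 1
        assert toy_binning.bin_index("chr2", 0) == 200

    def test_invalid_bin_size(self, toy_build):
        with pytest.raises(ValueError):
            make_bins(toy_build, 0)


class TestCountReads:
    def test_empty_bed_all_zero(self, toy_binning):
        counts = count_reads(pd.DataFrame(columns=["chrom", "start", "end"]), toy_binning)
        assert counts.total_reads == 0

    def test_half_open_boundary(self, toy_binning):
        # a read starting exactly at 50,000 belongs to the second bin
        reads = pd.DataFrame({"chrom": ["chr1"], "start": [50_000], "end": [50_100]})
        counts = count_reads(reads, toy_binning)
        assert counts.counts[0] == 0
        assert counts.counts[1] == 1

    def test_conservation(self, toy_binning):
        rng = np.random.default_rng(5)
        n = 2_000
        chroms = np.where(rng.random(n) < 0.5, "chr1", "chr2")
        starts = rng.integers(0, 10_000_000, n)
        reads = pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + 100})
        counts = count_reads(reads, toy_binning)
        assert counts.total_reads == n

    def test_matches_brute_force(self):
        build = GenomeBuild((("chr1", 500_000), ("chr2", 300_000)))
        binning = make_bins(build, 50_000)
        rng = np.random.default_rng(6)
        chroms = np.where(rng.random(500) < 0.6, "chr1", "chr2")
        limits = np.where(chroms == "chr1", 500_000, 300_000)
        starts = (rng.random(500) * limits).astype(np.int64)
        reads = pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + 50})
        fast = count_reads(reads, binning)
        assert (fast.counts == brute_force_counts(reads, binning)).all()

    def test_unknown_chromosome_error_and_skip(self, toy_binning):
        reads = pd.DataFrame({"chrom": ["chrUn"], "start": [10], "end": [60]})
        with pytest.raises(KeyError, match="chrUn"):
            count_reads(reads, toy_binning)
        counts = count_reads(reads, toy_binning, on_unknown_chrom="skip")
        assert counts.total_reads == 0

    def test_read_outside_chromosome(self, toy_binning):
        reads = pd.DataFrame({"chrom": ["chr1"], "start": [10_000_000], "end": [10_000_100]})
        with pytest.raises(ValueError, match="outside"):
            count_reads(reads, toy_binning)


class TestComputeLogr:
    def test_identical_samples_give_zero(self, toy_binning):
        rng = np.random.default_rng(7)
        counts = rng.poisson(100, len(toy_binning)).astype(np.int64)
        same = BinnedCounts(toy_binning, counts)
        profile = compute_logr(same, BinnedCounts(toy_binning, counts.copy()))
        assert profile.unmasked_logr == pytest.approx(np.zeros(profile.mask.size - profile.mask.sum()), abs=1e-12)

    def test_doubled_bins_sit_one_logr_above_background(self, toy_binning):
        n = len(toy_binning)
        normal = np.full(n, 100, dtype=np.int64)
        tumor = normal.copy()
        tumor[: n // 4] *= 2  # minority of bins doubled; median stays at background
        profile = compute_logr(BinnedCounts(toy_binning, tumor), BinnedCounts(toy_binning, normal))
        background = profile.logr[n // 4 :]
        doubled = profile.logr[: n // 4]
        assert np.median(background) == pytest.approx(0.0, abs=1e-12)
        assert (doubled - background.mean()).mean() == pytest.approx(1.0, abs=1e-9)

    def test_simulated_gain_recovery(self, desk_build, desk_binning):
        # oracle: closed-form expectation log2(1.5) for a pure single-copy gain
        gain_bins = 300
        events, remaining = [], gain_bins
        for name, length in desk_build.chromosomes:
            if remaining <= 0:
                break
            take = min(remaining, length // 50_000)
            events.append((name, 0, take * 50_000, 3))
            remaining -= take
        truth = CopyNumberTruth.from_events(desk_build, events, purity=1.0)
        diploid = CopyNumberTruth.from_events(desk_build, [])
        tumor = simulate_binned_counts(truth, desk_binning, 100.0, seed=8)
        normal = simulate_binned_counts(diploid, desk_binning, 100.0, seed=9)
        profile = compute_logr(tumor, normal)
        mean_gain = profile.logr[:gain_bins].mean()
        assert abs(mean_gain - np.log2(1.5)) < 0.05

    def test_low_normal_coverage_masked(self, toy_binning):
        n = len(toy_binning)
        normal = np.full(n, 100, dtype=np.int64)
        normal[:5] = 3  # below default min_normal_count=10
        tumor = np.full(n, 100, dtype=np.int64)
        profile = compute_logr(BinnedCounts(toy_binning, tumor), BinnedCounts(toy_binning, normal))
        assert profile.mask[:5].all()
        assert not profile.mask[5:].any()
        assert np.isnan(profile.logr[:5]).all()

    def test_zero_tumor_bins_get_half_count(self, toy_binning):
        n = len(toy_binning)
        normal = np.full(n, 100, dtype=np.int64)
        tumor = np.full(n, 100, dtype=np.int64)
        tumor[0] = 0
        profile = compute_logr(BinnedCounts(toy_binning, tumor), BinnedCounts(toy_binning, normal))
        assert np.isfinite(profile.logr[0])
        # 0.5 substitute: logr ~ log2(0.5/100) relative to flat background
        assert profile.logr[0] == pytest.approx(np.log2(0.5 / 100), abs=0.01)

    def test_library_size_invariance(self, toy_binning):
        rng = np.random.default_rng(10)
        tumor = BinnedCounts(toy_binning, rng.poisson(100, len(toy_binning)) + 1)
        normal = BinnedCounts(toy_binning, rng.poisson(100, len(toy_binning)) + 1)
        a = compute_logr(tumor, normal)
        b = compute_logr(tumor.scaled(7), normal, min_normal_count=10)
        c = compute_logr(tumor, normal.scaled(3), min_normal_count=10)
        np.testing.assert_allclose(a.logr, b.logr, atol=1e-12)
        np.testing.assert_allclose(a.logr, c.logr, atol=1e-12)

    def test_median_centered(self, desk_build, desk_binning):
        truth = simulate_copy_number_truth(desk_build, 5, seed=11)
        tumor = simulate_binned_counts(truth, desk_binning, 80.0, seed=12)
        normal = simulate_binned_counts(
            CopyNumberTruth.from_events(desk_build, []), desk_binning, 80.0, seed=13
        )
        profile = compute_logr(tumor, normal)
        assert np.median(profile.unmasked_logr) == pytest.approx(0.0, abs=1e-12)

    def test_all_masked_is_error(self, toy_binning):
        n = len(toy_binning)
        low = BinnedCounts(toy_binning, np.full(n, 2, dtype=np.int64))
        tumor = BinnedCounts(toy_binning, np.full(n, 100, dtype=np.int64))
        with pytest.raises(DegenerateInputError, match="masked"):
            compute_logr(tumor, low)

    def test_mismatched_binning(self, toy_binning, desk_binning):
        a = BinnedCounts(toy_binning, np.full(len(toy_binning), 10, dtype=np.int64))
        b = BinnedCounts(desk_binning, np.full(len(desk_binning), 10, dtype=np.int64))
        with pytest.raises(ValueError, match="binning"):
            compute_logr(a, b)


def _profile_pair_from_truth(truth, build, binning, depth, seed):
    diploid = CopyNumberTruth.from_events(build, [])
    tumor = simulate_binned_counts(truth, binning, depth, seed=seed)
    normal = simulate_binned_counts(diploid, binning, depth, seed=seed + 10_000)
    return compute_logr(tumor, normal)


class TestCompareProfiles:
    def test_self_comparison_r_one(self, desk_build, desk_binning):
        truth = simulate_copy_number_truth(desk_build, 8, seed=20)
        profile = _profile_pair_from_truth(truth, desk_build, desk_binning, 50.0, seed=21)
        cmp = compare_profiles(profile, profile)
        assert cmp.r == pytest.approx(1.0)
        assert cmp.p_text == "< 2.2e-16"

    def test_shared_truth_beats_independent_truths(self, desk_build, desk_binning):
        shared = simulate_copy_number_truth(desk_build, 15, seed=30, copy_range=(0, 4))
        other = simulate_copy_number_truth(desk_build, 15, seed=31, copy_range=(0, 4))
        a = _profile_pair_from_truth(shared, desk_build, desk_binning, 50.0, seed=32)
        b = _profile_pair_from_truth(shared, desk_build, desk_binning, 50.0, seed=33)
        c = _profile_pair_from_truth(other, desk_build, desk_binning, 50.0, seed=34)
        same = compare_profiles(a, b)
        independent = compare_profiles(a, c)
        assert same.r > 0.9
        assert independent.r < same.r

    def test_requires_joint_bins(self, toy_binning):
        from liquidbiopsy.cnv import CNVProfile

        n = len(toy_binning)
        masked = CNVProfile(toy_binning, np.full(n, np.nan), np.ones(n, dtype=bool))
        ok = CNVProfile(toy_binning, np.zeros(n), np.zeros(n, dtype=bool))
        with pytest.raises(DegenerateInputError):
            compare_profiles(masked, ok)

    def test_degenerate_variance(self, toy_binning):
        from liquidbiopsy.cnv import CNVProfile

        n = len(toy_binning)
        flat = CNVProfile(toy_binning, np.zeros(n), np.zeros(n, dtype=bool))
        varying = CNVProfile(toy_binning, np.linspace(-1, 1, n), np.zeros(n, dtype=bool))
        with pytest.raises(DegenerateInputError, match="constant"):
            compare_profiles(flat, varying)


class TestInstabilityScore:
    def test_flat_profile_zero(self, toy_binning):
        from liquidbiopsy.cnv import CNVProfile

        n = len(toy_binning)
        flat = CNVProfile(toy_binning, np.zeros(n), np.zeros(n, dtype=bool))
        assert instability_score(flat) == 0.0

    def test_everything_altered_one(self, toy_binning):
        from liquidbiopsy.cnv import CNVProfile

        n = len(toy_binning)
        hot = CNVProfile(toy_binning, np.ones(n), np.zeros(n, dtype=bool))
        assert instability_score(hot) == 1.0

    def test_recovers_simulated_altered_fraction(self, desk_build, desk_binning):
        # ~30% of bins gained; high depth keeps noise below the threshold
        n = len(desk_binning)
        gained = int(round(0.30 * n))
        events, remaining = [], gained
        for name, length in desk_build.chromosomes:
            if remaining <= 0:
                break
            take = min(remaining, length // 50_000)
            events.append((name, 0, take * 50_000, 3))
            remaining -= take
        truth = CopyNumberTruth.from_events(desk_build, events, purity=1.0)
        profile = _profile_pair_from_truth(truth, desk_build, desk_binning, 2000.0, seed=40)
        score = instability_score(profile, logr_threshold=0.15)
        assert abs(score - 0.30) < 0.05

    def test_bad_threshold(self, toy_binning):
        from liquidbiopsy.cnv import CNVProfile

        flat = CNVProfile(toy_binning, np.zeros(len(toy_binning)), np.zeros(len(toy_binning), dtype=bool))
        with pytest.raises(ValueError):
            instability_score(flat, logr_threshold=0.0)


class TestAttenuationFactor:
    def test_identical_profiles_one(self, toy_binning):
        from liquidbiopsy.cnv import CNVProfile

        rng = np.random.default_rng(50)
        values = rng.normal(0, 0.5, len(toy_binning))
        p = CNVProfile(toy_binning, values, np.zeros(len(toy_binning), dtype=bool))
        assert attenuation_factor(p, p) == pytest.approx(1.0)

    def test_exact_half_amplitude(self, toy_binning):
        from liquidbiopsy.cnv import CNVProfile

        rng = np.random.default_rng(51)
        ref_values = rng.normal(0, 0.5, len(toy_binning))
        mask = np.zeros(len(toy_binning), dtype=bool)
        ref = CNVProfile(toy_binning, ref_values, mask)
        obs = CNVProfile(toy_binning, 0.5 * ref_values, mask.copy())
        assert attenuation_factor(obs, ref) == pytest.approx(0.5)

    def test_dilution_attenuates(self, desk_build, desk_binning):
        truth_pure = simulate_copy_number_truth(desk_build, 10, seed=60, copy_range=(1, 3))
        truth_diluted = CopyNumberTruth(
            build=truth_pure.build, segments=truth_pure.segments, purity=0.3
        )
        reference = _profile_pair_from_truth(truth_pure, desk_build, desk_binning, 500.0, seed=61)
        observed = _profile_pair_from_truth(truth_diluted, desk_build, desk_binning, 500.0, seed=62)
        factor = attenuation_factor(observed, reference)
        assert 0.05 < factor < 0.7  # clearly attenuated, direction preserved

    def test_degenerate_reference(self, toy_binning):
        from liquidbiopsy.cnv import CNVProfile

        n = len(toy_binning)
        flat = CNVProfile(toy_binning, np.zeros(n), np.zeros(n, dtype=bool))
        obs = CNVProfile(toy_binning, np.ones(n), np.zeros(n, dtype=bool))
        with pytest.raises(DegenerateInputError):
            attenuation_factor(obs, flat)
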