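"""Random-region sampler distribution, coverage fractions, empirical p."""

import numpy as np
import pytest

from cnvmir.annotation import FeatureTrack
from cnvmir.coverage_null import (
    NullConfig,
    coverage_fraction,
    empirical_two_tailed_p,
    run_coverage_null,
    sample_random_regions,
)
from cnvmir.genome import CNVR, GenomeBuild, GenomicInterval
from cnvmir.io_formats import AnnotationFeature


def _track(positions, chrom="chr1", length=22):
    return FeatureTrack([
        AnnotationFeature(GenomicInterval(chrom, p, p + length), f"m{i}", "mirna")
        for i, p in enumerate(positions)
    ])


class TestCoverageFraction:
    def test_tiling_regions_cover_everything(self):
        track = _track([100, 5_000, 9_000])
        regions = [GenomicInterval("chr1", 0, 10_000)]
        assert coverage_fraction(regions, track, 3) == 1.0

    def test_no_regions(self):
        assert coverage_fraction([], _track([100]), 1) == 0.0

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            coverage_fraction([], _track([]), 0)

    def test_matches_per_feature_oracle(self):
        rng = np.random.default_rng(4)
        positions = [int(p) for p in rng.integers(0, 9_000, size=50)]
        track = _track(positions)
        for _ in range(30):
            regions = []
            for _ in range(int(rng.integers(1, 6))):
                s = int(rng.integers(0, 9_000))
                regions.append(GenomicInterval("chr1", s, s + int(rng.integers(100, 2_000))))
            oracle = sum(
                1 for p in positions
                if any(p < r.end and p + 22 > r.start for r in regions)
            )
            assert coverage_fraction(regions, track, 50) == pytest.approx(oracle / 50)

    def test_monotone_in_region_set(self):
        track = _track([int(p) for p in np.random.default_rng(9).integers(0, 9_000, 40)])
        small = [GenomicInterval("chr1", 1_000, 3_000)]
        big = small + [GenomicInterval("chr1", 6_000, 8_000)]
        assert coverage_fraction(big, track, 40) >= coverage_fraction(small, track, 40)


class TestSampler:
    def test_start_uniform_on_single_chromosome(self):
        genome = GenomeBuild({"chrA": 1_000})
        rng = np.random.default_rng(0)
        starts = [sample_random_regions([100], genome, rng)[0].start
                  for _ in range(10_000)]
        # uniform on [0, 900]: mean 450, sd 900/sqrt(12); 3 standard errors
        se = (900 / np.sqrt(12)) / np.sqrt(10_000)
        assert abs(np.mean(starts) - 450) < 3 * se
        assert min(starts) >= 0 and max(starts) <= 900

    def test_full_chromosome_forced_placement(self):
        genome = GenomeBuild({"chrA": 5_000})
        rng = np.random.default_rng(1)
        region, = sample_random_regions([5_000], genome, rng)
        assert (region.start, region.end) == (0, 5_000)

    def test_chromosome_choice_proportional_to_valid_starts(self):
        # valid starts for a 100 bp region: 900 on c1 vs 100 on c2
        genome = GenomeBuild({"c1": 999, "c2": 199})
        rng = np.random.default_rng(2)
        n = 20_000
        regions = sample_random_regions([100] * n, genome, rng)
        frac_c1 = sum(r.chrom == "c1" for r in regions) / n
        se = np.sqrt(0.9 * 0.1 / n)
        assert abs(frac_c1 - 0.9) < 3 * se

    def test_oversized_region_rejected(self):
        genome = GenomeBuild({"chrA": 1_000})
        with pytest.raises(ValueError, match="exceeds every chromosome"):
            sample_random_regions([2_000], genome, np.random.default_rng(0))

    def test_exclusion_mask_respected(self):
        genome = GenomeBuild({"chrA": 10_000})
        mask = [GenomicInterval("chrA", 0, 9_000)]
        rng = np.random.default_rng(3)
        regions = sample_random_regions([500] * 50, genome, rng, mask=mask)
        assert all(r.start >= 9_000 for r in regions)

    def test_non_overlapping_mode(self):
        genome = GenomeBuild({"chrA": 100_000})
        rng = np.random.default_rng(4)
        regions = sample_random_regions([5_000] * 10, genome, rng,
                                        allow_overlap=False)
        regions.sort(key=lambda r: r.start)
        for a, b in zip(regions, regions[1:]):
            assert a.end <= b.start


class TestEmpiricalP:
    def test_observed_above_all_nulls(self):
        null = list(np.linspace(0, 0.5, 1000))
        assert empirical_two_tailed_p(0.9, null) == pytest.approx(2 / 1001)

    def test_observed_equals_every_null(self):
        assert empirical_two_tailed_p(0.3, [0.3] * 100) == 1.0

    def test_observed_at_median(self):
        null = list(np.linspace(0, 1, 999))
        assert empirical_two_tailed_p(0.5, null) == 1.0

    def test_empty_null_errors(self):
        with pytest.raises(ValueError):
            empirical_two_tailed_p(0.5, [])


@pytest.fixture(scope="module")
def setup():
    genome = GenomeBuild({"chr1": 1_000_000, "chr2": 1_000_000})
    rng = np.random.default_rng(10)
    track = FeatureTrack([
        AnnotationFeature(GenomicInterval(iv.chrom, iv.start, iv.end), f"m{i}", "mirna")
        for i, iv in enumerate(
            sample_random_regions([22] * 500, genome, rng))
    ])
    cnvrs = [
        CNVR(iv, frozenset({f"c{j}"}), "test")
        for j, iv in enumerate(
            sample_random_regions([20_000] * 10, genome,
                                  np.random.default_rng(11)))
    ]
    return genome, track, cnvrs


class TestRunCoverageNull:
    def test_same_seed_identical(self, setup):
        genome, track, cnvrs = setup
        config = NullConfig(replicates=50, seed=99)
        r1 = run_coverage_null(cnvrs, track, genome, config)
        r2 = run_coverage_null(cnvrs, track, genome, config)
        assert r1 == r2

    def test_different_seeds_differ(self, setup):
        genome, track, cnvrs = setup
        r1 = run_coverage_null(cnvrs, track, genome, NullConfig(replicates=50, seed=1))
        r2 = run_coverage_null(cnvrs, track, genome, NullConfig(replicates=50, seed=2))
        assert r1.null_fractions != r2.null_fractions
        assert r1.observed_fraction == r2.observed_fraction  # same data

    def test_planted_track_detected(self, setup):
        """A track placed inside the regions gives a small p."""
        genome, _, cnvrs = setup
        background = sample_random_regions([22] * 70, genome,
                                           np.random.default_rng(12))
        inside = FeatureTrack([
            AnnotationFeature(
                GenomicInterval(r.interval.chrom, r.interval.start + 10 + 40 * k,
                                r.interval.start + 32 + 40 * k), f"p{j}_{k}", "mirna")
            for j, r in enumerate(cnvrs) for k in range(3)
        ] + [
            AnnotationFeature(iv, f"bg{k}", "mirna")
            for k, iv in enumerate(background)
        ])
        res = run_coverage_null(cnvrs, inside, genome,
                                NullConfig(replicates=199, seed=5), "planted")
        assert res.observed_fraction > res.null_mean
        assert res.p_value < 0.05
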