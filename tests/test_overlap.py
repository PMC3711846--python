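"""Coverage values, overlap curves, and the randomized-region null."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chipdomains import (
    GenomeModel,
    GenomicRegion,
    compare_samples,
    coverage_values,
    overlap_curve,
    randomize_regions,
)

GENOME = GenomeModel(("c1",), (1_000_000,))


def random_disjoint_regions(rng, n, max_len=2000, L=1_000_000, chrom="c1"):
    starts = np.sort(rng.choice(L // (2 * max_len), size=n, replace=False)) * 2 * max_len
    lengths = rng.integers(100, max_len, size=n)
    return [GenomicRegion(chrom, int(s), int(s + l)) for s, l in zip(starts, lengths)]


class TestCoverageValues:
    def test_identity(self):
        rs = [GenomicRegion("c1", 0, 100), GenomicRegion("c1", 500, 900)]
        np.testing.assert_array_equal(coverage_values(rs, rs), [1.0, 1.0])

    def test_half_overlap(self):
        q = [GenomicRegion("c1", 0, 100)]
        r = [GenomicRegion("c1", 50, 150)]
        assert coverage_values(q, r)[0] == 0.5

    def test_matches_per_bp_bitmask_oracle(self):
        rng = np.random.default_rng(7)
        query = random_disjoint_regions(rng, 200)
        reference = random_disjoint_regions(np.random.default_rng(8), 200)
        got = coverage_values(query, reference)
        mask = np.zeros(1_000_000, dtype=bool)
        for r in reference:
            mask[r.start : r.end] = True
        oracle = np.array([mask[q.start : q.end].sum() / q.length for q in query])
        np.testing.assert_array_equal(got, oracle)  # exact integer arithmetic

    def test_overlapping_query_set_rejected(self):
        q = [GenomicRegion("c1", 0, 100), GenomicRegion("c1", 50, 200)]
        with pytest.raises(ValueError):
            coverage_values(q, [GenomicRegion("c1", 0, 10)])

    def test_intersection_mass_symmetric(self):
        """sum(coverage * length) equals the total intersection bp in both
        directions."""
        rng = np.random.default_rng(9)
        a = random_disjoint_regions(rng, 100)
        b = random_disjoint_regions(np.random.default_rng(10), 120)
        mass_ab = (coverage_values(a, b) * [r.length for r in a]).sum()
        mass_ba = (coverage_values(b, a) * [r.length for r in b]).sum()
        assert mass_ab == mass_ba


class TestOverlapCurve:
    def test_all_ones(self):
        c = overlap_curve([1.0, 1.0, 1.0])
        assert (c.frac_all == 1).all()
        assert (c.frac_nonzero == 1).all()

    def test_direct_count_example(self):
        c = overlap_curve([0.0, 0.5, 1.0], thresholds=np.array([0.5]))
        assert c.frac_all[0] == pytest.approx(2 / 3)
        assert c.frac_nonzero[0] == 1.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(11)
        cov = rng.random(1000)
        thresholds = np.linspace(0, 1, 21)
        c = overlap_curve(cov, thresholds)
        for t, fa, fn in zip(thresholds, c.frac_all, c.frac_nonzero):
            assert fa == sum(1 for v in cov if v >= t) / len(cov)
            nz = [v for v in cov if v > 0]
            assert fn == sum(1 for v in nz if v >= t) / len(nz)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            overlap_curve([])

    def test_all_zero_coverage_reports_missing_nonzero(self):
        c = overlap_curve([0.0, 0.0])
        assert c.frac_nonzero is None
        assert c.n_nonzero == 0
        assert np.isnan(c.to_frame()["frac_nonzero"]).all()

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_curves_monotone_and_anchored(self, cov):
        c = overlap_curve(cov)
        assert (np.diff(c.frac_all) <= 1e-12).all()
        assert c.frac_all[0] == 1.0  # closed threshold at 0
        if c.frac_nonzero is not None:
            assert (np.diff(c.frac_nonzero) <= 1e-12).all()
            assert (c.frac_nonzero - c.frac_all >= -1e-12).all()


class TestRandomizeRegions:
    def test_whole_chromosome_region_forced(self):
        g = GenomeModel(("c",), (1000,))
        (r,) = randomize_regions([GenomicRegion("c", 0, 1000)], g, seed=1)
        assert (r.start, r.end) == (0, 1000)

    def test_lengths_and_counts_conserved(self):
        rng = np.random.default_rng(12)
        regs = random_disjoint_regions(rng, 50)
        shuffled = randomize_regions(regs, GENOME, seed=5)
        assert sorted(r.length for r in shuffled) == sorted(r.length for r in regs)
        assert all(r.chrom == "c1" for r in shuffled)
        # still disjoint and in bounds
        for a, b in zip(shuffled, shuffled[1:]):
            assert a.end <= b.start
        assert shuffled[-1].end <= 1_000_000

    def test_deterministic_per_seed(self):
        regs = random_disjoint_regions(np.random.default_rng(13), 30)
        a = randomize_regions(regs, GENOME, seed=9)
        b = randomize_regions(regs, GENOME, seed=9)
        assert [(r.start, r.end) for r in a] == [(r.start, r.end) for r in b]

    def test_infeasible_packing_rejected(self):
        # regions from a 2-kb assembly cannot be re-placed on a 1-kb one
        big = GenomeModel(("c",), (2000,))
        small = GenomeModel(("c",), (1000,))
        regs = [GenomicRegion("c", 0, 600), GenomicRegion("c", 700, 1300)]
        assert len(randomize_regions(regs, big, seed=0)) == 2
        with pytest.raises(ValueError):
            randomize_regions(regs, small, seed=0)

    def test_mean_coverage_equals_reference_mass(self):
        """Randomized 10%-mass regions vs a fixed 10%-mass reference: the mean
        coverage approaches 0.10 (uniform-placement expectation)."""
        reference = [GenomicRegion("c1", i * 100_000, i * 100_000 + 10_000) for i in range(10)]
        regs = [GenomicRegion("c1", i * 100_000 + 50_000, i * 100_000 + 60_000) for i in range(10)]
        means = []
        for s in range(100):
            shuffled = randomize_regions(regs, GENOME, seed=s)
            means.append(coverage_values(shuffled, reference).mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 0.10) < 4 * se + 1e-3


class TestCompareSamples:
    def test_identical_sets_real_curve_is_one(self):
        rng = np.random.default_rng(14)
        regs = random_disjoint_regions(rng, 40)
        table = compare_samples(
            {"a": regs, "b": list(regs)}, GENOME, n_randomizations=20, seed=2
        )
        assert set(table["pair"]) == {"a vs b", "b vs a"}
        assert (table["frac_all"] == 1.0).all()
        # randomized curve falls below the real one away from threshold 0
        mid = table[np.isclose(table["threshold"], 0.5)]
        assert (mid["rand_frac_all_mean"] < 1.0).all()

    def test_three_sets_give_six_ordered_pairs(self):
        rng = np.random.default_rng(15)
        sets = {f"s{i}": random_disjoint_regions(np.random.default_rng(20 + i), 30) for i in range(3)}
        table = compare_samples(sets, GENOME, n_randomizations=3, seed=1)
        assert table["pair"].nunique() == 6
        expected_cols = {
            "pair", "query", "reference", "threshold", "frac_all", "frac_nonzero",
            "n_regions", "n_nonzero", "rand_frac_all_mean", "rand_frac_all_sd",
        }
        assert expected_cols <= set(table.columns)

    def test_sparse_set_vs_own_randomization_gap(self):
        """<=10% genome mass: the real self-comparison sits at 1 while the
        randomized curve at threshold 0.5 stays far below."""
        regs = [GenomicRegion("c1", i * 100_000, i * 100_000 + 8_000) for i in range(10)]
        table = compare_samples(
            {"x": regs, "y": list(regs)}, GENOME, n_randomizations=50, seed=3
        )
        mid = table[np.isclose(table["threshold"], 0.5)]
        gap = mid["frac_all"] - mid["rand_frac_all_mean"]
        assert (gap > 0.5).all()

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            compare_samples({"only": [GenomicRegion("c1", 0, 10)]}, GENOME)
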