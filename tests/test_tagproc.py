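"""Tag filtering, best-alignment selection, anomaly removal, center shift."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chipdomains import (
    AlignedTag,
    GenomeModel,
    TagSet,
    filter_alignments,
    remove_anomalous_positions,
    select_best_alignment,
    shift_and_combine,
)

GENOME = GenomeModel(("c1", "c2"), (1_000_000, 500_000))


def make_tagset(rows):
    """rows: (read_id, chrom, pos, strand, mm28, n_aln[, total_mm])"""
    tags = [AlignedTag(*r) for r in rows]
    return TagSet.from_tags(tags, GENOME)


class TestFilterAlignments:
    def test_boundary_values(self):
        ts = make_tagset(
            [("a", "c1", 10, "+", 2, 5), ("b", "c1", 20, "+", 3, 1)]
        )
        out = filter_alignments(ts)
        assert list(out.frame["read_id"]) == ["a"]

    def test_empty_input(self):
        out = filter_alignments(make_tagset([]))
        assert len(out) == 0

    def test_matches_brute_force_refilter(self):
        rows = [
            (f"r{i}", "c1", 100 + i, "+", mm, na)
            for i, (mm, na) in enumerate(
                (mm, na) for mm in range(4) for na in (1, 5, 6)
            )
        ]
        ts = make_tagset(rows)
        out = filter_alignments(ts)
        expected = {r[0] for r in rows if r[4] <= 2 and r[5] <= 5}
        assert set(out.frame["read_id"]) == expected

    def test_idempotent_and_never_grows(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"r{i}", "c1", int(rng.integers(0, 1000)), "+",
             int(rng.integers(0, 5)), int(rng.integers(1, 8)))
            for i in range(200)
        ]
        ts = make_tagset(rows)
        once = filter_alignments(ts)
        twice = filter_alignments(once)
        assert len(once) <= len(ts)
        pd.testing.assert_frame_equal(once.frame, twice.frame)

    def test_provenance_records_removed_counts(self):
        ts = make_tagset([("a", "c1", 1, "+", 3, 1), ("b", "c1", 2, "+", 0, 9)])
        out = filter_alignments(ts)
        assert any("removed 1 by mismatch" in p and "1 by multimapping" in p
                   for p in out.provenance)


class TestSelectBestAlignment:
    def test_single_alignment_identity(self):
        ts = make_tagset([("a", "c1", 10, "+", 1, 1)])
        out = select_best_alignment(ts)
        assert len(out) == 1

    def test_fewest_total_mismatches_wins(self):
        ts = make_tagset(
            [("a", "c1", 10, "+", 0, 2, 1), ("a", "c2", 99, "-", 0, 2, 0)]
        )
        out = select_best_alignment(ts)
        assert list(out.frame["chrom"]) == ["c2"]

    def test_matches_per_read_sort_oracle(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(50):
            for _ in range(int(rng.integers(1, 5))):
                rows.append(
                    (f"read{i}", rng.choice(["c1", "c2"]),
                     int(rng.integers(0, 400_000)), rng.choice(["+", "-"]),
                     int(rng.integers(0, 3)), 3, int(rng.integers(0, 4)))
                )
        ts = make_tagset(rows)
        out = select_best_alignment(ts)
        # independent per-group brute force: sort alignments and take the first
        expected = {}
        for r in rows:
            key = (r[6], r[4], r[1], r[2], r[3])  # total_mm, mm28, chrom, pos, strand
            if r[0] not in expected or key < expected[r[0]][0]:
                expected[r[0]] = (key, r)
        got = {
            r.read_id: (r.chrom, r.pos, r.strand)
            for r in out.frame.itertuples(index=False)
        }
        assert got == {rid: (v[1][1], v[1][2], v[1][3]) for rid, v in expected.items()}
        assert set(got) == {r[0] for r in rows}  # no loss, no invention


class TestRemoveAnomalousPositions:
    def test_uniform_counts_nothing_removed(self):
        ts = make_tagset([(f"r{i}", "c1", i * 10, "+", 0, 1) for i in range(100)])
        out, removed = remove_anomalous_positions(ts)
        assert removed == []
        assert len(out) == 100

    def test_single_extreme_pileup_removed(self):
        rows = [(f"r{i}", "c1", i * 10, "+", 0, 1) for i in range(99)]
        rows += [(f"p{i}", "c1", 999_999, "+", 0, 1) for i in range(1000)]
        ts = make_tagset(rows)
        # two-pass oracle for the Z-score of the pileup position
        counts = np.array([1] * 99 + [1000], dtype=float)
        z_oracle = (1000 - counts.mean()) / counts.std(ddof=0)
        assert z_oracle > 7
        out, removed = remove_anomalous_positions(ts, z_threshold=7)
        assert removed == [("c1", 999_999, "+", 1000)]
        assert len(out) == 99

    def test_infinite_threshold_is_vacuous(self):
        rows = [(f"r{i}", "c1", 5, "+", 0, 1) for i in range(50)]
        rows += [(f"s{i}", "c1", i, "-", 0, 1) for i in range(20)]
        ts = make_tagset(rows)
        out, removed = remove_anomalous_positions(ts, z_threshold=np.inf)
        assert removed == []
        assert len(out) == len(ts)

    def test_poisson_background_modal_class_survives(self):
        """i.i.d. sparse Poisson counts: the modal (singleton) count class is
        never removed and the removed tag fraction stays marginal."""
        rng = np.random.default_rng(1)
        n_pos = 1_000_000
        counts = rng.poisson(0.01, size=n_pos)
        covered = np.flatnonzero(counts)
        rows = [
            (f"r{i}_{k}", "c1", int(p), "+", 0, 1)
            for i, p in enumerate(covered)
            for k in range(int(counts[p]))
        ]
        ts = make_tagset(rows)
        out, removed = remove_anomalous_positions(ts, z_threshold=7)
        assert all(c > 1 for (_, _, _, c) in removed)  # singletons untouched
        assert len(out) >= 0.97 * len(ts)


class TestShiftAndCombine:
    def test_plus_strand_shift(self):
        ts = make_tagset([("a", "c1", 1000, "+", 0, 1)])
        cs = shift_and_combine(ts, fragment_size=150)
        assert list(cs["c1"]) == [1075]

    def test_minus_strand_symmetric(self):
        ts = make_tagset([("a", "c1", 1150, "-", 0, 1)])
        cs = shift_and_combine(ts, fragment_size=150)
        assert list(cs["c1"]) == [1075]

    def test_fragment_ends_meet_within_1bp(self, simulated_pair):
        """Plus- and minus-strand 5' ends of one 150-bp fragment shift to
        centers at most 1 bp apart, for every simulated fragment."""
        chip, _ = simulated_pair
        f = chip.frame
        starts = np.where(f["strand"] == "+", f["pos"], f["pos"] - 149)
        plus_center = starts + 75
        minus_center = (starts + 149) - 75
        assert (np.abs(plus_center - minus_center) <= 1).all()

    def test_count_conserved_with_edge_clipping(self):
        ts = make_tagset([("a", "c1", 10, "-", 0, 1), ("b", "c1", 999_990, "+", 0, 1)])
        cs = shift_and_combine(ts, fragment_size=150)
        assert cs.n == 2
        assert list(cs["c1"]) == [0, 999_999]  # clipped to chromosome bounds

    @given(delta=st.integers(min_value=-500, max_value=500))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_translation_equivariance(self, delta):
        base = [5000, 7000, 9000]
        ts = make_tagset(
            [(f"r{i}", "c1", p + delta, "+", 0, 1) for i, p in enumerate(base)]
        )
        cs = shift_and_combine(ts)
        assert list(cs["c1"]) == [p + delta + 75 for p in base]


def test_retention_bookkeeping_is_exact(simulated_pair):
    """total - removed at each stage == retained, at every stage."""
    chip, _ = simulated_pair
    total = len(chip)
    f1 = filter_alignments(chip)
    f2 = select_best_alignment(f1)
    f3, removed_pos = remove_anomalous_positions(f2)
    removed_filter = total - len(f1)
    removed_best = len(f1) - len(f2)
    removed_anom = sum(c for (_, _, _, c) in removed_pos)
    assert total - removed_filter - removed_best - removed_anom == len(f3)
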