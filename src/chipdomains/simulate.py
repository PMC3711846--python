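"""Synthetic ChIP-seq tag simulator.

Emulates the statistical structure of a broad-domain histone-mark ChIP
experiment with a matched input control: unique fragment start positions are
drawn from a two-level mixture (per-bp weight ``fold`` inside planted
domains, 1 outside; the input is uniform), each unique fragment is emitted
``1 + k`` times with ``k`` geometric (PCR duplication), each emitted tag gets
a random strand — the plus-strand 5' end is the fragment start, the
minus-strand 5' end the fragment's last base — and rare extreme
single-position pileups ("hotspots", amplification artifacts) can be
injected at exact coordinates.  Per-tag aligner attributes (``mm28``,
``n_aln``) are drawn so that fractions ``mismatch_p`` / ``multimap_p`` fail
the corresponding quality filters.

Everything is deterministic for a fixed :class:`SimulationTruth`: the ChIP
and input samples use independent child RNG streams derived from one seed,
so changing one sample's tag count never perturbs the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .regions import GenomicRegion, check_disjoint, check_in_bounds, sort_regions
from .tags import TAG_COLUMNS, TagSet, _empty_frame


@dataclass
class SimulationTruth:
    """Full parameterization of one synthetic experiment.

    Parameters
    ----------
    genome
        Chromosomes to simulate on.
    domains
        Planted enriched domains (non-overlapping, in bounds).
    fold
        Per-bp enrichment of fragment starts inside domains (> 1).
    n_chip, n_input
        Unique-fragment counts for the ChIP and input libraries.
    fragment_size
        Mean DNA fragment length in bp; must be even so the half-fragment
        shift is integral. Default 150.
    dup_rate
        Mean number of extra (PCR-duplicate) copies per unique fragment;
        copies are ``k ~ Geometric`` shifted to support {0, 1, ...} with
        mean ``dup_rate``.
    hotspots
        ``(chrom, pos, count)`` triples: extra plus-strand tags stacked on a
        single coordinate, the worst case for the anomalous-position filter.
    mismatch_p
        Probability that a tag carries more mismatches in its first 28 bp
        than the filter allows.
    multimap_p
        Probability that a tag reports more alignments than the filter allows.
    seed
        Master seed; child streams are derived per sample.
    """

    genome: GenomeModel
    domains: list[GenomicRegion] = field(default_factory=list)
    fold: float = 5.0
    n_chip: int = 100_000
    n_input: int = 100_000
    fragment_size: int = 150
    dup_rate: float = 0.0
    hotspots: list[tuple[str, int, int]] = field(default_factory=list)
    mismatch_p: float = 0.0
    multimap_p: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        check_disjoint(self.domains)
        check_in_bounds(self.domains, self.genome)
        if self.fold <= 1:
            raise ValueError("fold must be > 1")
        if self.fragment_size <= 0 or self.fragment_size % 2:
            raise ValueError("fragment_size must be a positive even integer")
        for p, name in ((self.mismatch_p, "mismatch_p"), (self.multimap_p, "multimap_p")):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dup_rate < 0:
            raise ValueError("dup_rate must be >= 0")
        for chrom, pos, count in self.hotspots:
            if chrom not in self.genome or not 0 <= pos < self.genome.length(chrom):
                raise ValueError(f"hotspot ({chrom}, {pos}) out of bounds")
            if count < 0:
                raise ValueError("hotspot count must be >= 0")


def plant_domains(
    genome: GenomeModel,
    n_domains: int,
    length_range: tuple[int, int],
    seed: int,
) -> list[GenomicRegion]:
    """Place ``n_domains`` non-overlapping domains uniformly on the genome.

    Lengths are drawn uniformly from ``length_range`` (inclusive), each
    domain is assigned to a chromosome with probability proportional to
    chromosome length, and domains are placed uniformly at random without
    overlap.  Raises ``ValueError`` when the requested domain mass cannot be
    packed (no silent truncation).
    """
    if n_domains < 0:
        raise ValueError("n_domains must be >= 0")
    if n_domains == 0:
        return []
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid length_range {length_range}")
    if hi > max(genome.chrom_lengths):
        raise ValueError("largest requested domain exceeds every chromosome")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_domains)
    if lengths.sum() > genome.total_length:
        raise ValueError(
            f"requested domain mass {lengths.sum()} exceeds genome "
            f"size {genome.total_length}"
        )
    weights = np.asarray(genome.chrom_lengths, dtype=float)
    weights /= weights.sum()
    for _attempt in range(200):
        assignment = rng.choice(len(genome.chrom_names), size=n_domains, p=weights)
        ok = True
        for ci, L in enumerate(genome.chrom_lengths):
            mine = lengths[assignment == ci]
            if len(mine) and (mine.sum() > L or mine.max() > L):
                ok = False
                break
        if ok:
            break
    else:
        raise ValueError("could not pack requested domains into the genome")
    regions: list[GenomicRegion] = []
    for ci, chrom in enumerate(genome.chrom_names):
        mine = lengths[assignment == ci]
        if len(mine) == 0:
            continue
        mine = rng.permutation(mine)
        starts = _pack_uniform(int(genome.chrom_lengths[ci]), mine, rng)
        regions.extend(
            GenomicRegion(chrom, int(s), int(s + l)) for s, l in zip(starts, mine)
        )
    return sort_regions(regions)


def _pack_uniform(L: int, lengths: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform non-overlapping placement of intervals of given lengths on [0, L).

    Standard gap-sampling construction: draw the left-over space cut points
    uniformly, sort them, and lay the intervals down in order.
    """
    free = L - int(lengths.sum())
    if free < 0:
        raise ValueError("interval mass exceeds chromosome length")
    cuts = np.sort(rng.integers(0, free + 1, size=len(lengths)))
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    return cuts + offsets


def simulate_tags(truth: SimulationTruth) -> tuple[TagSet, TagSet]:
    """Simulate the (ChIP, input) tag pair described by ``truth``."""
    chip_rng = np.random.default_rng([int(truth.seed), 0])
    input_rng = np.random.default_rng([int(truth.seed), 1])
    chip = _simulate_sample(truth, chip_rng, "chip", truth.n_chip, enriched=True)
    inp = _simulate_sample(truth, input_rng, "input", truth.n_input, enriched=False)
    return chip, inp


def _segments(truth: SimulationTruth, enriched: bool):
    """Weighted fragment-start segments: (chrom idx, start, stop, weight).

    Fragment starts are restricted to [0, L - fragment_size] so fragments
    never extend past the chromosome end; domain weighting applies to the
    start coordinate.
    """
    segs = []
    frag = truth.fragment_size
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for d in sort_regions(truth.domains):
        by_chrom.setdefault(d.chrom, []).append(d)
    for ci, (chrom, L) in enumerate(zip(truth.genome.chrom_names, truth.genome.chrom_lengths)):
        hi = L - frag
        if hi < 0:
            continue
        if not enriched:
            segs.append((ci, 0, hi + 1, 1.0))
            continue
        cursor = 0
        for d in by_chrom.get(chrom, []):
            s, e = min(d.start, hi + 1), min(d.end, hi + 1)
            if cursor < s:
                segs.append((ci, cursor, s, 1.0))
            if s < e:
                segs.append((ci, s, e, truth.fold))
            cursor = max(cursor, e)
        if cursor < hi + 1:
            segs.append((ci, cursor, hi + 1, 1.0))
    if not segs:
        raise ValueError("no chromosome can hold a fragment of the requested size")
    return segs


def _simulate_sample(
    truth: SimulationTruth,
    rng: np.random.Generator,
    prefix: str,
    n_fragments: int,
    enriched: bool,
) -> TagSet:
    segs = _segments(truth, enriched)
    seg_w = np.array([(stop - start) * w for _, start, stop, w in segs])
    frag = truth.fragment_size

    # unique fragment start positions from the two-level mixture
    seg_chrom = np.array([s[0] for s in segs])
    seg_lo = np.array([s[1] for s in segs], dtype=np.int64)
    seg_len = np.array([s[2] - s[1] for s in segs], dtype=np.int64)
    if n_fragments > 0:
        which = rng.choice(len(segs), size=n_fragments, p=seg_w / seg_w.sum())
        starts = seg_lo[which] + rng.integers(0, seg_len[which])
        chrom_idx = seg_chrom[which]
    else:
        chrom_idx = np.empty(0, dtype=int)
        starts = np.empty(0, dtype=np.int64)

    # PCR duplication: 1 + k emitted copies per unique fragment
    if truth.dup_rate > 0 and n_fragments > 0:
        k = rng.geometric(1.0 / (1.0 + truth.dup_rate), size=n_fragments) - 1
    else:
        k = np.zeros(n_fragments, dtype=np.int64)
    copies = 1 + k
    starts = np.repeat(starts, copies)
    chrom_idx = np.repeat(chrom_idx, copies)
    n_tags = len(starts)

    # strands and 5' positions
    plus = rng.integers(0, 2, size=n_tags).astype(bool)
    pos = np.where(plus, starts, starts + frag - 1)

    # aligner attributes
    mm28 = rng.integers(0, 3, size=n_tags)
    mm_fail = rng.random(n_tags) < truth.mismatch_p
    mm28 = np.where(mm_fail, 3 + rng.integers(0, 3, size=n_tags), mm28)
    n_aln = rng.integers(1, 6, size=n_tags)
    aln_fail = rng.random(n_tags) < truth.multimap_p
    n_aln = np.where(aln_fail, 6 + rng.integers(0, 5, size=n_tags), n_aln)

    chrom_names = np.asarray(truth.genome.chrom_names, dtype=object)
    frame = pd.DataFrame(
        {
            "read_id": "",
            "chrom": chrom_names[chrom_idx] if n_tags else pd.Series(dtype=str),
            "pos": pos,
            "strand": np.where(plus, "+", "-") if n_tags else pd.Series(dtype=str),
            "mm28": mm28,
            "n_aln": n_aln,
        }
    )

    # hotspot pileups: exact coordinate, one strand, clean attributes
    if enriched and truth.hotspots:
        hs = pd.DataFrame(
            [
                (chrom, p, "+", 0, 1)
                for chrom, p, count in truth.hotspots
                for _ in range(count)
            ],
            columns=["chrom", "pos", "strand", "mm28", "n_aln"],
        )
        hs.insert(0, "read_id", "")
        frame = pd.concat([frame, hs], ignore_index=True)

    frame["read_id"] = [f"{prefix}_{i:08d}" for i in range(len(frame))]
    frame["total_mm"] = frame["mm28"]
    frame = frame[TAG_COLUMNS]
    if len(frame) == 0:
        frame = _empty_frame()
    ts = TagSet(frame, truth.genome, provenance=[f"simulated sample {prefix!r}: {len(frame)} tags"])
    return ts.sorted()
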