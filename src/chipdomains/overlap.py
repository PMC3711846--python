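"""Region-reproducibility analysis: coverage values, overlap curves, and
the randomized-region null.

For an ordered pair of region sets, each query region's *coverage value* is
the fraction of its base pairs that fall inside any region of the
reference set.  The *overlap curve* then gives, for a grid of thresholds
``t`` in [0, 1], the fraction of query regions with coverage >= ``t`` —
once over all regions and once restricted to regions with non-zero
coverage (regions entirely missed in the other sample would otherwise
drag the curve down and obscure how well the reproduced regions agree).

Significance is calibrated against a randomized-region null: the reference
set is re-placed uniformly at random, preserving per-chromosome region
counts and lengths and forbidding overlap, and the curve is averaged over
many randomizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .regions import GenomicRegion, check_disjoint, sort_regions
from .simulate import _pack_uniform

DEFAULT_THRESHOLDS = np.round(np.arange(0.0, 1.0001, 0.05), 10)


@dataclass
class OverlapCurve:
    """Fractions of regions reproduced, as a function of the coverage threshold.

    ``frac_all`` counts all query regions; ``frac_nonzero`` only those with
    coverage > 0 (``None`` when no region has non-zero coverage).  Both use
    closed thresholds (coverage >= t), so ``frac_all`` is 1 at t = 0.
    """

    thresholds: np.ndarray
    frac_all: np.ndarray
    frac_nonzero: np.ndarray | None
    n_regions: int
    n_nonzero: int
    pair_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair": self.pair_label,
                "threshold": self.thresholds,
                "frac_all": self.frac_all,
                "frac_nonzero": (
                    self.frac_nonzero
                    if self.frac_nonzero is not None
                    else np.full(len(self.thresholds), np.nan)
                ),
                "n_regions": self.n_regions,
                "n_nonzero": self.n_nonzero,
            }
        )


def coverage_values(
    query: list[GenomicRegion], reference: list[GenomicRegion]
) -> np.ndarray:
    """Per-query-region fraction of base pairs covered by the reference set.

    Both sets must be internally non-overlapping (merge first); the
    computation is exact integer bp arithmetic.
    """
    check_disjoint(query)
    check_disjoint(reference)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {r.chrom for r in reference}:
        rs = sort_regions([r for r in reference if r.chrom == chrom])
        by_chrom[chrom] = (
            np.array([r.start for r in rs], dtype=np.int64),
            np.array([r.end for r in rs], dtype=np.int64),
        )
    out = np.zeros(len(query))
    for qi, q in enumerate(query):
        if q.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[q.chrom]
        i0 = int(np.searchsorted(ends, q.start, side="right"))
        i1 = int(np.searchsorted(starts, q.end, side="left"))
        if i1 <= i0:
            continue
        inter = np.minimum(ends[i0:i1], q.end) - np.maximum(starts[i0:i1], q.start)
        out[qi] = int(inter[inter > 0].sum()) / q.length
    return out


def overlap_curve(
    coverages: np.ndarray | list[float],
    thresholds: np.ndarray = DEFAULT_THRESHOLDS,
    pair_label: str = "",
) -> OverlapCurve:
    """Build the reproduced-fraction curve from per-region coverage values."""
    cov = np.asarray(coverages, dtype=float)
    if len(cov) == 0:
        raise ValueError("empty coverage list")
    if cov.min() < 0 or cov.max() > 1:
        raise ValueError("coverage values must lie in [0, 1]")
    thresholds = np.asarray(thresholds, dtype=float)
    frac_all = (cov[None, :] >= thresholds[:, None]).mean(axis=1)
    nz = cov[cov > 0]
    if len(nz):
        frac_nonzero = (nz[None, :] >= thresholds[:, None]).mean(axis=1)
    else:
        frac_nonzero = None
    return OverlapCurve(
        thresholds=thresholds,
        frac_all=frac_all,
        frac_nonzero=frac_nonzero,
        n_regions=len(cov),
        n_nonzero=len(nz),
        pair_label=pair_label,
    )


def randomize_regions(
    regions: list[GenomicRegion], genome: GenomeModel, seed: int
) -> list[GenomicRegion]:
    """Uniformly re-place regions, preserving per-chromosome counts and lengths.

    The standard shuffle-with-lengths null: on each chromosome the same
    number of regions with identical lengths is placed uniformly at random
    without overlap.  Deterministic per seed; raises on infeasible packing.
    """
    rng = np.random.default_rng(seed)
    out: list[GenomicRegion] = []
    for chrom in genome.chrom_names:
        lengths = np.array(
            [r.length for r in sort_regions(regions) if r.chrom == chrom],
            dtype=np.int64,
        )
        if len(lengths) == 0:
            continue
        L = genome.length(chrom)
        if lengths.sum() > L:
            raise ValueError(
                f"cannot place {lengths.sum()} bp of regions on {chrom} (length {L})"
            )
        lengths = rng.permutation(lengths)
        starts = _pack_uniform(L, lengths, rng)
        out.extend(
            GenomicRegion(chrom, int(s), int(s + l)) for s, l in zip(starts, lengths)
        )
    return sort_regions(out)


def compare_samples(
    region_sets: dict[str, list[GenomicRegion]],
    genome: GenomeModel,
    thresholds: np.ndarray = DEFAULT_THRESHOLDS,
    n_randomizations: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise reproducibility table for every ordered pair of region sets.

    For each ordered pair (query, reference) the real overlap curve is
    computed, plus the mean and SD over ``n_randomizations`` of the curve
    against a randomized reference set.  Returns a tidy frame with one row
    per (pair, threshold).
    """
    if len(region_sets) < 2:
        raise ValueError("need at least two region sets to compare")
    thresholds = np.asarray(thresholds, dtype=float)
    rows: list[pd.DataFrame] = []
    for k, (qname, rname) in enumerate(permutations(region_sets, 2)):
        query, reference = region_sets[qname], region_sets[rname]
        curve = overlap_curve(
            coverage_values(query, reference), thresholds, f"{qname} vs {rname}"
        )
        rand_curves = np.empty((n_randomizations, len(thresholds)))
        for r in range(n_randomizations):
            shuffled = randomize_regions(
                reference, genome, seed=(int(seed) * 100003 + k * 1009 + r) % (2**31)
            )
            cov_r = coverage_values(query, shuffled)
            rand_curves[r] = (cov_r[None, :] >= thresholds[:, None]).mean(axis=1)
        frame = curve.to_frame()
        frame.insert(1, "query", qname)
        frame.insert(2, "reference", rname)
        frame["rand_frac_all_mean"] = rand_curves.mean(axis=0)
        frame["rand_frac_all_sd"] = rand_curves.std(axis=0, ddof=0)
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def plot_overlap_curves(table: pd.DataFrame, path: str) -> None:
    """Figure with one panel per pair: solid = all regions, dashed =
    non-zero-coverage regions, dotted = randomized-reference mean."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pairs = table["pair"].unique()
    fig, axes = plt.subplots(1, len(pairs), figsize=(4 * len(pairs), 3.5), squeeze=False)
    for ax, pair in zip(axes[0], pairs):
        sub = table[table["pair"] == pair]
        ax.plot(sub["threshold"], sub["frac_all"], "-", label="all regions")
        ax.plot(sub["threshold"], sub["frac_nonzero"], "--", label="non-zero coverage")
        ax.plot(sub["threshold"], sub["rand_frac_all_mean"], ":", label="randomized")
        ax.set_title(pair)
        ax.set_xlabel("coverage threshold")
        ax.set_ylabel("fraction of regions")
        ax.set_ylim(-0.02, 1.02)
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
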