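"""Tag-level quality processing.

The four steps applied to every library before density estimation and
region calling:

1. :func:`filter_alignments` — keep tags with at most ``max_mm28``
   mismatches in the first 28 bp and at most ``max_aln`` reported
   alignments (defaults 2 and 5).
2. :func:`select_best_alignment` — one alignment per read id, ranked by
   total mismatches, then prefix mismatches, then a deterministic
   lexicographic tie-break on (chrom, pos, strand).
3. :func:`remove_anomalous_positions` — discard all tags at
   (chrom, pos, strand) coordinates whose tag count is an outlier
   (Z > 7 by default) relative to all covered positions; such pileups are
   typically PCR-amplification artifacts.
4. :func:`shift_and_combine` — shift each 5' position half a fragment
   toward the fragment 3' end (+75 bp on the plus strand, −75 bp on the
   minus strand for 150-bp fragments) so both strands land on fragment
   centers, then drop strand information.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .tags import MM28_UNAVAILABLE, CenterSet, TagSet


def filter_alignments(tags: TagSet, max_mm28: int = 2, max_aln: int = 5) -> TagSet:
    """Apply the mismatch and multimapping filters.

    Tags with ``mm28 > max_mm28`` or ``n_aln > max_aln`` are removed.  Tags
    whose ``mm28`` is unavailable (sentinel ``-1``, e.g. from alignment
    files without prefix mismatch counts) skip the mismatch criterion with
    a warning.  Provenance records the counts removed by each criterion.
    """
    f = tags.frame
    unavailable = f["mm28"] == MM28_UNAVAILABLE
    if unavailable.any():
        warnings.warn(
            f"{int(unavailable.sum())} tags lack a first-28-bp mismatch count; "
            "the mismatch criterion is skipped for them",
            stacklevel=2,
        )
    ok_mm = (f["mm28"] <= max_mm28) | unavailable
    ok_aln = f["n_aln"] <= max_aln
    keep = ok_mm & ok_aln
    note = (
        f"filter_alignments(max_mm28={max_mm28}, max_aln={max_aln}): "
        f"removed {int((~ok_mm).sum())} by mismatch, {int((~ok_aln).sum())} by "
        f"multimapping ({int((~keep).sum())} total), kept {int(keep.sum())}"
    )
    return tags.with_frame(f[keep].reset_index(drop=True), note)


def select_best_alignment(tags: TagSet) -> TagSet:
    """Keep exactly one alignment per read id.

    Ranking: smallest ``total_mm``, then smallest ``mm28``, then
    lexicographically smallest (chrom, pos, strand).  Exact duplicate
    records collapse to one (logged in provenance).
    """
    f = tags.frame
    ranked = f.sort_values(
        ["total_mm", "mm28", "chrom", "pos", "strand"], kind="mergesort"
    )
    best = ranked.drop_duplicates("read_id", keep="first")
    best = best.sort_values(["chrom", "pos", "strand", "read_id"], kind="mergesort")
    n_dropped = len(f) - len(best)
    note = (
        f"select_best_alignment: {len(best)} reads, "
        f"dropped {n_dropped} secondary/duplicate alignments"
    )
    return tags.with_frame(best.reset_index(drop=True), note)


def remove_anomalous_positions(
    tags: TagSet, z_threshold: float = 7.0
) -> tuple[TagSet, list[tuple[str, int, str, int]]]:
    """Discard tags at anomalously deep single positions.

    Per-(chrom, pos, strand) tag counts ``c`` are computed over covered
    positions only; ``Z = (c - mean) / sd`` with the population standard
    deviation of those counts.  All tags at positions with ``Z >
    z_threshold`` (strict) are discarded in a single pass.  If every
    covered position has the same count (sd = 0) nothing is removed.

    Returns the filtered TagSet and the removed ``(chrom, pos, strand,
    count)`` records, sorted.
    """
    f = tags.frame
    if len(f) == 0:
        return tags.with_frame(f, "remove_anomalous_positions: empty input"), []
    counts = f.groupby(["chrom", "pos", "strand"], sort=True).size()
    mu = counts.to_numpy().mean()
    sd = counts.to_numpy().std(ddof=0)
    if sd == 0:
        note = f"remove_anomalous_positions(z={z_threshold}): uniform counts, removed 0"
        return tags.with_frame(f, note), []
    z = (counts - mu) / sd
    bad = counts[z > z_threshold]
    removed = [
        (chrom, int(pos), strand, int(c)) for (chrom, pos, strand), c in bad.items()
    ]
    if removed:
        bad_index = pd.MultiIndex.from_tuples([r[:3] for r in removed])
        mask = pd.MultiIndex.from_frame(f[["chrom", "pos", "strand"]]).isin(bad_index)
    else:
        mask = np.zeros(len(f), dtype=bool)
    note = (
        f"remove_anomalous_positions(z={z_threshold}): removed "
        f"{int(mask.sum())} tags at {len(removed)} anomalous positions"
    )
    return tags.with_frame(f[~mask].reset_index(drop=True), note), removed


def shift_and_combine(tags: TagSet, fragment_size: int = 150) -> CenterSet:
    """Shift 5' positions to fragment centers and combine strands.

    Plus-strand tags move ``+fragment_size/2``, minus-strand tags
    ``-fragment_size/2``.  Results are clipped to chromosome bounds (so
    tag counts are conserved) and returned strandless and sorted.
    """
    if fragment_size <= 0:
        raise ValueError("fragment_size must be positive")
    half = fragment_size // 2
    f = tags.frame
    shifted = f["pos"].to_numpy() + np.where(f["strand"].to_numpy() == "+", half, -half)
    positions: dict[str, np.ndarray] = {}
    chroms = f["chrom"].to_numpy()
    for chrom in tags.genome.chrom_names:
        sel = chroms == chrom
        p = shifted[sel]
        positions[chrom] = np.clip(p, 0, tags.genome.length(chrom) - 1)
    return CenterSet(tags.genome, positions)
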