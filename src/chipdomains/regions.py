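"""Genomic regions: 0-based half-open intervals with optional enrichment scores."""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import GenomeModel


@dataclass
class GenomicRegion:
    """A 0-based half-open interval ``[start, end)`` on a chromosome.

    ``z`` and ``fold`` carry enrichment scores when the region was produced
    by the caller; they stay ``None`` for truth domains and randomized
    regions.  ``label`` is free text (sample name, region id, ...).
    """

    chrom: str
    start: int
    end: int
    z: float | None = None
    fold: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.start = int(self.start)
        self.end = int(self.end)
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)


def sort_regions(regions: list[GenomicRegion]) -> list[GenomicRegion]:
    return sorted(regions, key=GenomicRegion.sort_key)


def total_bp(regions: list[GenomicRegion]) -> int:
    return sum(r.length for r in regions)


def check_disjoint(regions: list[GenomicRegion]) -> None:
    """Raise ``ValueError`` if any two regions on one chromosome overlap."""
    srt = sort_regions(regions)
    for a, b in zip(srt, srt[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(
                f"overlapping regions on {a.chrom}: "
                f"[{a.start},{a.end}) and [{b.start},{b.end})"
            )


def check_in_bounds(regions: list[GenomicRegion], genome: GenomeModel) -> None:
    for r in regions:
        if r.chrom not in genome:
            raise ValueError(f"region chromosome {r.chrom!r} not in genome")
        if r.end > genome.length(r.chrom):
            raise ValueError(
                f"region [{r.start},{r.end}) exceeds {r.chrom} "
                f"length {genome.length(r.chrom)}"
            )


def merge_regions(regions: list[GenomicRegion], gap: int = 0) -> list[GenomicRegion]:
    """Merge regions whose separation is <= ``gap`` bp. Scores are dropped."""
    out: list[GenomicRegion] = []
    for r in sort_regions(regions):
        if out and r.chrom == out[-1].chrom and r.start - out[-1].end <= gap:
            out[-1] = GenomicRegion(r.chrom, out[-1].start, max(out[-1].end, r.end))
        else:
            out.append(GenomicRegion(r.chrom, r.start, r.end))
    return out
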