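"""Containers for aligned sequencing tags and fragment centers.

``AlignedTag`` is the record for one mapped read: its 5' coordinate, strand,
and the two aligner-reported attributes the quality filters use — mismatches
within the first 28 bp (``mm28``) and the number of alignments reported for
the read (``n_aln``).  ``TagSet`` holds many tags as a pandas DataFrame plus
the genome they live on and a provenance trail of the filters applied.
``CenterSet`` holds strandless fragment-center coordinates after the
half-fragment shift.

``mm28`` may be the sentinel ``-1`` meaning "unavailable" (e.g. tags imported
from an alignment file without per-prefix mismatch counts); filters skip the
criterion for such tags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel

STRANDS = ("+", "-")

#: Column order of the in-memory tag frame. ``total_mm`` (total mismatches,
#: used only to rank alternative alignments of one read) is not part of the
#: on-disk dialect; readers set it equal to ``mm28``.
TAG_COLUMNS = ["read_id", "chrom", "pos", "strand", "mm28", "n_aln", "total_mm"]

MM28_UNAVAILABLE = -1


@dataclass(frozen=True)
class AlignedTag:
    read_id: str
    chrom: str
    pos: int
    strand: str
    mm28: int
    n_aln: int
    total_mm: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if self.n_aln < 1:
            raise ValueError("n_aln must be >= 1")
        if self.total_mm is None:
            object.__setattr__(self, "total_mm", self.mm28)


class TagSet:
    """A collection of aligned tags on a genome, with filter provenance.

    Parameters
    ----------
    frame
        DataFrame with columns :data:`TAG_COLUMNS`.
    genome
        The coordinate system; every tag position must satisfy
        ``0 <= pos < chrom_length``.
    provenance
        Audit trail: one line per processing step with counts removed.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        genome: GenomeModel,
        provenance: list[str] | None = None,
        validate: bool = True,
    ) -> None:
        frame = frame.reset_index(drop=True)
        missing = [c for c in TAG_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"tag frame missing columns {missing}")
        self.frame = frame[TAG_COLUMNS]
        self.genome = genome
        self.provenance = list(provenance or [])
        if validate:
            self._validate()

    def _validate(self) -> None:
        f = self.frame
        if len(f) == 0:
            return
        bad_strand = ~f["strand"].isin(STRANDS)
        if bad_strand.any():
            raise ValueError(f"invalid strand values: {f.loc[bad_strand, 'strand'].unique()!r}")
        if (f["n_aln"] < 1).any():
            raise ValueError("n_aln must be >= 1 for all tags")
        for chrom, sub in f.groupby("chrom", sort=False):
            if chrom not in self.genome:
                raise ValueError(f"tag chromosome {chrom!r} not in genome")
            L = self.genome.length(chrom)
            if (sub["pos"] < 0).any() or (sub["pos"] >= L).any():
                raise ValueError(f"tag position out of bounds on {chrom} (length {L})")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_tags(cls, tags: list[AlignedTag], genome: GenomeModel) -> "TagSet":
        frame = pd.DataFrame(
            [(t.read_id, t.chrom, t.pos, t.strand, t.mm28, t.n_aln, t.total_mm) for t in tags],
            columns=TAG_COLUMNS,
        )
        if len(frame) == 0:
            frame = _empty_frame()
        return cls(frame, genome)

    def to_tags(self) -> list[AlignedTag]:
        return [
            AlignedTag(r.read_id, r.chrom, int(r.pos), r.strand, int(r.mm28), int(r.n_aln), int(r.total_mm))
            for r in self.frame.itertuples(index=False)
        ]

    # -- plumbing ----------------------------------------------------------
    def with_frame(self, frame: pd.DataFrame, note: str | None = None) -> "TagSet":
        prov = self.provenance + ([note] if note else [])
        return TagSet(frame, self.genome, prov, validate=False)

    def sorted(self) -> "TagSet":
        f = self.frame.sort_values(
            ["chrom", "pos", "strand", "read_id"], kind="mergesort"
        ).reset_index(drop=True)
        return self.with_frame(f)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TagSet):
            return NotImplemented
        return self.frame.equals(other.frame) and self.genome == other.genome


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": pd.Series(dtype=str),
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "mm28": pd.Series(dtype=np.int64),
            "n_aln": pd.Series(dtype=np.int64),
            "total_mm": pd.Series(dtype=np.int64),
        }
    )


class CenterSet:
    """Per-chromosome sorted multisets of strandless fragment-center coordinates."""

    def __init__(self, genome: GenomeModel, positions: dict[str, np.ndarray]) -> None:
        self.genome = genome
        self.positions: dict[str, np.ndarray] = {}
        for chrom in genome.chrom_names:
            p = np.sort(np.asarray(positions.get(chrom, []), dtype=np.int64))
            if len(p) and (p[0] < 0 or p[-1] >= genome.length(chrom)):
                raise ValueError(f"center out of bounds on {chrom}")
            self.positions[chrom] = p
        extra = set(positions) - set(genome.chrom_names)
        if extra:
            raise ValueError(f"centers on unknown chromosomes: {sorted(extra)}")

    @property
    def n(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.positions[chrom]
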