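"""Genome model: ordered chromosome names and lengths.

A :class:`GenomeModel` stands in for a reference assembly (e.g. a fly or
mammalian genome) at whatever scale the analysis runs: it is just the
coordinate system every other container validates against.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome names and lengths, in a fixed order.

    Parameters
    ----------
    chrom_names
        Unique chromosome identifiers.
    chrom_lengths
        Length in base pairs for each chromosome, parallel to
        ``chrom_names``; every length must be >= 1.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.chrom_names)
        lengths = tuple(int(x) for x in self.chrom_lengths)
        object.__setattr__(self, "chrom_names", names)
        object.__setattr__(self, "chrom_lengths", lengths)
        if len(names) != len(lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for n, L in zip(names, lengths):
            if L < 1:
                raise ValueError(f"chromosome {n!r} has non-positive length {L}")

    @classmethod
    def from_dict(cls, lengths: dict[str, int]) -> "GenomeModel":
        return cls(tuple(lengths), tuple(lengths.values()))

    def to_dict(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths)
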