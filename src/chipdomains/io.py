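"""Readers and writers for every on-disk format the pipeline touches.

Native formats (all plain text, 0-based coordinates):

* **tag file** — tab-delimited ``read_id  chrom  pos0  strand  mm28  n_aln``
  with a ``#``-prefixed header naming the columns, sorted by
  (chrom, pos, strand, read_id).
* **BED3 / scored BED** — truth domains as BED3; called regions as BED3
  plus a name column and the region's Z and fold in columns 5-6.
* **bedGraph** — density tracks; one interval per grid step.
* **genome table** — ``chrom<TAB>length``.
* **flat key=value config** — serialized :class:`~.simulate.SimulationTruth`.

``import_sam`` additionally converts an external aligner's SAM output
(text) into a :class:`~.tags.TagSet`.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .regions import GenomicRegion, sort_regions
from .simulate import SimulationTruth
from .tags import MM28_UNAVAILABLE, TAG_COLUMNS, TagSet, _empty_frame

TAG_HEADER = "#read_id\tchrom\tpos0\tstrand\tmm28\tn_aln"


# ---------------------------------------------------------------- tag files
def write_tag_file(tags: TagSet, path: str | Path) -> None:
    """Write the tab-delimited tag format, sorted by (chrom, pos)."""
    f = tags.sorted().frame
    with open(path, "w") as fh:
        fh.write(TAG_HEADER + "\n")
        for r in f.itertuples(index=False):
            fh.write(f"{r.read_id}\t{r.chrom}\t{r.pos}\t{r.strand}\t{r.mm28}\t{r.n_aln}\n")


def read_tags(path: str | Path, genome: GenomeModel) -> TagSet:
    """Read a tag file back into a TagSet (``total_mm`` is set to ``mm28``)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}: malformed tag line {lineno}: expected 6 fields, got {len(parts)}")
            read_id, chrom, pos, strand, mm28, n_aln = parts
            try:
                rows.append((read_id, chrom, int(pos), strand, int(mm28), int(n_aln), int(mm28)))
            except ValueError:
                raise ValueError(f"{path}: malformed tag line {lineno}: non-integer field") from None
    frame = pd.DataFrame(rows, columns=TAG_COLUMNS) if rows else _empty_frame()
    return TagSet(frame, genome, provenance=[f"read {len(frame)} tags from {path}"])


# ---------------------------------------------------------------- BED
def read_bed(path: str | Path, genome: GenomeModel | None = None) -> list[GenomicRegion]:
    """Read BED3+ into regions; scored BEDs restore Z/fold from columns 5-6."""
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}: fewer than 3 fields")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}: malformed BED line {lineno}: non-integer coordinates") from None
            if end <= start or start < 0:
                raise ValueError(f"{path}: invalid interval on line {lineno}: [{start}, {end})")
            if genome is not None:
                if chrom not in genome:
                    raise ValueError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
                if end > genome.length(chrom):
                    raise ValueError(f"{path}: line {lineno}: interval exceeds {chrom} length")
            label = parts[3] if len(parts) > 3 and parts[3] != "." else ""
            z = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            fold = float(parts[5]) if len(parts) > 5 and parts[5] != "." else None
            regions.append(GenomicRegion(chrom, start, end, z=z, fold=fold, label=label))
    return regions


def write_bed(regions: list[GenomicRegion], path: str | Path) -> None:
    """Write plain BED3 (coordinates only)."""
    with open(path, "w") as fh:
        for r in sort_regions(regions):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def write_regions(regions: list[GenomicRegion], path: str | Path) -> None:
    """Write scored BED: chrom, start, end, name, Z, fold.

    Floats use 17-significant-digit formatting so the round trip through
    :func:`read_regions` is exact.
    """
    with open(path, "w") as fh:
        for i, r in enumerate(sort_regions(regions)):
            name = r.label or f"region_{i + 1:05d}"
            z = f"{r.z:.17g}" if r.z is not None else "."
            fold = f"{r.fold:.17g}" if r.fold is not None else "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{z}\t{fold}\n")


def read_regions(path: str | Path, genome: GenomeModel | None = None) -> list[GenomicRegion]:
    return read_bed(path, genome)


# ---------------------------------------------------------------- bedGraph
def write_bedgraph(tracks, path: str | Path) -> None:
    """Write density tracks as bedGraph (one line per grid step).

    ``tracks`` is a dict chrom -> DensityTrack or a single track.  Interval
    ``j`` is ``[start + j*step, start + (j+1)*step)``; intervals are sorted,
    non-overlapping, and cover exactly the evaluated grid.
    """
    if not isinstance(tracks, dict):
        tracks = {tracks.chrom: tracks}
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            t = tracks[chrom]
            for j, v in enumerate(t.values):
                a = t.start + j * t.step
                fh.write(f"{chrom}\t{a}\t{a + t.step}\t{v:.6g}\n")


# ---------------------------------------------------------------- genome table
def write_genome(genome: GenomeModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, L in zip(genome.chrom_names, genome.chrom_lengths):
            fh.write(f"{chrom}\t{L}\n")


def read_genome(path: str | Path) -> GenomeModel:
    names, lengths = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: malformed genome line {lineno}")
            names.append(parts[0])
            lengths.append(int(parts[1]))
    return GenomeModel(tuple(names), tuple(lengths))


# ---------------------------------------------------------------- SAM import
def import_sam(path: str | Path, genome: GenomeModel | None = None) -> TagSet:
    """Import mapped records from a SAM file as aligned tags.

    The 5' position is the leftmost aligned base for plus-strand reads and
    the *last* aligned base (``reference_end - 1``) for minus-strand reads.
    Mismatch counts come from the ``NM`` tag when present (used for both
    ``total_mm`` and ``mm28``; SAM has no per-prefix mismatch field) and
    are otherwise marked unavailable so the mismatch filter skips them.
    Mapping multiplicity comes from ``NH`` or ``X0`` when present, else 1
    (the multimapping filter then passes trivially); both fallbacks warn.
    """
    import pysam

    rows = []
    missing_nm = missing_naln = 0
    lengths: dict[str, int] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for ref, L in zip(sam.references, sam.lengths):
            lengths[ref] = L
        for rec in sam:
            if rec.is_unmapped:
                continue
            chrom = rec.reference_name
            if rec.is_reverse:
                strand, pos = "-", rec.reference_end - 1
            else:
                strand, pos = "+", rec.reference_start
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            else:
                nm = MM28_UNAVAILABLE
                missing_nm += 1
            if rec.has_tag("NH"):
                n_aln = int(rec.get_tag("NH"))
            elif rec.has_tag("X0"):
                n_aln = int(rec.get_tag("X0"))
            else:
                n_aln = 1
                missing_naln += 1
            total_mm = nm if nm != MM28_UNAVAILABLE else 0
            rows.append((rec.query_name, chrom, int(pos), strand, nm, n_aln, total_mm))
    if missing_nm:
        warnings.warn(
            f"{missing_nm} records lack the NM tag; their mismatch count is "
            "unavailable and the mismatch filter will skip them",
            stacklevel=2,
        )
    if missing_naln:
        warnings.warn(
            f"{missing_naln} records lack NH/X0 tags; n_aln assumed 1 "
            "(the multimapping filter passes trivially)",
            stacklevel=2,
        )
    if genome is None:
        genome = GenomeModel(tuple(lengths), tuple(lengths.values()))
    frame = pd.DataFrame(rows, columns=TAG_COLUMNS) if rows else _empty_frame()
    return TagSet(frame, genome, provenance=[f"imported {len(frame)} mapped records from {path}"])


# ---------------------------------------------------------------- truth config
def write_truth_config(truth: SimulationTruth, path: str | Path) -> None:
    """Serialize a SimulationTruth as a flat ``key = value`` text file."""
    genome = ",".join(
        f"{c}:{L}" for c, L in zip(truth.genome.chrom_names, truth.genome.chrom_lengths)
    )
    domains = ",".join(f"{d.chrom}:{d.start}-{d.end}" for d in truth.domains)
    hotspots = ",".join(f"{c}:{p}:{n}" for c, p, n in truth.hotspots)
    lines = [
        f"genome = {genome}",
        f"domains = {domains}",
        f"fold = {truth.fold:.17g}",
        f"n_chip = {truth.n_chip}",
        f"n_input = {truth.n_input}",
        f"fragment_size = {truth.fragment_size}",
        f"dup_rate = {truth.dup_rate:.17g}",
        f"hotspots = {hotspots}",
        f"mismatch_p = {truth.mismatch_p:.17g}",
        f"multimap_p = {truth.multimap_p:.17g}",
        f"seed = {truth.seed}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth_config(path: str | Path) -> SimulationTruth:
    kv: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: malformed config line {lineno}")
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
    chroms = dict(
        (part.split(":")[0], int(part.split(":")[1]))
        for part in kv["genome"].split(",")
        if part
    )
    genome = GenomeModel.from_dict(chroms)
    domains = []
    for part in kv.get("domains", "").split(","):
        if not part:
            continue
        chrom, span = part.split(":")
        a, b = span.split("-")
        domains.append(GenomicRegion(chrom, int(a), int(b)))
    hotspots = []
    for part in kv.get("hotspots", "").split(","):
        if not part:
            continue
        chrom, p, n = part.rsplit(":", 2)
        hotspots.append((chrom, int(p), int(n)))
    return SimulationTruth(
        genome=genome,
        domains=domains,
        fold=float(kv.get("fold", 5.0)),
        n_chip=int(kv.get("n_chip", 100_000)),
        n_input=int(kv.get("n_input", 100_000)),
        fragment_size=int(kv.get("fragment_size", 150)),
        dup_rate=float(kv.get("dup_rate", 0.0)),
        hotspots=hotspots,
        mismatch_p=float(kv.get("mismatch_p", 0.0)),
        multimap_p=float(kv.get("multimap_p", 0.0)),
        seed=int(kv.get("seed", 0)),
    )
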