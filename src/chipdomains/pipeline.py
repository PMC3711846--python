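"""End-to-end pipeline: simulate/load -> filter -> density -> call -> compare.

A :class:`RunConfig` names the samples (each ChIP sample paired with an
input), fixes every module parameter in one place, and points at an output
directory.  :func:`run_pipeline` executes the stages, writes every
intermediate artifact as a documented text format (so any stage can be
re-run standalone), and returns a :class:`RunSummary` whose retention
bookkeeping is exact: total tags minus the tags removed by each filter
equals the retained count at every stage.

Reruns with an identical config are byte-identical in their region BED and
curve TSV outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .calling import CallerParams, call_regions
from .density import compute_density, subtract_input
from .genome import GenomeModel
from .overlap import DEFAULT_THRESHOLDS, compare_samples
from .regions import GenomicRegion
from .simulate import SimulationTruth, simulate_tags
from .tagproc import (
    filter_alignments,
    remove_anomalous_positions,
    select_best_alignment,
    shift_and_combine,
)
from .tags import TagSet


@dataclass
class SampleSpec:
    """One library: either a tag file on disk or a simulated sample.

    ``sim_offset`` selects the simulation seed (``truth.seed + offset``);
    ChIP samples name their paired input sample via ``input``.
    """

    name: str
    role: str  # "chip" | "input"
    tag_file: str | None = None
    sim_offset: int | None = None
    input: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ("chip", "input"):
            raise ValueError(f"sample role must be 'chip' or 'input', got {self.role!r}")
        if (self.tag_file is None) == (self.sim_offset is None):
            raise ValueError(f"sample {self.name!r}: give exactly one of tag_file / sim_offset")


@dataclass
class RunConfig:
    """Everything one pipeline run depends on.

    Defaults are the analysis constants used throughout: mismatch limit 2
    (in the first 28 bp), alignment limit 5, anomaly threshold Z = 7,
    75-bp half-fragment shift (fragment_size 150), 50-bp kernel bandwidth,
    and caller thresholds Z >= 3 with fold >= 2.
    """

    genome: GenomeModel
    samples: list[SampleSpec] = field(default_factory=list)
    truth: SimulationTruth | None = None
    max_mm28: int = 2
    max_aln: int = 5
    z_anomaly: float = 7.0
    fragment_size: int = 150
    bandwidth: float = 50.0
    step: int = 10
    caller: CallerParams = field(default_factory=CallerParams)
    thresholds: np.ndarray = field(default_factory=lambda: DEFAULT_THRESHOLDS.copy())
    n_randomizations: int = 20
    outdir: str = "chipdomains_out"
    seed: int = 0

    def __post_init__(self) -> None:
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("sample names must be unique")
        inputs = {s.name for s in self.samples if s.role == "input"}
        for s in self.samples:
            if s.role == "chip":
                if s.input is None or s.input not in inputs:
                    raise ValueError(f"ChIP sample {s.name!r} has no paired input sample")
            if s.sim_offset is not None and self.truth is None:
                raise ValueError(f"sample {s.name!r} is simulated but no truth template given")


@dataclass
class RunSummary:
    """Per-sample retention bookkeeping plus called-region counts."""

    frame: pd.DataFrame
    outdir: Path
    curve_file: Path | None = None


_SUMMARY_COLUMNS = [
    "sample",
    "role",
    "total",
    "removed_quality",
    "after_quality",
    "removed_multiple",
    "after_best",
    "removed_anomalous",
    "anomalous_positions",
    "retained",
    "clusters",
]


def _obtain_tags(config: RunConfig, spec: SampleSpec, cache: dict) -> TagSet:
    if spec.tag_file is not None:
        return cio.read_tags(spec.tag_file, config.genome)
    key = int(spec.sim_offset)
    if key not in cache:
        truth = dataclasses.replace(config.truth, seed=config.truth.seed + config.seed + key)
        cache[key] = simulate_tags(truth)
    chip, inp = cache[key]
    return chip if spec.role == "chip" else inp


def run_pipeline(config: RunConfig) -> RunSummary:
    """Run every stage for every sample; write artifacts; return the summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cio.write_genome(config.genome, outdir / "genome.tsv")
    if config.truth is not None and config.truth.domains:
        cio.write_bed(config.truth.domains, outdir / "truth_domains.bed")

    sim_cache: dict = {}
    rows = []
    centers_by_sample: dict[str, object] = {}
    counts_by_sample: dict[str, int] = {}
    region_sets: dict[str, list[GenomicRegion]] = {}
    log: list[str] = []

    for spec in config.samples:
        stage = f"sample {spec.name!r}"
        try:
            raw = _obtain_tags(config, spec, sim_cache)
            cio.write_tag_file(raw, outdir / f"{spec.name}.raw.tags")
            total = len(raw)
            t_qual = filter_alignments(raw, config.max_mm28, config.max_aln)
            t_best = select_best_alignment(t_qual)
            t_clean, removed_pos = remove_anomalous_positions(t_best, config.z_anomaly)
            cio.write_tag_file(t_clean, outdir / f"{spec.name}.filtered.tags")
            centers = shift_and_combine(t_clean, config.fragment_size)
            centers_by_sample[spec.name] = centers
            counts_by_sample[spec.name] = centers.n
            tracks = compute_density(centers, config.bandwidth, config.step)
            cio.write_bedgraph(tracks, outdir / f"{spec.name}.density.bedGraph")
            log.extend(f"{spec.name}: {line}" for line in t_clean.provenance)
            rows.append(
                {
                    "sample": spec.name,
                    "role": spec.role,
                    "total": total,
                    "removed_quality": total - len(t_qual),
                    "after_quality": len(t_qual),
                    "removed_multiple": len(t_qual) - len(t_best),
                    "after_best": len(t_best),
                    "removed_anomalous": len(t_best) - len(t_clean),
                    "anomalous_positions": len(removed_pos),
                    "retained": len(t_clean),
                    "clusters": pd.NA,
                }
            )
        except Exception as err:
            raise RuntimeError(f"pipeline failed at stage {stage}: {err}") from err

    # region calling per ChIP sample, against its paired input
    for spec in config.samples:
        if spec.role != "chip":
            continue
        stage = f"region calling for {spec.name!r}"
        try:
            chip_centers = centers_by_sample[spec.name]
            input_centers = centers_by_sample[spec.input]
            regions = call_regions(chip_centers, input_centers, config.genome, config.caller)
            region_sets[spec.name] = regions
            cio.write_regions(regions, outdir / f"{spec.name}.regions.bed")
            chip_tracks = compute_density(chip_centers, config.bandwidth, config.step)
            input_tracks = compute_density(input_centers, config.bandwidth, config.step)
            sub = {
                chrom: subtract_input(
                    chip_tracks[chrom],
                    input_tracks[chrom],
                    counts_by_sample[spec.name],
                    counts_by_sample[spec.input],
                )
                for chrom in config.genome.chrom_names
            }
            cio.write_bedgraph(sub, outdir / f"{spec.name}.subtracted.bedGraph")
            for row in rows:
                if row["sample"] == spec.name:
                    row["clusters"] = len(regions)
            log.append(f"{spec.name}: called {len(regions)} regions")
        except Exception as err:
            raise RuntimeError(f"pipeline failed at stage {stage}: {err}") from err

    # pairwise reproducibility between ChIP samples
    curve_file = None
    if len(region_sets) >= 2 and all(len(r) for r in region_sets.values()):
        stage = "pairwise comparison"
        try:
            table = compare_samples(
                region_sets,
                config.genome,
                thresholds=config.thresholds,
                n_randomizations=config.n_randomizations,
                seed=config.seed,
            )
            curve_file = outdir / "overlap_curves.tsv"
            table.to_csv(curve_file, sep="\t", index=False, float_format="%.10g")
        except Exception as err:
            raise RuntimeError(f"pipeline failed at stage {stage}: {err}") from err

    frame = pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)
    summary = RunSummary(frame=frame, outdir=outdir, curve_file=curve_file)
    frame.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    (outdir / "summary.txt").write_text(summarize(summary))
    (outdir / "pipeline.log").write_text("\n".join(log) + ("\n" if log else ""))
    return summary


def _percent(part: int, whole: int) -> int:
    # round-half-away-from-zero, the convention of printed percent tables
    return int(np.floor(100.0 * part / whole + 0.5)) if whole else 0


def summarize(summary: RunSummary) -> str:
    """Text table: total reads, retained reads with integer percent, clusters."""
    lines = [f"{'sample':<16}{'role':<8}{'total reads':>14}  {'filtered reads':>20}  {'clusters':>9}"]
    for row in summary.frame.itertuples(index=False):
        filtered = f"{row.retained:,} ({_percent(row.retained, row.total)}%)"
        clusters = "n/a" if pd.isna(row.clusters) else str(int(row.clusters))
        lines.append(
            f"{row.sample:<16}{row.role:<8}{row.total:>14,}  {filtered:>20}  {clusters:>9}"
        )
    return "\n".join(lines) + "\n"


def summarize_outdir(outdir: str | Path) -> pd.DataFrame:
    """Rebuild per-sample counts by recounting lines in run artifacts.

    Independent of the in-memory bookkeeping: totals come from the raw tag
    files, retained counts from the filtered tag files, cluster counts from
    the region BEDs.  Raises if an expected artifact is missing.
    """
    outdir = Path(outdir)
    summary_file = outdir / "summary.tsv"
    if not summary_file.exists():
        raise FileNotFoundError(f"no summary.tsv under {outdir}")
    recorded = pd.read_csv(summary_file, sep="\t")
    rows = []
    for row in recorded.itertuples(index=False):
        raw = outdir / f"{row.sample}.raw.tags"
        filtered = outdir / f"{row.sample}.filtered.tags"
        if not raw.exists() or not filtered.exists():
            raise FileNotFoundError(f"missing tag artifacts for sample {row.sample!r}")
        total = _count_data_lines(raw)
        retained = _count_data_lines(filtered)
        regions_bed = outdir / f"{row.sample}.regions.bed"
        clusters: object = pd.NA
        if row.role == "chip":
            if not regions_bed.exists():
                raise FileNotFoundError(f"missing regions BED for ChIP sample {row.sample!r}")
            clusters = _count_data_lines(regions_bed)
        rows.append(
            {"sample": row.sample, "role": row.role, "total": total,
             "retained": retained, "clusters": clusters}
        )
    return pd.DataFrame(rows)


def _count_data_lines(path: Path) -> int:
    with open(path) as fh:
        return sum(1 for line in fh if line.strip() and not line.startswith("#"))


# ---------------------------------------------------------------- YAML config
def config_to_yaml(config: RunConfig, path: str | Path) -> None:
    doc = {
        "genome": config.genome.to_dict(),
        "samples": [dataclasses.asdict(s) for s in config.samples],
        "max_mm28": config.max_mm28,
        "max_aln": config.max_aln,
        "z_anomaly": config.z_anomaly,
        "fragment_size": config.fragment_size,
        "bandwidth": config.bandwidth,
        "step": config.step,
        "caller": dataclasses.asdict(config.caller),
        "thresholds": [float(t) for t in config.thresholds],
        "n_randomizations": config.n_randomizations,
        "outdir": str(config.outdir),
        "seed": config.seed,
    }
    if config.truth is not None:
        doc["truth"] = {
            "domains": [[d.chrom, d.start, d.end] for d in config.truth.domains],
            "fold": config.truth.fold,
            "n_chip": config.truth.n_chip,
            "n_input": config.truth.n_input,
            "fragment_size": config.truth.fragment_size,
            "dup_rate": config.truth.dup_rate,
            "hotspots": [list(h) for h in config.truth.hotspots],
            "mismatch_p": config.truth.mismatch_p,
            "multimap_p": config.truth.multimap_p,
            "seed": config.truth.seed,
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def config_from_yaml(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text())
    genome = GenomeModel.from_dict(doc["genome"])
    truth = None
    if "truth" in doc:
        t = doc["truth"]
        truth = SimulationTruth(
            genome=genome,
            domains=[GenomicRegion(c, a, b) for c, a, b in t.get("domains", [])],
            fold=t.get("fold", 5.0),
            n_chip=t.get("n_chip", 100_000),
            n_input=t.get("n_input", 100_000),
            fragment_size=t.get("fragment_size", 150),
            dup_rate=t.get("dup_rate", 0.0),
            hotspots=[tuple(h) for h in t.get("hotspots", [])],
            mismatch_p=t.get("mismatch_p", 0.0),
            multimap_p=t.get("multimap_p", 0.0),
            seed=t.get("seed", 0),
        )
    return RunConfig(
        genome=genome,
        samples=[SampleSpec(**s) for s in doc.get("samples", [])],
        truth=truth,
        max_mm28=doc.get("max_mm28", 2),
        max_aln=doc.get("max_aln", 5),
        z_anomaly=doc.get("z_anomaly", 7.0),
        fragment_size=doc.get("fragment_size", 150),
        bandwidth=doc.get("bandwidth", 50.0),
        step=doc.get("step", 10),
        caller=CallerParams(**doc.get("caller", {})),
        thresholds=np.asarray(doc.get("thresholds", DEFAULT_THRESHOLDS)),
        n_randomizations=doc.get("n_randomizations", 20),
        outdir=doc.get("outdir", "chipdomains_out"),
        seed=doc.get("seed", 0),
    )


def toy_config(outdir: str | Path, seed: int = 0) -> RunConfig:
    """Bundled toy experiment: two simulated ChIP replicates plus an input
    on a 2-Mb two-chromosome genome, with duplication, filter failures and
    hotspot pileups switched on.  Completes in seconds."""
    from .simulate import plant_domains

    genome = GenomeModel(("chr2L", "chr2R"), (1_200_000, 800_000))
    domains = plant_domains(genome, 10, (10_000, 40_000), seed=917)
    truth = SimulationTruth(
        genome=genome,
        domains=domains,
        fold=6.0,
        n_chip=30_000,
        n_input=30_000,
        fragment_size=150,
        dup_rate=0.3,
        hotspots=[("chr2L", 500_000, 400), ("chr2R", 200_000, 300)],
        mismatch_p=0.05,
        multimap_p=0.03,
        seed=0,
    )
    samples = [
        SampleSpec("input", "input", sim_offset=0),
        SampleSpec("rep1", "chip", sim_offset=0, input="input"),
        SampleSpec("rep2", "chip", sim_offset=1, input="input"),
    ]
    return RunConfig(
        genome=genome, samples=samples, truth=truth,
        n_randomizations=10, outdir=str(outdir), seed=seed,
    )
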