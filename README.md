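# chipdomains

Tag-level processing, broad-domain enrichment calling, and
region-reproducibility analysis for ChIP-seq experiments — the kind of
genome-wide comparison used to validate that a library built from very
little DNA (tens of picograms of ChIP material, e.g. a repressive histone
mark like H3K27me3 in *Drosophila*) recovers the same enriched domains as a
conventional nanogram-scale library.  A synthetic tag simulator with known
ground truth makes every stage verifiable without downloading any data.

## Who this is for

Anyone who has aligned ChIP-seq tags (or wants to simulate them) and needs

* the standard tag-level cleanup: mismatch/multimapping filters,
  best-alignment selection, removal of anomalous single-position pileups,
  and the half-fragment shift that moves 5′ tag positions onto fragment
  centers;
* smoothed tag-density tracks and input-subtracted profiles;
* broad regions of enrichment called against a matched input control;
* a quantitative answer to "how reproducible are the called regions
  between two libraries?", calibrated against a randomized-region null.

## The model in brief

Tags are 5′-end coordinates of sequenced fragments.  After filtering
(keep tags with ≤ 2 mismatches in the first 28 bp and ≤ 5 reported
alignments, best alignment per read), positions whose per-strand tag count
has Z > 7 relative to all covered positions are discarded as amplification
artifacts.  Surviving 5′ positions are shifted ±75 bp (half the 150-bp
mean fragment size) toward the fragment 3′ end and the strands combined,
giving fragment centers *c₁ … cₙ*.

The density track is a Gaussian kernel sum with 50-bp bandwidth,

  d(x) = Σᵢ φ(x − cᵢ; σ = 50) (tags/bp),

and the input-subtracted profile is d_chip − (n_chip/n_input)·d_input.

Regions of enrichment are called on 1-kb bins.  With per-bin ChIP count
*c*, input count *i*, depth ratio *s* = n_chip/n_input and pseudocount
0.5, the null expectation is λ = s·i + 0.5 and

  Z = (c − λ) / √(λ(1 + s)),  fold = (c + 0.5)/λ.

Bins with Z ≥ 3 **and** fold ≥ 2 are enriched; enriched bins within 1 kb
merge, regions shorter than 2 kb are dropped, and each region is re-scored
over its merged span.  The variance term λ(1 + s) accounts for the
sampling noise of the input library as well as the ChIP counts, which
keeps the null tail at its nominal size at matched depths (see
`docs/methods.md`).

Reproducibility between two region sets is measured per region as the
*coverage value* — the fraction of its base pairs inside any region of the
other set — summarized as the fraction of regions with coverage ≥ t over a
threshold grid (for all regions, and restricted to regions with non-zero
coverage), and compared with the same curve against reference regions
re-placed uniformly at random with lengths and per-chromosome counts
preserved.

## Worked example

The bundled toy experiment simulates two ChIP replicates plus an input on
a 2-Mb two-chromosome genome with 10 planted domains (10–40 kb, fold 6),
PCR duplication, filter-failing tags and two hotspot pileups:

```sh
chipdomains run --outdir toy_demo --seed 0
```

prints

```
sample          role       total reads        filtered reads   clusters
input           input           39,138          35,683 (91%)        n/a
rep1            chip            39,649          35,970 (91%)         10
rep2            chip            39,819          36,075 (91%)         10
```

Each row is one library: simulated tags in, tags surviving all three
filters (with the retention percentage), and the number of called regions
of enrichment — both replicates recover the 10 planted domains.  The run
directory contains the filtered tag files, density and input-subtracted
bedGraph tracks, scored region BEDs

```
chr2L  124000  161000  region_00001  50.126680280988943  3.7148088035534195
```

(columns: coordinates, name, aggregate Z, aggregate fold), and the
pairwise reproducibility table `overlap_curves.tsv`, which at coverage
threshold 0.5 reads

```
pair          threshold  frac_all  frac_nonzero  rand_frac_all_mean
rep1 vs rep2  0.5        1         1             0.12
```

— every rep1 region is at least half-covered by rep2 regions, while
randomly re-placed regions would reproduce only ~12% of them.

The same stages are available as library functions
(`simulate_tags`, `filter_alignments`, `select_best_alignment`,
`remove_anomalous_positions`, `shift_and_combine`, `compute_density`,
`subtract_input`, `call_regions`, `coverage_values`, `overlap_curve`,
`randomize_regions`, `compare_samples`, `run_pipeline`) and as standalone
CLI subcommands (`simulate`, `filter`, `density`, `call`, `compare`,
`run`, `summarize`); externally aligned reads can be imported from SAM
with `chipdomains.import_sam`.

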