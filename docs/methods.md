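# Methods

This note documents the models, numerical choices and limitations behind
`chipdomains`, in the order data flows through the pipeline.

## Synthetic tag generator

The simulator produces the statistical structure a broad-domain histone
ChIP experiment exhibits, not sequence-level realism.  One
`SimulationTruth` fixes a genome, a set of non-overlapping enriched
domains, and the parameters below; the ChIP and input libraries are drawn
from independent child RNG streams of one master seed, so resizing one
library never perturbs the other, and identical truths give byte-identical
tag files.

* **Fragment starts** are drawn from a two-level mixture: per-bp weight
  `fold` inside domains, 1 outside (input: uniform).  Starts are
  restricted to `[0, L − fragment_size]`, so no fragment leaves its
  chromosome.  The closed-form in-domain mass — e.g. domains covering 10%
  of the genome at fold 5 give 0.1·5/(0.1·5 + 0.9) ≈ 0.357 of fragments —
  is what the mixture tests check against binomial error.
* **PCR duplication**: each unique fragment is emitted `1 + k` times with
  `k` geometric on {0, 1, …} with mean `dup_rate`.  Geometric is the
  simplest one-parameter law with a tail heavy enough to exercise the
  anomaly filter; real amplification-bias distributions are
  condition-specific and not modelled.  Low-input (picogram-scale)
  libraries are emulated simply by a larger `dup_rate` than
  nanogram-scale ones, which reproduces the qualitative signature that a
  larger proportion of their tags share a mapped position while most
  covered positions still hold a single tag.
* **Strand and 5′ position**: each emitted tag gets a fair-coin strand;
  plus-strand 5′ = fragment start, minus-strand 5′ = fragment end − 1.
* **Hotspots** inject a stated number of extra tags at one exact
  coordinate on one strand — the worst case for the anomaly filter, mimicking
  extreme amplification pileups.
* **Filter attributes**: `mm28` (mismatches in the first 28 bp) and
  `n_aln` (alignments reported) are drawn so that fractions `mismatch_p` /
  `multimap_p` of tags fail the respective filters; values are otherwise
  uniform over the passing range.  There is no base-level error model.

Not emulated: mappability and GC structure (background is uniform per
base), fragment-length dispersion (all fragments have the stated size),
chromatin accessibility bias, barcode/multiplexing artifacts.  Passing
tests therefore demonstrate algorithmic correctness on data with the
assumed mixture structure, not robustness to every bias of real
libraries; `import_sam` exists precisely so the pipeline can be pointed
at real alignments.

Domain placement (`plant_domains`, also the randomized-region null) uses
the gap-sampling construction: draw the cut points of the leftover space
uniformly, sort, and lay intervals down in a random order — uniform over
non-overlapping configurations, with an explicit error (never silent
truncation) when the requested interval mass cannot be packed.

## Tag processing

Defaults are the analysis constants used throughout: `max_mm28 = 2`,
`max_aln = 5`, anomaly threshold `Z = 7`, shift 75 bp (half of the 150-bp
mean fragment size), kernel bandwidth 50 bp, caller thresholds `Z ≥ 3`
and `fold ≥ 2`.

* **Quality filters** keep tags with `mm28 ≤ 2` and `n_aln ≤ 5`.  Tags
  imported from SAM without an `NM` tag carry the sentinel `mm28 = −1`
  ("unavailable"); the mismatch criterion is skipped for them with a
  warning rather than silently passing or failing.  SAM records lacking
  `NH`/`X0` get `n_aln = 1` with a warning.  `NM` counts mismatches over
  the whole alignment, so when it is present it is used for both
  `total_mm` and `mm28`; SAM simply has no per-prefix mismatch field.
* **Best alignment per read**: smallest `total_mm`, then smallest `mm28`,
  then lexicographic (chrom, pos, strand).  The tie-break carries no
  biological meaning; it exists to make output deterministic and is
  stable under input order (mergesort throughout).
* **Anomalous positions**: per-(chrom, pos, strand) counts over *covered*
  positions only; `Z = (c − μ)/σ` with the population SD; strict `Z > 7`;
  a single pass (μ, σ are not recomputed after removal).  Covered-only
  keeps the statistic independent of genome size; including the zero
  class would make μ and σ shrink with genome length and eventually flag
  every covered position.  If all counts are equal (σ = 0) nothing is
  removed.  In the sparse regime (counts ∈ {1, 2}) this filter does flag
  count-2 positions — with mostly-singleton coverage a doubleton is a
  14-σ outlier; the modal singleton class is never removed.
* **Shift and combine**: `+fragment_size/2` on the plus strand,
  `−fragment_size/2` on the minus strand, exactly as stated magnitudes.
  Because the minus-strand 5′ end is `start + fragment_size − 1`, the two
  strands of one fragment land 1 bp apart (`start + 75` vs `start + 74`
  at 150 bp); we accept this 1-bp asymmetry rather than inventing an
  asymmetric rounding rule.  Shifted positions are clipped to chromosome
  bounds so tag counts are conserved (clipping is logged via provenance).

Every step appends one provenance line with the counts it removed; the
pipeline summary's retention arithmetic (total − removed per stage =
retained) is exact by construction and re-checked against file line
counts.

## Density tracks

`d(x) = Σᵢ φ(x − cᵢ; σ = bandwidth)` evaluated on a fixed grid.  Choices:

* **Grid step 10 bp** (≤ bandwidth/5), making discretization error
  negligible relative to the 50-bp kernel.
* **Truncation at ±6σ.**  The omitted tail mass is < 2·10⁻⁹ per tag, so
  truncated tracks agree with the untruncated O(n·grid) sum to well
  within 10⁻⁶ of the track scale.  (At ±5σ the pointwise omission,
  ≈ 3.7·10⁻⁶ of the peak per tag, is visible at that tolerance near the
  truncation edge, which is why the support is one σ wider than a typical
  speed-first choice.)  Agreement is asserted as
  |truncated − oracle| ≤ 10⁻⁶·max(oracle) + 10⁻⁶·|oracle|: a strict
  pointwise ratio is unattainable for *any* finite truncation at grid
  points far from all tags, where the exact sum underflows toward zero.
* **Unit-mass kernel**, so track units are tags/bp and a track integrates
  to its tag count (±1% for tags ≥ 5σ from chromosome ends).  Published
  browser figures use arbitrary y-axis units; we do not reproduce any
  particular scaling.
* **Input subtraction** scales by the global depth ratio
  `n_chip/n_input` of total filtered tags — the simplest normalization
  consistent with comparing two libraries of different depth; negative
  values are preserved, not clamped.

## Enrichment caller

A transparent binned Poisson caller, *not* a re-implementation of any
published peak caller's internals: the two published thresholds it honors
are `Z ≥ 3` and `fold ≥ 2`.

* **Bin 1 kb**: broad repressive-mark domains span tens to hundreds of
  kb, so 1 kb resolution is ample, and at desk-scale depths (≈ 50
  tags/bin) keeps counts in the normal-approximation regime.
* **Statistic**: with per-bin chip count `c`, input count `i`, depth
  ratio `s`, pseudocount 0.5: λ = s·i + 0.5, `Z = (c − λ)/√(λ(1+s))`,
  `fold = (c + 0.5)/λ`.  The `(1+s)` factor is the variance of
  `c − s·i` under a Poisson null: λ estimated from a finite input
  fluctuates with variance ≈ s·λ, and ignoring that term inflates the
  null SD to √2 at matched depths (≈ 1.5% of bins past Z = 3 instead of
  the nominal 0.135%).  With the correction, exact Poisson computation
  gives P(Z ≥ 3) = 0.40% at per-bin mean 50 and 0.30% at mean 100 —
  discreteness and the estimated λ account for the remaining excess over
  the normal bound, and the rate does not grow with depth.
* **Pseudocount 0.5** guards the fold ratio against zero-input bins.
* **Merging**: enriched bins separated by ≤ max_gap (default one bin)
  merge; regions shorter than min_len (default two bins) are dropped;
  each region is re-scored (aggregate Z and fold) over its merged span.
  Raising either threshold can only shrink the called bp (monotonicity is
  property-tested).

## Reproducibility analysis

* **Coverage value** of a query region = fraction of its bp inside the
  union of the reference set (exact integer arithmetic; both sets must be
  internally non-overlapping — merge first, the code refuses otherwise).
* **Curves** use closed thresholds (coverage ≥ t), so the all-regions
  curve is anchored at 1 for t = 0.  The non-zero-coverage variant
  excludes regions entirely missed in the other sample; when no region
  has non-zero coverage the variant is reported as missing rather than 0.
* **Randomized null**: the reference set of each ordered pair is
  re-placed uniformly (lengths and per-chromosome counts preserved,
  overlap forbidden) and the curve averaged over `n_randomizations`
  (default 100; the pipeline's toy config uses 10) with per-threshold SD
  reported.  The expected coverage of a region against a randomized
  reference equals the reference's mass fraction of the chromosome (up to
  edge effects), which the Monte-Carlo tests verify.  Which side is
  shuffled is a convention; the expectation is the same either way.

## Pipeline, determinism, problem sizes

One YAML `RunConfig` fixes all parameters; every stage writes documented
text formats (tag files, BED, bedGraph, TSV) so any stage can be re-run
standalone from the CLI.  All randomness flows from explicit integer
seeds through `numpy` generators; reruns with the same config are
byte-identical in their region/curve/summary outputs (region scores are
written with 17 significant digits so BED round trips are exact to the
float).

Test and verification scenarios run on deliberately desk-scale problems —
a 2-Mb genome, 2·10⁴–10⁵ tags per library, 10–20 planted domains — chosen
so every scenario has ample per-bin counts for the statistics being
tested while the whole suite stays fast.  The statistics are
scale-free (rates, fractions, Z-scores), so nothing in the method depends
on these sizes.

## Known limitations

* The caller assumes Poisson bin counts; overdispersion from residual
  duplicates (after the anomaly filter) or chromatin structure would
  widen the null beyond the stated calibration.
* Input subtraction and scaling use one global depth ratio; no local
  background model.
* The anomaly filter is per-exact-position and single-pass; clustered
  artifacts spanning several positions are handled only insofar as each
  position individually exceeds Z = 7.
* `import_sam` cannot recover a true first-28-bp mismatch count from
  standard SAM fields; the mismatch filter is approximated by `NM` or
  skipped (with a warning) where `NM` is absent.
* The simulator's uniform background means mappability artifacts of real
  genomes are untested by the synthetic suite.
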