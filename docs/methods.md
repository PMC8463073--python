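# Methods

## Data model and coordinate conventions

All coordinates are 0-based, half-open (BED native); 1-based inputs must
be converted on read. A minus-strand gene's TSS is the last base of its
half-open interval (`end − 1`). Every profile, window, and offset is
expressed in transcription orientation: negative offsets are upstream of
the anchor for both strands. One convention throughout prevents
off-by-one drift between stages.

Coverage is held in binned tracks (default bin 5 bp). A bin's value is
the integral of the piecewise-constant bedGraph signal over the bin
divided by the bin width, with uncovered bases contributing zero; where
bedGraph intervals overlap — a point the dialect leaves ambiguous — later
lines overwrite earlier ones, deterministically, with a warning. The
5 bp default keeps summit estimates at the ~10 bp granularity at which
promoter-architecture offsets are conventionally reported. Tracks are
normalized to counts per million (CPM) via a single library-size scalar;
any fragment-size scaling is folded into that scalar by the caller,
since the package ingests coverage, not reads.

Smoothing is Gaussian with SD = bandwidth (default 25 bp for summit
estimation), truncated at ±4 SD and renormalized at array edges, so
non-negative input stays non-negative and interior mass is conserved.

## Metagene profiles and profile offsets

A metagene profile is the per-offset mean (or median; mean is the
default, matching the convention for published occupancy curves) of a
factor's coverage across anchors, on a symmetric grid of half-width
`flank` (default 1000 bp, the visual range over which promoter
architecture is usually displayed). Anchors whose window leaves the
chromosome are dropped and counted. The offset between two factors is
the difference of their smoothed profile argmaxes; ties break toward the
smaller absolute offset, then upstream (deterministic and conservative),
and a maximum on the grid edge is an error rather than a truncated
estimate.

## Summit calling and pairing

Within each candidate region the summit is the argmax of the smoothed
signal, reported at the center base of its bin; a call requires the
summit height to clear `min_enrichment` (default 2×) times a background
level, which defaults to the track's genome-wide median CPM. This is a
deliberately parameter-light, per-region caller: the package's analyses
need one summit per pre-defined region, not genome-wide FDR-controlled
peak discovery.

Summits are paired by shared region id, mirroring per-promoter analysis
and avoiding cross-genome matching ambiguity; regions lacking a detected
summit in either factor are excluded and counted, as are pairs farther
apart than `max_distance` (default 500 bp). Quantiles use linear
interpolation (boxplot convention). The replicate-vs-replicate distance
distribution of a single factor provides the null scale: with
per-replicate summit jitter SD σ the distances are |N(0, 2σ²)|, whose
median is 0.6745·√2·σ — the closed form the tests check against (≈44.8 bp
at σ = 47 bp). For two factors at true offset Δ the median of
|N(Δ, 2σ²)| is the Monte-Carlo oracle (≈90.7 bp at Δ = 90, σ = 47).

## Occupancy statistics

The per-region occupancy scalar defaults to the smoothed summit height
within the region (`window_mean` around the anchor is the alternative;
the method is recorded in the table). Correlations default to log10 with
pseudocount 0.1 CPM, since occupancy scatter is heavy-tailed and
published scatter plots are on compressed scales. Ratio analysis
median-centers the pseudocounted ratio so the median normalized ratio is
exactly 1.0, and calls high/low groups at ±1 log2 (two-fold) by default;
the cut is a package choice exposed as a parameter, since colored
scatter groups in the literature rarely state one. Deciles are
rank-based bins whose sizes differ by at most one. Label enrichment is
the upper hypergeometric tail (including the observed count) with fold =
(k/n)/(K/N), plus Benjamini–Hochberg adjustment; the implementation is
`scipy.stats.hypergeom`, cross-checked in the tests against exhaustive
enumeration of all draws at universe sizes ≤ 12.

## Pausing index

Per gene: mean CPM in a promoter-proximal window (default −50..+300 bp
around the TSS, a generous bracket for the promoter-proximal peak, which
has no canonical delimitation) divided by the mean CPM 2000–4000 bp
downstream of the TSS. For genes shorter than the body window the window
is truncated at the TES and flagged `short_gene_adjusted`; genes with
fewer than `min_body` = 500 bp of usable body, or zero body signal, are
excluded with a status rather than raising a division error. The index
is invariant under global track scaling.

## Peak-shape classification

Per gene, local maxima of the smoothed track are sought in a TSS zone
(±50 bp) and a downstream zone (+80..+300 bp, orientation-aware). Both
present, separated by ≥ 40 bp, with minor/major height ≥ 0.3 → bimodal;
otherwise the qualifying (or dominant) component decides at_TSS vs
downstream, and none if nothing clears background. The zone bounds and
ratio are explicit stand-ins for a criterion the literature leaves
qualitative; they are configurable, and merged peaks closer than the
separation threshold are classified deterministically by the dominant
maximum. A two-Gaussian decomposition was considered for merged peaks
and deliberately left out of the default path: the maxima rule is
parameter-light and directly testable against planted truth.

## Synthetic data generator

The generator emulates the data regime of multi-factor promoter ChIP-seq
rather than read-level sequencing: no FASTQ, mappability, or GC model.
Per factor, coverage around each anchor is occupancy × Gaussian(offset +
jitter, peak SD) evaluated at bin centers, plus a uniform background.

Defaults and what they emulate:

- **Summit offsets** — preset architectures encode the published
  promoter geometry: human/mouse mode has the GTF-class factor at the
  TSS, paused Pol II +50 bp, SP1-class activators −80 bp; fly mode has
  TBP and Mediator at the TSS, TAFs and paused Pol II +60 bp, GAGA-class
  factors −60 bp.
- **Peak SD 60 bp** — a ~140 bp FWHM single-PIC footprint, typical of
  sonication-resolution ChIP peaks.
- **Jitter SD 47 bp** — per-region, per-replicate summit displacement
  chosen so that the replicate-null median is ~45 bp, the experimental
  variation observed between biological replicates.
- **Occupancy** — log10 occupancy ~ N(1.5, 1.0): heavy-tailed scatter
  over ~±3 decades around ~30 CPM, matching the appearance of published
  occupancy dot plots; no published distribution exists, so this is a
  calibration choice. Coupled factors add N(0, σ_n) on log10, giving the
  closed-form Pearson 1/√(1+σ_n²/σ_b²) used for validation.
- **Discordant subsets** — a planted fraction of promoters shifts the
  numerator factor by a log2 amount and tags the gene class, making
  ratio-classifier recall directly measurable.
- **Downstream peaks** — a planted subset carries a second component at
  +150 bp (default) with minor/major height 0.6 (bimodal) or a fully
  shifted peak.
- **Gene-body plateau** — the Pol II factor can carry a uniform plateau
  from TSS to TES at `body_level_ratio` (default 0.1) of its peak
  height; an optional `occupancy_exponent` scales the per-gene ratio by
  (occupancy/median)^γ so a positive γ plants a falling pausing index
  with rising occupancy — substrate for the decile analysis.
- **Enhancers** — two divergent PICs at ±100 bp around the midpoint
  (200 bp spacing; divergent PICs are typically too close to resolve,
  and no measured spacing exists, so this is a round choice). Each
  enhancer draws an asymmetry weight shared across factors, so the
  dominant PIC — and hence the single called summit — is the same for
  every factor, keeping per-region pairing well defined.
- **Noise** — optional Poisson count noise on binned values before
  normalization, off by default so geometry tests are exact; background
  0.05 CPM.

Region layout places each promoter/enhancer in its own slot wide enough
to contain its gene body and flanks, so no signal leaks into a
neighbor's analysis windows. Anchors are placed at bin centers (≡ 2 mod
5 for 5 bp bins): real TSSs are not bin-aligned, and a summit at a bin
boundary would be recoverable only up to a tie. One RNG stream per
(purpose, factor, replicate) is derived from the master seed via named
`SeedSequence` keys, so adding a factor or replicate never perturbs
other draws and a fixed seed is bit-reproducible.

What passing tests on this generator do **not** show about real data:
real ChIP peaks are asymmetric and multi-modal, backgrounds are
non-uniform (accessibility, copy number), occupancy coupling is not
homoscedastic on the log scale, and replicate variation includes
efficiency differences beyond positional jitter. Parameter-recovery
results here validate the estimators' correctness, not their robustness
to those real-data pathologies.

## Pipeline and reproducibility

A run is one YAML document: exactly one of a `simulate` or `inputs`
block plus an `analysis` block of stage switches. Validation returns a
list of violated constraints with dotted paths before anything runs;
independent stages continue past a failed one, with failures collected.
Every stage's defaults are materialized into `manifest.json` alongside
package/library versions and SHA-256 checksums of inputs, so default
drift is visible and a manifest plus seed reproduces the run byte for
byte. bedGraph output uses shortest-round-trip float formatting, which
makes re-analyzing persisted tracks bit-identical to the in-memory
end-to-end run (a property the test suite asserts on whole files).

## Problem sizes used in the validation suite

Parameter-recovery checks use 10,000 regions for stochastic quantities
(distance medians, discordant fractions, correlations; sampling error of
the correlation at n = 10,000 is ~0.004) and 1,000 promoters for
noise-free offset recovery, where the estimate is exact by construction.
Distance simulations use compact regions (flank 600 bp, gene length
400 bp) since only summit windows matter there; pausing analyses use
6 kb genes so the 2000–4000 bp body window is untruncated.

## Known limitations

- One summit per factor per region; multi-PIC regions beyond the
  two-PIC enhancer model are out of scope.
- One TSS per gene row; isoform choice is delegated to the input table.
- The summit caller is not a genome-wide peak caller and reports no FDR.
- bigWig input is not supported; convert to bedGraph first.
- Hypergeometric enrichment is over user-supplied labels; no ontology
  service is queried.
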