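# Methods

`leaderbin` implements, as a self-contained and testable pipeline, the
evaluation framework behind *leaderboard metagenomics*: sequence many
samples at moderate depth, assemble and bin the abundant ("leaderboard")
community members, and evaluate the resulting short-read assemblies
against internal reference genome bins built from high-accuracy
long-read-style contigs of the same samples. This note records the
models, their assumptions, the tunable parameters, and the design
choices made where the methodology left the design open.

## Synthetic communities (`simdata`)

**Genomes and markers.** A community of *G* genomes is generated as
i.i.d. nucleotide sequence at a per-genome GC target, with *M* = 40
universal single-copy marker loci of 300 bp planted one per
equal-width slot. Marker families share a canonical sequence per family
and diverge at 5% per genome, mimicking conserved single-copy
protein-coding genes. Downstream completeness and redundancy are
resolved through the provenance annotations every emitted contig
carries (source genome and interval), which makes marker accounting
exact and deterministic; an exact k-mer detector
(`binscore.detect_markers_kmer`) is available for external FASTA whose
bins match a marker database near-verbatim, but HMM-based marker search
is out of scope.

**Abundances.** Per genome, latent log-abundances follow a stationary
AR(1) process across the sample axis with marginal spread `sigma_log`
(default 1.0) and lag-1 autocorrelation `rho`; columns are normalized
to sum to one. `sigma_log = 0` gives a flat community; `rho = 1` gives
identical samples. Default S = 12 samples for binning experiments —
differential-coverage binning is most reliable with more than ten
abundance profiles.

**Coverage.** Expected per-base depth is `abundance × total_depth` with
Poisson per-base noise. The `transposase` preset multiplies the
expectation by a GC-deviation penalty (`exp(-2·s·|GC_local − GC_mean|)`
on 200-bp windows, sensitivity *s* = 3) and by dropout windows (2 kbp
windows at 5% of the expectation covering ~5% of the genome), then
renormalizes the combined factor to mean one. This is a declared
stand-in for tagmentation coverage unevenness; no quantitative model of
that bias was available to calibrate against, so the parameters are
round numbers chosen to reproduce the qualitative signature (excess
low-coverage bases at matched mean depth).

**Assembly emulation.** Short-read assembly is emulated by
coverage-threshold fragmentation: the genome is cut wherever
(optionally smoothed) depth falls below `break_depth` (default 2×), and
runs of at least `min_contig` (500 bp) are emitted with substitutions
and indels injected at stated per-base rates. Smoothing
(`smooth_window`, default off; 100 bp in the pipeline) models breakage
at read-length scale rather than at single anomalous bases — unsmoothed
Poisson noise would fragment even well-covered genomes below ~8×. This
model deliberately ignores repeats, chimeras and graph artifacts; real
assemblies are accepted as FASTA + depth TSV at every evaluation stage.

**Long-read-style references.** Each genome is tiled end-to-end by
segments of 3–10 kbp with substitutions injected at 0.1% — the
error regime of synthetic long reads, which are accurate enough to act
as internal references yet not error-free, so measured mismatch rates
of assemblies include a reference-error floor of ~100 per 100 kbp.

## Bin scoring and selection (`binscore`)

Completeness *C* is the fraction of marker families with ≥ 1 fully
contained copy; redundancy *R* the fraction with ≥ 2 copies. *R* is
normalized by *M* so that *C* and *R* are commensurate in the score.
Bin abundance *A* is the length-weighted mean contig depth in the bin's
origin sample (length weighting is a robustness choice; plain averaging
of per-contig depths would let short contigs dominate). The score is

    score = w_c·C − w_r·R + w_a·(A / A_max),  (w_c, w_r, w_a) = (1, 1, 10)

with A_max the most abundant bin's depth in that sample. The abundance
weight dominates by design: among complete, clean candidates the most
abundant genomes are preferred as internal references. Reference
selection filters at C > 0.85 and takes the top five by score (ties:
higher C, then bin id). MAG tiers use strict inequalities:
high-quality draft requires C > 0.90 and contamination < 0.05, medium
C > 0.70 and contamination < 0.10; contamination is taken to be *R*
when only marker data exist.

## Reference-based evaluation (`refeval`)

Contigs ≥ 500 bp are aligned to reference contigs by exact 21-mer
seeding on both strands (seeds occurring > 100 times are masked as
repeats); per (contig, reference) pair the seed span is extended to the
available sequence ends and aligned semi-globally with banded edit
distance (edlib), with an edit-distance cap of max(200, 10% of the
segment) and a window pad of max(2%, 50 bp) for indel drift. The
extended CIGAR gives exact mismatch and indel counts. Blocks under 95%
identity are discarded (the conventional reference-evaluation default);
ambiguous bases never match. One best block is kept per pair; a contig
may align to several references.

Metrics: genome fraction = percent of reference bases covered by ≥ 1
block (overlaps counted once); mismatch and indel rates are per 100 kbp
of aligned reference bases, an indel run of length L counting L events
(switchable in principle to per-run counting, but per-base counting
matches the per-100-kbp rate framing); N50 is the largest L such that
contigs ≥ L sum to at least half the assembly; totals above {3, 5, 10,
50} kbp and the largest aligned contig are reported per reference.
`fraction_vs_abundance` computes per-reference-contig genome fraction
against a per-contig depth proxy for abundance-stratified recovery
curves. Misassembly-event classification (relocations, inversions) and
NGA50 are out of scope.

## Differential-coverage binning (`binning`)

Features are 136 canonical (reverse-complement-collapsed)
tetranucleotide frequencies plus log-coverage: `log(depth_s + 1)` per
sample (*per-sample* mode) or a single `log(Σ_s depth_s + 1)` (*pooled*
mode — the profile a single pooled read set would produce, emulating a
low-N high-depth strategy; pooling is depth-sum, i.e. read-pooling
equivalent, not depth-mean). Clustering is PCA retaining 90% variance
followed by full-covariance Gaussian mixtures for each K in range, K
chosen by minimum BIC; non-converged fits are skipped with a warning.

Two numerical choices matter. First, no per-dimension standardization
is applied before PCA: frequencies and log depths are already on
commensurate scales, and standardizing would inflate the per-4-mer
sampling noise of short contigs to the same weight as the coverage
signal, degrading model selection. Second, all statistics (PCA, EM) are
computed on a canonically sorted copy of the feature matrix and labels
are predicted row-wise on the original order, so assignments are
exactly invariant to contig input order. The default binning length
floor is 1 kbp (the floor the original tools used is not constrained;
it is configurable).

The mode comparison runs both coverage modes on identical contigs and
reports per-genome best-bin completeness/contamination and their
deltas, plus adjusted Rand index against genome-of-origin truth. The
constructed separability experiment uses *composition twins* — a
genome re-sampled from its own 3rd-order Markov chain, preserving
tetranucleotide statistics in expectation while destroying identity —
with anticorrelated abundance trajectories, so that pooled coverage
(whose sums are equal for both twins) destroys the only separating
signal. This demonstrates the direction of the per-sample advantage,
not its magnitude on any real data set.

## Dereplication (`derep`)

Pairwise bin similarity uses bottom-5000 MinHash sketches of canonical
21-mers (splitmix64 mixing) and the Mash relation
`ANI = 1 + ln(2J/(1+J))/k`, clamped to [0, 1] — adequate in the ≥ 99%
replicate regime this stage discriminates; alignment-based ANI is not
attempted. Clustering is two-stage single linkage: coarse groups at
90% ANI, replicate clusters at 99% (configurable). Within a cluster the
winner maximizes `completeness − 5 × contamination` (the core of the
standard dereplication quality formula, dropping its N50 and
strain-heterogeneity terms), ties broken by total length then bin id;
winner origins are tallied over all clusters and over clusters whose
winner is a high-quality draft.

## Index plates (`indexes`)

384 i7 and 384 i5 error-correcting indices are assigned by a cyclic
rotation: well *w* of plate *p* receives `(i7[w], i5[(w+p) mod 384])`.
Within every plate all indices and all pairs are distinct, and any pair
recurs only after 384 plates = 147,456 libraries. The rotation schedule
itself (cyclic +1 per plate) is the simplest scheme achieving that
period and is an assumption; indices are abstract ids 0–383, with real
oligo sequences supplied by the user as TSV.

## Pipeline scale and determinism (`io`/`pipeline`/`cli`)

The demo `run-all` uses G = 10 genomes of 500 kbp (≈ 5 Mbp of
community sequence), S = 12 samples, total depth 300×, GC targets
spread over 0.35–0.65, and two chemistry presets (ligation-like uniform
with indel rate 2×10⁻⁵; transposase-like biased with indel rate
2×10⁻⁴; both at substitution rate 2×10⁻⁴). The binning-mode comparison
runs on the long-read tiling contigs (with Poisson-resampled per-contig
sample depths), which are the fragmented multi-sample substrate of the
run — emulated short-read assemblies at adequate uniform depth are
nearly unfragmented and would make clustering trivial. Every stage
derives its seed from the top-level seed and the stage name (BLAKE2
hash, < 2³¹); every writer is byte-stable; reruns of the same config
reproduce the run directory verbatim, and read subsampling (reservoir,
mates synchronized, default ten million pairs) is deterministic given
its seed.

## What passing tests do and do not show

The simulator omits read-level artifacts (quality profiles, adapters,
paired-end mechanics), repeat structure, strain mixtures, and
inter-genome homology beyond the shared marker families. Passing the
suite therefore certifies the *evaluation machinery* — the score
equation, the metrics and their oracles, the mode-comparison direction
under the constructed conditions, dereplication at the stated ANI
regimes — not the performance of any laboratory protocol on real
communities. Real contig FASTA and coverage TSV inputs are accepted at
every evaluation stage for exactly that reason.
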