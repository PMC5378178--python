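# Methods

This note records the models, defaults and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Replication-rate model (PTR)

A population in which a fraction of cells is replicating over-represents
origin-proximal DNA. With bidirectional replication from a single origin,
expected coverage at circular origin-distance fraction `d ∈ [0, 0.5]` is

    E[cov](d) = cov_ter · PTR^(1 − 2d)

so log-coverage falls linearly from origin to terminus on each replichore
and the peak-to-trough ratio (PTR = cov_ori / cov_ter) summarizes growth:
1.0 is no detectable replication, 2.0 is on average one active fork pair
per cell. Assumptions: a single origin, a terminus roughly opposite it,
and coverage unbiased apart from the replication gradient.

`estimate_ptr` bins coverage in circular sliding windows (default 10 kb
window, 100 bp slide), median-filters the bins (kernel = one window of
bins, i.e. 101 bins at the defaults, circular wrap), and excludes
zero-coverage bins and the top/bottom 1% of filtered bins before reading
off peak and trough. Bins are indexed by their *centers* so the peak bin
straddles the origin symmetrically; with the defaults this keeps the
noise-free bias below ~1% at PTR 2 on a 2 Mb genome. Two modes:

* `gc_skew` — peak/trough are the filtered values at an externally
  supplied ori/ter (the recommended mode when the skew call passed QC);
* `coverage` — peak/trough are the global filtered extrema subject to a
  circular separation of 40–60% of the genome. The constraint encodes the
  terminus-opposite-origin geometry and stops prophage or repeat coverage
  spikes from posing as origins.

PTR is reported as max/min (always ≥ 1) and the peak/trough positions are
reported separately, so a flipped skew convention cannot silently invert
the ratio; a flag records when the supplied "origin" carried less coverage
than the "terminus". Tracks with raw median coverage below 5× produce an
explicit no-call rather than a clamped estimate, and downstream statistics
drop no-calls. Whether peak/trough should be raw or filtered bin values is
not externally fixed; filtered values are used and the choice is flagged
here.

Growth statistics use the tie-corrected Mann-Whitney U test between body
sites (exact null for small tie-free samples, scipy's automatic policy)
and Spearman rank correlation (ties mid-ranked) of PTR against day of
life within a site.

## GC skew, ori/ter, and QC

Windowed skew is `(G − C)/(G + C)` per window (0 where a window has no G
or C); the default window is 1 kb, non-overlapping, which resolves ori/ter
to ~0.1% of a 1–5 Mb genome. No canonical window size exists for this
statistic; 1 kb is this package's default and is configurable.

Ori/ter are the extrema of the **detrended** cumulative skew: the running
sum minus its linear closure trend `(i+1)·total/n`. Detrending makes the
track exactly circular, so extremum positions are *exactly* equivariant
under genome rotation — on the raw cumulative sum they are not, because
the total skew of a real sequence is not exactly zero. Convention: leading
strand G-rich, minimum → origin, maximum → terminus. When a coverage track
is supplied the convention is auto-checked against the coverage peak and
flipped with a logged warning if the peak sits nearer the skew maximum. A
constant cumulative skew returns an explicit no-call.

QC replaces a manual inspection step with a score: the detrended
cumulative skew of a correctly assembled chromosome is a two-segment
sawtooth, so the score is the minimum over the two replichore segments of
the R² of the *anchored* linear fit (the continuous circular sawtooth
through the called extrema), clamped to [0, 1]; pass requires ≥ 0.8
(configurable). The anchored, per-segment-minimum form was chosen over an
unconstrained two-segment least-squares fit because free fits score pure
random walks generously (~24% above 0.8 in simulation); the anchored
minimum passes ~2% of random walks while scoring ideal genomes above 0.95
down to skew amplitude 0.05.

## Contig ordering

Anchoring is exact-match seeding: maximal exact matches of length ≥ k
(default k = 31) between contig and reference, found on both strands via a
k-mer index of the doubled reference (each circular locus indexed once;
match copies shifted by +L let chains cross the origin), merged per
diagonal, and chained into the highest-weight collinear chain by O(n²)
weighted LIS. Chained anchors may overlap by up to k−1 bases where a match
crosses the wrap point; the overlap is subtracted from the chain weight.
Exact matching is sufficient for same-species drafts (> 99% ANI) and keeps
the step deterministic and dependency-free.

Contigs whose chain covers < 20% of their length are discarded with a
recorded reason. Retained contigs take the strand of their best chain,
are placed at the median reference position of their chained bases (mod
L), sorted by placement (ties: longer contig first, then contig id), and
concatenated **without gap padding** — the core genome is a coordinate
scaffold for windowed statistics, and gaps would distort them. Coverage
liftover reverses '-'-strand tracks and writes each at its core offset.
Reference selection (when several complete references exist) is the
caller's responsibility.

## Consensus ANI and population census

The mask is the union of: the first/last 100 bp of every scaffold
(default `end_buffer`), all supplied conserved intervals (rRNA/tRNA BED),
and positions below 5× depth (default `min_depth`) — the quantitative
buffers are this package's defaults for qualitative rules, both
configurable and logged. A variant position is an unmasked position where
`(depth − ref_count)/depth ≥ 0.80`; the conflict fraction uses total depth
rather than the top alternate allele, matching the notion of "reads
conflicting with the reference". Consensus ANI is exactly
`1 − variants/unmasked_length`. Identity requires ANI **strictly** above
0.999. Breadth counts positions with depth ≥ 1 (threshold configurable);
phage/plasmid carriage requires breadth ≥ 0.99.

Colonist calls: a genome is a colonist of a body site if any sample of
that site attributes ≥ 1% of its non-human reads to it. The
depth-normalised presence cutoff for low-abundance detection is
`100 · (0.1 · genome_length / read_length) / min(total_sample_reads)` —
the read percentage equal to 0.1× coverage in the shallowest sample —
shared by all samples; presence at the cutoff is inclusive. Populations
are connected components of the pairwise-identity relation; a population
is multi-site iff it is a colonist of ≥ 2 body sites of one infant, and
populations spanning infants are counted separately.

## SNV trajectories and cohorts

Candidate sites need, in ≥ 1 sample with depth ≥ 3, a most-abundant
non-reference allele at frequency ≥ 0.2; the trajectory's alternate allele
is then fixed to the globally most abundant non-reference base. Retention
requires all four of: depth ≥ 10 in every sample, frequency > 0.2 in ≥ 2
samples, position outside conserved regions, and an autocorrelation gate.
The autocorrelation statistic is not externally specified; lag-1
autocorrelation of the chronologically ordered frequencies with threshold
≥ 0 is used (exposed as `autocorr_min`), which removes sample-to-sample
zigzag noise while keeping any smoothly varying trajectory. A constant
trajectory is scored 1.0 (perfectly self-consistent) rather than NaN.

Clustering is agglomerative with average linkage on correlation distance
(1 − Pearson r), cut at 0.275. Whether that cutoff was originally meant
for correlation or Euclidean distance is ambiguous; correlation distance
is the default here because cohort membership is about trajectory *shape*,
not amplitude, and both metric and linkage are configurable. Constant
trajectories get distance 1 to everything (correlation undefined);
undefined frequencies (zero depth) are rejected rather than imputed.
Between-site differentiation is a two-sided Fisher exact test on the
(alt, non-alt) × (site A, site B) read-count table, Bonferroni-corrected
over the retained variant positions.

## CRISPR

Spacer identity is strand-agnostic exact sequence equality (no fuzzy
spacer clustering); array alignment is the longest common subsequence of
spacer identities, so shared blocks respect array order and duplicated
spacers are reported at every position. Protospacer search reports every
full-length occurrence of a spacer on either strand with ≤ 1 mismatch
(default), via a pigeonhole-seeded scan (split into max_mismatch+1 exact
chunks, candidates verified by Hamming distance). Hits within one
repeat+spacer length of a full-length repeat match are excluded — a spacer
flanked by repeats is the CRISPR array itself, not a target — and targets
flagged as CRISPR-containing can be excluded wholesale.

"Unique regions" of two array variants are the maximal intervals of one
locus whose every 30 bp window (configurable) is absent from the other
locus on either strand. Variant mixture per sample is
`rate_A / (rate_A + rate_B)` with counts divided by unique-region length
by default (unbiased mapping expectation; raw-count mode behind a flag),
and a no-call when both counts are zero. SNV↔array linkage is Pearson
correlation over shared samples, Bonferroni-corrected over all SNV ×
variant pairs; constant series are no-calls.

## Synthetic data: what it emulates, and what it does not

The generator produces, with recorded ground truth: genomes whose G/C
composition is biased per replichore (skew imposed on *sequence*, default
amplitude 0.1 — mid-range for bacterial chromosomes); coverage tracks
drawn Poisson around the PTR gradient (or rounded expectations in
noise-free mode) — Poisson is the simplest model of shotgun sampling;
pileups built by binomial sampling of haplotype mixtures at planted sites
with uniform base errors elsewhere (errors drawn uniformly from the three
non-reference bases); fragmented assemblies whose cut points are
controlled separately from shuffling/strand flips, so the fragment
multiset is reproducible across arrangement seeds; trajectory benchmarks
whose latent cohort curves are distinct circular Fourier modes on the
sample grid — mutually orthogonal, hence at correlation distance exactly
1, making the planted partition identifiable by construction; and CRISPR
systems with protospacers planted at 0/1/2 mismatches plus an optional
full array planted in one phage to exercise repeat filtering.

Synthetic study tables stand in for per-sample summaries that would
ordinarily come from read mapping: a growth table with 135 gut
measurements carrying a planted PTR-vs-age rank correlation of 0.31 and
25 mouth/skin measurements drawn systematically faster (1 + lognormal, so
PTR ≥ 1 always), and a two-infant colonization plan with seven multi-site
populations and none shared between infants.

Not emulated: read-level artifacts (mapping bias, duplicated reads, indels,
strand bias), assembly chimeras, horizontal transfer, recombination
between haplotypes, uneven GC-dependent coverage, or cross-taxon read
recruitment into conserved regions. Passing tests therefore demonstrate
correctness of the estimators under their stated statistical model, not
robustness to every artifact of real sequencing; the masking and QC gates
are the designed defenses against the latter and are exercised on planted
failure modes only.

## Numerical choices and degenerate inputs

* Circular coordinates are 0-based; distances are computed modulo genome
  length throughout.
* Bins/windows are reported at centers (PTR) or starts (skew profile);
  rotation equivariance of ori/ter is exact for window-aligned rotations.
* Ties: placement ties break by contig length then id; `fcluster`
  assignment order is scipy's; Mann-Whitney uses average ranks.
* Degenerate inputs produce explicit errors or no-calls, never silent
  clamps: empty tracks, fully masked genomes, zero-depth Fisher tables,
  constant skew, constant correlation series, sub-5× coverage.
* Determinism: every stochastic routine takes a seed or Generator;
  identical seeds give byte-identical outputs.

## Problem sizes used in the test and acceptance runs

PTR recovery runs 20 seeds × 4 planted ratios on 2 Mb tracks at 50×;
skew/ordering checks use 100–400 kb genomes (1 kb windows, 10 contigs);
consensus-ANI bookkeeping uses 100 kb pileups; trajectory benchmarks use
5–17 samples at depth 100–500 with 35–47 planted variants. These sizes
were chosen to give each estimator its asymptotic regime (bin counts,
anchor uniqueness, binomial depth) while keeping the full suite fast.

## Known limitations

* Ordering assumes a collinear same-species reference; large inversions
  or rearrangements between draft and reference will fragment chains and
  can push true contigs under the 20% coverage rule.
* The PTR separation constraint assumes ter roughly opposite ori; genomes
  with strongly asymmetric replichores would need a wider band.
* The cohort count at a fixed cutoff is sensitive to the distance metric
  for borderline trajectories; the 0.275 default is calibrated for
  correlation distance.
* Consensus ANI treats every unmasked position independently; linked
  errors (e.g. a misassembled segment that escapes masking) appear as
  clustered false variants.
* The variant caller fixes one alternate allele per site; genuinely
  triallelic sites are collapsed to the dominant alternate.
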