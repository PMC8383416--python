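# Methods

This note documents the models, parameter defaults, numerical choices and
known limitations of circlechrom, in the order the pipeline runs.

## Circle detection from split alignments

A read that traverses the head-to-tail junction of a circular template
produces two alignment segments.  The classifier accepts a read-ordered
segment pair as junction evidence iff (i) both segments are strictly longer
than `min_seg_len` (default 1000 bp), (ii) both map to the same chromosome,
(iii) both map to the same strand, and (iv) the pair is outward-oriented.
"Outward" is formalized as: for a + strand pair the later segment's
reference interval ends at or before the earlier segment's start
(`b.ref_end <= a.ref_start`); mirrored for −.  This is exactly the geometry
produced by a single traversal of at most one junction crossing with read
length at most the circle size — the test suite checks the inequality form
against an independent base-by-base circular-walk oracle on an exhaustive
grid of two-segment configurations.  Colinear splits (ordinary linear
templates with gaps or deletions) are rejected because they are explained
without a circle.

Segments may overlap on the read by up to `read_overlap_slack` (default
100 bp, an allowance for supplementary-alignment trimming artifacts); larger
overlaps reject the pair.  Each read contributes at most one candidate — the
qualifying pair with the largest combined segment length, ties to the
smaller start — reflecting that one read is one molecule.  Candidates
outside `size_range` (default 50 bp – 100 kb, both ends configurable because
assembled circle lengths in this assay family reach the megabase range) are
dropped.  Candidates are clustered by single linkage: linked when both
breakpoints agree within `tolerance` (default 50 bp, typical long-read
breakpoint wobble); record breakpoints are lower medians of members, support
counts distinct reads.

## Circular references and liftover

Each record gets a private reference `N^pad + rotate(core, rotation) +
N^pad`, where `rotate` moves the first `rotation` bases of the genomic
interval to the end.  The default rotation `size // 2` centers the junction
so window scoring near it has full context on both sides.  The default pad
is 10 kb — enough to keep desk-scale reads mappable past the core without
ballooning the reference; it is a parameter, so much larger pads can be used
when reads far exceed circle sizes.  Liftover between reference and genome
coordinates is exact on the core (`genome_pos = origin_start + (pos − pad +
rotation) mod size`) and undefined on pads; the round-trip identity is
property-tested over randomized (size, rotation, pad).  Signed junction
distance is the circular distance to the junction point, positive
downstream, in (−size/2, size/2].

Re-alignment of reads to these references is out of scope (an external
aligner's job); instead, genome-coordinate calls of junction-supporting
reads are re-expressed in circle coordinates through the inverse liftover,
which is equivalent for simulated data with exact alignments.

## Probability mixture and the m6A cutoff

Raw per-base m6A probabilities from a treated sample are fitted,
untransformed on [0, 1], with a 2-component Gaussian mixture by EM.
Gaussians on a bounded support leak probability mass past the boundaries;
the fit accepts this (densities are not truncated) for fidelity to the
distribution actually observed, and the resulting bias on component means is
well under 0.01 at the default parameters.  Initialisation is deterministic:
means at the 25th/75th percentiles, equal weights, both sds at half the
inter-quartile spread (floored at 1e-3).  Convergence is a log-likelihood
improvement below `tol` (1e-6) within `max_iter` (500); the per-iteration
log-likelihood is asserted non-decreasing.  A fit with component means
closer than 0.02 or a weight under 0.01 is flagged degenerate: not
converged, no cutoff, diagnostic attached.

The cutoff is the posterior crossover: the smallest point between the means
where the weighted signal density reaches the weighted noise density, found
by a sign-change scan on a 4001-point grid refined by Brent's method
(xtol 1e-6).  A closed-form solution of the log-density-equality quadratic
serves as its oracle in the tests, never as the implementation.  The
published constant 0.53 remains available as a fixed bypass
(`--fixed-cutoff` / `cutoff=0.53`, the pipeline default), since how that
constant was derived from a fit is not specified anywhere; both pathways are
first-class.  Binarization is strict: methylated iff probability is over
the cutoff, so a call at exactly the cutoff is unmethylated and methylated
counts are non-increasing in the cutoff.

Specificity of a cutoff is the fraction of control (unmethylated-sample)
values below it.  Sensitivity is defined here as: among treated values the
fit assigns to the signal component (posterior > 0.5), the fraction at or
above the cutoff.  Ground truth for "true positive" is not observable in
real data, so this definition — fixed and documented — is what the package
reports.

## Accessibility scores

The bulk score of a bin is the pooled methylation ratio: m6A bases in all
covered reads under the bin divided by adenosine bases in all covered reads
under the bin.  Bins are 50 bp sliding every 5 bp, tiled from coordinate 0
(the phase is a convention; only sizes are inherent to the method), complete
bins only.  Everywhere a regional average is reported it is the
count-weighted pooled ratio, never a mean of bin ratios.  Strand-resolved
tracks restrict to calls on one strand; both-strand counts equal the sum of
the strand-resolved counts bin by bin.

Metagene profiles anchor at TSS or TES, flank ±500 bp on the 5-bp grid,
flip − strand genes so positive offsets run transcription-downstream, and
average per-gene pooled ratios over genes with defined coverage.  When
pooling several sources (e.g. circle-derived vs linear calls), each source's
counts are first divided by its mean per-site read depth (calls per distinct
covered adenosine site) — a scale normalization under which duplicating
every read changes nothing.  No formula for depth normalization is canonical
in this assay family; this one is the package's choice.  Expression strata
rank genes by descending expression: top 25% high, 25–75% medium, bottom
25% low, boundaries at `ceil(n * 0.25)`, ties promoted to the better
stratum.

Nucleosome dyads are called from a track as the midpoints of contiguous
below-threshold bin runs of at least `min_run_bins` (default 15 bins ≈
120 bp of bin starts).  The expected track is flat across the interior of a
147-bp footprint, so the literal argmin within a footprint is
noise-positioned; the run midpoint is the consistent estimator.  The default
threshold is the midpoint of the 10th and 90th percentiles of defined bin
ratios.  The same logic locates flat-topped metagene peaks
(`profile_peak_offset`: midpoint of the above-half-maximum run containing
the argmax).

## Single-molecule calls and COA

For one read and a non-overlapping window grid (default 200 bp — about the
resolution of accessible regions in this assay — tiled from 0), the open
posterior aggregates the raw probabilities of the window's adenosines as
independent draws from the fitted mixture's signal vs noise component, under
a configurable prior (default 0.5).  Windows with fewer than `min_A`
(default 2) covered adenosines are no-calls.  Open requires posterior
strictly above 0.5; an exact tie is called closed (documented tie-break).
The posterior is monotone in every single probability.

COA between windows i and j is the mean over spanning molecules (defined
state in both windows; at least `N`, default 5) of
`1 − |Aᵢ − Aⱼ| / (Aᵢ + Aⱼ)`.  With binary A the term is an agreement
indicator once the undefined 0/0 case (both closed) is taken as 1 — the only
convention making COA of a window with itself equal 1 when the window is
closed.  A continuous mode uses the open posteriors as A instead; binary is
the default.  Pairs are restricted to one reference.  The distance summary
averages defined entries per window separation; its background level is the
mean over separations in the top quarter of the available range, and the
reported correlation range is the largest separation whose mean exceeds that
background.

## The simulator

The generator emulates the assay at desk scale: a 100 kb uniform-random
genome (vs gigabase real genomes), 8 non-overlapping genes with alternating
strands and log-normal expression, chromatin as an alternating 147 bp
nucleosome / 50 bp linker tiling with a 300 bp NDR centered at each TSS,
5 excision circles of 2–10 kb, reads of 5–50 kb (the real 10–100 kb scaled
with the genome) at 30x mean depth, and per-base probabilities drawn from
clamped Gaussians — noise N(0.49, 0.05) under nucleosomes, signal
N(0.85, 0.08) in open chromatin, matching the mixture the analysis fits
(model-consistent by design; a Beta-draw flag exercises mis-specification).
A fixed `round(0.009 · n_reads)` count of reads derives from circles — the
0.9% composition observed after exonuclease enrichment of circular DNA —
with uniform entry points; a read crossing the junction emits two
same-strand outward segments, with optional ±`breakpoint_jitter` on the
junction-side endpoints.  An optional strand asymmetry subtracts a constant
from the − strand signal mean.  Everything is deterministic under one seed.

At these conditions ~110 reads are drawn, so typically a single circle read
exists and only one of the five truth circles is represented by a
junction-spanning read.  Detection recovery is therefore measured against
the *detectable* truth: circles with at least one junction-spanning read
whose both arms exceed the detector's minimum segment length — a detector
cannot recover molecules that were never sequenced.  Precision is measured
against the full catalog.  When no circle is detectable, recall is vacuously
1 (nothing to miss), and with no detections precision is vacuously 1.

What passing tests show — and what they do not: the simulator has no
sequencing error, no alignment noise beyond the optional breakpoint jitter,
no mappability structure, no copy-number variation, and its probability
model is the one the analysis assumes.  Green tests therefore demonstrate
correctness of the computations and recoverability under the stated
conditions, not performance on real nanopore data.

## Determinism and degenerate inputs

All randomness flows from explicit seeds (numpy `default_rng`); the EM fit
involves no sampling at all.  The pipeline manifest (parameters, per-stage
counts, output SHA-256 checksums, no timestamps) is byte-identical across
reruns with identical inputs and seed.  Degenerate situations are defined,
not accidental: zero-adenosine bins have undefined ratio and are omitted
from bedGraph; zero-coverage regions raise on pooled averaging; an
all-identical probability set is a degenerate fit; a `cutoff="fit"` run
without a control file is a configuration error; any stage failure writes a
FAILED marker naming the stage and keeps partial outputs.
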