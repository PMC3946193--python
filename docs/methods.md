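# Methods

## Promoter model and scoring

A sigma-70 promoter is modelled as two hexamer boxes — the -35 element
(consensus TTGACA) and the -10 element (consensus TATAAT) — separated by a
spacer of near-17 bp. The score of a candidate is pure match counting:
one point per base identical to the consensus in each box (no gaps, `N`
never matches), plus a spacer-length bonus of +3 at 17 bp, +2 at 16 or
18 bp, and +1 at 15 or 19 bp. The maximum is therefore 6 + 6 + 3 = 15 and
the maximum box-only score is 12. No position-weight-matrix energies,
extended -10 (TG) element, or UP element are modelled: the scheme is
deliberately a transparent match count.

The scanner enumerates every (-35 start, spacer length ∈ 15..19) pair with
a 1-bp slide on both strands; the minus strand is scanned on the reverse
complement and reported in forward coordinates, with `pos35` always the
leftmost forward coordinate of the -35 segment. Retention requires at
least 4/6 matches in *each* box and at least 8/12 summed (the two
conditions are redundant at the defaults but independently configurable,
and a strict-inequality variant is provided because "more than 4 of 6" can
be read either way; the inclusive reading is the default since it
reproduces the ≥ 4/6 conservation aggregates). A hit scoring below 12 is
never discarded on that account — 12 is the box-score ceiling, not a
filter. Overlapping hits are all emitted; `best_hit` deduplicates per
region by total score, with ties broken by spacer closest to 17 bp, then
larger -10 match count (the -10 box dominates promoter opening), then
leftmost position. Scanned regions for per-spacer analysis are extended
20 bp into each flanking gene so boxes abutting a gene start are not lost.

The scanner's correctness is pinned to an independent brute-force triple
enumeration (plain string comparison, no shared code) on random 2-kb
sequences, hit-for-hit.

## Peak calling

Probe ratios are Cy5/Cy3 with the Cy3 denominator floored at 1e-6 of its
median to keep zero-intensity reference probes finite. The cutoff is
*relative*: `cutoff_frac` (default 0.02) times the genome-wide maximum
ratio. Peaks are maximal runs of above-cutoff probes with at least
`min_probes` (default 2) members; the peak interval is [first probe start,
last probe start + probe length), the summit the highest-ratio probe
(first wins ties). Runs separated by a single sub-threshold probe are not
merged — no merge rule is defensible without a fragment-level signal
model. On circular tracks a run touching both array ends is stitched
across the origin (such a peak's start/end wrap). A perfectly flat track
is a single genome-spanning run: the relative cutoff admits every probe.
This is the documented degenerate case; meaningful calling requires the
maximum ratio to exceed `1/cutoff_frac` times the baseline, which holds
for any real enrichment experiment.

Raising the cutoff cannot increase the peak count on tracks of isolated
unimodal peaks (runs shrink without splitting); on arbitrary multimodal
signal a higher cutoff can split a run in two, so the monotonicity
property is stated — and tested — for the former regime.

## Spacer orientation and promoter bounds

Spacers are the positive gaps between adjacent annotated genes (sorted by
start; overlapping or abutting pairs yield none). Orientation uses
annotated strand only — (−,+) → A divergent, equal strands → B
codirectional, (+,−) → C convergent — with no UTR or leader-peptide
modelling; operon-level reasoning is delegated to an `operon` attribute
supplied in the annotation, and a spacer whose flanking genes share an
operon id is flagged internal. Peaks are assigned to the feature
containing their *summit* (overlap fractions would need the unknown
fragment distribution); summits stranded between features (possible where
overlapping genes suppressed a spacer) go to the nearest feature and are
logged. The constitutive-promoter count from peak-bearing spacers is
bounded below by n_A + n_B (each bound spacer holds at least one
promoter) and above by 2·n_A + n_B (a divergent spacer can drive both
directions); type C contributes nothing.

Reported means and percentages use exact rational arithmetic rounded
half-up (2 decimals for means, integers for percentages). Note
203/669 = 30.3%, which this pipeline reports as computed rather than the
sometimes-seen 31%.

## Conservation and logo statistics

The conservation cross-tab bins each hit's -35 and -10 match counts into
{6, 5, 4, ≤3}; the full 4×4 table is exposed rather than any coarser
grouping, and the headline aggregate is the fraction with ≥ 4/6 in both
boxes. Logo information content per column is R(i) = 2 − H(i) bits with
H the Shannon entropy of the {A,C,G,T} frequencies, `N` excluded
position-wise, uniform background and no small-sample correction (the
correction is < 0.02 bits at the hundreds of sequences this is meant
for); letter heights are frequency × R(i). H-NS silencing counts double
the type-A contribution — H-NS filaments spread cooperatively over a
bound spacer, so one bound divergent spacer silences both promoters.

## Kinetic model

The single-round mixed assay preincubates template with holoenzyme for
time t, then adds substrate plus heparin so only pre-formed open
complexes transcribe. The observable adopted is the minimal irreversible
model consistent with a "final level" and a "time to plateau":

    y(t) = A · (1 − exp(−k·t))

Parameter I is the plateau A (binding level, relative RNA units);
parameter II is the reciprocal time to reach `plateau_frac` (default
0.95, configurable since "reaching the plateau" is operational) of A:
param_II = k / ln(1/(1−plateau_frac)), monotone in k and independent of
A. The default time grid is 0.5, 1, 2.5, 5, 7.5, 10, 15 min; longer
points (e.g. 30 min) are accepted if present. Band intensities are
divided by the transcript's U (or T, for DNA-written sequences) count
before fitting, since ³²P-UTP incorporation scales with U content.

Fitting is trust-region least squares (scipy `curve_fit`) with residuals
weighted by the observed signal (sigma ∝ y, floored at 1e-3 of the
maximum): gel-band noise is multiplicative, and relative weighting is the
appropriate estimator for it — at 5% lognormal noise it reduces the
median relative error of k from ~5% to ~4% on the default grid without
affecting the exact zero-noise recovery. Initialization: A₀ = max(y),
k₀ = ln2 / (first time reaching A₀/2). A fit whose rate implies the curve
is already at > 99% of plateau by the first time point is flagged
`saturated` (k is then only grid-bounded, not resolved); non-convergence
or non-positive estimates are flagged `failed`, never silently coerced.
Within a mutation set, activities are reported relative to the most
active template, so exactly one template reads 1.0.

## Synthetic data: what it emulates and what it does not

The generator produces (a) i.i.d. genomes at a chosen GC fraction;
(b) gene-pair layouts realizing requested spacer classes and lengths
(fixed 300-bp genes, deterministic sequential placement); (c) promoters
planted with exact per-box match counts — mismatch positions uniform over
the six, substitute base uniform over the three non-consensus bases — so
that a recount always returns the planted counts; (d) probe signal at
105-bp spacing with 60-b probes, a constant Cy3 baseline, and triangular
peak kernels of 150-bp half-width reflecting the ~200–300 bp selected
fragment length, with multiplicative lognormal noise (ratios are
positive, so lognormal is the natural noise family); (e) saturating
exponential time courses on the assay's grid. Genomes default to linear;
a circular flag enables wraparound.

It does **not** emulate selection-cycle enrichment bias, PCR bias,
probe-affinity variation, correlated noise along the array, genome-scale
gene-density heterogeneity, or sequence composition beyond i.i.d. bases.
Passing recovery tests therefore demonstrates the correctness of the
algorithms under their stated signal models — not calling performance on
real arrays, where normalization artefacts and binding-site clustering
dominate. Genome-scale counts from any specific organism's dataset are
outside what synthetic recovery can certify.

## Numerical conventions

Coordinates are 0-based half-open throughout; GFF3 output converts to its
1-based closed convention, BED stays 0-based half-open. All generators
take explicit integer seeds and are byte-reproducible for a fixed seed.
Rounding of reported ratios is half-up. Degenerate inputs (empty tracks,
all-zero signal, zero-U transcripts, empty hit lists) raise or warn
explicitly as documented per function.

## Problem sizes

Default test problem sizes — 2-kb scan-oracle sequences (100 of them),
50 planted promoters, 50-kb peak-recovery genomes, 200 noisy kinetic
replicates — are the smallest sizes at which every recovery statement is
sharp (binomial GC bounds, median-error bands); all scale linearly for
users who want larger checks.
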