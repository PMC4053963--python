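# Methods

This note documents the models and procedures implemented in `vlincscan`,
the assumptions behind them, the parameters that matter, what the synthetic
data generator does and does not emulate, and the numerical choices made
where the underlying procedure leaves room.

## Coordinate conventions

All coordinates are 0-based half-open (BED convention) internally; readers
accept a `one_based` flag for browser-style 1-based inclusive inputs and
convert on ingest. Strands are `+`, `-` or `.` (unstranded); in every
strand-specific comparison `.` matches both strands, which is how
unstranded regions are compared against stranded annotations. Touching
intervals do not overlap, but merging with a maximum gap of 0 joins them
(their separation is 0 bases). Boundary adjustments clip to `[0, chromosome
length)` and silently drop intervals that collapse, logging a count —
chromosome-edge behaviour is otherwise unspecified by the procedures and
this is the least surprising resolution.

## Region calling

**Strand-specific (contig) caller.** Four stages: (1) remove contigs
sharing ≥ 1 base with a same-strand gene body (gene body = transcription
start to end; exon union plus introns equals the full span, so no exon
structure is needed); opposite-strand genes never remove contigs;
(2) merge surviving contigs across gaps ≤ `merge_gap_1` (default 1000 bp);
(3) keep merged blocks ≥ `min_length` (default 50 000 bp); (4) merge the
survivors across gaps ≤ `merge_gap_2` (default 5000 bp). The stage order is
load-bearing: sub-50 kb blocks are discarded *before* the second merge and
cannot be rescued by it. Merging never crosses chromosome or strand
boundaries.

**Unstranded (density) caller.** (1) zero out positions inside genes on
either strand; (2) compute the density threshold as the nearest-rank
`density_percentile` (default 0.80) of per-base density over positions with
*nonzero* density, after gene removal; (3) keep positions with density ≥
threshold; (4) merge across gaps ≤ `density_merge_gap` (500 bp in "blood
mode", 1000 bp in "mouse mode"); (5) keep regions ≥ `min_length`.

Two choices here are assumptions rather than specified behaviour, both
config-overridable in effect: the percentile is taken over *positions*
(base-weighted), and zero-density positions are excluded — including the
overwhelmingly zero genome would pin the 80th percentile at 0 and make the
threshold vacuous. Nearest-rank avoids interpolation ambiguity and makes
the threshold scale-free, so whether densities are depth-normalised before
thresholding is immaterial.

## Promoter and repeat annotation

Promoters are chromatin-state segments (`Active`/`Weak`/`Poised`) per cell
line; "All" means their union. A region is associated with a promoter when
the promoter shares ≥ 1 base with a 10 kb window centred on the region's 5'
boundary (both boundaries for unstranded regions). This window criterion is
equivalent, up to the single boundary base, to asking whether the boundary
point falls inside the promoter extended by 5 kb per side — which is why
the enrichment null measures occupied space with ±5 kb-extended promoters.

Promoter–repeat overlap is strand-blind (chromatin states and RepeatMasker
strands are not comparable); the repeat class of a promoter uses the
precedence LTR > other retroposon > none. Cell-line-specific Active
promoters are the target line's Active segments sharing no base with *any*
state's segment in any other line.

Positional classes for stranded regions: `antisense` (≥ 1 base shared with
an opposite-strand gene), `bidirectional` (not antisense; 5' end within
`divergent_window` of an opposite-strand gene's 5' end, head-to-head),
`standalone-like` (> 50 kb from every gene boundary, no gene overlap),
`other`. There is no community-standard definition of divergent
transcription distance; the default window of 1000 bp is this package's
choice and is a parameter.

Reduced-alignability flags: a region is flagged when mean alignability over
the 5 kb upstream of its 5' end (either end for unstranded regions) falls
below `threshold` (default 0.5; the underlying analyses state no cutoff, so
this is a package default). Windows truncated by a chromosome edge are
evaluated over the available span.

## The enrichment null

All five procedures share one construction. The genome (sum of supplied
chromosome sizes) minus an *anti-space* defines where a tested region's 5'
boundary could have fallen; the fraction of that space covered by the
(±5 kb-extended) subject features gives the per-region success probability.

Anti-space variants:

* same-strand genes ∪ blacklist (stranded promoter test; a gene on the
  opposite strand counts as intergenic);
* both-strand genes ∪ blacklist (unstranded promoter test, set-vs-set
  test);
* genes ∪ inter-gene gaps shorter than 50 kb, **without** the blacklist
  (repeat-family tests).

In every variant the tested regions themselves are subtracted from the
anti-space. Per-region extensions: the anti-space interval's 5'-side
boundary is extended by the region length L_i (left for plus-strand, right
for minus-strand) in the one-window tests; both boundaries by ⌊L_i/2⌋ in the
set-vs-set test (integer floor; a 1-base difference is immaterial at these
scales). For the unstranded promoter test each region gets two
probabilities p_i± from left/right-extended anti-spaces, combined as
p_i = 1 − (1 − p_i⁺)(1 − p_i⁻).

The denominator |Space_i| − V (V = union length of all tested regions)
deliberately inflates p_i, making the resulting binomial tail an upper
bound on the p-value under multiple tested regions; the test suite asserts
both this monotonicity and, by Monte-Carlo (500 repetitions per procedure,
uniformly redrawn subject features on a 20 Mb genome), that the empirical
false-positive rate at α ∈ {0.01, 0.05} does not exceed α plus three
binomial standard errors. V is a single global quantity even though the
stranded test builds its anti-space per strand; a global V is the more
conservative correction and keeps one space model per analysis.

Numerical choices: p_i and m/N are clamped to [0, 1] (tiny toy genomes can
otherwise push them out of range); |Space_i| ≤ V raises a "degenerate
space" error. Tail probabilities come from the regularized incomplete beta
function; when the survival function underflows double precision the
implementation switches to a direct log-space sum of binomial pmf terms, so
`log10_p` is finite at any depth while `p_value` is floored at ~1e-323.

**Repeat-family tests.** Same-family repeat copies are collapsed into
clusters: copies in the same promoter, or in promoters assigned to the same
region, share a cluster; a copy overlapping several promoters is first
split at each promoter; copies outside all promoters are singletons and
different families never co-cluster. n = clusters overlapping region
promoters; N = clusters overlapping promoters that intersect the eligible
space (anti-space intervals shrunk by 5 kb per side); p = total region
promoter length over total eligible promoter length. Region promoters are
counted into the eligible promoter set by construction, which guarantees
n ≤ N and p ≤ 1. When no cluster touches an eligible promoter the result
is N = 0 with p-value 1 (an absent family is unremarkable, not an error).
The strand-resolved variant computes (n±, N±, p±) relative to region
strand and reports the explicit upper bound P(B(N⁺+N⁻, max(p⁺, p⁻)) ≥
n⁺+n⁻); the suite checks this bounds the exact convolution of the two
per-strand binomials. Cluster independence is a model assumption of the
procedure, not something the code enforces. No multiple-testing correction
is applied across families or cell lines — raw p-values are reported (the
pipeline's report adds an optional Bonferroni column that never gates
output).

## Expression quantification

raw(v, s) = Σ base counts of sample-s contigs sharing ≥ 1 base with region
v; matching is strand-specific when both carry strand, and a contig
straddling a boundary contributes its full count (proportional attribution
is available but off by default — the wholesale reading is the simplest
consistent one). Contigs with counts > 1e6 are removed before anything
else, including the depth denominator, as likely artifacts. value = raw ×
(2e10 / sample total bases) × (1e6 / region length); the sample total
defaults to the sample's summed retained contig counts and can be
overridden with externally known sequenced-base totals. Zeros are replaced
by the dataset-wide minimum nonzero value before any ratio. Group-ratio
summaries (max malignant / max primary, etc.) are arithmetic means of
per-region ratios, with a geometric-mean option. The intron/exon statistic
uses mean per-base densities so transcript length does not confound, and
excludes single-exon transcripts and transcripts with zero exonic signal
from both the per-transcript table and the cohort median.

## The synthetic-data generator

`simulate_annotation` packs genes and planted regions onto `synthchr*`
chromosomes (defaults: 2 × 20 Mb, 60 genes of 5–50 kb, 6 cell lines ×
5 regions of 50 kb–1 Mb log-uniform) at uniformly random positions with a
guaranteed ≥ 12 kb separation, places an Active promoter (2 kb) at each
planted region's 5' boundary in its source line, embeds an LTR of a
designated family in that promoter at a group-dependent rate (defaults
0.03 primary / 0.10 immortalized / 0.25 malignant / 0.50 embryonic-stem —
the malignancy/pluripotency gradient), and adds per-line decoy promoters
(LTR-embedded at 2%), background repeats, and blacklist intervals.
Background repeats avoid all promoters so that promoter repeat content is
governed solely by the embedding fractions. Expression is log-normal around
a per-region baseline with a strong source-sample boost and group-dependent
off-sample factors that make LTR-driven regions both more cell-specific and
more malignant/pluripotent-skewed; the scale is kept below the quantifier's
1e6-count artifact cutoff. One global seed drives named substreams
(annotation / contigs / density / shuffle), so regenerating one layer does
not perturb the others.

`emit_contigs` tiles each region in its source sample with boundary-exact
contigs (gaps 50–400 bp, far below the first merge threshold) and emits
sparse isolated contigs (15 kb spacing) for cross-sample expression, plus
short isolated noise contigs — both structurally incapable of forming a
≥ 50 kb call. `emit_density` writes each sample's regions at their
expression values and sizes background noise adaptively: with S signal
bases and B_min bases in the weakest region, ~4S − 2.5·B_min noise bases at
half the weakest value put the nearest-rank 80th percentile exactly at the
weakest planted signal, so noise falls below threshold and every planted
region survives thresholding by construction. `null_shuffle` redraws
features length-preserving and uniformly over an eligible space and is the
permutation oracle for the calibration tests.

What the generator does *not* emulate — and therefore what passing tests do
not show about real data: mappability structure and alignment artifacts,
splicing and exonic structure inside regions, overlapping or nested genes,
non-uniform repeat and gene landscapes, sequencing-depth heterogeneity
along the genome, and chromatin-state segmentation error. Caller recovery
is exact on this generator because gaps and flanks are controlled; on real
coverage, boundary precision is limited by the data.

## Problem sizes in tests and the acceptance script

The suite exercises calibration at 500 Monte-Carlo repetitions per
procedure on a 20 Mb genome with 20 tested regions and 60 subject features
per draw; signal recovery at 50 regions with 30% family seeding against 2%
background; quantification recovery at 500 regions. The acceptance script
uses a 2 × 20 Mb genome with 6 × 8 planted regions for calling and
expression, a 4 × 25 Mb single-line world with 40 regions for the family
test, and 200 null repetitions for the reported false-positive rate. These
sizes give stable statistics at interactive runtimes and are the package's
reference configurations.

## Known limitations

* The enrichment null is deliberately conservative; reported p-values are
  upper bounds and lose power when tested regions cover a large fraction of
  eligible space.
* The per-strand upper bound of the strand-resolved family test can be very
  loose when the two strands have unequal eligible promoter sets.
* The caller has no notion of expression discontinuity inside a merged
  block; two adjacent transcription units separated by less than the merge
  gap are called as one region.
* Cell-line-specific region sets depend on a specificity-index cutoff
  (default ≥ 5 via the expression module) that has no canonical value; any
  downstream count of "line-specific" regions inherits that choice.
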