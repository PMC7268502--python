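# Methods

## Scope and assumptions

`cnvmeta` starts from caller outputs, never from reads or alignments. It
assumes three input roles with complementary strengths: a *coverage*
caller that reports absolute copy numbers gap-free but with a systematic
bias and depth-dependent noise; a *hybrid* caller whose amplification
magnitudes are trustworthy once harmonised but which leaves prediction
gaps; and a *referee* whose deletion/amplification direction is reliable
while its magnitudes are not (they are never used numerically). The
sample is assumed approximately diploid overall: bias and threshold
estimation read the bulk of the CN frequency distribution as the
ploidy-state population.

Coordinates are 0-based half-open throughout; 1-based-inclusive input
(GFF, `one_based` track dialect) is converted on read. Chromosome names
are canonicalised by stripping any `chr` prefix. Chromosomes are
processed independently; segments never span chromosomes. Ploidy is 2 on
autosomes and, on X/Y, 2 for a female sample and 1 for a male one;
unknown contigs fall back to the default ploidy with a warning.

## Harmonisation

**Bias correction (coverage caller).** The bias is `P - peak`, where
`peak` is the mode of the length-weighted CN histogram. Histogram bins
are 0.05 CN units wide and *centred* on multiples of 0.05, so a value
sitting exactly on the grid is represented by its own centre. The peak
is searched within `[P - 0.5, P + 0.5]` — the window inside which any
correction could apply — with ties towards the smaller CN and the global
mode as fallback; restricting to a window rather than picking "the local
maximum nearest P" keeps the estimate stable when sampling noise puts
spurious local maxima on the flank of the diploid peak. Each value is
then corrected by `factor x bias` with `factor = min(CN/2, 1)`; the
*applied* correction (the product, not the bias itself) is clamped to
±0.5 CN and results are floored at 0. The estimate is genome-wide, not
per chromosome.

**Log2 ratios vs a matched sample.** The genome-wide length-weighted
median of the log2 values is subtracted (recentring the genome bulk on
the ploidy) before mapping through `P * 2^x`.

**Ratios vs a zero-coverage null alignment.** These are non-negative by
construction and exhibit a distortion that grows exponentially with the
amplification. The equaliser `q(y) = (1 + y/100)^(0.75 y)` multiplies
them back onto the absolute scale; `y q(y)` is strictly increasing, so
the synthetic generator can invert it uniquely (Brent's method on
`[0, target]`, xtol 1e-13) when emulating this caller. Base divisor
(100) and exponent coefficient (0.75) are config keys. No attempt is
made to refit the distortion from data; the correction is a fixed
calibration.

**Thresholds.** `T2` is the interior local minimum (bin strictly below
both neighbours) of the normalised coverage histogram within [2, 2.3];
among several candidates the lowest frequency wins, ties towards the
smaller CN. Without an interior minimum the midpoint 2.15 is used, with
a warning. `T1 = 2P - T2` mirrors it below the ploidy. The search
interval is a config key and does not scale with ploidy (it is defined
for the diploid setting).

## Consensus

The genome is cut at the union of every track's interval endpoints, so a
bin is entirely inside or outside each caller's call and no proration is
ever needed. Per bin the rule table is:

| coverage | hybrid | referee | consensus |
|---|---|---|---|
| class c | class c (agree) | — | value from coverage if c is deletion/normal, from hybrid if amplification |
| present | absent | — | coverage value stands (including amplifications) |
| absent | present | — | hybrid value stands |
| class a | class b ≠ a | matches a (or b) | value of the matching caller |
| class a | class b ≠ a | silent or matches neither | `CN = P` |
| absent | absent | — | `CN = P`, rule `no_evidence` |

The referee's direction is derived from its value relative to the
chromosome ploidy (a value exactly at `P`, like an absent call, is no
evidence) or taken from an explicit deletion/duplication class; it never
supplies a numeric copy number. On agreement the value is *selected by
source*, not averaged — averaging would re-admit the weaker caller's
magnitude error on exactly the class it is weak on.

Each bin's error score is `(CN_coverage - CN_hybrid)^2` on the
*harmonised* scale (the subtraction is only meaningful on one scale),
with an absent coverage value counted as 0 (its rare gaps correspond to
unsequenced regions) and an absent hybrid value as the ploidy. Adjacent
bins whose consensus CN agrees after rounding to one decimal are merged;
rounding is half-away-from-zero (deterministic and locale-independent),
and merged CN and error are bin-length-weighted means. Merged neighbours
therefore always differ at one decimal: values that round alike lie in a
convex interval, so their weighted mean rounds alike too. The recorded
rule of a merged segment is the one covering most bases (first wins on
ties). No minimum segment length is imposed.

## Gene-level evaluation

A gene's predicted copy number is the length-weighted mean of the
overlapping segments, with uncovered bases contributing the chromosome
ploidy; genes on chromosomes absent from the prediction get the plain
ploidy with a warning, and truth-table genes missing from the gene set
are reported, never dropped silently. When the truth table carries an
evaluated length (a truth segment covering only part of the gene), it is
carried on the pair records.

Metrics: MSE, MAE, MLRE = mean |ln((x+1)/(x̂+1))| (the +1 guards the log
at zero copies), and the residual-variance score: true CNs are rounded
to the nearest integer to form groups, the *population* variance of the
residuals is computed per group (singletons contribute 0), and the group
variances are averaged. Classes for the Matthews correlation use
deletion < 1.75 and amplification > 2.75 at ploidy 2 (boundaries are
normal); for other ploidies the boundaries scale proportionally
(0.875 P and 1.375 P). The MCC is computed on one-vs-rest confusion
counts summed over the three classes; a zero denominator yields 0 with a
warning.

## Synthetic scenarios

The generator emulates caller outputs directly — reads are never
simulated. Per chromosome it draws 30-50 non-overlapping CNV segments,
lengths uniform in [10, 100] kbp, copy numbers from {0, 1, 3, ..., 8}
(never 2), on a diploid background; placement distributes the leftover
space uniformly between segments. Defaults: two chromosomes of 8 Mb —
large enough to host the densest draw while keeping a full scenario
around a couple of seconds.

* *Coverage emulation*: gap-free 450-bp bins (the scale of the coverage
  caller's segments), value = overlap-weighted truth − 0.1 (the peak
  shift the bias correction targets) + Gaussian noise, floored at 0.
* *Hybrid emulation*: 400-bp bins (the hybrid caller's configured bin
  size); the emitted value solves `y q(y) = true CN` (exact numerical
  inverse of the equaliser), plus Gaussian noise on the ratio scale; a
  fraction of bins is dropped at random.
* *Referee emulation*: a random subset of the true CNV segments;
  amplified segments are inflated by `exp(Exponential(2))` capped at
  1000, deleted ones shrunk by Uniform(0,1), so the direction is correct
  by construction while magnitudes are useless.

The low-coverage study conditions used by the end-to-end tests are
per-bin CN noise 0.5 on both primary callers, 30% hybrid gaps, and a
referee seeing half of the CNV segments. 120 genes per chromosome
(5-40 kbp) are tiled at random; a gene's true CN is the length-weighted
truth over its extent, mirroring the prediction mapping. All randomness
flows from one `numpy` Generator seeded per scenario; the seed is echoed
in every output header, and repeated runs are byte-identical.

What the generator does *not* emulate: GC-content and mappability bias,
read-level noise, breakpoint placement error (emulated tracks inherit
truth-aligned bin grids), subclonal mixtures, and correlated noise
between callers. Passing tests therefore demonstrate the internal
consistency and the arbitration logic of the consensus under its own
assumptions, not performance on real sequencing data.

## Numerical choices and degenerate inputs

* One-decimal equality uses decimal (string-based) rounding, so binary
  float artefacts (2.04999...98) round as printed.
* An empty track is a validation error for bias estimation and
  conversion; an empty referee file is accepted (warning) and simply
  provides no evidence.
* A flat CN histogram yields bias 0 with a warning.
* All readers reject NaN/infinite values and overlapping or unsorted
  intervals with the offending line or interval named.
* Writers emit full-precision (`repr`) columns next to the one-decimal
  display column, so read-write round-trips are exact.

## Known limitations

The bias model corrects a single ploidy-anchored peak shift; callers
whose bias varies per integer CN state are only partially corrected (the
linear factor approximates this). The T2 search assumes a diploid bulk;
heavily aneuploid genomes may need a custom search interval. The
equaliser constants are fixed calibration, not refitted. Gene mapping
treats genes as plain intervals (strand carried but unused, no exon
structure).
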