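# Methods

This note records the statistical model behind each stage of the
pipeline, the defaults and why they are what they are, what the
synthetic-data generators do and do not emulate, and the design choices
made where the underlying procedure was genuinely open.

## Biosets and the differential-expression filter

A bioset is the filtered gene list of one two-group comparison.  Fold
changes are stored on the signed linear convention (−2 means two-fold
down; no stored |fc| < 1), because downstream filters and ranks are
specified on linear folds.  Gene identifiers are upper-cased and
whitespace-trimmed before any matching; public compendia mix probe ids
and symbols and no canonical reconciliation rule exists, so this
normalization is a pragmatic stand-in and is applied uniformly.
Duplicate identifiers in an input file keep the record with the largest
|fold change|, since biosets are subsequently rank-ordered by effect
size.

`derive_bioset` implements the compendium-style filter on log2
intensities: a per-gene two-sided t-test (Welch by default, Student
optional) at p < 0.05 with no multiple-test correction, |linear fold
change| = 2^|Δmean| ≥ 1.2, and a low-expression rule.  Two points are
deliberate:

- The low-expression rule is computed on **per-gene group means**: a
  gene is removed when its mean sits at or below the 20th percentile of
  the gene-mean distribution in *both* groups (inclusive boundary).
  Whether the rule should use per-sample or group-mean values is
  ambiguous in compendium documentation; group means are the stable
  choice and the boundary convention is tested.  Setting the percentile
  to 0 disables the rule entirely (the inclusive boundary would
  otherwise always remove the minimum gene).
- Welch's test at n = 3–4 per group is *conservative*: its true size at
  nominal 0.05 is ≈ 0.04.  The test suite therefore checks the nominal
  null rate with the Student variant (exact for iid normal groups) and
  only bounds the Welch rate from above.

## Biomarker construction

Three filters, each a pure contraction of the candidate set:

1. **Directional consistency** — the gene has one sign in every
   activation bioset where it is differentially expressed and appears
   in at least ⌈(n+1)/2⌉ of the n activation biosets (4 of 7 at the
   default panel size; the boundary is inclusive).
2. **Genetic dependence** — the gene appears in the factor-knockdown
   bioset with the opposite sign.  Presence is required: a target gene
   absent from the knockdown profile is excluded, not given the benefit
   of the doubt.  This is the strict reading under which well-known but
   factor-independent targets drop out.
3. **Effect size** — mean |linear fold change| ≥ 1.5 (inclusive),
   averaged **only over the activation biosets where the gene is
   differentially expressed**.  Averaging over all n biosets would
   require imputing fc = 1 for absences and systematically understate
   genes that pass the majority rule at 4–6 of 7.

The filters commute on genes that pass all three (the result is an
intersection), but they are applied in the order above so that stage
counts are interpretable.  The majority denominator is always the size
of the supplied activation panel; whether a genetic-activation bioset
(e.g. repressor knockdown) belongs in that panel is the caller's
decision.

## The signed running-Fisher score

The score of a ranked query list q against a target set T on a shared
universe of N genes is a prefix scan: for each prefix of size i the
exact hypergeometric upper tail P(X ≥ |prefix ∩ T|) with X ~
Hypergeom(N, |T|, i) is computed; the minimum tail over the scan is
multiplied by the number of prefixes evaluated (Bonferroni over the
scan) and capped at 1.  Ranking is by descending |fold change| with
lexicographic gene-id tie-breaks for determinism.  The published
description of the underlying rank-based test does not fully specify
the scan or its multiplicity correction; the prefix-scan +
Bonferroni-by-scan-length construction was fixed here because it is
reproducible, conservative, and monotone (enlarging the universe with
overlaps fixed can only sharpen significance).  Published scores from
the proprietary implementation are therefore provenance anchors, not
numerical targets.

Directional aggregation: query and target are split into up/down
sub-lists; concordant pairings (up/up, down/down) contribute
+(−log10 p), discordant pairings (up/down, down/up) contribute
−(−log10 p).  An empty sub-list contributes p = 1, i.e. zero.  The
construction is exactly antisymmetric under flipping every target sign,
so suppression profiles mirror activation profiles; a value of 0 is
reported as direction "none".  Thresholds ±4 on the signed −log10(p)
define activation and suppression calls throughout.

Null calibration: against ~100-gene signatures on a 2,000-gene
universe, uniformly random 200-gene targets cross |S| ≥ 4 in well under
1% of 10,000 replicates (measured by the acceptance script).  The scan
correction is deliberately conservative; the ±4 band is then a stringent
compendium-wide call.

## Compendium analyses

- `chemical_max_call` uses the maximum score over a chemical's biosets
  regardless of dose and time; suppression mode symmetrically uses the
  minimum (the activation-only published rule is mirrored because the
  score itself is antisymmetric).
- `chemical_enrichment` tests each chemical with ≥ 3 biosets on the 2×2
  table [chemical active, chemical not; others active, others not]
  against the whole compendium *including* the chemical's own biosets
  (matching the worked 239-vs-45,163 example), one-sided (greater),
  with Benjamini–Hochberg adjustment spanning exactly the chemicals
  tested.  `bh_adjust` returns true step-up adjusted p-values.  Note
  that published per-chemical "BH-corrected" values forming an exact
  arithmetic progression in rank are BH critical thresholds, not
  adjusted p-values; this module reports adjusted p-values and the two
  should not be compared numerically.  BH adjustment is monotone in the
  rank order and capped at 1; it is *not* numerically idempotent, and
  no such property is asserted.
- `confusion_metrics` reports a metric as absent (None) when its
  denominator is zero rather than coercing it.
- `trend_fit` is OLS with R²; a constant response is reported as
  R² = 0 (no trend), a constant predictor is an error.

## ChIP annotation and ARE matching

Coordinates: BED peaks are 0-based half-open; TSS positions are
1-based.  A gene is associated with a peak when the peak overlaps
[TSS − 10 kb, TSS + 10 kb], inclusive at both edges and strand-agnostic
(bi-directional promoters); the window is TSS-centered.  The
implementation uses an interval tree and is tested against a quadratic
brute-force check.

"Relatedness" of a sequence window to a PWM is the min–max normalized
score (S − S_min)/(S_max − S_min) ∈ [0, 1], the convention of the
standard PWM-matching functions; `N` bases score as the column minimum.
Matches require relatedness ≥ 0.8 and both strands are scanned, with
minus-strand hits mirrored back to forward coordinates.  Count matrices
are converted to log-odds with pseudocount 0.25 against a uniform
background.

## Reporter-assay analysis

Per-cell intensities are transformed by log(intensity + 0.001); a
treated cell is GFP-positive when strictly above T = Q3 + 0.25·IQR of
the matching vehicle population (linear-interpolation quantiles; a
zero-IQR vehicle degrades T to Q3).  The gate is invariant under any
transform affine on the log scale applied to both wells.

The concentration–response of the positive fraction is fitted by OLS on
a natural cubic spline basis with 3 degrees of freedom in log10
concentration (tested concentrations are log-spaced, so the log axis is
the defensible choice).  The point of departure is the lowest
concentration on a dense log-spaced grid where the fitted mean clears
an *effective threshold* of 0.1 plus the pointwise one-sided 90%
confidence half-width of the fitted mean, linearly interpolated between
grid points.  The verbal rule "0.1 + the upper 90% confidence limit of
the regression" is not implementable literally (a fit can never exceed
its own upper confidence bound plus 0.1); reading the confidence term
as the *half-width* preserves the stated intent — the response must
exceed 0.1 by more than the local replicate uncertainty — and reduces
to the plain 0.1 crossing as noise vanishes.  A curve already above
threshold at the lowest tested concentration is reported as
below-range at that concentration; a curve that never crosses has no
POD.  Raising the threshold can never lower the POD.

## Synthetic data: what it emulates, what it does not

All generators are driven by one seed; each consumes a substream
derived by a fixed offset, so outputs are independent of call order and
reproducible byte-for-byte.

- **Expression matrices**: per-gene log2 baselines ~ N(8, 1.5²),
  per-sample noise sd 0.25 (log2), 3 replicates per group.  Signature
  genes (100 of 2,000, random directions) shift by ±log2(2.0) in
  activators, with per-gene dropout 0.2; the knockdown condition
  applies the opposite shift with **full penetrance** — it models a
  hard genetic perturbation, and the genetic filter's presence
  requirement makes partial-penetrance knockdowns a known way to lose
  true signature genes (see limitations).  Signature genes are drawn
  from baselines above the 30th percentile: a factor's target battery
  is measurably expressed, and this prevents the low-expression filter
  from masking embedded truth.
- **Bioset panels** (the biomarker builder's study conditions): 7
  activation biosets carrying the signature at fc 2.0 (±0.15 log2
  jitter) with per-bioset dropout 0.2 plus 150 random noise genes, and
  a knockdown bioset with every signature gene inverted.  With dropout
  0.2, a signature gene reaches the 4-of-7 majority with probability
  P(Bin(7, 0.8) ≥ 4) ≈ 0.967, so expected recovery sits near 96.7% and
  the ≥ 95% recovery property is measured as the mean over 20 replicate
  panels rather than one noisy draw.
- **Compendium**: activators echo a dose-scaled fraction of the
  signature concordantly (0.4→1.0 of genes across each chemical's dose
  series), suppressors are sign-flipped mirrors, nulls are random gene
  sets of comparable size; annotations carry a log-spaced dose grid and
  exposure times for trend analyses.
- **Genomic fixtures**: two chromosomes with TSSs spaced 22 kb apart —
  wider than the 10 kb window plus the ±9 kb peak-placement range, so a
  peak annotates exactly the gene it was placed for.  Planted motifs
  are the PWM consensus at recorded offsets/strands; background peak
  sequence is rejection-sampled to contain no window at ≥ 0.8
  relatedness, so the ground truth "no motif here" is literally true.
- **Reporter cells**: background log intensities are left-skewed
  (4 − Exp(1); a bounded autofluorescence ceiling), which puts ~1.3% of
  background cells above the Q3 + 0.25·IQR gate — a realistic small
  baseline positive fraction (a normal background would put 15.6% of
  vehicle cells above its own gate, and a 0.1 threshold on the positive
  fraction would be meaningless).  Induced cells draw from a clearly
  separated bright distribution; the per-cell induction probability
  follows a gentle logistic in log10 concentration (steepness 2,
  plateau 0.6) parameterized directly by the concentration where the
  expected measured fraction crosses 0.1.  The gentle slope matters:
  a 3-df spline tracks it faithfully, whereas a cliff-like sigmoid is
  smoothed and biases the crossing; 400 cells per well and per-plate
  vehicle gating keep sampling noise below the bracket width.

Not emulated: probe-level artifacts, batch effects, platform-specific
normalization, paired designs, image segmentation, and the biological
correlation structure of real transcriptomes (genes are independent
given the signature).  Passing tests therefore demonstrate the
*procedural* correctness and calibration of the pipeline under its own
assumptions, not performance on real compendium data.

## Problem sizes and numerical choices

Default test and acceptance problem sizes — 2,000-gene universe,
100-gene signature, 60-bioset compendium, 10,000 null replicates, 20
replicate panels, 10-concentration dose series with 3 plates — were
chosen so the whole suite runs in well under a minute of scoring time
on one CPU while keeping Monte-Carlo standard errors small relative to
every asserted margin.  Hypergeometric tails use exact scipy
implementations and are verified against exhaustive rational-arithmetic
enumeration for all universes up to N = 12.  Fold changes round-trip
bit-exactly through TSV (repr on write, round-trip float parsing on
read).  Ties in effect-size ranking break lexicographically; scores of
exactly 0 get direction "none"; thresholds (±4 calls, 1.5 mean fc, 4-of-7
support, 0.8 relatedness, 0.1 POD threshold) are all inclusive.

## Known limitations

- The prefix-scan correction is conservative; absolute score magnitudes
  are not comparable to other running-Fisher implementations, only
  orderings and threshold calls are meaningful.
- The genetic filter requires knockdown *presence*; with noisy or
  partially penetrant knockdown data it removes true targets, and
  recovery degrades accordingly.
- The POD confidence construction is a pointwise mean-CI half-width; it
  does not model between-plate variance components.
- Welch-based bioset derivation is conservative at n ≤ 4 per group, so
  realized DEG counts run slightly below nominal expectations.
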