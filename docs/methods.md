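# Methods

## Coordinate and rounding conventions

All intervals are 0-based and end-exclusive, so an interval's size is
`end − start`; sizes are printed in kb rounded to two decimals and carrier
frequencies in percent rounded to one decimal. These conventions reproduce
the arithmetic of published aCGH survey tables (e.g. 21,494,311 − 21,475,933
= 18,378 bp = 18.38 kb, and 21 carriers of 39 samples = 53.8%). Mean calls
per individual are stored at full precision and *truncated* to two decimals
by the formatter (267/39 = 6.846… prints as 6.84), matching the printed
convention rather than round-half rules.

## Segmentation

The segmenter is standard circular binary segmentation. Within one
chromosome track the probe sequence is treated as a circle; for every arc
the pooled-variance two-sample *t* between the probes inside and outside the
arc is computed, and the arc maximising |T| proposes up to two change
points. Because an arc and its complement give the same |T|, only arc
lengths up to n/2 are enumerated (wrapping allowed), which the implementation
evaluates as a matrix of windowed prefix sums. Ties in |T| are broken by the
lexicographically smallest cut pair, and a split whose second cut falls at
the sequence end is reported in its equivalent (0, i) form, so results are
reproducible and match exhaustive enumeration exactly.

Split acceptance uses a permutation test:
p = (1 + #{permuted max |T| ≥ |T_obs|}) / (n_perm + 1), with defaults
n_perm = 1000 and α = 0.01 and a mandatory seed. Two implementation details
matter for speed but not for results:

* the recursion's accept/reject decision stops the permutation stream early
  only when the remaining permutations cannot change the decision, so the
  outcome is identical to running all permutations;
* for mean-centered data the arc *t* is a monotone transform of
  s²·n/(d(n−d)) (s the arc sum, d its length), so each permutation only needs
  windowed sums, not sums of squares.

The vendor pipeline this emulates advertises a "modified" CBS whose
modifications are unpublished; whether they alter the statistic or only the
post-processing is unknowable, so this package implements the classic
statistic with every knob exposed: `alpha`, `n_perm`, `min_probes` (minimum
probes on each side of a cut, default 2), `max_arc` (an optional cap on the
searched arc length; capping bounds work per permutation at O(n·max_arc) and
sacrifices only sensitivity to events longer than the cap), and `prune_sd`.
Pruning merges adjacent segments whose means differ by less than
`prune_sd × σ̂` where σ̂ = 1.4826·median(|Δx|)/√2, the scaled MAD of
successive probe differences — robust to the segment structure itself.
Merging repeats until stable, so pruning is idempotent. Degenerate inputs:
tracks shorter than 4 probes (or 2·min_probes) are returned unsplit;
noise-free two-level tracks yield an infinite *t*, which is handled
explicitly and recovered exactly; constant tracks are detected after
centering and report T = 0.

## Calling, aggregation and filters

Thresholds follow the "above +0.3 / below −0.6" wording as strict
inequalities, with at least 5 consecutive probes; a segment mean of exactly
0.3 or −0.6 is not called. Segment genomic bounds are first-probe start to
last-probe start + probe length (60-mers by default).

Cross-sample merging is not specified in the survey literature this
pipeline follows; here calls cluster by ≥50% reciprocal overlap (connected
components), region bounds are the union of member calls, and the status is
"Amplification & Deletion" when both directions contributed. Whether a
published region's bounds are union or intersection of carrier calls is
ambiguous; union is the default and the overlap fraction is a parameter.
The ≥10% frequency filter is inclusive by default with a strict-`>` flag,
since the narrative uses both "at least 10%" and ">10%" for the same filter.

## Rarity annotation

Coverage is the percentage of the *query* region covered by the union of
intersecting reference records (not reciprocal overlap), so stacked records
cannot exceed 100% and the measure is invariant under splitting a record
into abutting pieces. Classes: exactly 0 → novel, below 50 → rare, 50 or
more → common (the "<50%" wording defines rare, so the boundary is common).
Gene content uses any-overlap inclusion ("within the demarcated region" is
read permissively); a containment-only mode is available. Symbol
verification drops symbols absent from the supplied valid list and logs the
count.

## Cohort statistics and association

The cohort summary's total span is the sum of call sizes (calls are
patient-specific, so a recurrent region counts once per carrier) and the
genome fraction uses the genome model's total length as denominator — the
denominator is never hard-coded. The gain:loss ratio is reported to one
decimal and flagged undefined when there are no losses. The group partition
classifies each region of either group as unique or shared under an overlap
rule (any overlap by default, reciprocal optional); shared loci are kept
per-group so the partition is exhaustive and disjoint by construction.

Association uses the Pearson chi-square on the 2×2 carrier table without
continuity correction by default; with cohort sizes of tens and carrier
counts in single digits the expected cells are small, so a Fisher-exact mode
is provided and used where this package itself reports an association
p-value.

One documented inconsistency in the source material: its abstract counts 22
regions common to the two patient groups while the results text counts 42
shared; this package takes no side — both partitions are recomputable from
any input with `partition_regions`.

## EASE enrichment

The EASE score removes one hit from the gene list before taking the
one-sided hypergeometric upper tail: p = P(X ≥ k−1) at unchanged margins,
so k ≤ 1 always gives p = 1 and the score is never smaller than the
unmodified Fisher p. P-values are computed with exact integer/rational
arithmetic (`math.comb` + `Fraction`) and converted to float once, which
keeps them reproducible to full double precision; tests cross-check against
scipy's hypergeometric survival function and against independent brute-force
tail summation. The reported percentage is hits / mapped-list-size × 100
(two decimals), the mapped list being the deduplicated intersection of the
input list with the collection background — this matches the published
"involved genes / total genes" arithmetic (34 hits reported as 44.16%
implies a 77-gene mapped list). The background is always an explicit input;
no whole-genome default is assumed. No multiple-testing correction is
applied by default (published tables report raw modified-Fisher p at ≤0.05);
Benjamini–Hochberg is available behind a flag. GO and KEGG collections are
both treated as flat GMT sets — no DAG propagation.

## qPCR interpretation

Copy number is 2 × 2^(−ΔΔCt) with ΔCt = mean(target Ct) − mean(reference
Ct) and ΔΔCt relative to a diploid calibrator; the standard error propagates
replicate scatter of both assays through the delta method. Decision bands
operationalise "around 2" / "1" / "3 or above" with midpoint cuts at 1.5 and
2.5 copies (both configurable).

## Synthetic data: what it emulates and what it does not

The generator emulates the *design* of a two-group aCGH study: a 39 + 10
two-group cohort, a jittered probe tiling whose full-size preset reaches
~410,739 probes at 5.3 kb mean spacing (probes are placed on a grid of the
target pitch with independent ±20% jitter, which fixes the probe count at
⌊length/spacing⌋ and the mean spacing at the target), planted CNVs drawn
independently per sample with per-group Bernoulli carrier frequencies, and
probe values of log2(copy/2) inside carried intervals plus Gaussian noise
(default sd 0.15 in log2 units) with a small outlier admixture (probability
10⁻³, sd 1.0). Copy number 0 is capped at log2 ratio −4 to mimic saturation.
The default planted regions mirror the frequency spectrum of a NAFLD-type
survey: shared common gains/losses at 33–54%, case-only regions near 10–13%
including two rare (30% engineered database coverage) and two novel (0%)
loci whose gene counts are 1, 1, 5 and 2, and one sex-chromosome CNV to
exercise the autosome filter.

The reference database is engineered so each planted region's union
coverage equals its target exactly (a leading-fraction record for partial
targets, a padded containing record for 100%), with background records kept
20 kb clear of planted regions. The gene resources provide a 1,000-symbol
universe, a 70-symbol curated disease list of which 2 symbols are
deliberately invalid (so the combined 9 + 70 list verifies to 77 mapped
genes), and one planted gene set whose enrichment in the combined list is
real and exactly recomputable. Enrichment defaults operate on the *combined*
list (region genes ∪ disease genes) against the background; enriching two
lists separately and intersecting the significant terms is possible with the
same primitives.

Not modelled: dye bias, GC waves, spatial artefacts, mosaicism,
sex-chromosome dosage, linkage between carriers, and vendor normalisation —
the simulator emits already-normalised ratios, reflecting that the
measurement chain upstream of segmentation is out of scope. Passing
recovery tests therefore demonstrates correctness of the segmentation →
calling → annotation chain under the stated noise model, not robustness to
raw-array artefacts.

## Problem sizes and runtime choices

The default test genome is a scaled-down toy (three ~10–11 Mb autosomes plus
an X), giving ~2,000 probes per autosome at 5.3 kb spacing so that
whole-pipeline simulations run in seconds; the full-size array design is a
preset (`survey_array_genome`). Recovery experiments run 20 seeded cohorts
with probe sd 0.15 and planted effects |log2| ≥ 0.585 over ≥11 probes; for
these runs segmentation uses n_perm = 100 (the configured minimum) with
`max_arc = 64` probes — ample for planted events of ≤ 25 probes — as the
package's own speed/sensitivity trade-off. Null-calibration experiments use
the full defaults (n_perm = 1000, uncapped arcs) on 100-probe tracks.
Observed under these conditions (recomputed by the test suite and
`scripts/acceptance.py` on every run): pooled recovery F1 ≈ 0.99 against a
≥0.9 requirement, zero rarity-class errors, and a null split rate
statistically compatible with α = 0.01.

## Known limitations

* The permutation p-value is discrete; at n_perm = 100 the smallest
  attainable p is 1/101, so α below ~0.0099 silently disables splitting.
* Arc-length capping (`max_arc`) makes events longer than the cap invisible
  to the statistic; leave it unset when large events matter.
* Region aggregation by connected components can chain overlapping calls
  into regions larger than any single call (union bounds).
* The simulator's carrier draws are independent across samples and regions;
  no population structure or linkage is modelled, so frequency-based
  filters see idealised binomial sampling noise.
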