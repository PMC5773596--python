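# Methods

This note documents the models, parameter choices and numerical decisions
behind `knockmore`, and what the synthetic-data tests do and do not show
about real screening data.

## Ratio screen

**Strain de-duplication.** One strain is kept per gene: a zygosity cohort
phenotyped in both sexes is preferred over a sex-discordant one, and
homozygotes over heterozygotes. Residual same-gene duplicates (a
reference-strain situation) are retained and flagged rather than dropped.

**Body-mass residual adjustment.** Absolute VO₂ and metabolic rate are
dominated by body mass, so comparing raw means across strains mostly
compares masses. Per (center, sex) stratum, mutants and wild types
jointly, an ordinary least-squares line of the parameter on mean body mass
is fitted; the adjusted value is the residual plus the prediction at the
stratum mean mass. This keeps the measurement scale (ml/h, kcal/h), leaves
the stratum mean unchanged (residuals sum to zero), and makes the adjusted
values exactly uncorrelated with mass within the stratum. The operation is
idempotent. Strata with fewer than 3 animals cannot support a line and are
left unadjusted with a warning.

**Ratios.** ratio = mean(mutant)/mean(wild-type) per (gene, parameter,
sex, center), controls being all same-center/same-sex wild types (no
time-windowing; the contemporaneous-control window of a real screen is
not modelled). Rows with fewer than 7 mutants (the consortium's power
floor per sex, configurable) are dropped; a zero wild-type mean rejects
the row into an error record. Optional per-parameter validity bounds
implement the screen's quality-control step; default off.

**Outlier calling.** For each (parameter, sex), per-center rows of all
genes are pooled into one distribution (a multi-center gene contributes
one row per center; no merge rule across centers is imposed). Cutoffs are
the empirical 5th/95th percentiles (linear interpolation); comparisons
are strict, so heavy ties at a cutoff can only reduce the flag rate,
keeping the combined two-tail rate ≤ 10% for any input. Distributions
with fewer than 20 genes are skipped. The 28 (parameter, sex, tail) lists
union to the strong-phenotype gene set. The equivalent normal-reference
thresholds are mean ± 1.645 s.d. (the 0.95 normal quantile).

**Permutation enrichment.** The statistic is the fraction of candidate
genes inside the outlier band of ≥1 distribution. The null permutes the
gene↔ratio assignment *within* each (parameter, sex) distribution —
strata-wise rather than global shuffling preserves each distribution's
shape and tail counts exactly. With continuous ratios this is equivalent
to flagging k uniformly random rows per stratum, which is how it is
vectorised (batched uniform draws with a k-th order-statistic threshold;
memory-bounded batches). p = (#null ≥ observed + 1)/(n + 1), never zero.
Against a single-stratum fixture the estimator agrees with the exact
hypergeometric tail.

**Novelty classification.** A tidy annotation table (gene, source ∈ {MP,
GO, KEGG, other}, metabolic flag, screen-derived flag) replaces live
database queries. Screen-derived MP rows are removed first (avoiding
circular discovery), then: metabolic MP term → known-metabolic; else
metabolic GO biological process or KEGG Metabolism membership →
known-metabolic; else any annotation (e.g. GO molecular function only) →
known-nonmetabolic; else unannotated.

## CPMA

The cross-phenotype statistic is a likelihood-ratio test on
x_i = −ln p_i over n traits: uniform p-values make x_i ~ Exp(1); the
alternative is Exp(λ) with MLE λ̂ = n/Σx_i, giving
statistic = 2(n ln λ̂ − n + Σx_i) ≥ 0, zero iff λ̂ = 1. The test is
two-sided by construction: both an excess of small p-values (λ̂ < 1) and
a pile-up near 1 (λ̂ > 1) score positive. The statistic is referred to
χ²₁ and reported as score = −log₁₀(tail); the tail is computed through
the normal-tail identity sf(x) = 2Φ(−√x) in log space, which stays finite
for arbitrarily extreme SNPs. p-values are clamped to [1e−300, 1−1e−16]
before logging. Score > 3.1 flags a SNP. Rows with missing trait entries
are dropped rather than imputed. The closed form is verified against a
numeric maximisation of the exponential log-likelihood (grid + bounded
refinement) to 1e−8, and the null calibration against the χ²₁ reference
at 50,000 simulated SNPs; with 16 traits the Wilks approximation carries
a small (<0.5 percentage point) liberal bias at loose thresholds, visible
in the calibration numbers.

SNP quality control retains bi-allelic SNPs with MAF ≥ 0.05 and call rate
≥ 0.75 (inclusive), then prunes linkage greedily in input order at
r < 0.8 — greedy order-dependence is deliberate and documented, as no
pruning algorithm is canonical. The per-test Bonferroni threshold is
α/n_tests. Lookup p-values are binned into genome-wide (≤5e−8),
lookup-corrected (≤2.59e−6), suggestive (≤1e−3), nominal (≤0.05) and weak
classes, which partition (0, 1].

## Promoter scanning and MORE mining

**Scanner.** Matrix similarity of a window is the sum of per-position
base probabilities normalised by the maximal attainable sum, so the
consensus scores exactly 1.0; log-odds scoring is deliberately not used,
matching the similarity-threshold convention of commercial scanners.
Default threshold 0.85 per matrix, configurable. Both strands are scanned
(reverse strand = forward scan with the reverse-complemented matrix),
windows containing N are skipped, overlaps are allowed, and scores are
rounded to 12 decimals so threshold comparisons are exact. The scanner is
verified against an exhaustive per-window oracle.

**Distance convention.** Adjacent-element distances are start-to-start on
forward coordinates. (Whether the original tooling anchors start-to-start
or end-to-start is not documented anywhere; start-to-start makes ranges
independent of matrix length.)

**Mining.** Level-wise candidate growth: every ordered element pair with
occurrences at distance ≥ 10 bp seeds candidate distance windows (each
occurrence distance opens a window of width dist_var; windows supported
by ≥ quorum promoters are kept and tightened); candidates grow one
element at a time by joining on their last element, and after every
extension the support and per-gap ranges are re-derived from the actual
occurrence chains (forward/backward reachability over per-element match
lists, polynomial, no chain enumeration). Reported ranges are therefore
the tightest intervals covering the supporting occurrences, with width ≤
dist_var and minimum ≥ 10 bp by construction. Cassettes have 3–6
elements; a cassette whose element list is a contiguous sub-list of a
longer one with identical support is suppressed as non-maximal.
Candidates are canonically sorted, so mining is invariant to promoter
input order. The quorum starts at the promoter-set size and is lowered
until cassettes appear (floor 3); if nothing is found at dist_var 20 the
search repeats at 30; sets still empty are negative. Exactness at desk
scale was preferred over the heuristics a genome-scale miner would need.

**Matching.** A promoter hits a cassette when it contains ordered,
strand-consistent matches with all gaps inside the ranges; a MORE set
hits when any member cassette hits. The opposite-strand reading of the
promoter is also tried by transforming match coordinates to the reverse
complement frame, which recovers cassettes written on the other strand.

**MORE sets.** Union-find grouping: identical elements+order always
merge; cassettes of ≥4 elements differing at exactly one position merge
when support overlap |A∩B|/min(|A|,|B|) exceeds 0.8 (the overlap
denominator is a design choice; only ">80% overlap" is specified by the
method's description). Grouping is transitive, idempotent and
order-invariant.

**Enrichment.** expected = |test set| × genome-wide hit rate;
ratio = observed/expected; ratio ≥ 2 declares association; the
opposite-direction phenotype set is evaluated as a control. A zero
genome-wide hit count leaves the ratio undefined (reported 0, not
associated).

## Networks and validation

Genes sharing ≥1 enriched MORE set under the same sub-phenotype
(parameter, sex, direction) are connected by undirected edges annotated
with the shared set ids and tags; cross-phenotype sharing is reported via
node groupings, not edges. Pathway networks connect genes sharing a KEGG
pathway (optionally restricted to the Metabolism class); the overlay
labels each edge more/pathway/both. Prediction validation bins genes into
0 vs ≥1 cassette matches (the published "1–11" is an observed range, not
a rule) and applies the conventional two-sided Fisher's exact test (sum
of hypergeometric probabilities ≤ the observed table's), verified against
full enumeration at small margins.

## Synthetic data

The phenotype generator emulates the statistical structure the screen
assumes: center/sex-stratified cohorts (default 7 mutants/sex — the
consortium's power floor — and 50 wild types/sex per center, a typical
control-pool size; one center per gene, round-robin), multiplicative
lognormal noise (ratios stay positive and right-skew-capable; default
cv 0.1 reproduces tail widths between the tight calorimetry and loose
clinical-chemistry distributions of real screens), fixed center offset
factors, body mass driving VO₂/MR linearly (default 1.5 ml/h/g, with
calorimetry noise kept small so mass is the dominant variance source —
the premise of the residual adjustment), and RER clipped to the
physiological 0.7–1.0 band. Knockout effects are multiplicative on one
(parameter, sex). The generator does not model litter effects, pedigree,
temporal drift or batch structure, so passing tests demonstrate
correctness of the statistical machinery, not robustness to those
real-data complications.

Promoters are i.i.d. bases at configurable GC (default 0.5, length
601 bp — a compact proximal-promoter window; real promoter annotations
are proprietary to the original tooling). Planted cassettes write PWM
consensus sites (reverse-complemented on −) at gaps drawn uniformly
within the stated ranges; a truth table records exact coordinates, and
planted coordinates always rescan positive at the default threshold.
Planting refuses overlapping elements and spans exceeding the promoter.

GWAS matrices are i.i.d. uniform per trait under the null; signal SNPs
draw −ln p ~ Exp(mean λ) per trait, so λ > 1 enriches small p-values
jointly across traits. λ = 1 is exactly the null.

All generators are deterministic under a fixed seed, to the byte in the
written files.

## Problem sizes

Defaults were chosen so the full test suite runs in well under a minute
and the acceptance script in seconds: null-calibration runs use 10,000
genes (ratio screen) and 50,000 SNPs (CPMA), permutation checks 10,000
permutations, mining fixtures 12–40 promoters of 601 bp with a 5-matrix
library. These sizes give Monte-Carlo standard errors comfortably below
the tolerances being checked; nothing in the implementation is specific
to them.

## Known limitations

- The ratio screen deliberately mirrors the pragmatic consortium
  procedure; it is not a mixed-model or reference-range framework and
  assigns no per-gene significance.
- Greedy LD pruning and the χ²₁ reference for CPMA are approximations
  (documented above).
- Mining is exact but exponential in the worst case for adversarial
  match densities; it is intended for promoter sets of tens of sequences,
  not genome-scale discovery.
- Scanner scores are matrix-similarity, not calibrated binding
  affinities; thresholds are per-matrix conventions, not p-values.
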