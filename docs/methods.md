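# Methods

## Scope and model

`rarecnv` analyses case–control cohorts of discrete CNV calls. The unit of
observation is a *call* (sample, chromosome, 1-based inclusive interval,
integer copy number ≠ 2, marker count, LOD confidence, caller tag). The
statistical object everywhere downstream is the 2×2 *carrier table*: how many
cases and controls carry ≥ 1 qualifying CNV at a locus, gene, or gene set.
Carrier status is binary — a sample with three qualifying calls at a gene
counts once. This collapsing is what makes rare variants testable: single
rare CNVs are individually hopeless at n ≈ 600, but their aggregated
frequency over a gene or pathway can be compared between arms.

All coordinates are 1-based and fully inclusive internally (a call at
100..200 has 101 bases); BED-style input/output converts at the boundary.
Chromosome names are compared verbatim, so the package is assembly-agnostic.

## QC cascade

Applied in order, each step on the survivors of the previous one:

1. **Dual-caller consensus.** A primary-caller call is kept iff the same
   sample has a secondary-caller call of the same direction (both deletions
   or both duplications) with `overlap / primary length ≥ 0.10`. The
   denominator is the primary call's length (asymmetric by design) and the
   primary caller's boundaries are authoritative downstream — the secondary
   caller confirms, never reshapes. Direction agreement is required because a
   1-copy and a 3-copy call at one locus are contradictory evidence.
2. **Call quality.** Keep iff LOD confidence > 2 (strict: exactly 2.0 is
   removed), markers ≥ 5, and length in [4,000, 1,000,000] bases (both ends
   inclusive).
3. **Sample quality.** Remove a sample (and all its calls) iff
   calls > 110, total CNV length > 7.5 Mb, median copy-number variance > 2,
   or LRR SD > 0.4 — all strict inequalities, so a sample at exactly 110
   calls survives. Call counts and total lengths are recomputed from the
   calls surviving steps 1–2; the two array-quality metrics are input
   metadata (they derive from probe intensities the package never sees).
4. **Segmental duplications (rare stratum only).** Remove a rare call iff
   the union of segdup regions covers > 50% of its bases (union coverage,
   so overlapping segdup fragments are not double-counted; exactly 50% is
   kept). Segdup-rich loci are prone to artefactual calls.

Steps 1–2 are per-call set intersections, hence order-independent among
themselves; the `QcReport` records removals per filter and these sum to
input − output.

## Frequency mapping and strata

CNV regions are connected components of the call-overlap graph per
chromosome (overlap = ≥ 1 shared base, transitively closed); the region span
is the union envelope. A region's carrier count is the **maximum stack**: a
sweep-line over member-call breakpoints finds the leftmost interval covered
by the most *distinct samples* (same-sample calls are merged first). The
carrier frequency is max-stack / cohort size; regions with frequency
strictly above 1% form the common stratum, all others (including exactly 1%)
the rare stratum, and member calls inherit their region's stratum. By
default deletions and duplications pool when building regions and counting
the stack; `direction={any,del,dup}` restricts both.

## Association

**Exact 2×2 inference.** Two-sided Fisher p-values sum hypergeometric point
probabilities ≤ the observed one (relative tolerance 1e-7 for floating-point
ties); a table with an empty carrier margin is reported as p = 1. The odds
ratio is the conditional MLE under the noncentral hypergeometric likelihood
with the exact conditional confidence interval (scipy's implementation; the
test suite cross-checks it against a direct likelihood grid search and the
Fisher p against full enumeration). A zero cell on one side gives an
infinite (or zero) estimate with the finite one-sided exact bound; a table
with no carriers at all is reported as missing.

**Permutation min-p FWER.** All multiplicity correction shuffles
case/control labels over the fixed call-to-sample mapping. For each of
`n_perm` shuffles the full battery of tests is recomputed and its minimal p
recorded; the empirical family-wise p of test *i* is
`(1 + #{perm : min_p ≤ p_obs_i}) / (n_perm + 1)` — conservative, never zero,
with floor `1/(n_perm+1)`, and monotone in the unadjusted p within one
battery. Because the carrier margins are permutation-invariant, the
implementation precomputes, per test, the Fisher p as a function of the case
carrier count, which makes each permutation a boolean matrix product.

**Locus scan (common stratum).** Test loci are the atomic intervals bounded
by member-call breakpoints within each common region; a sample is a carrier
at a locus iff ≥ 1 of its calls of the requested direction overlaps it.
Consecutive atoms with identical carrier sets collapse into one test. The
outermost locus of a region is excluded when its carrier set is a proper
subset of its inner neighbour's — the signature of pure boundary
truncation, which generates spurious "edge" loci whose carriers differ from
the core only because call boundaries are imprecise. (No published rule
exists for this exclusion; this subset criterion is the package's
formalisation.)

**Gene association (rare stratum).** Carrier iff ≥ 1 rare call shares ≥ 1
base with the gene (no minimum overlap fraction). Genes with zero carriers
are skipped. Each tested gene gets a Fisher p, the min-p empirical p over
the gene battery, and the exact odds ratio. An optional known-CNV reference
(BED with a frequency column) flags significant genes whose case carrier
frequency does not exceed the frequency already reported at that locus in
reference populations — such hits are likely artefacts, since a genuinely
pathogenic variant should be rarer in reference cohorts than in cases.

**Burden (rare stratum).** Four per-sample metrics — call count, distinct
genes hit, mean call length, total call length — in three type strata (all,
deletions only, duplications only). Zero-call samples contribute 0 to
count/genes/total but are excluded from mean length (the mean of an empty
set is undefined, and zeros would make the group means uninterpretable).
The test statistic is the case:control ratio of group means; its one-sided
permutation p counts shuffles with a ratio at least as large as observed,
with the same (1+X)/(n+1) estimator. Rate and gene-rate ratios are invariant
to length units.

**Percentages.** Published CNV association tables conventionally divide
carrier counts by the *combined* cohort size; result tables here emit both
the per-arm and the combined-denominator percentages.

## Pathway local FDR

Each gene set's carrier table is summarised as the signed square root of the
likelihood-ratio statistic G (0·log 0 ≡ 0; sign positive when the case
carrier proportion exceeds the control one). It is finite for zero cells,
antisymmetric in the arms, and approximately N(0,1) under the null for
well-filled tables. Sets annotating < 5 or > 700 genes (counted against the
supplied gene models) are discarded before testing.

The empirical-Bayes machinery treats the observed statistics as draws from a
mixture `f = p0·f0 + (1−p0)·f1` and reports per set the local false
discovery rate `fdr(z) = min(1, p0·f0(z)/f(z))` and `posterior = 1 − fdr`.
Estimation, on ~25 equal-width bins spanning the pooled observed + permuted
range:

- **f0** from the pooled label-permutation statistics (`n_perm × n_sets`
  draws) by Lindsey's method: a ridge-stabilised degree-5 polynomial fit to
  the log bin counts, weighted by √count, with a half-count continuity
  correction for empty bins. The permutation sample is large enough that
  this smooth fit is reliable out into the tails.
- **f** as the *empirical* binned density of the observed statistics
  themselves (half-count correction for empty bins). With only a few hundred
  sets, smoothing the observed side with a global polynomial systematically
  underestimates the density at an isolated outlier — the fit is dominated
  by the null bulk — which inflates the tail fdr roughly tenfold in
  simulation and defeats the purpose of the analysis. The empirical-count
  choice is the density-ratio construction at its rawest: the fdr of a set
  compares how many sets were *observed* in its bin against how many the
  permutation null *expects* there.
- **p0** defaults to the capped median over occupied bins of f/f0.

Under a fully null simulation ≥ 95% of sets get fdr > 0.5 and essentially
none fall below 0.05. On the positive tail the fdr is monotone in z as long
as the fitted f0 is monotone beyond the mode, which holds for the smooth
fit. Each reported set is annotated with its most-carried member gene, so
set-level signal driven by a single gene-level association is visible at a
glance; a gene-exclusion mode reruns the analysis with a named gene's calls
removed to confirm such driving.

A caution from the package's own calibration experiments: the permutation
null of the signed √G statistic on sparse carrier tables is heavier-tailed
than N(0,1) (discrete small-margin tables place real mass at |z| ≥ 3.5), so
moderate planted effects — around ten case carriers against two control
carriers in a 189/380 cohort — genuinely sit at local fdr ≈ 0.05–0.1, not
far below it. Detection of such effects is borderline by nature, and in
simulation the planted set reaches fdr < 0.05 in roughly 40% of draws, with
the truly attainable ceiling (ranking alone, by an exact-test oracle) near
80%.

## Depth-based copy number

For targeted sequencing follow-up, each sample's depth ratio is
`region reads / region length / total reads`, scaled by 1e9 for readability.
The ratio is proportional to copy number, and a cohort histogram separates
into clusters. Exact zeros are assigned copy number 0 before clustering —
zero reads over a captured region means no template DNA, i.e. homozygous
deletion — and the remaining ratios are split into k−1 contiguous groups by
exact dynamic-programming minimisation of the within-cluster sum of squares
(deterministic; no random initialisation; verified against an exhaustive
split scan). Nonzero clusters are labelled 1, 2, … in increasing ratio
order. That default labelling is wrong when the cohort's lowest nonzero
cluster is not copy number 1 — the classic failure mode when software
assumes the modal cluster is diploid — so an anchor sample of known copy
number can be named to shift the nonzero labels (exact zeros always remain
copy number 0). Concordance between two assignments counts samples placed
in the same *cluster* after the label permutation maximising agreement, so
relabelled but identical partitions score perfectly.

## Synthetic cohorts

The generator emulates a post-QC array cohort. Defaults are the published
cohort conditions: 189 cases / 380 controls; per-sample call counts
Poisson(5.17) for cases and Poisson(4.8) for controls; 60% deletions
(matching the 2.9 : 1.9 deletion:duplication rate split); lengths log-normal
(μ = 10.57, σ = 1.2 on the log scale) truncated to the QC window
[4 kb, 1 Mb], parameters chosen once so the truncated mean is ≈ 77 kb.
Positions are uniform over a surrogate genome of 22 × 120 Mb chromosomes;
gene models (default 200 genes of 10–100 kb) and gene sets (default 50 sets
of 5–50 genes) are placed by the same structural stream. The secondary
caller's view is derived from the primary calls by Gaussian boundary jitter
(σ = 500 bp), false-negative drops (2%) and Poisson false-positive additions
(5%), so the consensus filter has realistic work. Planted risk effects are
*additional* carrier calls at a named gene or across a set's genes with
stated per-arm penetrances — never rate shifts — so true carrier status is
unambiguous and recorded in a truth table. One master seed spawns
independent sub-streams (structure, background calls, planted effects,
caller noise), so changing the noise settings does not perturb the
background cohort.

The depth-count generator plants copy-number classes by largest-remainder
apportionment of the requested proportions (52/40/8% of 62 → 32/25/5),
zero reads for copy number 0, and Poisson reads around
`center × region length × total reads / 1e9` otherwise; the default
coverage puts the heterozygous-deletion class at ~Poisson(625) reads, i.e. a
ratio standard deviation ≈ 0.02 — the cleanly separated regime of a deep
capture experiment. For set-level calibration studies a direct
carrier-matrix generator plants one enriched set (expected ~10 case vs ~2
control carriers) among null sets whose shared carrier probability is drawn
uniformly from 0.5–5% per set.

What the cohort generator does **not** emulate: probe-level intensity noise,
genomic clustering of CNV hotspots, linkage between nearby variants, allele
dosage, or population structure. A green test on synthetic cohorts
establishes the statistical machinery — error control, recovery, boundary
semantics — not biological realism of any particular genome.

## Numerical conventions and edge cases

- Empirical p-values are (1 + exceedances)/(n_perm + 1) everywhere; ties
  count as exceedances (conservative).
- Fisher point-probability ties are absorbed with relative tolerance 1e-7.
- The conditional-MLE odds ratio is solved numerically (tolerance well below
  the 2-decimal reporting precision); zero-cell tables report ±∞ with the
  finite exact bound, empty tables report missing.
- Sweep-line ties between equal-depth loci resolve to the leftmost interval.
- Region merging treats ≥ 1 shared base as overlap; adjacency (end + 1 =
  start) is not overlap.
- Malformed input rows fail the whole read by default; a permissive mode
  skips them with line-numbered warnings, because silently dropped rows
  corrupt carrier counts.
- Every permutation-based output records its seed and n_perm in a header
  comment; pipeline runs write a manifest with input checksums sufficient to
  reproduce every number.

## Known limitations

- The locus-scan edge-exclusion rule is one defensible formalisation of
  boundary-truncation artefacts; others (e.g. frequency-based trimming)
  would give slightly different locus batteries.
- Local-FDR estimates with only a few dozen gene sets are unstable (a
  warning fires below 10 sets); the estimator is designed for hundreds of
  sets.
- Stratified permutation (e.g. within batches) is not implemented; labels
  are exchangeable marginally.
- The depth module consumes a read-count table; alignment, duplicate
  marking and mapping-quality filtering are upstream concerns.
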