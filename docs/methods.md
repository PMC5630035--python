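# Methods

## The missense tolerance ratio

A transcript is represented by its coding sequence on the coding strand plus
the exon intervals that place it on the genome; minus-strand transcripts
store the CDS already on the coding strand and reverse only the genomic map,
with forward-strand VCF alleles reverse-complemented on ingest. The stop
codon, when present, is recorded but excluded from all analysis: windows,
possible-SNV enumeration and observed-site mapping run over protein codons
1..L under the standard genetic code only.

For each codon, a window of the index codon ± `window_radius` codons
(default 15, i.e. 31 codons / 93 coding nucleotides; terminal windows are
truncated rather than padded) tallies

* **possible** missense and synonymous SNVs — every single-base change in
  the window, each treated as equally likely (a trinucleotide
  mutation-rate-weighted denominator is a natural extension but is not
  implemented; the equal-probability rule is the baseline definition);
* **observed** missense and synonymous variants — *distinct* quality-passing
  sites, deduplicated by (genomic position, alt allele). Allele counts do
  not enter the tallies; a site observed once and a site observed 300 times
  contribute equally.

MTR is the observed missense proportion divided by the possible missense
proportion. It is null (not zero) for windows with no observed variants;
null windows are excluded from the deviation tests, the gene percentiles and
the downstream rank tests. This handles the 0/0 case that the ratio's
construction otherwise leaves undefined, while keeping MTR = 0 meaningful
(synonymous-only windows).

Each window with at least one observed variant gets a two-sided exact
binomial test of k = observed missense in n = observed missense+synonymous
against p₀ = possible missense proportion, using the minimum-likelihood-sum
convention for two-sidedness (the sum of all outcome probabilities no larger
than the observed outcome's). Benjamini–Hochberg adjustment is applied
study-wide across every window of every transcript in the invocation by
default; a per-gene family is available (`fdr_scope = gene`). Gene
percentile thresholds (5th/25th/50th by default) are linear-interpolation
empirical percentiles over the per-codon MTR values — one value per codon,
not per unique window.

## Control stratification and pathogenic qualification

Reference-cohort missense variants passing the database creators' quality
filters are stratified into three mutually exclusive presumed-benign groups:
v1 singletons (global allele count exactly 1); v2 singletons absent at any
frequency from v1; and v2 non-singletons with MAF < 0.05% in each of the
seven ancestry groups, excluding the first two groups. Population MAFs are
taken from `AF_<pop>` fields or computed as AC/AN; a population with AN = 0
is treated as failing the rarity screen (conservative). Missing population
frequencies make Group-3 evaluation an explicit error rather than a silent
pass. "Singleton" means global AC = 1 as reported, with hemizygous counts
taken at face value.

Pathogenic-candidate records pass a two-tier screen. First, classification:
ClinVar Pathogenic/Likely Pathogenic and/or HGMD DM, with consensus required
when both databases report the variant (one pathogenic, one not → fails).
Second, segregation: qualified iff the variant arose de novo, or segregated
among all (and more than three) genotyped affected carriers, with no
genotyped affected non-carrier and at most one genotyped unaffected carrier.
Phenotype matching is case-insensitive substring matching against a fixed
epilepsy keyword list, with "glucose" active only for *SLC2A1* (GLUT1
deficiency); "west syndrome" is matched as the two-word phrase so that
unrelated "western …" phenotypes do not hit.

Per-codon coverage is the mean over the codon's three genomic positions of
the fraction of samples at ≥ 10× depth; positions absent from the coverage
table contribute 0 and flag the codon, so sparse coverage depresses the
displayed trace instead of silently dropping codons.

## Enrichment statistics

* **Quartile test** — one-sided exact binomial: k = case variants whose
  codon MTR ≤ the gene's 25th-percentile threshold (ties inside, matching
  the depletion semantics), n = case variants on codons with an MTR
  estimate, p₀ = 0.25 by default. Because percentile ties can make the
  nominal quartile inexact, an alternative mode uses the empirical fraction
  of codons at or below the threshold as p₀; both are reported by the CLI.
  Distinct variants are counted, not distinct codons.
* **Rank test** — two-sided Mann–Whitney U between case and control MTR
  values; exact null when the pooled sample is ≤ 25 without ties, normal
  approximation with tie correction otherwise.
* **Presence test** — two-sided Fisher exact on 2×2 presence/absence counts.

## The GPP pipeline

The pipeline order is fixed: impute → near-zero-variance prune →
correlation prune → importance → model selection.

1. **Imputation** — missing rank scores are filled with the per-gene
   per-feature median of the successfully annotated variants.
2. **Near-zero variance** — a feature is removed when the most-common /
   second-most-common value ratio exceeds 4 (the 80/20 rule) *and* distinct
   values are < 5% of rows.
3. **Correlation pruning** — while any remaining pair has |Pearson r| >
   0.75, the worst pair's member with the larger mean absolute correlation
   against the currently remaining features is removed; means are
   recomputed after every elimination (exact order).
4. **Shadow-feature importance** — each run pairs every feature with a
   column-permuted shadow copy and fits a random forest (default seed 15,
   1000 runs, 500 trees, 4 candidate features per split). The forest is
   assembled tree-by-tree from bootstrap-sampled sklearn decision trees so
   that out-of-bag mean-decrease-accuracy is available: per tree, the drop
   in OOB accuracy when a column is permuted; Z = mean/SD of per-tree drops.
   A feature scores a hit when its Z beats the run's best shadow; hits are
   tested against Binomial(runs, ½) at a Bonferroni-corrected 0.05 —
   significantly more hits ⇒ informative, significantly fewer ⇒
   uninformative, otherwise inconclusive. *Highly informative* additionally
   requires the feature's minimum non-outlier Z (1.5×IQR whisker
   convention) to exceed the maximum shadow Z over all runs. Note the hit
   test needs enough runs to be decisive at all: with k features, at least
   ⌈log₂(k/0.05)⌉ runs are required before even a perfect hit record clears
   the Bonferroni bar.
5. **Model selection** — forward–backward stepwise logistic regression over
   the importance-ranked candidates, starting from intercept-only or
   intercept + raw codon MTR when the MTR passed its own per-gene screen
   (default p < 0.0045; the MTR enters as a raw value, its sign learned by
   the fit). A step is accepted only when the incumbent's Akaike relative
   likelihood against the candidate, exp((AIC_new − AIC_old)/2), is ≤ 0.05
   — i.e. the new model must beat the old by ΔAIC ≈ 6. Forward selection
   halts at the first rejection; after each acceptance every included
   feature is re-tested for removal under the same criterion. Maximum
   likelihood fits use statsmodels; on non-convergence or runaway
   coefficients (perfect separation, which small synthetic sets do produce)
   the fit falls back to a weak L2 penalty (α = 0.01) with AIC computed from
   the unpenalized log-likelihood at the penalized estimates, and the model
   records the fallback. A "global model" mode pools all genes' rows through
   the same selection path.

GPP scores are inverse-logit linear predictors; AUC is the rank-based
probability that a random case outscores a random control with ties at ½
(identically U/(n₁n₂)).

## The synthetic test bed

The generator emulates the analysis inputs at desk scale, as pure functions
of (config, seed):

* transcripts with uniform (optionally GC-biased) codon usage, no internal
  stop, an ATG start and trailing stop, split over a configurable exon
  structure on either strand;
* standing variation in which every possible missense/synonymous SNV is
  observed independently with probability `site_variation_prob`
  (default 0.06, reproducing the ~15 distinct variants per 31-codon window
  that a ~277k-chromosome cohort yields), thinned by a per-region
  `missense_retention` inside planted depletion regions (default: the
  middle quarter of the transcript retaining 20%); allele counts follow a
  singleton-heavy spectrum (P(AC=1)=0.7, geometric tail);
* pathogenic-candidate records concentrated in the depleted regions
  (default 80%), with evidence fields arranged so a configurable share
  (default 0.58, the fraction of reported pathogenic variants that survive
  segregation screening) qualifies;
* Beta(20,1)-distributed per-site coverage fractions;
* feature matrices with planted class separation d in SD units, mapped to
  rank scores in [0,1]; a planted feature's expected single-feature AUC is
  Φ(d/√2).

What the simulator does **not** emulate: linkage between sites,
trinucleotide mutation-rate heterogeneity, sequencing-depth-driven
missingness, ancestry structure in allele frequencies, and correlated
feature panels mimicking real tool families. Passing tests therefore
demonstrate that the estimators and selection machinery behave correctly
under their stated sampling assumptions, not that real cohorts satisfy those
assumptions.

## Numerical choices and problem sizes

Exact binomial and Fisher tests, the Mann–Whitney test, and BH adjustment
delegate to scipy/statsmodels; the test suite checks each against
brute-force enumeration oracles. Percentiles use numpy's linear
interpolation. Confidence intervals for logistic coefficients are Wald
intervals, which at the n ≈ 2000 scales used for recovery checks are
indistinguishable from profile intervals.

Validation runs use reduced forest sizes (≈12 Boruta iterations of 60 trees)
and 20-replicate Monte Carlo designs; these sizes give stable pass/fail
behaviour for the planted effect sizes while keeping the whole suite fast.
Production defaults (1000 iterations, 500 trees) remain the package
defaults.

## Known limitations

* The equal-probability possible-SNV denominator ignores mutation-rate
  heterogeneity (CpG transitions in particular); depleted windows rich in
  hypermutable contexts will be mildly mis-calibrated.
* Window estimates at neighbouring codons share 30/31 of their data, so the
  per-window tests are strongly dependent; the BH adjustment controls FDR
  over an exchangeable family only approximately (PRDS holds for positively
  dependent one-sided statistics, but the two-sided exact test is discrete
  and conservative to begin with).
* The hit-count reading of the shadow-feature test is coarser than a full
  Z-distribution comparison at very small run counts.
* ClinVar/HGMD free-text review steps that were manual in the source
  workflow (e.g. "not provided" classifications) are out of scope; records
  must arrive with structured classification strings.
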