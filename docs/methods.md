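# Methods

## Model and scope

`gprior` triages annotated small variants at the level of the individual
case rather than the cohort.  The underlying assumption is genetic
heterogeneity: in phenotypes such as idiopathic pregnancy loss, different
cases are expected to carry different causative alleles, so per-individual
filtering — which also accommodates de novo mutations — is preferred over
aggregate burden or association testing, which the sample sizes involved
could not power anyway.  Both heterozygous and hemizygous carriers are
retained: a variant may act in compound heterozygosis or epistasis, or be a
de novo dominant.

The pipeline operates strictly downstream of alignment, variant calling,
normalization and annotation.  Inputs are biallelic-decomposed VCFs whose
records carry transcript-level annotations in a single INFO field
(configurable dialect, VEP-`CSQ`-like by default).  The upstream refinement
convention — total site depth > 10 and call quality > 20, both strict — is
checked on entry as a validation (warning by default, error in strict
mode), never re-applied as a filter: the caller's QC is the caller's
responsibility.

## Filter semantics and numerical choices

**Frequency clause (Filter I.b).**  "Rare in the reference populations" is
an AND over reference sets: every *recorded* frequency must be strictly
below `af_threshold`; absent entries pass.  The default 5% is deliberately
permissive relative to the common 1% convention for rare variants, to keep
alleles with mild effects acting recessively or in compound heterozygosis.
The threshold is strict: a frequency of exactly 0.05 fails.

**Score clause (Filter I.c).**  The scaled deleteriousness score is
PHRED-like: scaled score s marks the top 10^(−s/10) fraction of possible
substitutions, so a rank percentile p converts to the threshold
−10·log₁₀(1 − p/100) in closed form (90 → 10.0, 99 → 20.0, 99.8 → 26.99).
The conversion uses the precomputed genome-wide scale, not a re-ranking
within the analyzed table, because percentile statements about single
variants are only meaningful on that scale; an empirical within-table mode
(`cadd_mode="empirical"`) is available for annotation dialects whose scores
are not genome-wide calibrated.  The clause is evaluated on the damaging
(HIGH/MODERATE) annotations of the gene, pairing the score with
pLI > `pli_threshold` (strict).  Absent scores never satisfy the clause —
missingness is never imputed as zero anywhere in the package.

**Qualification unit.**  A variant qualifies for a gene if *any* transcript
annotation of the gene qualifies; all qualifying transcripts are reported,
which is why transcript counts exceed variant counts in the output.

**Filter II.**  Hits are counted per gene across the whole case cohort in
(variant, sample) occurrences; a per-unique-variant mode is available
(`filter2_unit`).  The cap is strict (default > 5 removes).  The rationale
is empirical: genes that accumulate many hits in a small cohort are
enriched for private calls typical of mapping artifacts.

**Filter III.**  Replicate subsets are drawn without replacement within a
replicate and independently across replicates, each replicate's generator
seeded as (seed, replicate index), so profiles are reproducible and any
replicate can be regenerated in isolation.  A gene counts at most once per
replicate (presence/absence).  The profile is computed by running Filter I
once on the full control table and intersecting each hit's carriers with
the replicate subsets; this is exactly equivalent to restricting the table
and re-running the filter, because the Filter I predicate depends only on
the variant and its annotations, never on cohort composition — the
equivalence is asserted against a literal restrict-and-rerun oracle in the
tests.  Exhaustive enumeration replaces Monte Carlo when C(n, k) is below
`exhaustive_cap`.  The exclusion threshold is strict (frequency exactly
5/100 survives at the 0.05 default).  Missing control genotypes are
non-carriers, as in cases.

**Filter IV.**  Applied last, on the hits surviving Filter III.  The
non-private depth interval is closed and pooled over the whole cohort
rather than per sample, since per-sample intervals would be too unstable at
these hit counts.  With no non-private hits the range is undefined and the
filter is the identity (with a warning).

**Determinism.**  Record order is file order and every stage preserves or
subsets it; the output table is sorted by (chromosome, position, alt,
sample, transcript).  Identical inputs, configuration and seed give
byte-identical outputs.

## STR aneuploidy screening

Peak-area ratios are taken first-listed over second-listed (peaks stay in
allele-length order), matching the asymmetric printed bounds: normal
heterozygote in [0.8, 1.4], trisomic diallelic below 0.6 or above 1.8.
The gaps (0.6, 0.8) and (1.4, 1.8] are deliberately classified
`inconclusive` rather than forced into a category.  Triallelic equality
(1:1:1) uses a ±25% pairwise-ratio tolerance, configurable, since "equal
peak area" needs an operational definition under measurement noise.
A chromosome needs two trisomic markers for a trisomy call and two normal
heterozygous markers for a euploid call; anything less is `no_call` — the
screen refuses to assert euploidy from uninformative homozygous markers.
Triploidy requires every evaluable chromosome trisomic, with at least two
evaluable.  The X-dosage assay (an X-specific product ratioed against a
near-identical chromosome-3 product) is carried as pseudo-chromosome
`X_dosage`; its ratio is reported for manual monosomy-X interpretation but
never auto-called, because a single-locus dosage assay does not meet the
two-marker evidence rule.  Contamination is flagged when, at ≥ 2 shared
loci (configurable), the embryo shows more than two alleles and the
supernumerary alleles are attributable to the maternal profile.

## The synthetic benchmark

`synthetic_data.generate_cohorts` emulates the decision-relevant structure
of an annotated case/control experiment:

- cohort allele frequencies from Beta(0.5, 9.5) (rare-heavy, mean 5%);
  reference-set frequencies as log-normally perturbed copies of the control
  frequency (shared ancestry), except private variants (21% of background
  by default, matching the private fraction typical of small cohorts)
  which carry no reference entries;
- impact mixture 5/30/35/30% HIGH/MODERATE/LOW/MODIFIER; scaled scores
  drawn as −10·log₁₀(U), the distribution implied by uniform genome-wide
  rank; 20% of genes with pLI > 0.9 and 5% without a pLI value;
- Hardy–Weinberg genotypes per cohort (hemizygous on chrX for male
  samples), ~1% missing calls, negative-binomial per-sample depths
  (mean 30, shape 8) floored at 6 — the cohorts represent post-QC callable
  sites, and the floor gives the Filter IV decoys an unambiguous target;
- per case sample, `n_planted` (default 3) planted detrimental variants,
  each in its own reserved gene with a single case carrier and no control
  carriers, alternating between the score clause (scaled score ≥ 15,
  pLI > 0.9) and the list clause (gene inserted into exactly two lists,
  score kept below threshold so the recorded criterion is exact);
- decoys engineered per removal route: reference-common and low-impact
  variants (Filter I), genes with 7 rare damaging variants spread over the
  cases (Filter II), genes carried by ~64% of controls yet rare in the
  reference sets (Filter III), and private variants with depth 2 in
  otherwise well-covered carriers (Filter IV).

The default acceptance cohort is 10 cases / 200 controls / 2000 variants —
sizes chosen so the full pipeline, including the resampling null, runs in
seconds while every filter still has non-trivial work at each stage.  The
simulator's default `n_controls` is 929, the size of a typical
public-diversity-panel control set.

What passing the benchmark shows: the decision logic of all four filters,
the null estimator and the STR classifier are implemented exactly as
specified, including every strict boundary, and the pipeline is
deterministic.  What it does not show: performance on real embryo genomes.
The generator has no linkage disequilibrium, no mutation-rate or sequence
context model, no annotation errors, no population stratification between
cases and controls, and its planted variants are constructed to be
unambiguous — real causative alleles are not.  Recovery rates on this
benchmark are a correctness check, not a sensitivity estimate.

## Known limitations

- Gene symbols are matched by exact upper-cased string; no HGNC alias
  resolution.  Lists and annotations must share a nomenclature.
- No inheritance-mode logic (no parental genomes) and no phasing; compound
  heterozygosity is visible only as multiple hits in one gene.
- The frequency clause uses one global frequency per reference set; 
  per-subpopulation maxima would be stricter where annotations provide them.
- Population stratification between cases and controls is assumed checked
  upstream (e.g. by PCA); the null model does not correct for it.
- Coding regions only, by way of the impact vocabulary: MODIFIER-only
  (typically non-coding) annotations never qualify.
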