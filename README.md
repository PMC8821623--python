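# gprior

Variant prioritization for small case cohorts — built for euploid
miscarriage genomics, where a handful of embryo genomes must be sifted for
putatively detrimental small variants without the sample sizes that
association testing needs — plus QF-PCR STR screening of chromosomal
aneuploidies and a synthetic cohort generator that makes the whole pipeline
testable end to end.

## Who this is for

Groups sequencing small case collections (miscarried embryos, rare-disease
probands) who need a reproducible, per-individual triage of annotated
variant calls: which rare, damaging variants in which genes deserve manual
curation?  The pipeline consumes normalized, biallelic-decomposed VCFs that
already carry functional annotations (VEP-style `CSQ` blocks with gene,
transcript, impact, consequence terms, scaled CADD score, reference
allele frequencies and gene pLI), one or more candidate gene lists as plain
text, and a control cohort VCF in the same annotation dialect.

## The method

Four sequential filters over (variant, carrier sample, gene) occurrences
("hits"):

- **Filter I** retains a hit when (a) some transcript of the gene has
  HIGH or MODERATE predicted impact, (b) the allele frequency is
  < `af_threshold` (default 5%) in *every* reference population that
  recorded the allele (absent entries pass — an allele unseen in a
  reference set cannot be common in it), and (c) the gene is in at least
  `min_list_membership` (default 2) of the candidate lists, **or** the
  variant has scaled CADD ≥ −10·log₁₀(1 − p/100) for percentile p
  (default 90 → threshold 10.0) in a gene with pLI > 0.9.
- **Filter II** removes hits in genes with more than `max_hits_per_gene`
  (default 5) hits across the cohort — pile-ups are likely alignment
  artifacts.  The inequality is strict: exactly 5 hits survive.
- **Filter III** resamples the control cohort (default 100 replicates of
  10 individuals), runs Filter I on each replicate, and removes case hits
  in genes selected by chance in strictly more than `null_freq_threshold`
  (default 5%) of replicates.  An exhaustive mode enumerates all
  C(n, k) subsets when feasible.
- **Filter IV** removes *private* hits (absent from all reference sets)
  whose read depth falls outside the closed [min, max] depth range of
  non-private hits.

The STR module classifies QF-PCR peak-area profiles: a two-peak ratio
(first/second) in [0.8, 1.4] is a normal heterozygote, below 0.6 or above
1.8 a trisomic diallelic pattern, three ~1:1:1 peaks a trisomic triallelic
pattern.  Two trisomic STRs on a chromosome call a trisomy; trisomic
patterns on every evaluable chromosome indicate triploidy; extra embryo
alleles matching maternal blood flag contamination.

See `docs/methods.md` for assumptions, parameter rationale, and what the
synthetic benchmark does and does not establish.

## Worked example

Generate a synthetic cohort with known ground truth, then prioritize:

```sh
gp simulate --out demo --n-cases 10 --n-controls 200 --n-variants 2000 --seed 7
# wrote 2000 case and 2000 control variants, 5 gene lists,
# 30 planted / 70 decoy variants to demo

gp prioritize --cases demo/cases.vcf --controls demo/controls.vcf \
  --gene-list embryo_development=demo/genelist_embryo_development.txt \
  --gene-list lethal=demo/genelist_lethal.txt \
  --gene-list essential=demo/genelist_essential.txt \
  --gene-list ddd=demo/genelist_ddd.txt \
  --gene-list miscarriage_candidates=demo/genelist_miscarriage_candidates.txt \
  --seed 7 --out demo_run
# hits per stage: [91, 70, 34, 31]; 31 unique variants in 31 genes (75 transcripts)
```

Filter I found 91 hits; the per-gene cap removed 21, the control
resampling null removed 36 more, and the private-depth check another 3.
The 31 survivors include all 30 planted detrimental variants (the truth
table is in `demo/truth.tsv`) and none of the 70 decoys.
`demo_run/prioritized.tsv` holds one row per (variant, sample, qualifying
transcript) with the clause that selected it:

```
chrom  pos      id           ref alt sample   gene      transcript   impact ... criterion
chr1   3840000  rs802760008  A   C   CASE005  GENE0375  GENE0375.t1  HIGH   ... score
chr1   3840000  rs802760008  A   C   CASE005  GENE0375  GENE0375.t2  HIGH   ... score
```

STR screening of a simulated trisomy-22 sample:

```python
>>> from gprior import generate_str_profiles, call_sample
>>> karyotype = {c: 2 for c in ("13", "15", "16", "18", "21", "22", "X")}
>>> karyotype["22"] = 3
>>> call = call_sample(generate_str_profiles(karyotype, noise_cv=0.05, seed=3))
>>> call.chromosome_calls
{'13': 'euploid', '15': 'euploid', '16': 'euploid', '18': 'euploid',
 '21': 'euploid', '22': 'trisomy', 'X': 'euploid'}
>>> call.triploidy
False
```

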