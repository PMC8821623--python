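"""Independent brute-force reference implementations of the filter stages.

Everything here is written as plain nested-loop predicate evaluation over
the domain objects, deliberately sharing no code with the package's filter
implementations, so oracle-equivalence tests are meaningful.
"""

from __future__ import annotations

import itertools
import math

from gprior.varmodel import CohortTable


def brute_cadd_threshold(percentile: float) -> float:
    return -10.0 * math.log10(1.0 - percentile / 100.0)


def brute_is_private(rec, reference_sets=("1000G", "gnomAD")) -> bool:
    observed = False
    for ann in rec.annotations:
        for name in reference_sets:
            if name in ann.ref_afs and ann.ref_afs[name] > 0:
                observed = True
    return not observed


def brute_filter_one(table, lists, config):
    """Set of (variant key, sample, gene) hits by direct predicate evaluation."""
    threshold = brute_cadd_threshold(config.cadd_percentile)
    out = set()
    for rec in table.variants:
        for sample in table.samples:
            gt = next(g for g in rec.genotypes if g.sample_id == sample)
            if gt.missing or gt.dosage < 1:
                continue
            for gene in {a.gene_symbol for a in rec.annotations}:
                anns = [a for a in rec.annotations if a.gene_symbol == gene]
                impact_ok = any(a.impact in ("HIGH", "MODERATE") for a in anns)
                af_ok = True
                for a in rec.annotations:
                    for af in a.ref_afs.values():
                        if af >= config.af_threshold:
                            af_ok = False
                list_ok = (
                    lists is not None
                    and sum(
                        gene.upper() in lists.lists[n] for n in lists.order
                    )
                    >= config.min_list_membership
                )
                score_ok = False
                for a in anns:
                    if a.impact not in ("HIGH", "MODERATE"):
                        continue
                    if (
                        a.cadd_scaled is not None
                        and a.pli is not None
                        and a.cadd_scaled >= threshold
                        and a.pli > config.pli_threshold
                    ):
                        score_ok = True
                if impact_ok and af_ok and (list_ok or score_ok):
                    out.add((rec.key, sample, gene))
    return out


def brute_filter_two(hit_triples, max_hits_per_gene):
    """Group-count-threshold oracle over (key, sample, gene) triples."""
    counts = {}
    for _, _, gene in hit_triples:
        counts[gene] = counts.get(gene, 0) + 1
    return {t for t in hit_triples if counts[t[2]] <= max_hits_per_gene}


def brute_filter_three(hit_triples, gene_freq, threshold):
    return {t for t in hit_triples if gene_freq.get(t[2], 0.0) <= threshold}


def brute_filter_four(hits_with_flags):
    """Oracle over (triple, private, depth) tuples; returns surviving triples."""
    nonprivate = [d for _, priv, d in hits_with_flags if not priv]
    if not nonprivate:
        return {t for t, _, _ in hits_with_flags}
    lo, hi = min(nonprivate), max(nonprivate)
    return {
        t
        for t, priv, d in hits_with_flags
        if not priv or (lo <= d <= hi)
    }


def brute_null_profile(controls: CohortTable, lists, config):
    """Exact chance-selection frequencies by restricting the cohort to each
    subset of ``sample_size`` controls and re-running the brute Filter I."""
    from gprior.varmodel import VariantRecord

    counts: dict[str, int] = {}
    subsets = list(
        itertools.combinations(controls.samples, config.sample_size)
    )
    for subset in subsets:
        restricted = CohortTable(
            samples=list(subset),
            variants=[
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alt,
                    variant_id=rec.variant_id,
                    qual=rec.qual,
                    site_depth=rec.site_depth,
                    annotations=list(rec.annotations),
                    genotypes=[g for g in rec.genotypes if g.sample_id in subset],
                )
                for rec in controls.variants
            ],
        )
        genes = {gene for _, _, gene in brute_filter_one(restricted, lists, config)}
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return {g: k / len(subsets) for g, k in counts.items()}
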