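"""Filter stages of the prioritization pipeline (Filters I, II and IV).

Filter I retains (variant, carrier sample, gene) occurrences — *hits* —
where the variant has a moderate/high predicted impact on the gene, is rare
in every reference population that recorded it, and either lies in a gene
found in at least ``min_list_membership`` candidate lists or combines a high
scaled deleteriousness score with strong loss-of-function constraint
(pLI > ``pli_threshold``).

Filter II removes hits in genes that accumulate more than
``max_hits_per_gene`` hits across the whole case cohort, on the assumption
that such pile-ups are sequencing/alignment artifacts.

Filter IV removes *private* hits (variants unobserved in all reference
sets) whose read depth falls outside the closed depth range spanned by
non-private hits, a guard against calls supported by aberrant coverage.

Filter III (the resampling null over a control cohort) lives in
:mod:`gprior.nullmodel`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .genelists import GeneListCollection
from .varmodel import DAMAGING_IMPACTS, CohortTable, VariantRecord

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_SETS = ("1000G", "gnomAD")


@dataclass
class FilterConfig:
    """Tunable parameters of the four filtering stages.

    Defaults encode the pipeline's standard operating point: allele
    frequency < 5% in each recording reference population, scaled
    deleteriousness above the 90th percentile combined with pLI > 0.9,
    membership in at least 2 candidate lists, a cap of 5 hits per gene,
    and a null built from 100 resamples of 10 control individuals with a
    5% chance-selection cutoff.
    """

    af_threshold: float = 0.05
    cadd_percentile: float = 90.0
    pli_threshold: float = 0.9
    min_list_membership: int = 2
    max_hits_per_gene: int = 5
    null_freq_threshold: float = 0.05
    replicates: int = 100
    sample_size: int = 10
    seed: int = 42
    # "scale": closed-form genome-wide percentile -> scaled-score threshold;
    # "empirical": percentile of the scores observed in the analyzed table.
    cadd_mode: str = "scale"
    # Filter II counting unit: "occurrence" = (variant, sample) hits;
    # "variant" = unique variants per gene.
    filter2_unit: str = "occurrence"
    exhaustive_null: bool = False
    exhaustive_cap: int = 500_000
    strict_qc: bool = False
    min_depth: int = 10
    min_qual: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.af_threshold <= 1.0:
            raise ValueError("af_threshold outside [0, 1]")
        if not 0.0 < self.cadd_percentile < 100.0:
            raise ValueError("cadd_percentile outside (0, 100)")
        if not 0.0 <= self.pli_threshold <= 1.0:
            raise ValueError("pli_threshold outside [0, 1]")
        if self.min_list_membership < 1:
            raise ValueError("min_list_membership must be >= 1")
        if self.max_hits_per_gene < 1:
            raise ValueError("max_hits_per_gene must be >= 1")
        if not 0.0 <= self.null_freq_threshold <= 1.0:
            raise ValueError("null_freq_threshold outside [0, 1]")
        if self.replicates < 1 or self.sample_size < 1:
            raise ValueError("replicates and sample_size must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        if self.cadd_mode not in ("scale", "empirical"):
            raise ValueError("cadd_mode must be 'scale' or 'empirical'")
        if self.filter2_unit not in ("occurrence", "variant"):
            raise ValueError("filter2_unit must be 'occurrence' or 'variant'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class Hit:
    """A (variant, sample, gene) occurrence retained by Filter I.

    ``qualifying_transcripts`` lists every transcript of the gene whose
    impact qualifies; ``criterion`` records which Filter I clause fired
    ("list", "score" or "both"); ``private`` marks absence from all
    reference sets; ``depth`` is the carrier's read depth at the site.
    """

    variant: VariantRecord
    sample_id: str
    gene_symbol: str
    qualifying_transcripts: tuple[str, ...]
    criterion: str
    private: bool
    depth: int

    def __post_init__(self) -> None:
        if self.criterion not in ("list", "score", "both"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if not self.qualifying_transcripts:
            raise ValueError("hit without qualifying transcripts")


def cadd_percentile_to_threshold(percentile: float) -> float:
    """Scaled-score threshold corresponding to a genome-wide rank percentile.

    A scaled (PHRED-like) deleteriousness score s places a variant in the
    top 10^(-s/10) fraction of all possible substitutions, so the score at
    the p-th percentile is -10*log10(1 - p/100): 90 -> 10.0, 99 -> 20.0,
    99.8 -> ~26.99.
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError(f"percentile {percentile} outside (0, 100)")
    return -10.0 * math.log10(1.0 - percentile / 100.0)


def is_private(
    variant: VariantRecord,
    reference_sets: Sequence[str] = DEFAULT_REFERENCE_SETS,
) -> bool:
    """True iff the alternate allele is unobserved in every named reference set.

    An annotation entry of exactly 0 counts as unobserved; any positive
    frequency in any named set makes the variant non-private.
    """
    for ann in variant.annotations:
        for name in reference_sets:
            af = ann.ref_afs.get(name)
            if af is not None and af > 0:
                return False
    return True


def _resolve_cadd_threshold(table: CohortTable, config: FilterConfig) -> float:
    if config.cadd_mode == "empirical":
        scores = [
            a.cadd_scaled
            for rec in table.variants
            for a in rec.annotations
            if a.cadd_scaled is not None
        ]
        if not scores:
            return math.inf
        return float(np.percentile(scores, config.cadd_percentile))
    return cadd_percentile_to_threshold(config.cadd_percentile)


def filter_one(
    table: CohortTable,
    lists: GeneListCollection | None,
    config: FilterConfig,
    reference_sets: Sequence[str] | None = None,
) -> list[Hit]:
    """Filter I: emit hits for rare, impactful, list- or score-supported variants.

    A hit is one (variant, carrier sample, gene) where:

    a. some transcript annotation of the gene has HIGH or MODERATE impact;
    b. every reference-set frequency recorded for the variant is strictly
       below ``af_threshold`` (absent entries pass — an allele unseen in a
       reference set cannot be common in it);
    c. the gene appears in at least ``min_list_membership`` candidate lists,
       or some qualifying transcript has scaled score at or above the
       percentile threshold in a gene with pLI strictly above
       ``pli_threshold``.  Absent scores can never satisfy the clause.

    Carriers are non-missing genotypes with dosage >= 1 (heterozygous,
    homozygous-alternate and hemizygous calls alike).  Output order follows
    record order, then annotation order, then cohort sample order.
    """
    threshold = _resolve_cadd_threshold(table, config)
    if reference_sets is None:
        found = sorted(
            {
                name
                for rec in table.variants
                for a in rec.annotations
                for name in a.ref_afs
            }
        )
        reference_sets = tuple(found) or DEFAULT_REFERENCE_SETS
    hits: list[Hit] = []
    for rec in table.variants:
        if any(
            af >= config.af_threshold
            for a in rec.annotations
            for af in a.ref_afs.values()
        ):
            continue
        carriers = [g for g in rec.genotypes if g.is_carrier]
        if not carriers:
            continue
        private = is_private(rec, reference_sets)
        by_gene: dict[str, list] = {}
        for a in rec.annotations:
            by_gene.setdefault(a.gene_symbol, []).append(a)
        for gene, anns in by_gene.items():
            qualifying = [a for a in anns if a.impact in DAMAGING_IMPACTS]
            if not qualifying:
                continue
            list_ok = (
                lists is not None
                and lists.membership_count(gene) >= config.min_list_membership
            )
            score_ok = any(
                a.cadd_scaled is not None
                and a.pli is not None
                and a.cadd_scaled >= threshold
                and a.pli > config.pli_threshold
                for a in qualifying
            )
            if not (list_ok or score_ok):
                continue
            criterion = "both" if (list_ok and score_ok) else ("list" if list_ok else "score")
            transcripts = tuple(a.transcript_id for a in qualifying)
            for g in carriers:
                hits.append(
                    Hit(
                        variant=rec,
                        sample_id=g.sample_id,
                        gene_symbol=gene,
                        qualifying_transcripts=transcripts,
                        criterion=criterion,
                        private=private,
                        depth=g.depth,
                    )
                )
    return hits


@dataclass
class Filter2Result:
    """Hits surviving the per-gene hit cap, plus the removed genes and counts."""

    hits: list[Hit]
    removed_genes: dict[str, int] = field(default_factory=dict)


def filter_two(hits: Iterable[Hit], config: FilterConfig) -> Filter2Result:
    """Filter II: drop every hit in genes with more than ``max_hits_per_gene`` hits.

    Counting is cohort-wide; the unit is (variant, sample) occurrences by
    default, or unique variants per gene with ``filter2_unit='variant'``.
    The inequality is strict: a gene with exactly the cap survives.
    """
    hits = list(hits)
    counts: dict[str, int] = {}
    if config.filter2_unit == "variant":
        seen: set[tuple] = set()
        for h in hits:
            key = (h.gene_symbol, h.variant.key)
            if key not in seen:
                seen.add(key)
                counts[h.gene_symbol] = counts.get(h.gene_symbol, 0) + 1
    else:
        for h in hits:
            counts[h.gene_symbol] = counts.get(h.gene_symbol, 0) + 1
    removed = {g: c for g, c in counts.items() if c > config.max_hits_per_gene}
    survivors = [h for h in hits if h.gene_symbol not in removed]
    if removed:
        logger.info(
            "Filter II removed %d gene(s) with > %d hits",
            len(removed),
            config.max_hits_per_gene,
        )
    return Filter2Result(hits=survivors, removed_genes=removed)


@dataclass
class Filter4Result:
    """Hits surviving the private-variant depth check, plus removed hits."""

    hits: list[Hit]
    removed: list[Hit] = field(default_factory=list)
    depth_range: tuple[int, int] | None = None


def filter_four(hits: Iterable[Hit]) -> Filter4Result:
    """Filter IV: remove private hits with depth outside the non-private range.

    The closed interval [min, max] of read depth is pooled over all
    non-private hits in the cohort; private hits strictly outside it are
    removed.  With no non-private hits the depth range is undefined and the
    input passes through unchanged (with a warning).
    """
    hits = list(hits)
    nonprivate = [h.depth for h in hits if not h.private]
    if not nonprivate:
        logger.warning(
            "Filter IV: no non-private hits to define a depth range; passing "
            "all %d hit(s) through unchanged",
            len(hits),
        )
        return Filter4Result(hits=hits, removed=[], depth_range=None)
    lo, hi = min(nonprivate), max(nonprivate)
    removed = [h for h in hits if h.private and (h.depth < lo or h.depth > hi)]
    survivors = [h for h in hits if not (h.private and (h.depth < lo or h.depth > hi))]
    return Filter4Result(hits=survivors, removed=removed, depth_range=(lo, hi))
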