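"""Filter III: a resampling null for genes selected by chance.

Small cohorts of healthy controls are resampled (without replacement within
a replicate, independently across replicates) and Filter I is applied to
each resampled subset.  The fraction of replicates in which a gene yields at
least one hit estimates its chance of being selected in a cohort of that
size for reasons unrelated to the phenotype.  Case hits in genes whose
chance-selection frequency exceeds ``null_freq_threshold`` are removed.

Because the Filter I predicate is evaluated per variant and per gene —
independent of which other samples are present — the profile is computed by
running Filter I once on the full control table and intersecting the carrier
samples of each hit with every replicate subset, which is exactly equivalent
to restricting the table and re-running the filter, replicate by replicate.

An exhaustive mode enumerates all C(n, k) subsets instead of Monte Carlo
sampling whenever their number is below a configurable cap, giving exact
chance-selection frequencies (and an oracle for testing the sampler).
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .filters import FilterConfig, Hit, filter_one
from .genelists import GeneListCollection
from .varmodel import CohortTable

logger = logging.getLogger(__name__)


@dataclass
class NullGeneProfile:
    """Per-gene fraction of control replicates in which the gene passed Filter I.

    ``gene_counts`` stores the integer number of replicates that retained
    each gene, so every frequency is k/``replicate_count``; genes absent
    from the map have frequency 0.
    """

    replicate_count: int
    sample_size: int
    gene_counts: dict[str, int] = field(default_factory=dict)
    seed: int | None = None
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        for gene, k in self.gene_counts.items():
            if not 0 <= k <= self.replicate_count:
                raise ValueError(
                    f"{gene}: retained count {k} outside [0, {self.replicate_count}]"
                )

    def freq(self, gene: str) -> float:
        return self.gene_counts.get(gene, 0) / self.replicate_count

    @property
    def gene_freq(self) -> dict[str, float]:
        return {g: k / self.replicate_count for g, k in self.gene_counts.items()}

    def genes_above(self, threshold: float) -> list[str]:
        """Genes with chance-selection frequency strictly above ``threshold``."""
        return sorted(
            g for g, k in self.gene_counts.items()
            if k / self.replicate_count > threshold
        )

    def to_tsv(self, path: str | Path) -> None:
        lines = [
            f"#replicates={self.replicate_count}\tsample_size={self.sample_size}"
            f"\tseed={'' if self.seed is None else self.seed}"
            f"\texhaustive={int(self.exhaustive)}",
            "gene\tretained_replicates\tfrequency",
        ]
        for gene in sorted(self.gene_counts):
            k = self.gene_counts[gene]
            lines.append(f"{gene}\t{k}\t{k / self.replicate_count!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NullGeneProfile":
        lines = Path(path).read_text().splitlines()
        if not lines or not lines[0].startswith("#"):
            raise ValueError(f"{path}: missing profile metadata header line")
        meta = dict(
            kv.split("=", 1) for kv in lines[0].lstrip("#").split("\t")
        )
        counts: dict[str, int] = {}
        for line in lines[2:]:
            if not line.strip():
                continue
            gene, k, _freq = line.split("\t")
            counts[gene] = int(k)
        return cls(
            replicate_count=int(meta["replicates"]),
            sample_size=int(meta["sample_size"]),
            gene_counts=counts,
            seed=int(meta["seed"]) if meta.get("seed") else None,
            exhaustive=bool(int(meta.get("exhaustive", "0"))),
        )


def resample_replicates(
    control_samples: Sequence[str],
    sample_size: int,
    replicates: int,
    seed: int,
) -> list[list[str]]:
    """Draw ``replicates`` subsets of ``sample_size`` distinct individuals.

    Sampling is uniform without replacement within a replicate and
    independent across replicates.  Each replicate's generator is seeded
    from (seed, replicate index), so the sequence is fully reproducible and
    any replicate can be regenerated in isolation.
    """
    n = len(control_samples)
    if sample_size > n:
        raise ValueError(
            f"sample_size {sample_size} exceeds control cohort size {n}"
        )
    subsets = []
    for i in range(replicates):
        rng = np.random.default_rng((seed, i))
        idx = rng.choice(n, size=sample_size, replace=False)
        subsets.append([control_samples[j] for j in idx])
    return subsets


def _genes_by_sample(hits: Iterable[Hit]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for h in hits:
        out.setdefault(h.sample_id, set()).add(h.gene_symbol)
    return out


def null_gene_profile(
    controls: CohortTable,
    lists: GeneListCollection | None,
    config: FilterConfig,
    exhaustive: bool | None = None,
) -> NullGeneProfile:
    """Estimate each gene's chance of passing Filter I in a resampled cohort.

    A gene counts at most once per replicate (presence/absence), however
    many hits it yields there.  With ``exhaustive`` (or
    ``config.exhaustive_null``) all C(n, sample_size) subsets are enumerated
    — exact frequencies — provided their number does not exceed
    ``config.exhaustive_cap``.
    """
    if exhaustive is None:
        exhaustive = config.exhaustive_null
    hits = filter_one(controls, lists, config)
    genes_by_sample = _genes_by_sample(hits)
    if exhaustive:
        total = math.comb(len(controls.samples), config.sample_size)
        if total > config.exhaustive_cap:
            raise ValueError(
                f"exhaustive enumeration of {total} subsets exceeds the cap "
                f"({config.exhaustive_cap}); use Monte Carlo resampling"
            )
        subsets: Iterable[Sequence[str]] = itertools.combinations(
            controls.samples, config.sample_size
        )
        replicate_count = total
        seed: int | None = None
    else:
        subsets = resample_replicates(
            controls.samples, config.sample_size, config.replicates, config.seed
        )
        replicate_count = config.replicates
        seed = config.seed
    counts: Counter[str] = Counter()
    for subset in subsets:
        genes: set[str] = set()
        for s in subset:
            genes |= genes_by_sample.get(s, set())
        counts.update(genes)
    return NullGeneProfile(
        replicate_count=replicate_count,
        sample_size=config.sample_size,
        gene_counts=dict(counts),
        seed=seed,
        exhaustive=exhaustive,
    )


@dataclass
class Filter3Result:
    """Hits surviving the chance-selection cutoff, plus the excluded genes.

    ``excluded_genes`` is the full set of genes above the cutoff in the
    null profile; ``excluded_case_genes`` is its intersection with genes
    actually hit in the cases (the genes whose hits were removed).
    """

    hits: list[Hit]
    excluded_genes: list[str] = field(default_factory=list)
    excluded_case_genes: list[str] = field(default_factory=list)


def filter_three(
    hits: Iterable[Hit],
    profile: NullGeneProfile,
    config: FilterConfig,
) -> Filter3Result:
    """Filter III: remove hits in genes selected too often by chance.

    The cutoff is strict: a gene whose chance-selection frequency exceeds
    ``null_freq_threshold`` loses all its hits; a gene exactly at the
    threshold survives.
    """
    hits = list(hits)
    excluded = profile.genes_above(config.null_freq_threshold)
    excluded_set = set(excluded)
    survivors = [h for h in hits if h.gene_symbol not in excluded_set]
    case_genes = {h.gene_symbol for h in hits}
    return Filter3Result(
        hits=survivors,
        excluded_genes=excluded,
        excluded_case_genes=sorted(excluded_set & case_genes),
    )
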