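"""Shared fixtures: a written synthetic cohort and random-table builders."""

from __future__ import annotations

import numpy as np
import pytest

from gprior.filters import FilterConfig
from gprior.genelists import GeneListCollection
from gprior.synthetic_data import SimulationParams, write_cohorts
from gprior.varmodel import Annotation, CohortTable, GenotypeCall, VariantRecord

GENE_POOL = [f"G{i:02d}" for i in range(1, 31)]
IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small synthetic cohort written to disk, shared across tests."""
    out = tmp_path_factory.mktemp("sim")
    params = SimulationParams(
        n_genes=200, n_variants=600, n_cases=6, n_controls=60, seed=11
    )
    paths, cases, controls, collection, truth = write_cohorts(out, params)
    return {
        "params": params,
        "paths": paths,
        "cases": cases,
        "controls": controls,
        "lists": collection,
        "truth": truth,
    }


def make_random_table(
    rng: np.random.Generator, n_variants: int, n_samples: int
) -> tuple[CohortTable, GeneListCollection, dict[str, float | None]]:
    """A random annotated cohort exercising every annotation corner case."""
    samples = [f"S{i:03d}" for i in range(n_samples)]
    pli_by_gene: dict[str, float | None] = {
        g: (float(rng.random()) if rng.random() < 0.8 else None) for g in GENE_POOL
    }
    variants = []
    for i in range(n_variants):
        n_ann = 1 + int(rng.integers(3))
        annotations = []
        genes = rng.choice(GENE_POOL, size=n_ann, replace=True)
        for t, gene in enumerate(genes):
            ref_afs = {}
            for name in ("1000G", "gnomAD"):
                if rng.random() < 0.7:
                    af = float(rng.beta(0.2, 2.0))
                    if rng.random() < 0.1:
                        af = 0.0
                    ref_afs[name] = af
            annotations.append(
                Annotation(
                    gene_symbol=str(gene),
                    transcript_id=f"{gene}.t{t}",
                    impact=IMPACTS[int(rng.integers(4))],
                    consequence_terms=frozenset({"missense_variant"}),
                    cadd_scaled=float(rng.uniform(0, 40)) if rng.random() < 0.8 else None,
                    ref_afs=ref_afs,
                    pli=pli_by_gene[str(gene)],
                )
            )
        genotypes = []
        for s in samples:
            missing = rng.random() < 0.1
            ploidy = 1 if rng.random() < 0.1 else 2
            dosage = 0 if missing else int(rng.integers(ploidy + 1))
            genotypes.append(
                GenotypeCall(s, dosage, ploidy, int(rng.integers(1, 60)), missing)
            )
        variants.append(
            VariantRecord(
                chrom=f"chr{1 + i % 5}",
                pos=1000 + i,
                ref="A",
                alt="T",
                qual=60.0,
                site_depth=50,
                annotations=annotations,
                genotypes=genotypes,
            )
        )
    n_lists = 3 + int(rng.integers(4))
    lists = {
        f"L{k}": set(
            str(g)
            for g in rng.choice(GENE_POOL, size=1 + int(rng.integers(10)), replace=False)
        )
        for k in range(n_lists)
    }
    collection = GeneListCollection.from_dict(lists)
    return CohortTable(samples=samples, variants=variants), collection, pli_by_gene


def make_random_config(rng: np.random.Generator, n_samples: int) -> FilterConfig:
    """Random but valid filter configuration for oracle-equivalence runs."""
    return FilterConfig(
        af_threshold=float(rng.choice([0.01, 0.05, 0.1])),
        cadd_percentile=float(rng.choice([80.0, 90.0, 99.0])),
        pli_threshold=float(rng.choice([0.5, 0.9])),
        min_list_membership=int(rng.choice([1, 2, 3])),
        max_hits_per_gene=int(rng.choice([1, 2, 5])),
        null_freq_threshold=float(rng.choice([0.0, 0.05, 0.5])),
        replicates=20,
        sample_size=max(1, min(3, n_samples - 1)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
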