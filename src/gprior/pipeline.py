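"""End-to-end orchestration of the four-stage prioritization.

``run_gp`` reads the case cohort, validates the upstream call-quality
thresholds, loads the candidate gene lists, builds (or loads) the control
resampling null, applies Filter I -> II -> III -> IV in that fixed order,
and writes the prioritized-variant table plus a machine-readable stage
summary.  Filter IV's non-private depth range is computed on the hits
surviving Filter III, i.e. it is applied last.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .filters import (
    Filter2Result,
    Filter4Result,
    FilterConfig,
    Hit,
    filter_four,
    filter_one,
    filter_two,
)
from .genelists import GeneListCollection, load_gene_lists
from .nullmodel import Filter3Result, NullGeneProfile, filter_three, null_gene_profile
from .varmodel import (
    DEFAULT_DIALECT,
    AnnotationDialect,
    CohortTable,
    read_annotated_vcf,
    validate_upstream_qc,
    write_prioritized_table,
)

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """The run is missing a required input (controls or a precomputed null)."""


@dataclass
class StageSummary:
    """Per-stage hit counts and summary statistics of one pipeline run.

    Hit counts are (variant, sample, gene) occurrences and are
    non-increasing across stages; per-stage unique-variant counts are also
    reported because the two units differ whenever several samples or genes
    share a variant.  Per-sample statistics are mean +/- sd (sample
    standard deviation) over all cohort samples, samples without surviving
    hits counting as zero.
    """

    n_samples: int = 0
    n_input_variants: int = 0
    qc_depth_violations: int = 0
    qc_qual_violations: int = 0
    hits_filter1: int = 0
    hits_filter2: int = 0
    hits_filter3: int = 0
    hits_filter4: int = 0
    unique_variants_by_stage: dict[str, int] = field(default_factory=dict)
    unique_variants: int = 0
    unique_genes: int = 0
    unique_transcripts: int = 0
    per_sample: dict[str, dict[str, float]] = field(default_factory=dict)
    removed_genes_filter2: dict[str, int] = field(default_factory=dict)
    excluded_genes_filter3: list[str] = field(default_factory=list)
    excluded_case_genes_filter3: list[str] = field(default_factory=list)
    removed_hits_filter4: int = 0
    filter4_depth_range: tuple[int, int] | None = None
    config: dict = field(default_factory=dict)

    def stage_counts(self) -> list[int]:
        return [self.hits_filter1, self.hits_filter2, self.hits_filter3, self.hits_filter4]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _unique_variants(hits: Sequence[Hit]) -> int:
    return len({h.variant.key for h in hits})


def _per_sample_stats(hits: Sequence[Hit], samples: Sequence[str]) -> dict:
    per_var: dict[str, set] = {s: set() for s in samples}
    per_gene: dict[str, set] = {s: set() for s in samples}
    per_tx: dict[str, set] = {s: set() for s in samples}
    for h in hits:
        per_var[h.sample_id].add(h.variant.key)
        per_gene[h.sample_id].add(h.gene_symbol)
        per_tx[h.sample_id].update(h.qualifying_transcripts)
    out = {}
    for name, data in (("variants", per_var), ("genes", per_gene), ("transcripts", per_tx)):
        counts = np.array([len(data[s]) for s in samples], dtype=float)
        out[name] = {
            "mean": float(counts.mean()) if len(counts) else 0.0,
            "sd": float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
        }
    return out


def summarize(
    cases: CohortTable,
    hits1: Sequence[Hit],
    r2: Filter2Result,
    r3: Filter3Result,
    r4: Filter4Result,
    config: FilterConfig,
    qc_depth: int = 0,
    qc_qual: int = 0,
) -> StageSummary:
    """Assemble the stage summary from the filter results."""
    final = r4.hits
    summary = StageSummary(
        n_samples=cases.n_samples,
        n_input_variants=len(cases),
        qc_depth_violations=qc_depth,
        qc_qual_violations=qc_qual,
        hits_filter1=len(hits1),
        hits_filter2=len(r2.hits),
        hits_filter3=len(r3.hits),
        hits_filter4=len(final),
        unique_variants_by_stage={
            "filter1": _unique_variants(hits1),
            "filter2": _unique_variants(r2.hits),
            "filter3": _unique_variants(r3.hits),
            "filter4": _unique_variants(final),
        },
        unique_variants=_unique_variants(final),
        unique_genes=len({h.gene_symbol for h in final}),
        unique_transcripts=len(
            {tx for h in final for tx in h.qualifying_transcripts}
        ),
        per_sample=_per_sample_stats(final, cases.samples),
        removed_genes_filter2=dict(r2.removed_genes),
        excluded_genes_filter3=list(r3.excluded_genes),
        excluded_case_genes_filter3=list(r3.excluded_case_genes),
        removed_hits_filter4=len(r4.removed),
        filter4_depth_range=r4.depth_range,
        config=config.to_dict(),
    )
    counts = summary.stage_counts()
    if any(b > a for a, b in zip(counts, counts[1:])):
        raise AssertionError(f"stage hit counts increased: {counts}")
    return summary


def run_gp(
    case_path: str | Path,
    *,
    control_path: str | Path | None = None,
    profile_path: str | Path | None = None,
    gene_list_paths: Sequence[str | Path],
    gene_list_names: Sequence[str],
    config: FilterConfig | None = None,
    out_dir: str | Path | None = None,
    dialect: AnnotationDialect = DEFAULT_DIALECT,
) -> tuple[list[Hit], StageSummary]:
    """Run the full prioritization and optionally write its outputs.

    Either ``control_path`` (a control VCF from which the resampling null is
    built) or ``profile_path`` (a precomputed null profile TSV) must be
    supplied.  When ``out_dir`` is given, the prioritized table
    (``prioritized.tsv``), the null profile (``null_profile.tsv``, if
    computed here), and the stage summary (``summary.json``) are written
    there.  With identical inputs, configuration and seed the outputs are
    byte-identical across runs.
    """
    if control_path is None and profile_path is None:
        raise ConfigurationError(
            "either a control VCF or a precomputed null profile is required"
        )
    config = config or FilterConfig()
    cases = read_annotated_vcf(case_path, dialect)
    logger.info("cases: %d samples, %d variants", cases.n_samples, len(cases))
    qc = validate_upstream_qc(
        cases, config.min_depth, config.min_qual, strict=config.strict_qc
    )
    lists = load_gene_lists(gene_list_paths, gene_list_names)

    hits1 = filter_one(cases, lists, config)
    logger.info("Filter I: %d hits", len(hits1))
    r2 = filter_two(hits1, config)
    logger.info("Filter II: %d hits", len(r2.hits))

    profile_computed = False
    if profile_path is not None:
        profile = NullGeneProfile.from_tsv(profile_path)
    else:
        controls = read_annotated_vcf(control_path, dialect)
        profile = null_gene_profile(controls, lists, config)
        profile_computed = True
    r3 = filter_three(r2.hits, profile, config)
    logger.info(
        "Filter III: %d hits (%d gene(s) excluded)", len(r3.hits), len(r3.excluded_case_genes)
    )
    r4 = filter_four(r3.hits)
    logger.info("Filter IV: %d hits", len(r4.hits))

    summary = summarize(
        cases, hits1, r2, r3, r4, config,
        qc_depth=len(qc.depth_violations), qc_qual=len(qc.qual_violations),
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_prioritized_table(r4.hits, out / "prioritized.tsv")
        if profile_computed:
            profile.to_tsv(out / "null_profile.tsv")
        summary.to_json(out / "summary.json")
    return r4.hits, summary
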