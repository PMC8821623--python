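"""Synthetic annotated cohorts, candidate gene lists and STR profiles.

The generator emulates the structure the prioritization pipeline expects —
a small case cohort and a larger control cohort sharing an annotation
dialect, five candidate gene lists, and per-sample STR peak-area profiles —
with fully controllable allele-frequency spectra, impact mixtures, score
distributions, read depths and private-variant fractions.  Alongside the
background it plants detrimental variants that must survive every filter
and decoys engineered to be removed by a designated filter, recorded in a
:class:`TruthTable` so every stage can be tested end to end without any
external data.

Genotypes are drawn under Hardy-Weinberg equilibrium at each variant's
cohort allele frequency; reference-set frequencies are noisy copies of the
control-cohort frequency (shared ancestry) except for planted and private
variants.  Everything is reproducible from a single seed; per-component
sub-generators keep case and control draws independent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .aneuploidy_screen import STRProfile
from .genelists import GeneListCollection, write_gene_list
from .varmodel import (
    Annotation,
    CohortTable,
    GenotypeCall,
    VariantRecord,
    chrom_sort_key,
    write_annotated_vcf,
)

logger = logging.getLogger(__name__)

DEFAULT_LIST_NAMES = (
    "embryo_development",
    "lethal",
    "essential",
    "ddd",
    "miscarriage_candidates",
)

#: Chromosomes screened by the QF-PCR aneuploidy assay.
DEFAULT_SCREEN_CHROMS = ("13", "15", "16", "18", "21", "22", "X")

# Per-sample depths below this are not emitted for background calls; the
# cohorts emulate variant sets already screened for callable coverage, so
# only engineered low-depth decoys fall under it.
MIN_CALLABLE_DEPTH = 6

_CONSEQUENCES = {
    "HIGH": ("stop_gained", "splice_donor_variant", "frameshift_variant"),
    "MODERATE": ("missense_variant", "inframe_deletion"),
    "LOW": ("synonymous_variant", "splice_region_variant"),
    "MODIFIER": ("intron_variant", "upstream_gene_variant", "3_prime_UTR_variant"),
}


def _default_impact_mix() -> dict[str, float]:
    return {"HIGH": 0.05, "MODERATE": 0.30, "LOW": 0.35, "MODIFIER": 0.30}


@dataclass
class SimulationParams:
    """Knobs of the cohort simulator.

    ``af_spectrum`` gives the Beta shape pair for cohort allele
    frequencies (rare-heavy by default); ``cadd_distribution`` is either
    ``"phred_uniform"`` — scores drawn as -10*log10(U), the distribution
    implied by a uniform genome-wide rank — or ``("uniform", lo, hi)``.
    ``pli_mix`` is the fraction of genes with pLI above 0.9;
    ``depth_model`` is the (mean, shape) of a negative-binomial per-sample
    read depth.  ``n_planted`` detrimental variants are planted per case
    sample; the decoy counts control how many variants are engineered to be
    removed by each filter.
    """

    n_genes: int = 400
    n_variants: int = 2000
    n_cases: int = 10
    n_controls: int = 929
    af_spectrum: tuple[float, float] = (0.5, 9.5)
    impact_mix: Mapping[str, float] = field(default_factory=_default_impact_mix)
    cadd_distribution: str | tuple = "phred_uniform"
    pli_mix: float = 0.2
    private_fraction: float = 0.21
    depth_model: tuple[float, float] = (30.0, 8.0)
    n_planted: int = 3
    missing_rate: float = 0.01
    n_common_decoys: int = 25
    n_low_impact_decoys: int = 25
    n_overload_genes: int = 2
    overload_hits: int = 7
    n_recurrent_genes: int = 3
    n_lowdepth_private: int = 3
    list_names: tuple[str, ...] = DEFAULT_LIST_NAMES
    seed: int = 42

    def __post_init__(self) -> None:
        total_mix = sum(self.impact_mix.values())
        if abs(total_mix - 1.0) > 1e-9:
            raise ValueError(f"impact_mix probabilities sum to {total_mix}, not 1")
        for frac in (self.pli_mix, self.private_fraction, self.missing_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_planted * self.n_cases > self.n_variants:
            raise ValueError(
                f"{self.n_planted * self.n_cases} planted variants exceed "
                f"n_variants={self.n_variants}"
            )
        if self.n_special_variants > self.n_variants:
            raise ValueError(
                f"planted + decoy variants ({self.n_special_variants}) exceed "
                f"n_variants={self.n_variants}"
            )
        if self.n_reserved_genes + 20 > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} leaves too few background genes after "
                f"reserving {self.n_reserved_genes}"
            )
        if self.overload_hits <= 5:
            raise ValueError("overload_hits must exceed the default per-gene cap of 5")

    @property
    def n_planted_total(self) -> int:
        return self.n_planted * self.n_cases

    @property
    def n_reserved_genes(self) -> int:
        return (
            self.n_planted_total
            + self.n_overload_genes
            + self.n_recurrent_genes
            + self.n_lowdepth_private
        )

    @property
    def n_special_variants(self) -> int:
        return (
            self.n_planted_total
            + self.n_common_decoys
            + self.n_low_impact_decoys
            + self.n_overload_genes * self.overload_hits
            + self.n_recurrent_genes
            + self.n_lowdepth_private
        )


@dataclass(frozen=True)
class PlantedVariant:
    """One engineered detrimental (variant, sample, gene) with its Filter I clause."""

    key: tuple[str, int, str, str]
    sample_id: str
    gene: str
    clause: str  # "score" | "list"


@dataclass(frozen=True)
class DecoyVariant:
    """One engineered artifact variant with the filter expected to remove it."""

    key: tuple[str, int, str, str]
    gene: str
    expected_filter: str  # "filter1" .. "filter4"


@dataclass
class TruthTable:
    """Ground truth of the simulated cohorts: planted entries and decoys."""

    planted: list[PlantedVariant] = field(default_factory=list)
    decoys: list[DecoyVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        planted_keys = {p.key for p in self.planted}
        decoy_keys = {d.key for d in self.decoys}
        if planted_keys & decoy_keys:
            raise ValueError("planted and decoy variant keys overlap")

    def to_tsv(self, path: str | Path) -> None:
        lines = ["kind\tchrom\tpos\tref\talt\tsample\tgene\tlabel"]
        for p in self.planted:
            c, pos, ref, alt = p.key
            lines.append(f"planted\t{c}\t{pos}\t{ref}\t{alt}\t{p.sample_id}\t{p.gene}\t{p.clause}")
        for d in self.decoys:
            c, pos, ref, alt = d.key
            lines.append(f"decoy\t{c}\t{pos}\t{ref}\t{alt}\t\t{d.gene}\t{d.expected_filter}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        table = cls()
        lines = Path(path).read_text().splitlines()[1:]
        for line in lines:
            if not line.strip():
                continue
            kind, chrom, pos, ref, alt, sample, gene, label = line.split("\t")
            key = (chrom, int(pos), ref, alt)
            if kind == "planted":
                table.planted.append(PlantedVariant(key, sample, gene, label))
            else:
                table.decoys.append(DecoyVariant(key, gene, label))
        return table


class _VariantSpec:
    """Mutable staging record used while assembling the cohorts."""

    __slots__ = (
        "gene", "impact", "cadd", "ref_afs", "case_dosage", "ctrl_dosage",
        "case_missing", "ctrl_missing", "case_depth_override",
    )

    def __init__(self, gene, impact, cadd, ref_afs, case_dosage, ctrl_dosage,
                 case_missing=None, ctrl_missing=None, case_depth_override=None):
        self.gene = gene
        self.impact = impact
        self.cadd = cadd
        self.ref_afs = ref_afs
        self.case_dosage = case_dosage
        self.ctrl_dosage = ctrl_dosage
        self.case_missing = case_missing
        self.ctrl_missing = ctrl_missing
        # sample_id -> fixed FORMAT depth (engineered low-coverage decoys)
        self.case_depth_override = case_depth_override or {}


def _draw_cadd(rng: np.random.Generator, spec: str | tuple) -> float:
    if spec == "phred_uniform":
        return float(-10.0 * np.log10(rng.uniform(1e-12, 1.0)))
    kind, lo, hi = spec
    if kind != "uniform":
        raise ValueError(f"unknown cadd_distribution {spec!r}")
    return float(rng.uniform(lo, hi))


def _hw_dosage(
    rng: np.random.Generator, q: float, ploidy: np.ndarray
) -> np.ndarray:
    """Hardy-Weinberg dosages for mixed ploidy (diploid binomial, haploid Bernoulli)."""
    return rng.binomial(ploidy, q)


def _depths(rng: np.random.Generator, params: SimulationParams, n: int) -> np.ndarray:
    mean, shape = params.depth_model
    p = shape / (shape + mean)
    d = rng.negative_binomial(shape, p, size=n)
    return np.maximum(d, MIN_CALLABLE_DEPTH)


def generate_cohorts(
    params: SimulationParams,
) -> tuple[CohortTable, CohortTable, GeneListCollection, TruthTable]:
    """Generate matched case/control cohorts, gene lists and a truth table.

    Planted variants are rare (tiny reference frequencies), damaging
    (HIGH/MODERATE impact) and satisfy exactly one Filter I clause each
    (alternating score and list); each lives in its own reserved gene with a
    single case carrier and no control carriers, so at the default
    configuration every planted hit survives the full pipeline.  Decoys
    cover each removal route: common variants and low-impact variants
    (Filter I), hit-overloaded genes (Filter II), genes common among
    controls (Filter III) and low-depth private variants (Filter IV).
    """
    p = params
    rng_gene = np.random.default_rng((p.seed, 1))
    rng_list = np.random.default_rng((p.seed, 2))
    rng_var = np.random.default_rng((p.seed, 3))
    rng_case = np.random.default_rng((p.seed, 4))
    rng_ctrl = np.random.default_rng((p.seed, 5))

    case_samples = [f"CASE{i + 1:03d}" for i in range(p.n_cases)]
    ctrl_samples = [f"CTRL{i + 1:04d}" for i in range(p.n_controls)]
    # alternating sex; males are hemizygous on chrX
    case_male = np.arange(p.n_cases) % 2 == 0
    ctrl_male = np.arange(p.n_controls) % 2 == 0

    genes = [f"GENE{i + 1:04d}" for i in range(p.n_genes)]
    n_bg = p.n_genes - p.n_reserved_genes
    background_genes = genes[:n_bg]
    cursor = n_bg
    planted_genes = genes[cursor:cursor + p.n_planted_total]
    cursor += p.n_planted_total
    overload_genes = genes[cursor:cursor + p.n_overload_genes]
    cursor += p.n_overload_genes
    recurrent_genes = genes[cursor:cursor + p.n_recurrent_genes]
    cursor += p.n_recurrent_genes
    lowdepth_genes = genes[cursor:cursor + p.n_lowdepth_private]

    # chromosome and base position per gene; reserved genes stay autosomal
    gene_chrom: dict[str, str] = {}
    gene_base: dict[str, int] = {}
    for i, g in enumerate(genes):
        if g in background_genes and i % 23 == 22:
            gene_chrom[g] = "chrX"
        else:
            gene_chrom[g] = f"chr{(i % 22) + 1}"
        gene_base[g] = 100_000 + i * 10_000

    # per-gene constraint scores; reserved score-bearing genes forced > 0.9
    gene_pli: dict[str, float | None] = {}
    for g in genes:
        u = rng_gene.random()
        if u < 0.05:
            gene_pli[g] = None
        elif u < 0.05 + p.pli_mix:
            gene_pli[g] = float(0.901 + 0.098 * rng_gene.random())
        else:
            gene_pli[g] = float(0.9 * rng_gene.random())

    # planted clause assignment: alternate score/list deterministically
    planted_clause = {}
    for s_idx in range(p.n_cases):
        for j in range(p.n_planted):
            gene = planted_genes[s_idx * p.n_planted + j]
            planted_clause[gene] = "score" if (s_idx + j) % 2 == 0 else "list"
    for gene, clause in planted_clause.items():
        if clause == "score":
            gene_pli[gene] = float(0.95 + 0.04 * rng_gene.random())
    for gene in overload_genes + recurrent_genes + lowdepth_genes:
        gene_pli[gene] = float(0.95 + 0.04 * rng_gene.random())

    # five candidate lists drawn from background genes; planted list-clause
    # genes are inserted into exactly two lists
    list_size = max(5, n_bg // 8)
    lists: dict[str, set[str]] = {}
    for name in p.list_names:
        members = rng_list.choice(background_genes, size=list_size, replace=False)
        lists[name] = set(members)
    names = list(p.list_names)
    for gene, clause in planted_clause.items():
        if clause == "list":
            two = rng_list.choice(len(names), size=2, replace=False)
            for k in two:
                lists[names[k]].add(gene)
    collection = GeneListCollection.from_dict({n: lists[n] for n in names})

    impacts = list(p.impact_mix)
    impact_probs = np.array([p.impact_mix[i] for i in impacts])

    specs: list[_VariantSpec] = []
    truth = TruthTable()
    # index of spec -> (kind, payload) so keys can be attached after placement
    roles: list[tuple[str, object] | None] = []

    def _background_genotypes(q, gene):
        on_x = gene_chrom[gene] == "chrX"
        case_ploidy = np.where(case_male & on_x, 1, 2)
        ctrl_ploidy = np.where(ctrl_male & on_x, 1, 2)
        case_dos = _hw_dosage(rng_case, q, case_ploidy)
        ctrl_dos = _hw_dosage(rng_ctrl, q, ctrl_ploidy)
        case_miss = rng_case.random(p.n_cases) < p.missing_rate
        ctrl_miss = rng_ctrl.random(p.n_controls) < p.missing_rate
        return case_dos, ctrl_dos, case_miss, ctrl_miss

    def _noisy_af(q):
        return float(min(q * math.exp(rng_var.normal(0.0, 0.2)), 0.9))

    zeros_case = np.zeros(p.n_cases, dtype=int)
    zeros_ctrl = np.zeros(p.n_controls, dtype=int)

    # --- background variants -------------------------------------------------
    n_background = p.n_variants - p.n_special_variants
    for _ in range(n_background):
        gene = background_genes[int(rng_var.integers(n_bg))]
        q = float(rng_var.beta(*p.af_spectrum))
        private = rng_var.random() < p.private_fraction
        impact = impacts[int(rng_var.choice(len(impacts), p=impact_probs))]
        cadd = _draw_cadd(rng_var, p.cadd_distribution)
        ref_afs = {} if private else {"1000G": _noisy_af(q), "gnomAD": _noisy_af(q)}
        case_dos, ctrl_dos, case_miss, ctrl_miss = _background_genotypes(q, gene)
        specs.append(
            _VariantSpec(gene, impact, cadd, ref_afs, case_dos, ctrl_dos,
                         case_miss, ctrl_miss)
        )
        roles.append(None)

    # --- planted detrimental variants ---------------------------------------
    for s_idx, sample in enumerate(case_samples):
        for j in range(p.n_planted):
            gene = planted_genes[s_idx * p.n_planted + j]
            clause = planted_clause[gene]
            impact = "HIGH" if j % 2 == 0 else "MODERATE"
            if clause == "score":
                cadd = float(15.0 + 25.0 * rng_var.random())
            else:
                # below the default 90th-percentile scaled threshold, so the
                # recorded criterion is exactly "list"
                cadd = float(9.0 * rng_var.random())
            ref_afs = {
                "1000G": float(1e-4 * (0.5 + rng_var.random())),
                "gnomAD": float(5e-5 * (0.5 + rng_var.random())),
            }
            case_dos = zeros_case.copy()
            case_dos[s_idx] = 1
            specs.append(
                _VariantSpec(gene, impact, cadd, ref_afs, case_dos, zeros_ctrl)
            )
            roles.append(("planted", (sample, gene, clause)))

    # --- decoys removed by Filter I ------------------------------------------
    for _ in range(p.n_common_decoys):
        gene = background_genes[int(rng_var.integers(n_bg))]
        q = float(rng_var.uniform(0.1, 0.4))
        impact = "MODERATE" if rng_var.random() < 0.7 else "HIGH"
        cadd = float(15.0 + 20.0 * rng_var.random())
        ref_afs = {
            "1000G": max(_noisy_af(q), 0.06),
            "gnomAD": max(_noisy_af(q), 0.06),
        }
        case_dos, ctrl_dos, case_miss, ctrl_miss = _background_genotypes(q, gene)
        specs.append(
            _VariantSpec(gene, impact, cadd, ref_afs, case_dos, ctrl_dos,
                         case_miss, ctrl_miss)
        )
        roles.append(("decoy", (gene, "filter1")))
    for _ in range(p.n_low_impact_decoys):
        gene = background_genes[int(rng_var.integers(n_bg))]
        q = float(rng_var.beta(*p.af_spectrum))
        impact = "LOW" if rng_var.random() < 0.5 else "MODIFIER"
        cadd = float(15.0 + 20.0 * rng_var.random())
        ref_afs = {"1000G": _noisy_af(q), "gnomAD": _noisy_af(q)}
        case_dos, ctrl_dos, case_miss, ctrl_miss = _background_genotypes(q, gene)
        specs.append(
            _VariantSpec(gene, impact, cadd, ref_afs, case_dos, ctrl_dos,
                         case_miss, ctrl_miss)
        )
        roles.append(("decoy", (gene, "filter1")))

    # --- hit-overloaded genes (Filter II) ------------------------------------
    for gi, gene in enumerate(overload_genes):
        for h in range(p.overload_hits):
            cadd = float(15.0 + 20.0 * rng_var.random())
            ref_afs = {
                "1000G": float(1e-4 * (0.5 + rng_var.random())),
                "gnomAD": float(5e-5 * (0.5 + rng_var.random())),
            }
            case_dos = zeros_case.copy()
            case_dos[h % p.n_cases] = 1
            specs.append(
                _VariantSpec(gene, "MODERATE", cadd, ref_afs, case_dos, zeros_ctrl)
            )
            roles.append(("decoy", (gene, "filter2")))

    # --- control-recurrent genes (Filter III) --------------------------------
    for gene in recurrent_genes:
        cadd = float(15.0 + 20.0 * rng_var.random())
        ref_afs = {
            "1000G": float(1e-4 * (0.5 + rng_var.random())),
            "gnomAD": float(5e-5 * (0.5 + rng_var.random())),
        }
        case_dos = zeros_case.copy()
        case_dos[0] = 1
        # common among controls but rare in the reference sets, so the gene
        # is selected in nearly every control replicate
        ctrl_dos = rng_ctrl.binomial(2, 0.4, size=p.n_controls)
        specs.append(_VariantSpec(gene, "MODERATE", cadd, ref_afs, case_dos, ctrl_dos))
        roles.append(("decoy", (gene, "filter3")))

    # --- low-depth private variants (Filter IV) -------------------------------
    for i, gene in enumerate(lowdepth_genes):
        cadd = float(15.0 + 20.0 * rng_var.random())
        sample_idx = i % p.n_cases
        case_dos = zeros_case.copy()
        case_dos[sample_idx] = 1
        specs.append(
            _VariantSpec(
                gene, "MODERATE", cadd, {}, case_dos, zeros_ctrl,
                case_depth_override={case_samples[sample_idx]: 2},
            )
        )
        roles.append(("decoy", (gene, "filter4")))

    # --- place variants on the genome and materialize records ----------------
    gene_counter: dict[str, int] = {}
    placements = []
    bases = "ACGT"
    for spec in specs:
        k = gene_counter.get(spec.gene, 0)
        gene_counter[spec.gene] = k + 1
        chrom = gene_chrom[spec.gene]
        pos = gene_base[spec.gene] + k * 10
        ref = bases[int(rng_var.integers(4))]
        alt = bases[(bases.index(ref) + 1 + int(rng_var.integers(3))) % 4]
        vid = f"rs{int(rng_var.integers(10_000_000, 999_999_999))}" \
            if rng_var.random() < 0.3 else "."
        # quarter-point grid: exactly representable in the 32-bit floats
        # VCF readers use for QUAL, so write -> read round-trips bit-exactly
        qual = float(round(rng_var.uniform(30.0, 600.0) * 4) / 4)
        site_depth = int(rng_var.integers(300, 3000))
        placements.append((chrom, pos, ref, alt, vid, qual, site_depth))

    order = sorted(
        range(len(specs)),
        key=lambda i: (chrom_sort_key(placements[i][0]), placements[i][1]),
    )

    case_variants: list[VariantRecord] = []
    ctrl_variants: list[VariantRecord] = []
    for i in order:
        spec = specs[i]
        chrom, pos, ref, alt, vid, qual, site_depth = placements[i]
        key = (chrom, pos, ref, alt)
        role = roles[i]
        if role is not None:
            kind, payload = role
            if kind == "planted":
                sample, gene, clause = payload
                truth.planted.append(PlantedVariant(key, sample, gene, clause))
            else:
                gene, which = payload
                truth.decoys.append(DecoyVariant(key, gene, which))
        on_x = chrom == "chrX"
        n_tx = 1 + int(rng_var.integers(3))
        annotations = []
        for t in range(n_tx):
            term = _CONSEQUENCES[spec.impact][int(rng_var.integers(len(_CONSEQUENCES[spec.impact])))]
            annotations.append(
                Annotation(
                    gene_symbol=spec.gene,
                    transcript_id=f"{spec.gene}.t{t + 1}",
                    impact=spec.impact,
                    consequence_terms=frozenset({term}),
                    cadd_scaled=spec.cadd,
                    ref_afs=dict(spec.ref_afs),
                    pli=gene_pli[spec.gene],
                )
            )
        case_depths = _depths(rng_case, p, p.n_cases)
        ctrl_depths = _depths(rng_ctrl, p, p.n_controls)

        def _calls(samples, male, dosage, missing, depths, overrides):
            calls = []
            for si, sid in enumerate(samples):
                ploidy = 1 if (on_x and male[si]) else 2
                miss = bool(missing[si]) if missing is not None else False
                dos = 0 if miss else int(min(dosage[si], ploidy))
                depth = int(overrides.get(sid, depths[si]))
                calls.append(GenotypeCall(sid, dos, ploidy, depth, miss))
            return calls

        common = dict(
            chrom=chrom, pos=pos, ref=ref, alt=alt, variant_id=vid,
            qual=qual, site_depth=site_depth,
        )
        case_variants.append(
            VariantRecord(
                **common,
                annotations=list(annotations),
                genotypes=_calls(
                    case_samples, case_male, spec.case_dosage,
                    spec.case_missing, case_depths, spec.case_depth_override,
                ),
            )
        )
        ctrl_variants.append(
            VariantRecord(
                **common,
                annotations=list(annotations),
                genotypes=_calls(
                    ctrl_samples, ctrl_male, spec.ctrl_dosage,
                    spec.ctrl_missing, ctrl_depths, {},
                ),
            )
        )

    cases = CohortTable(samples=case_samples, variants=case_variants)
    controls = CohortTable(samples=ctrl_samples, variants=ctrl_variants)
    return cases, controls, collection, truth


@dataclass
class CohortPaths:
    """File locations of a written synthetic cohort."""

    case_vcf: Path
    control_vcf: Path
    gene_lists: dict[str, Path]
    truth_tsv: Path


def write_cohorts(
    out_dir: str | Path, params: SimulationParams
) -> tuple[CohortPaths, CohortTable, CohortTable, GeneListCollection, TruthTable]:
    """Generate cohorts and serialize them in the dialects the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cases, controls, collection, truth = generate_cohorts(params)
    case_vcf = out / "cases.vcf"
    control_vcf = out / "controls.vcf"
    write_annotated_vcf(cases, case_vcf)
    write_annotated_vcf(controls, control_vcf)
    list_paths = {}
    for name in collection.names:
        path = out / f"genelist_{name}.txt"
        write_gene_list(collection.lists[name], path, name=name)
        list_paths[name] = path
    truth_tsv = out / "truth.tsv"
    truth.to_tsv(truth_tsv)
    paths = CohortPaths(case_vcf, control_vcf, list_paths, truth_tsv)
    return paths, cases, controls, collection, truth


def generate_str_profiles(
    karyotype: Mapping[str, int],
    loci_per_chromosome: int = 4,
    noise_cv: float = 0.05,
    seed: int = 0,
    sample_id: str = "S1",
    heterozygosity: float = 0.9,
) -> list[STRProfile]:
    """Simulate QF-PCR STR profiles for a sample of known karyotype.

    ``karyotype`` maps chromosome labels to copy numbers in {1, 2, 3}.
    Disomic loci emit two peaks near 1:1 (heterozygous, probability
    ``heterozygosity``) or a single uninformative peak; trisomic loci emit
    two peaks near 2:1/1:2 or three near 1:1:1 with equal probability.
    Peak areas carry multiplicative log-normal noise with coefficient of
    variation ``noise_cv`` (exact dosage ratios at ``noise_cv=0``).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(noise_cv**2))
    profiles: list[STRProfile] = []
    for chrom, copies in karyotype.items():
        if copies not in (1, 2, 3):
            raise ValueError(f"{chrom}: unsupported copy number {copies}")
        for j in range(loci_per_chromosome):
            base = float(rng.uniform(800.0, 1600.0))
            sizes = sorted(int(s) for s in rng.choice(np.arange(10, 31), 3, replace=False))
            if copies == 1:
                doses, alleles = [1], sizes[:1]
            elif copies == 2:
                if rng.random() < heterozygosity:
                    doses, alleles = [1, 1], sizes[:2]
                else:
                    doses, alleles = [2], sizes[:1]
            else:
                if rng.random() < 0.5:
                    doses, alleles = [1, 1, 1], sizes[:3]
                elif rng.random() < 0.5:
                    doses, alleles = [2, 1], sizes[:2]
                else:
                    doses, alleles = [1, 2], sizes[:2]
            if noise_cv > 0:
                factors = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=len(doses)))
            else:
                factors = np.ones(len(doses))
            areas = tuple(float(base * d * f) for d, f in zip(doses, factors))
            profiles.append(
                STRProfile(
                    sample_id=sample_id,
                    locus=f"{chrom}_STR{j + 1}",
                    chromosome=chrom,
                    peak_areas=areas,
                    alleles=tuple(alleles),
                )
            )
    return profiles
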