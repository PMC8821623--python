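"""Domain model and I/O for annotated small-variant cohorts.

The pipeline consumes normalized, biallelic-decomposed VCFs whose functional
annotations (gene symbol, transcript, impact class, consequence terms,
scaled deleteriousness score, reference-population allele frequencies and
per-gene loss-of-function constraint) live in a single INFO field of
pipe-delimited, comma-separated transcript blocks, following the VEP ``CSQ``
convention.  The exact layout is configurable through
:class:`AnnotationDialect` so other annotators (or the built-in cohort
simulator) can be read identically.

Coordinates are 1-based VCF positions throughout; no conversion layer.
Hemizygous calls (male X/Y) are represented as ``ploidy=1`` genotypes and
count as carriers alongside diploid heterozygotes.  Missing genotypes are
excluded from carrier counts, never treated as reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

IMPACT_LEVELS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
#: Impact classes considered damaging enough to qualify a transcript (Filter I).
DAMAGING_IMPACTS = frozenset({"HIGH", "MODERATE"})


class DialectError(ValueError):
    """The VCF does not carry the annotation INFO field the dialect expects."""


class NormalizationError(ValueError):
    """A record is multiallelic; input must be decomposed upstream (e.g. vt)."""


class ConsequenceParseError(ValueError):
    """A transcript annotation block does not match the dialect layout."""


class ValidationError(RuntimeError):
    """Strict-mode upstream quality-control failure."""


def _default_af_fields() -> dict[str, str]:
    return {"AF_1000G": "1000G", "AF_gnomAD": "gnomAD"}


@dataclass(frozen=True)
class AnnotationDialect:
    """Layout of per-transcript annotation blocks inside one INFO key.

    ``subfields`` gives the pipe-delimited order; the ``*_field`` attributes
    name the roles, and ``af_fields`` maps annotation subfields to the
    reference-population set they describe (absent subfield value means the
    allele was not observed in that set).
    """

    info_key: str = "CSQ"
    subfields: tuple[str, ...] = (
        "Gene",
        "Transcript",
        "IMPACT",
        "Consequence",
        "CADD",
        "AF_1000G",
        "AF_gnomAD",
        "pLI",
    )
    gene_field: str = "Gene"
    transcript_field: str = "Transcript"
    impact_field: str = "IMPACT"
    consequence_field: str = "Consequence"
    cadd_field: str = "CADD"
    pli_field: str = "pLI"
    af_fields: Mapping[str, str] = field(default_factory=_default_af_fields)

    @property
    def reference_sets(self) -> tuple[str, ...]:
        return tuple(self.af_fields.values())

    def csq_format(self) -> str:
        return "|".join(self.subfields)


DEFAULT_DIALECT = AnnotationDialect()


@dataclass(frozen=True)
class Annotation:
    """One transcript-level functional annotation of a variant.

    ``cadd_scaled`` is a PHRED-like scaled deleteriousness score; ``pli`` is
    the gene-level probability of loss-of-function intolerance.  Both are
    optional: an absent score is *absent*, never zero, and downstream filters
    treat it as unable to satisfy score-based clauses.
    """

    gene_symbol: str
    transcript_id: str
    impact: str
    consequence_terms: frozenset[str] = frozenset()
    cadd_scaled: float | None = None
    ref_afs: Mapping[str, float] = field(default_factory=dict)
    pli: float | None = None

    def __post_init__(self) -> None:
        if self.impact not in IMPACT_LEVELS:
            raise ValueError(
                f"impact {self.impact!r} not in {IMPACT_LEVELS}"
            )
        for name, af in self.ref_afs.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency {af} for {name} outside [0, 1]")
        if self.pli is not None and not 0.0 <= self.pli <= 1.0:
            raise ValueError(f"pLI {self.pli} outside [0, 1]")
        if self.cadd_scaled is not None and self.cadd_scaled < 0:
            raise ValueError(f"scaled deleteriousness score {self.cadd_scaled} < 0")


@dataclass(frozen=True)
class GenotypeCall:
    """Per-sample genotype at one site.

    ``dosage`` counts alternate alleles; hemizygous calls carry ``ploidy=1``.
    ``missing=True`` means the call is ignored by every filter (the dosage is
    set to 0 but has no meaning).
    """

    sample_id: str
    dosage: int
    ploidy: int = 2
    depth: int = 0
    missing: bool = False

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2):
            raise ValueError(f"ploidy {self.ploidy} not in (1, 2)")
        if not self.missing and not 0 <= self.dosage <= self.ploidy:
            raise ValueError(f"dosage {self.dosage} exceeds ploidy {self.ploidy}")
        if self.depth < 0:
            raise ValueError("negative read depth")

    @property
    def is_carrier(self) -> bool:
        return not self.missing and self.dosage >= 1


@dataclass
class VariantRecord:
    """One normalized biallelic variant with annotations and genotype calls."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_id: str = "."
    qual: float = 0.0
    site_depth: int = 0
    annotations: list[Annotation] = field(default_factory=list)
    genotypes: list[GenotypeCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position {self.pos} < 1 (positions are 1-based)")
        ids = [g.sample_id for g in self.genotypes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate sample ids in genotypes at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """(chrom, pos, ref, alt) identity of the variant."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def genotype(self, sample_id: str) -> GenotypeCall:
        for g in self.genotypes:
            if g.sample_id == sample_id:
                return g
        raise KeyError(sample_id)

    @property
    def genes(self) -> list[str]:
        """Gene symbols annotated on this record, in annotation order."""
        seen: dict[str, None] = {}
        for a in self.annotations:
            seen.setdefault(a.gene_symbol, None)
        return list(seen)


@dataclass
class CohortTable:
    """An ordered cohort: sample list plus variant records in file order.

    All downstream determinism relies on record order being file order.
    """

    samples: list[str]
    variants: list[VariantRecord]

    def __post_init__(self) -> None:
        expect = tuple(self.samples)
        for rec in self.variants:
            if tuple(g.sample_id for g in rec.genotypes) != expect:
                raise ValueError(
                    f"genotype sample set at {rec.chrom}:{rec.pos} does not match cohort samples"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def __len__(self) -> int:
        return len(self.variants)


def _opt_float(raw: str) -> float | None:
    """Parse an optional numeric subfield; absent or unparseable -> None, never 0."""
    raw = raw.strip()
    if raw in ("", "."):
        return None
    try:
        return float(raw)
    except ValueError:
        return None


def parse_consequence_field(
    raw: str, dialect: AnnotationDialect = DEFAULT_DIALECT
) -> list[Annotation]:
    """Parse one INFO annotation string into transcript-level annotations.

    The string is a comma-separated list of pipe-delimited blocks, one per
    transcript, in the subfield order declared by ``dialect``.  A block with
    the wrong number of subfields raises :class:`ConsequenceParseError`
    naming the block index.
    """
    annotations: list[Annotation] = []
    for i, block in enumerate(raw.split(",")):
        parts = block.split("|")
        if len(parts) != len(dialect.subfields):
            raise ConsequenceParseError(
                f"annotation block {i}: expected {len(dialect.subfields)} "
                f"subfields, got {len(parts)}"
            )
        rec = dict(zip(dialect.subfields, parts))
        terms = frozenset(
            t for t in rec[dialect.consequence_field].split("&") if t
        )
        ref_afs: dict[str, float] = {}
        for sub, setname in dialect.af_fields.items():
            af = _opt_float(rec.get(sub, ""))
            if af is not None:
                ref_afs[setname] = af
        annotations.append(
            Annotation(
                gene_symbol=rec[dialect.gene_field],
                transcript_id=rec[dialect.transcript_field],
                impact=rec[dialect.impact_field],
                consequence_terms=terms,
                cadd_scaled=_opt_float(rec.get(dialect.cadd_field, "")),
                ref_afs=ref_afs,
                pli=_opt_float(rec.get(dialect.pli_field, "")),
            )
        )
    return annotations


def read_annotated_vcf(
    path: str | Path, dialect: AnnotationDialect = DEFAULT_DIALECT
) -> CohortTable:
    """Read an annotated, biallelic-decomposed VCF into a :class:`CohortTable`.

    Records whose annotation string fails to parse are reported through the
    module logger (position and reason) and excluded; they are never silently
    dropped.  A multiallelic record raises :class:`NormalizationError`; a
    record without the dialect's INFO key raises :class:`DialectError`.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    skipped: list[tuple[str, int, str]] = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise NormalizationError(
                f"multiallelic record at {v.CHROM}:{v.POS}: decompose "
                "multiallelic sites upstream (e.g. with vt) before prioritization"
            )
        raw = v.INFO.get(dialect.info_key)
        if raw is None:
            raise DialectError(
                f"record {v.CHROM}:{v.POS} lacks the INFO/{dialect.info_key} "
                "annotation field expected by the dialect"
            )
        try:
            annotations = parse_consequence_field(raw, dialect)
        except (ConsequenceParseError, ValueError) as exc:
            skipped.append((v.CHROM, v.POS, str(exc)))
            continue
        site_depth = int(v.INFO.get("DP") or 0)
        fmt_dp = v.format("DP") if samples else None
        genotypes: list[GenotypeCall] = []
        for si, g in enumerate(v.genotypes):
            alleles = g[:-1]
            ploidy = len(alleles)
            missing = any(a < 0 for a in alleles)
            dosage = 0 if missing else sum(1 for a in alleles if a == 1)
            depth = site_depth  # fall back to site depth when FORMAT/DP absent
            if fmt_dp is not None:
                d = int(fmt_dp[si][0])
                if d >= 0:
                    depth = d
            genotypes.append(
                GenotypeCall(samples[si], dosage, ploidy, depth, missing)
            )
        variants.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=v.ALT[0],
                variant_id=v.ID or ".",
                qual=float(v.QUAL) if v.QUAL is not None else 0.0,
                site_depth=site_depth,
                annotations=annotations,
                genotypes=genotypes,
            )
        )
    if skipped:
        detail = "; ".join(f"{c}:{p} ({m})" for c, p, m in skipped[:10])
        logger.warning(
            "%d record(s) failed annotation parsing and were excluded: %s%s",
            len(skipped),
            detail,
            " ..." if len(skipped) > 10 else "",
        )
    return CohortTable(samples=samples, variants=variants)


def _fmt_opt(x: float | None) -> str:
    # repr() gives the shortest string that round-trips a double exactly
    return "" if x is None else repr(float(x))


def _gt_string(g: GenotypeCall) -> str:
    if g.ploidy == 1:
        return "." if g.missing else str(g.dosage)
    if g.missing:
        return "./."
    return {0: "0/0", 1: "0/1", 2: "1/1"}[g.dosage]


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Natural chromosome ordering: 1..22 numerically, then X, Y, MT, others."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if name.upper() in special:
        return (0, special[name.upper()], "")
    return (1, 0, name)


def write_annotated_vcf(
    table: CohortTable,
    path: str | Path,
    dialect: AnnotationDialect = DEFAULT_DIALECT,
) -> None:
    """Serialize a cohort as a plain VCF v4.2 in the given annotation dialect.

    Writing then re-reading reproduces the table exactly (float subfields are
    emitted with round-trip precision).
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth at the locus">',
        f'##INFO=<ID={dialect.info_key},Number=.,Type=String,Description="'
        f'Functional annotation. Format: {dialect.csq_format()}">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Per-sample read depth">',
    ]
    for chrom in sorted({v.chrom for v in table.variants}, key=chrom_sort_key):
        lines.append(f"##contig=<ID={chrom}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if table.samples:
        header += ["FORMAT"] + list(table.samples)
    lines.append("\t".join(header))
    for rec in table.variants:
        blocks = []
        for a in rec.annotations:
            parts = []
            for sub in dialect.subfields:
                if sub == dialect.gene_field:
                    parts.append(a.gene_symbol)
                elif sub == dialect.transcript_field:
                    parts.append(a.transcript_id)
                elif sub == dialect.impact_field:
                    parts.append(a.impact)
                elif sub == dialect.consequence_field:
                    parts.append("&".join(sorted(a.consequence_terms)))
                elif sub == dialect.cadd_field:
                    parts.append(_fmt_opt(a.cadd_scaled))
                elif sub == dialect.pli_field:
                    parts.append(_fmt_opt(a.pli))
                elif sub in dialect.af_fields:
                    parts.append(_fmt_opt(a.ref_afs.get(dialect.af_fields[sub])))
                else:
                    parts.append("")
            blocks.append("|".join(parts))
        info = f"DP={rec.site_depth};{dialect.info_key}={','.join(blocks)}"
        row = [
            rec.chrom,
            str(rec.pos),
            rec.variant_id or ".",
            rec.ref,
            rec.alt,
            repr(float(rec.qual)),
            "PASS",
            info,
        ]
        if table.samples:
            row.append("GT:DP")
            row += [f"{_gt_string(g)}:{g.depth}" for g in rec.genotypes]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class QCReport:
    """Upstream call-quality validation result (depth/quality thresholds)."""

    min_depth: int
    min_qual: float
    n_records: int
    depth_violations: list[tuple[str, int]] = field(default_factory=list)
    qual_violations: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_violations(self) -> int:
        return len(self.depth_violations) + len(self.qual_violations)

    @property
    def ok(self) -> bool:
        return self.n_violations == 0


def validate_upstream_qc(
    table: CohortTable,
    min_depth: int = 10,
    min_qual: float = 20.0,
    strict: bool = False,
) -> QCReport:
    """Check the upstream call-refinement thresholds on every record.

    Records are expected to have total site depth strictly greater than
    ``min_depth`` and quality strictly greater than ``min_qual`` (both
    inequalities strict, matching the upstream refinement convention).
    Validation never mutates the table; in non-strict mode violations are
    logged as warnings and the pipeline proceeds, in strict mode a
    :class:`ValidationError` naming the counts is raised.
    """
    report = QCReport(min_depth=min_depth, min_qual=min_qual, n_records=len(table))
    for rec in table.variants:
        if not rec.site_depth > min_depth:
            report.depth_violations.append((rec.chrom, rec.pos))
        if not rec.qual > min_qual:
            report.qual_violations.append((rec.chrom, rec.pos))
    if not report.ok:
        msg = (
            f"upstream QC: {len(report.depth_violations)} record(s) with site "
            f"depth <= {min_depth}, {len(report.qual_violations)} with quality "
            f"<= {min_qual} (of {report.n_records})"
        )
        if strict:
            raise ValidationError(msg)
        logger.warning(msg)
    return report


def _prioritized_columns(refsets: Sequence[str]) -> list[str]:
    return (
        ["chrom", "pos", "id", "ref", "alt", "sample", "gene", "transcript",
         "impact", "consequence", "cadd", "pli"]
        + [f"af_{name}" for name in refsets]
        + ["dosage", "ploidy", "depth", "private", "criterion"]
    )


def hits_to_frame(hits: Iterable) -> pd.DataFrame:
    """Expand hits into the prioritized-variant table, one row per transcript.

    Rows are deterministically ordered by (chrom, pos, alt, sample,
    transcript); the ``criterion`` column records which Filter I clause fired
    (``list``, ``score`` or ``both``).
    """
    hits = list(hits)
    refsets = sorted(
        {name for h in hits for a in h.variant.annotations for name in a.ref_afs}
    ) or ["1000G", "gnomAD"]
    columns = _prioritized_columns(refsets)
    rows = []
    for h in hits:
        gt = h.variant.genotype(h.sample_id)
        ann_by_tx = {a.transcript_id: a for a in h.variant.annotations}
        var_afs = {}
        for a in h.variant.annotations:
            for name, af in a.ref_afs.items():
                var_afs.setdefault(name, af)
        for tx in h.qualifying_transcripts:
            a = ann_by_tx[tx]
            row = {
                "chrom": h.variant.chrom,
                "pos": h.variant.pos,
                "id": h.variant.variant_id,
                "ref": h.variant.ref,
                "alt": h.variant.alt,
                "sample": h.sample_id,
                "gene": h.gene_symbol,
                "transcript": tx,
                "impact": a.impact,
                "consequence": "&".join(sorted(a.consequence_terms)),
                "cadd": a.cadd_scaled,
                "pli": a.pli,
                "dosage": gt.dosage,
                "ploidy": gt.ploidy,
                "depth": h.depth,
                "private": bool(h.private),
                "criterion": h.criterion,
            }
            for name in refsets:
                row[f"af_{name}"] = var_afs.get(name)
            rows.append(row)
    frame = pd.DataFrame(rows, columns=columns)
    if len(frame):
        order = frame.assign(_ck=frame["chrom"].map(chrom_sort_key)).sort_values(
            ["_ck", "pos", "alt", "sample", "transcript"], kind="mergesort"
        )
        frame = order.drop(columns="_ck").reset_index(drop=True)
    return frame


def write_prioritized_table(hits: Iterable, path: str | Path) -> None:
    """Write the prioritized-variant TSV (header-only when there are no hits)."""
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def read_prioritized_table(path: str | Path) -> pd.DataFrame:
    """Read a prioritized-variant TSV back into a DataFrame."""
    return pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "id": str, "ref": str, "alt": str}
    )
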