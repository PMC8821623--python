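"""QF-PCR STR peak-ratio screening for chromosomal aneuploidies.

Quantitative fluorescent PCR amplifies short-tandem-repeat (STR) markers and
reports the fluorescence peak area of each allele; relative areas reflect
allele dosage.  In a normal heterozygote the two peaks have a ratio close to
1:1 (0.8 to 1.4:1).  A trisomy produces either a *diallelic* pattern — two
peaks at roughly 2:1 dosage, ratio below 0.6 or above 1.8 — or a
*triallelic* pattern of three peaks of equal area (1:1:1).  Evidence from at
least two different STRs on the same chromosome is required to call a
trisomy, and trisomic patterns at every chromosome-specific STR panel
indicate triploidy.  Maternal contamination is flagged by comparing embryo
alleles with maternal-blood alleles at shared loci.

Ratios are taken first-listed over second-listed peak (peaks stay in allele
length order), matching the asymmetric bounds above.  Ratios falling in the
gaps (0.6, 0.8) or (1.4, 1.8] are classified ``inconclusive``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

PATTERNS = (
    "normal_heterozygous",
    "homozygous_uninformative",
    "trisomic_diallelic",
    "trisomic_triallelic",
    "inconclusive",
)
TRISOMIC_PATTERNS = frozenset({"trisomic_diallelic", "trisomic_triallelic"})
CHROMOSOME_CALLS = ("euploid", "trisomy", "no_call")

#: Pseudo-chromosome used for the X-dosage assay (an X-specific product
#: ratioed against a chromosome-3 product of near-identical sequence).  Its
#: ratio is reported for monosomy-X interpretation but never auto-called.
X_DOSAGE = "X_dosage"


@dataclass(frozen=True)
class STRProfile:
    """Peak areas of one STR marker in one sample.

    ``alleles`` optionally records the allele identities (repeat lengths) in
    the same order as ``peak_areas``; they are required only by the maternal
    contamination check.
    """

    sample_id: str
    locus: str
    chromosome: str
    peak_areas: tuple[float, ...]
    alleles: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.peak_areas:
            raise ValueError(f"{self.locus}: no peak areas")
        if any(a <= 0 for a in self.peak_areas):
            raise ValueError(f"{self.locus}: peak areas must be positive")
        if self.alleles is not None and len(self.alleles) != len(self.peak_areas):
            raise ValueError(f"{self.locus}: alleles and peak areas differ in length")


@dataclass(frozen=True)
class STRPattern:
    """Dosage pattern classification of one STR marker."""

    locus: str
    pattern: str

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")


@dataclass
class AneuploidyCall:
    """Sample-level karyotype screening result."""

    sample_id: str
    chromosome_calls: dict[str, str] = field(default_factory=dict)
    triploidy: bool = False
    maternal_contamination: bool = False
    x_dosage_ratio: float | None = None


def classify_str(
    profile: STRProfile,
    normal_low: float = 0.8,
    normal_high: float = 1.4,
    trisomic_low: float = 0.6,
    trisomic_high: float = 1.8,
    triallelic_tol: float = 0.25,
) -> STRPattern:
    """Classify one STR profile into a dosage pattern.

    One peak is uninformative (homozygous).  Two peaks are classified by the
    ratio of the first-listed to the second-listed area: within
    [``normal_low``, ``normal_high``] is a normal heterozygote; below
    ``trisomic_low`` or above ``trisomic_high`` is a trisomic diallelic
    pattern; the gaps in between are inconclusive.  Three peaks with all
    pairwise ratios within 1 +/- ``triallelic_tol`` form a trisomic
    triallelic pattern (1:1:1), otherwise inconclusive.  More than three
    peaks suggest contamination and raise an error.
    """
    if not trisomic_low < normal_low < normal_high < trisomic_high:
        raise ValueError(
            "thresholds must satisfy trisomic_low < normal_low < "
            "normal_high < trisomic_high"
        )
    areas = profile.peak_areas
    if len(areas) > 3:
        raise ValueError(
            f"{profile.locus}: {len(areas)} peaks; more than 3 alleles "
            "suggests contamination — check maternal profiles"
        )
    if len(areas) == 1:
        return STRPattern(profile.locus, "homozygous_uninformative")
    if len(areas) == 2:
        r = areas[0] / areas[1]
        if normal_low <= r <= normal_high:
            return STRPattern(profile.locus, "normal_heterozygous")
        if r < trisomic_low or r > trisomic_high:
            return STRPattern(profile.locus, "trisomic_diallelic")
        return STRPattern(profile.locus, "inconclusive")
    lo, hi = 1.0 - triallelic_tol, 1.0 + triallelic_tol
    equal = all(
        lo <= areas[i] / areas[j] <= hi
        for i in range(3)
        for j in range(3)
        if i != j
    )
    return STRPattern(
        profile.locus, "trisomic_triallelic" if equal else "inconclusive"
    )


def call_chromosome(patterns: Sequence[STRPattern]) -> str:
    """Combine the patterns of one chromosome's STR panel into a call.

    At least two trisomic patterns (diallelic or triallelic) on distinct
    markers are evidence of trisomy; otherwise at least two normal
    heterozygous patterns support euploidy; anything less is a no-call.
    """
    n_trisomic = sum(p.pattern in TRISOMIC_PATTERNS for p in patterns)
    n_normal = sum(p.pattern == "normal_heterozygous" for p in patterns)
    if n_trisomic >= 2:
        return "trisomy"
    if n_normal >= 2:
        return "euploid"
    return "no_call"


def call_sample(
    profiles: Iterable[STRProfile],
    normal_low: float = 0.8,
    normal_high: float = 1.4,
    trisomic_low: float = 0.6,
    trisomic_high: float = 1.8,
    triallelic_tol: float = 0.25,
) -> AneuploidyCall:
    """Screen one sample: per-chromosome calls plus a triploidy flag.

    Triploidy is flagged when every evaluable chromosome (at least two of
    them) is trisomic.  The X-dosage assay pseudo-chromosome is excluded
    from chromosome calling; its 2-peak ratio is reported in
    ``x_dosage_ratio`` for manual monosomy-X interpretation.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no STR profiles supplied")
    sample_ids = {p.sample_id for p in profiles}
    if len(sample_ids) != 1:
        raise ValueError(f"profiles from multiple samples: {sorted(sample_ids)}")
    by_chrom: dict[str, list[STRProfile]] = {}
    for p in profiles:
        by_chrom.setdefault(p.chromosome, []).append(p)
    call = AneuploidyCall(sample_id=profiles[0].sample_id)
    for chrom, group in by_chrom.items():
        if chrom == X_DOSAGE:
            two_peak = [p for p in group if len(p.peak_areas) == 2]
            if two_peak:
                areas = two_peak[0].peak_areas
                call.x_dosage_ratio = areas[0] / areas[1]
            continue
        patterns = [
            classify_str(
                p, normal_low, normal_high, trisomic_low, trisomic_high,
                triallelic_tol,
            )
            for p in group
        ]
        call.chromosome_calls[chrom] = call_chromosome(patterns)
    evaluable = [c for c in call.chromosome_calls.values() if c != "no_call"]
    call.triploidy = len(evaluable) >= 2 and all(c == "trisomy" for c in evaluable)
    return call


def check_maternal_contamination(
    embryo: Iterable[STRProfile],
    maternal: Iterable[STRProfile],
    min_loci: int = 2,
) -> bool:
    """Flag maternal-cell contamination of an embryo sample.

    A locus is suspicious when the embryo shows more than two alleles and
    the supernumerary alleles can all be attributed to the mother (at most
    two alleles are not in the maternal allele set).  Contamination is
    flagged when at least ``min_loci`` shared loci are suspicious.  Allele
    identities are required on both profiles; absence of shared loci is an
    error.
    """
    maternal_alleles: dict[str, set[int]] = {}
    for p in maternal:
        if p.alleles is None:
            raise ValueError(f"maternal profile {p.locus}: allele identities required")
        maternal_alleles.setdefault(p.locus, set()).update(p.alleles)
    shared = 0
    suspicious = 0
    for p in embryo:
        if p.locus not in maternal_alleles:
            continue
        if p.alleles is None:
            raise ValueError(f"embryo profile {p.locus}: allele identities required")
        shared += 1
        alleles = set(p.alleles)
        if len(alleles) > 2:
            extra = alleles - maternal_alleles[p.locus]
            if len(extra) <= 2:
                suspicious += 1
    if shared == 0:
        raise ValueError("no loci shared between embryo and maternal profiles")
    return suspicious >= min_loci


def read_str_table(path: str | Path) -> list[STRProfile]:
    """Read STR profiles from a TSV with columns
    ``sample locus chromosome peak_areas [alleles]`` (comma-separated lists).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "locus", "chromosome", "peak_areas"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    profiles = []
    for row in frame.itertuples(index=False):
        areas = tuple(float(x) for x in str(row.peak_areas).split(","))
        alleles = None
        if "alleles" in frame.columns and isinstance(row.alleles, str):
            alleles = tuple(int(float(x)) for x in row.alleles.split(","))
        profiles.append(
            STRProfile(
                sample_id=row.sample,
                locus=row.locus,
                chromosome=row.chromosome,
                peak_areas=areas,
                alleles=alleles,
            )
        )
    return profiles


def write_str_table(profiles: Iterable[STRProfile], path: str | Path) -> None:
    """Write STR profiles in the TSV dialect read by :func:`read_str_table`."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "sample": p.sample_id,
                "locus": p.locus,
                "chromosome": p.chromosome,
                "peak_areas": ",".join(repr(a) for a in p.peak_areas),
                "alleles": ""
                if p.alleles is None
                else ",".join(str(a) for a in p.alleles),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def calls_to_frame(calls: Iterable[AneuploidyCall]) -> pd.DataFrame:
    """Per-chromosome call table, one row per (sample, chromosome)."""
    rows = []
    for c in calls:
        for chrom, verdict in c.chromosome_calls.items():
            rows.append({"sample": c.sample_id, "chromosome": chrom, "call": verdict})
    return pd.DataFrame(rows, columns=["sample", "chromosome", "call"])


def write_screen_summary(calls: Iterable[AneuploidyCall], path: str | Path) -> None:
    """Write the sample-level screening summary as JSON."""
    out = {}
    for c in calls:
        out[c.sample_id] = {
            "chromosome_calls": c.chromosome_calls,
            "triploidy": c.triploidy,
            "maternal_contamination": c.maternal_contamination,
            "x_dosage_ratio": c.x_dosage_ratio,
        }
    Path(path).write_text(json.dumps(out, indent=2) + "\n")
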