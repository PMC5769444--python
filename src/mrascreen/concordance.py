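"""Concordance of screened calls against a high-confidence truth set.

Benchmarking follows the Genome-in-a-Bottle convention: inside the
high-confidence regions the truth set asserts complete genotypes, so the
absence of a truth variant at a compared site means the truth genotype is
homozygous reference.  Calls outside the confident regions are excluded from
comparison, never counted as discordant.  Each discordant site receives
exactly one class, in fixed priority order:

``allele_mismatch``
    a truth record exists at the position with different REF/ALT alleles;
``position_mismatch``
    a truth indel within a window (default +/- 10 bp) explains the
    disagreement as a representation shift;
``genotype_mismatch``
    otherwise.

A low-complexity-context flag (homopolymer run >= 5 or dinucleotide repeat
>= 4 units within +/- 10 bp of the site) is computed orthogonally from the
reference sequence, since repetitive context co-occurs with, but does not
itself define, a mismatch class.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .genotyper import GenotypeCall
from .intervals import point_in_regions
from .vcfnorm import (
    BiallelicVariant,
    CoordinateError,
    MalformedRecordError,
    NotAVariantError,
    Reference,
    ReferenceMismatchError,
    fetch_sequence,
    get_contig_length,
    normalize,
)

__all__ = [
    "TruthRecord",
    "SiteComparison",
    "ConcordanceReport",
    "read_truth_vcf",
    "restrict_to_confident",
    "compare",
    "flag_low_complexity",
    "percent",
]

ALLELE_MISMATCH = "allele_mismatch"
POSITION_MISMATCH = "position_mismatch"
GENOTYPE_MISMATCH = "genotype_mismatch"


def percent(fraction: float) -> float:
    """Render a fraction as a percentage rounded half-up to 2 decimals."""
    return float(Decimal(fraction * 100).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TruthRecord:
    """One truth-set genotype: alleles plus an unordered diploid GT."""

    contig: str
    pos: int
    ref: str
    alt: str
    gt: tuple[int, int]

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


def read_truth_vcf(path) -> list[TruthRecord]:
    """Load truth genotypes from a single-sample VCF (first ALT per record)."""
    records: list[TruthRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        sample = samples[0] if samples else None
        for rec in vcf:
            alt = str((rec.alts or (rec.ref,))[0]).upper()
            if sample is not None:
                gt_raw = rec.samples[sample].get("GT")
                if gt_raw is None or None in gt_raw:
                    continue
                gt = tuple(sorted(int(a) for a in gt_raw))
            else:
                gt = (1, 1)  # site-only truth VCF: presence implies ALT
            records.append(TruthRecord(rec.contig, rec.pos, str(rec.ref).upper(), alt, gt))
    return records


def restrict_to_confident(
    calls: list[GenotypeCall],
    confident_regions: dict[str, IntervalTree],
) -> tuple[list[GenotypeCall], int]:
    """Keep calls whose position lies inside a confident interval.

    Returns (kept calls, number excluded).
    """
    kept = [c for c in calls if point_in_regions(confident_regions, c.site.contig, c.site.pos - 1)]
    return kept, len(calls) - len(kept)


def _has_homopolymer(context: str, min_run: int = 5) -> bool:
    run = 1
    for i in range(1, len(context)):
        if context[i] == context[i - 1]:
            run += 1
            if run >= min_run:
                return True
        else:
            run = 1
    return False


def _has_dinucleotide_repeat(context: str, min_units: int = 4) -> bool:
    span = 2 * min_units
    for i in range(len(context) - span + 1):
        unit = context[i:i + 2]
        if unit[0] == unit[1]:
            continue
        if all(context[i + 2 * j:i + 2 * j + 2] == unit for j in range(min_units)):
            return True
    return False


def flag_low_complexity(contig: str, pos: int, reference: Reference, window: int = 10) -> bool:
    """True iff the +/-window context holds a homopolymer run >= 5 or a
    dinucleotide repeat >= 4 units; the window is truncated at contig ends."""
    start0 = max(pos - 1 - window, 0)
    end0 = min(pos + window, get_contig_length(reference, contig))
    context = fetch_sequence(reference, contig, start0, end0)
    return _has_homopolymer(context) or _has_dinucleotide_repeat(context)


@dataclass(frozen=True)
class SiteComparison:
    """Outcome of comparing one call against the truth set."""

    call: GenotypeCall
    truth_gt: tuple[int, int] | None
    concordant: bool
    discordance_class: str | None
    low_complexity: bool


@dataclass
class ConcordanceReport:
    """Counts and per-site outcomes of a concordance comparison."""

    n_genotyped: int
    n_compared: int
    n_concordant: int
    n_discordant: int
    comparisons: list[SiteComparison]

    @property
    def rate(self) -> float:
        return self.n_concordant / self.n_compared if self.n_compared else 0.0

    @property
    def rate_pct(self) -> float:
        return percent(self.rate)

    @property
    def discordant_pct(self) -> float:
        return percent(self.n_discordant / self.n_compared) if self.n_compared else 0.0

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "n_genotyped": self.n_genotyped,
                "n_compared": self.n_compared,
                "n_concordant": self.n_concordant,
                "n_discordant": self.n_discordant,
                "concordance_rate_pct": self.rate_pct,
                "discordant_pct": self.discordant_pct,
            }]
        )

    def site_frame(self) -> pd.DataFrame:
        rows = []
        for cmp_ in self.comparisons:
            site = cmp_.call.site
            rows.append({
                "contig": site.contig,
                "pos": site.pos,
                "ref": site.ref,
                "alt": site.alt,
                "call_gt": cmp_.call.gt_string,
                "truth_gt": ("/".join(map(str, cmp_.truth_gt)) if cmp_.truth_gt else "."),
                "concordant": cmp_.concordant,
                "discordance_class": cmp_.discordance_class or "",
                "low_complexity": cmp_.low_complexity,
            })
        return pd.DataFrame(
            rows,
            columns=["contig", "pos", "ref", "alt", "call_gt", "truth_gt",
                     "concordant", "discordance_class", "low_complexity"],
        )


def _normalized_truth(truth: list[TruthRecord], reference: Reference | None) -> list[TruthRecord]:
    if reference is None:
        return truth
    out = []
    for rec in truth:
        if rec.ref == rec.alt:
            out.append(rec)
            continue
        try:
            norm = normalize(BiallelicVariant(rec.contig, rec.pos, rec.ref, rec.alt, 0.0, 0.0), reference)
        except (ReferenceMismatchError, CoordinateError, NotAVariantError, MalformedRecordError):
            out.append(rec)
            continue
        out.append(TruthRecord(norm.contig, norm.pos, norm.ref, norm.alt, rec.gt))
    return out


def compare(
    calls: list[GenotypeCall],
    truth: list[TruthRecord],
    reference: Reference | None = None,
    position_window: int = 10,
    low_complexity_window: int = 10,
    n_genotyped: int | None = None,
) -> ConcordanceReport:
    """Compare calls (already restricted to confident regions) to the truth.

    A call is concordant iff its diploid genotype equals the truth genotype
    at its locus; a missing truth record means implied truth 0/0 (the
    high-confidence-region convention).  Truth records are harmonized by
    normalization first when a reference is supplied, so equivalent indel
    representations match before any discordance is declared.  No-call
    records are excluded from the comparison.
    """
    truth = _normalized_truth(truth, reference)
    by_key: dict[tuple[str, int, str, str], TruthRecord] = {}
    by_pos: dict[tuple[str, int], list[TruthRecord]] = {}
    indels_by_contig: dict[str, list[TruthRecord]] = {}
    for rec in truth:
        by_key[(rec.contig, rec.pos, rec.ref, rec.alt)] = rec
        by_pos.setdefault((rec.contig, rec.pos), []).append(rec)
        if rec.is_indel:
            indels_by_contig.setdefault(rec.contig, []).append(rec)

    comparisons: list[SiteComparison] = []
    n_concordant = 0
    compared = [c for c in calls if c.gt is not None]
    for call in compared:
        site = call.site
        exact = by_key.get((site.contig, site.pos, site.ref, site.alt))
        at_pos = by_pos.get((site.contig, site.pos), [])
        if exact is not None:
            truth_gt = exact.gt
        elif not at_pos:
            truth_gt = (0, 0)  # implied hom-ref inside confident regions
        else:
            truth_gt = None  # truth present with different alleles
        concordant = truth_gt is not None and call.gt == truth_gt
        discordance_class = None
        if not concordant:
            nearby_indel = any(
                abs(rec.pos - site.pos) <= position_window
                and (rec.contig, rec.pos, rec.ref, rec.alt) != (site.contig, site.pos, site.ref, site.alt)
                for rec in indels_by_contig.get(site.contig, ())
            )
            if truth_gt is None:
                discordance_class = ALLELE_MISMATCH
            elif nearby_indel:
                discordance_class = POSITION_MISMATCH
            else:
                discordance_class = GENOTYPE_MISMATCH
        low_complexity = (
            flag_low_complexity(site.contig, site.pos, reference, low_complexity_window)
            if reference is not None
            else False
        )
        if concordant:
            n_concordant += 1
        comparisons.append(SiteComparison(call, truth_gt, concordant, discordance_class, low_complexity))

    n_compared = len(compared)
    return ConcordanceReport(
        n_genotyped=n_genotyped if n_genotyped is not None else len(calls),
        n_compared=n_compared,
        n_concordant=n_concordant,
        n_discordant=n_compared - n_concordant,
        comparisons=comparisons,
    )
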