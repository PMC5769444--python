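"""Homozygous-reference screening of genotype calls at MRA panel sites.

A screen positive is a confident homozygous-reference call at a panel site:
the individual carries two copies of the minor (possibly disease-associated)
reference allele, which standard variant calling would silently skip.  Calls
are filtered on depth (DP > 20) and reference genotype quality (RGQ > 30,
i.e. a wrong-genotype probability below 0.001), both strict and
configurable.  Because reference alleles are reported as "no change" in
HGVS-style nomenclature, passing records carry a reference-equals notation
note alongside the allele-level genotype string.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
import pysam

from .genotyper import GenotypeCall, phred_to_error_prob
from .intervals import NamedRegion

__all__ = [
    "ScreenStatus",
    "ScreenRecord",
    "classify_call",
    "filter_homref",
    "report",
    "companion_variant_table",
    "prioritize_by_genes",
    "write_screen_vcf",
    "wrong_call_probability",
]


def wrong_call_probability(rgq: float) -> float:
    """Probability that a hom-ref call with the given RGQ is wrong: 10^(-RGQ/10)."""
    return phred_to_error_prob(rgq)


class ScreenStatus(str, enum.Enum):
    PASS = "pass"
    FAIL_DP = "fail_dp"
    FAIL_RGQ = "fail_rgq"
    FAIL_GENOTYPE = "fail_genotype"
    NO_CALL = "no_call"


@dataclass(frozen=True)
class ScreenRecord:
    """One screened call with its filter status and reporting annotations."""

    site: object  # PanelSite
    call: GenotypeCall
    status: ScreenStatus
    carried_minor_allele: str
    notation_note: str


def classify_call(call: GenotypeCall, dp_threshold: int = 20, rgq_threshold: int = 30) -> ScreenStatus:
    """Assign exactly one screen status to a call (strict thresholds)."""
    if call.gt is None:
        return ScreenStatus.NO_CALL
    if call.gt != (0, 0):
        return ScreenStatus.FAIL_GENOTYPE
    if call.dp <= dp_threshold:
        return ScreenStatus.FAIL_DP
    if call.rgq is None or call.rgq <= rgq_threshold:
        return ScreenStatus.FAIL_RGQ
    return ScreenStatus.PASS


def _notation(call: GenotypeCall) -> str:
    site = call.site
    if call.gt == (0, 0):
        # Reference-equals notation: the reference allele is "no change".
        return f"{site.contig}:g.{site.pos}{site.ref}=; {call.allele_string}"
    return call.allele_string


def filter_homref(
    calls: Iterable[GenotypeCall],
    dp_threshold: int = 20,
    rgq_threshold: int = 30,
) -> list[ScreenRecord]:
    """Turn every call into a :class:`ScreenRecord` with its status.

    The statuses partition the input: ``pass`` iff the genotype is 0/0 with
    DP strictly above ``dp_threshold`` and RGQ strictly above
    ``rgq_threshold``.  Input order is preserved.
    """
    return [
        ScreenRecord(
            site=call.site,
            call=call,
            status=classify_call(call, dp_threshold, rgq_threshold),
            carried_minor_allele=call.site.ref,
            notation_note=_notation(call),
        )
        for call in calls
    ]


def _record_row(record: ScreenRecord) -> dict:
    site, call = record.site, record.call
    return {
        "contig": site.contig,
        "pos": site.pos,
        "id": site.id,
        "carried_minor_allele": record.carried_minor_allele,
        "ref_af": round(site.ref_af, 4),
        "rarity": site.rarity,
        "genotype": call.allele_string,
        "dp": call.dp,
        "rgq": call.rgq,
        "clinical_significance": "|".join(sig for sig, _ in site.clinical),
        "phenotype": "|".join(ph for _, ph in site.clinical if ph),
        "notation": record.notation_note,
        "status": record.status.value,
    }


_REPORT_COLUMNS = [
    "contig", "pos", "id", "carried_minor_allele", "ref_af", "rarity",
    "genotype", "dp", "rgq", "clinical_significance", "phenotype",
    "notation", "status",
]


def report(records: list[ScreenRecord], clinical_only: bool = False) -> pd.DataFrame:
    """Tabulate passing records (one row each, in input order).

    ``clinical_only`` restricts the table to records with a non-empty
    clinical annotation.  An empty result still carries the full header.
    """
    rows = [
        _record_row(r)
        for r in records
        if r.status is ScreenStatus.PASS and (not clinical_only or r.site.clinical)
    ]
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)


def companion_variant_table(records: list[ScreenRecord]) -> pd.DataFrame:
    """Het / hom-alt findings at panel sites (status ``fail_genotype``).

    These are standard-calling findings — the individual carries the major,
    typically non-pathogenic allele — reported separately because they are
    not screen positives but inform interpretation.
    """
    rows = [_record_row(r) for r in records if r.status is ScreenStatus.FAIL_GENOTYPE]
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)


def prioritize_by_genes(
    records: list[ScreenRecord],
    gene_regions: list[NamedRegion],
) -> list[tuple[str, ScreenRecord]]:
    """Pair records with the named gene interval(s) they fall in.

    A record overlapping several gene intervals is emitted once per gene;
    records outside every interval are dropped.  Intervals are 0-based
    half-open, compared against the REF span of the site.
    """
    out: list[tuple[str, ScreenRecord]] = []
    for record in records:
        start0 = record.site.pos - 1
        end0 = start0 + len(record.site.ref)
        for region in gene_regions:
            if region.contig == record.site.contig and region.start < end0 and start0 < region.end:
                out.append((region.name, record))
    return out


def write_screen_vcf(
    records: list[ScreenRecord],
    path,
    sample: str = "SAMPLE",
    dp_threshold: int = 20,
    rgq_threshold: int = 30,
) -> None:
    """Write all screened records with FILTER codes; passes get FILTER=PASS.

    Failing records are retained with codes ``DP_LE_<t>`` / ``RGQ_LE_<t>`` /
    ``NOT_HOMREF`` / ``NO_CALL`` so the full screen is auditable.
    """
    from .genotyper import _calls_header

    filter_codes = {
        ScreenStatus.FAIL_DP: f"DP_LE_{dp_threshold}",
        ScreenStatus.FAIL_RGQ: f"RGQ_LE_{rgq_threshold}",
        ScreenStatus.FAIL_GENOTYPE: "NOT_HOMREF",
        ScreenStatus.NO_CALL: "NO_CALL",
    }
    header = _calls_header([r.call for r in records], sample)
    header.filters.add(filter_codes[ScreenStatus.FAIL_DP], None, None, f"Depth <= {dp_threshold}")
    header.filters.add(filter_codes[ScreenStatus.FAIL_RGQ], None, None, f"RGQ <= {rgq_threshold}")
    header.filters.add("NOT_HOMREF", None, None, "Heterozygous or homozygous-alternate call")
    header.filters.add("NO_CALL", None, None, "No read evidence")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for record in records:
            call, site = record.call, record.site
            rec = out.new_record(
                contig=site.contig,
                start=site.pos - 1,
                stop=site.pos - 1 + len(site.ref),
                alleles=(site.ref, site.alt),
                id=site.id or None,
            )
            rec.qual = call.site_quality
            rec.info["REF_AF"] = float(site.ref_af)
            if record.status is ScreenStatus.PASS:
                rec.filter.add("PASS")
            else:
                rec.filter.add(filter_codes[record.status])
            data = rec.samples[sample]
            data["GT"] = call.gt if call.gt is not None else (None, None)
            data["DP"] = call.dp
            data["AD"] = call.ad
            if call.pl is not None:
                data["PL"] = call.pl
                data["GQ"] = call.gq
            if call.rgq is not None:
                data["RGQ"] = call.rgq
            out.write(rec)
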