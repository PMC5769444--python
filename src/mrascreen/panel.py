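"""Minor-reference-allele panel construction from population frequency data.

A minor reference allele (MRA) site is a locus at which an alternate allele
is commoner in the population than the genome reference allele.  Carriers of
the (possibly pathogenic) reference allele look like "no variant" to standard
callers, so such sites are collected into a screening panel: frequency
records are decomposed and normalized, sites whose major ALT exceeds the
allele-frequency cutoff (default 0.5) are selected, classified by rarity of
the reference allele, optionally joined with clinical significance records,
subset to enrichment regions, and written as VCF and BED panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Union

import pysam
from intervaltree import IntervalTree

from .intervals import NamedRegion, point_in_regions
from .vcfnorm import (
    BiallelicVariant,
    info_get,
    CoordinateError,
    IngestStats,
    MalformedRecordError,
    NotAVariantError,
    PopulationSiteRecord,
    Reference,
    ReferenceMismatchError,
    decompose,
    iter_population_records,
    normalize,
)

__all__ = [
    "PanelSite",
    "PanelStats",
    "build_panel",
    "classify_rarity",
    "annotate_clinical",
    "subset_by_regions",
    "write_panel_vcf",
    "write_panel_bed",
    "read_panel_vcf",
    "harmonize_contig",
]

_log = logging.getLogger(__name__)

RARE = "rare"
COMMON = "common"


@dataclass(frozen=True)
class PanelSite:
    """One decomposed, normalized MRA site.

    ``ref`` is the minor (reference) allele, ``alt`` the major alternate
    allele that exceeded the selection cutoff.  ``ref_af`` is the frequency of
    the reference allele at the original locus (``origin_ref_freq`` of the
    source record); ``clinical`` holds (significance, phenotype) pairs from a
    ClinVar-style join, possibly empty.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    ref_af: float
    alt_af: float
    rarity: str
    clinical: tuple[tuple[str, str], ...] = ()
    id: str = ""

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def locus(self) -> str:
        return f"{self.contig}:{self.pos}"


@dataclass
class PanelStats:
    """Run summary for panel construction."""

    records_in: int = 0
    sites_selected: int = 0
    decompose_failures: int = 0
    normalization_failures: int = 0


def classify_rarity(site_or_af: Union[PanelSite, float], rare_cutoff: float = 0.01) -> str:
    """Classify a reference-allele frequency as ``rare`` (< cutoff) or ``common``."""
    ref_af = getattr(site_or_af, "ref_af", site_or_af)
    return RARE if ref_af < rare_cutoff else COMMON


def build_panel(
    records: Iterable[PopulationSiteRecord],
    reference: Reference,
    af_cutoff: float = 0.5,
    rare_cutoff: float = 0.01,
    mode: str = "alt",
    stats: PanelStats | None = None,
) -> list[PanelSite]:
    """Select MRA sites from a stream of population frequency records.

    In the default ``"alt"`` mode a decomposed, normalized biallelic variant
    is selected when its own ALT frequency strictly exceeds ``af_cutoff``; at
    most one ALT per locus can qualify when the cutoff is >= 0.5.  The
    alternative ``"ref"`` mode selects loci whose pre-split reference-allele
    frequency is strictly below ``af_cutoff`` and emits the most frequent ALT;
    the two modes differ only at multi-allelic loci where no single ALT is
    major.  Unparseable or reference-inconsistent variants are skipped and
    counted in ``stats``.  The result is sorted by (contig, pos, ref, alt).
    """
    if mode not in ("alt", "ref"):
        raise ValueError(f"unknown selection mode {mode!r}")
    stats = stats if stats is not None else PanelStats()
    sites: list[PanelSite] = []
    for record in records:
        stats.records_in += 1
        try:
            pieces = decompose(record)
        except MalformedRecordError as exc:
            stats.decompose_failures += 1
            _log.warning("skipping record: %s", exc)
            continue
        if mode == "alt":
            selected = [v for v in pieces if v.alt_freq > af_cutoff]
        else:
            origin_ref = pieces[0].origin_ref_freq if pieces else 1.0
            selected = [max(pieces, key=lambda v: v.alt_freq)] if (pieces and origin_ref < af_cutoff) else []
        for variant in selected:
            try:
                norm = normalize(variant, reference)
            except (ReferenceMismatchError, CoordinateError, NotAVariantError, MalformedRecordError) as exc:
                stats.normalization_failures += 1
                _log.warning("skipping variant: %s", exc)
                continue
            sites.append(
                PanelSite(
                    contig=norm.contig,
                    pos=norm.pos,
                    ref=norm.ref,
                    alt=norm.alt,
                    ref_af=norm.origin_ref_freq,
                    alt_af=norm.alt_freq,
                    rarity=classify_rarity(norm.origin_ref_freq, rare_cutoff),
                    id=norm.id,
                )
            )
            stats.sites_selected += 1
    sites.sort(key=lambda s: s.key)
    return sites


def harmonize_contig(name: str, style: str | None) -> str:
    """Add or strip a ``chr`` prefix (``style`` in {"chr", "nochr", None})."""
    if style == "chr":
        return name if name.startswith("chr") else "chr" + name
    if style == "nochr":
        return name[3:] if name.startswith("chr") else name
    return name


def _clinical_index(
    clinical,
    reference: Reference | None,
    sig_key: str,
    pheno_keys: tuple[str, ...],
    contig_style: str | None,
    stats: IngestStats | None,
) -> dict[tuple[str, int, str, str], list[tuple[str, str]]]:
    """Index (significance, phenotype) pairs by normalized variant key."""

    def _join(value) -> str:
        if value is None:
            return ""
        if isinstance(value, (tuple, list)):
            return "|".join(str(v) for v in value)
        return str(value)

    index: dict[tuple[str, int, str, str], list[tuple[str, str]]] = {}
    with pysam.VariantFile(str(clinical)) as vcf:
        for rec in vcf:
            sig = _join(info_get(rec, sig_key)).replace("_", " ")
            if not sig:
                if stats is not None:
                    stats.missing_frequency_skipped += 1
                _log.warning("%s:%d: no %s field; clinical record skipped", rec.contig, rec.pos, sig_key)
                continue
            pheno = ""
            for key in pheno_keys:
                pheno = _join(info_get(rec, key)).replace("_", " ")
                if pheno:
                    break
            contig = harmonize_contig(rec.contig, contig_style)
            for alt in rec.alts or ():
                alt = str(alt).upper()
                variant = BiallelicVariant(contig, rec.pos, str(rec.ref).upper(), alt, 0.0, 0.0, rec.id or "")
                if reference is not None:
                    try:
                        variant = normalize(variant, reference)
                    except (ReferenceMismatchError, CoordinateError, NotAVariantError, MalformedRecordError):
                        continue
                key = (variant.contig, variant.pos, variant.ref, variant.alt)
                index.setdefault(key, []).append((sig, pheno))
    return index


def annotate_clinical(
    sites: list[PanelSite],
    clinical,
    reference: Reference | None = None,
    sig_key: str = "CLNSIG",
    pheno_keys: tuple[str, ...] = ("CLNDN", "CLNDBN", "PHENO"),
    contig_style: str | None = None,
    stats: IngestStats | None = None,
) -> list[PanelSite]:
    """Join ClinVar-style significance records onto panel sites.

    The join is on exact (contig, pos, ref, alt) after both sides are
    normalized (panel sites are normalized by construction; the clinical side
    is normalized here when a reference is supplied).  Matched sites gain all
    matching (significance, phenotype) pairs; unmatched sites are returned
    unchanged.  Records without a significance field are skipped and counted.
    """
    index = _clinical_index(clinical, reference, sig_key, pheno_keys, contig_style, stats)
    annotated = []
    for site in sites:
        matches = index.get(site.key)
        annotated.append(replace(site, clinical=tuple(matches)) if matches else site)
    return annotated


def subset_by_regions(sites: list[PanelSite], regions: dict[str, IntervalTree]) -> list[PanelSite]:
    """Keep sites whose (0-based) position falls inside some region interval.

    ``regions`` maps contig names to interval trees of 0-based half-open
    intervals (see :func:`mrascreen.intervals.read_bed`).  Region contigs
    absent from the panel are ignored with a warning.  Order is preserved.
    """
    panel_contigs = {s.contig for s in sites}
    for contig in regions:
        if contig not in panel_contigs:
            _log.warning("region contig %r not present in panel; ignored", contig)
    return [s for s in sites if point_in_regions(regions, s.contig, s.pos - 1)]


def _sorted_with_warning(sites: list[PanelSite]) -> list[PanelSite]:
    ordered = sorted(sites, key=lambda s: s.key)
    if ordered != list(sites):
        _log.warning("panel sites were not sorted; sorting before write")
    return ordered


def write_panel_vcf(sites: list[PanelSite], path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write panel sites as a biallelic VCF with REF_AF/ALT_AF/RARITY INFO.

    Clinical pairs are stored in CLNSIG/PHENO INFO keys joined by ``|``;
    spaces in phenotype text are encoded as underscores (the ClinVar
    convention) and decoded again by :func:`read_panel_vcf`.
    """
    sites = _sorted_with_warning(sites)
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    seen: dict[str, int] = {}
    for site in sites:
        needed = site.pos + len(site.ref) + 1000
        seen[site.contig] = max(seen.get(site.contig, 0), needed)
    for contig in sorted(seen):
        length = (contig_lengths or {}).get(contig, seen[contig])
        header.contigs.add(contig, length=length)
    header.info.add("REF_AF", 1, "Float", "Population frequency of the (minor) reference allele")
    header.info.add("ALT_AF", 1, "Float", "Population frequency of the major alternate allele")
    header.info.add("RARITY", 1, "String", "Reference-allele rarity class (rare/common)")
    header.info.add("CLNSIG", ".", "String", "Clinical significance labels (| joined)")
    header.info.add("PHENO", ".", "String", "Clinical phenotypes (| joined, _ for spaces)")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in sites:
            rec = out.new_record(
                contig=site.contig,
                start=site.pos - 1,
                stop=site.pos - 1 + len(site.ref),
                alleles=(site.ref, site.alt),
                id=site.id or None,
            )
            rec.info["REF_AF"] = float(site.ref_af)
            rec.info["ALT_AF"] = float(site.alt_af)
            rec.info["RARITY"] = site.rarity
            if site.clinical:
                rec.info["CLNSIG"] = tuple(sig.replace(" ", "_") for sig, _ in site.clinical)
                rec.info["PHENO"] = tuple((ph or ".").replace(" ", "_") for _, ph in site.clinical)
            out.write(rec)


def write_panel_bed(sites: list[PanelSite], path) -> None:
    """Write panel sites as BED6 (chromStart = pos-1, chromEnd = pos-1+len(ref))."""
    sites = _sorted_with_warning(sites)
    with open(path, "w") as out:
        for site in sites:
            start = site.pos - 1
            out.write(
                f"{site.contig}\t{start}\t{start + len(site.ref)}\t{site.id or '.'}\t0\t.\n"
            )


def read_panel_vcf(path) -> list[PanelSite]:
    """Load a panel VCF written by :func:`write_panel_vcf` (or equivalent)."""
    sites: list[PanelSite] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alt = str((rec.alts or ("N",))[0]).upper()
            ref_af = float(rec.info.get("REF_AF", 0.0))
            alt_af = float(rec.info.get("ALT_AF", 1.0 - ref_af))
            sigs = rec.info.get("CLNSIG")
            phenos = rec.info.get("PHENO")
            clinical: tuple[tuple[str, str], ...] = ()
            if sigs:
                if not isinstance(sigs, (tuple, list)):
                    sigs = (sigs,)
                if phenos is None:
                    phenos = ("",) * len(sigs)
                elif not isinstance(phenos, (tuple, list)):
                    phenos = (phenos,)
                clinical = tuple(
                    (
                        str(sig).replace("_", " "),
                        "" if str(ph) == "." else str(ph).replace("_", " "),
                    )
                    for sig, ph in zip(sigs, phenos)
                )
            rarity = str(rec.info.get("RARITY", "")) or classify_rarity(ref_af)
            sites.append(
                PanelSite(
                    contig=rec.contig,
                    pos=rec.pos,
                    ref=str(rec.ref).upper(),
                    alt=alt,
                    ref_af=ref_af,
                    alt_af=alt_af,
                    rarity=rarity,
                    clinical=clinical,
                    id=rec.id or "",
                )
            )
    return sites
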