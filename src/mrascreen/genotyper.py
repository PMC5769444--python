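"""Genotype-given-alleles calling of panel sites from alignments.

Standard callers treat homozygous-reference loci as "no variation" and emit
nothing there, so carriers of a pathogenic reference allele are invisible.
This module genotypes every panel site directly: read evidence is collected
into a pileup column per site and diploid genotype likelihoods over the two
panel alleles are computed under the standard independent-read model.  For a
genotype (a1, a2) the per-read likelihood is

    L(read | a1, a2) = 1/2 P(obs | a1) + 1/2 P(obs | a2)

with P(obs | allele) = 1 - eps on a match and eps/3 on a mismatch, where
eps = 10^(-q/10) comes from the observation quality.  Likelihoods are
reported as phred-scaled, normalized PLs; the genotype quality GQ is the gap
between the two smallest PLs, and for homozygous-reference calls it is
reported as the reference genotype quality RGQ — the quality metric of the
screen, since the VCF site quality (QUAL) is 0 at reference sites.
"""

from __future__ import annotations

import logging
import math
import os
import tempfile
from dataclasses import dataclass
from typing import Iterable, Union

import pysam

from .panel import PanelSite

__all__ = [
    "Observation",
    "PileupColumn",
    "GenotypeCall",
    "GENOTYPES",
    "pileup",
    "genotype_given_alleles",
    "call_sites",
    "open_alignments",
    "phred_to_error_prob",
    "write_calls_vcf",
    "read_calls_vcf",
]

_log = logging.getLogger(__name__)

#: Diploid genotypes over {REF=0, ALT=1}, ordered as in VCF PL convention.
GENOTYPES: tuple[tuple[int, int], ...] = ((0, 0), (0, 1), (1, 1))

PL_CAP = 2550
GQ_CAP = 99
MIN_PHRED = 2  # floor on observation quality when converting to error prob


def phred_to_error_prob(q: float) -> float:
    """Error probability for a phred-scaled quality: 10^(-q/10)."""
    return 10.0 ** (-q / 10.0)


@dataclass(frozen=True)
class Observation:
    """One read's evidence at a site: supported allele and qualities.

    ``allele_index`` is 0 for the panel REF allele, 1 for the panel ALT and
    -1 for any other spelled sequence (contributes a mismatch to both
    alleles).
    """

    allele_index: int
    quality: int
    mapping_quality: int


@dataclass(frozen=True)
class PileupColumn:
    """Filtered read evidence at one panel site."""

    contig: str
    pos: int
    observations: tuple[Observation, ...]

    @property
    def depth(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class GenotypeCall:
    """Diploid call at a panel site.

    ``gt`` is an unordered genotype tuple over {0, 1} or None for a no-call;
    ``pl`` is the normalized phred-scaled likelihood triple for (0/0, 0/1,
    1/1); ``rgq`` (reference genotype quality) is present exactly for
    homozygous-reference calls and equals ``gq``; ``site_quality`` is 0 for
    homozygous-reference calls, following the VCF QUAL convention that makes
    RGQ, not QUAL, the usable quality at reference sites.
    """

    site: PanelSite
    gt: tuple[int, int] | None
    dp: int
    ad: tuple[int, int]
    pl: tuple[int, int, int] | None
    gq: int | None
    rgq: int | None
    site_quality: float

    @property
    def is_homref(self) -> bool:
        return self.gt == (0, 0)

    @property
    def gt_string(self) -> str:
        if self.gt is None:
            return "./."
        return f"{self.gt[0]}/{self.gt[1]}"

    @property
    def allele_string(self) -> str:
        """Genotype rendered with allele letters (e.g. ``T/T``)."""
        if self.gt is None:
            return "./."
        alleles = (self.site.ref, self.site.alt)
        return f"{alleles[self.gt[0]]}/{alleles[self.gt[1]]}"


def _spell_read(read: pysam.AlignedSegment, start0: int, end0: int):
    """Spell a read's sequence over a reference span, CIGAR-aware.

    Returns (bases, base_qualities) for read positions aligned within
    [start0, end0), including insertions anchored on a base inside the span.
    Deleted reference positions contribute no bases.
    """
    seq = read.query_sequence
    quals = read.query_qualities
    bases: list[str] = []
    out_quals: list[int] = []
    ref_cursor = read.reference_start
    query_cursor = 0
    for op, length in read.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X
            lo = max(ref_cursor, start0)
            hi = min(ref_cursor + length, end0)
            if lo < hi:
                off = query_cursor + (lo - ref_cursor)
                bases.extend(seq[off:off + (hi - lo)])
                out_quals.extend(quals[off:off + (hi - lo)])
            ref_cursor += length
            query_cursor += length
        elif op == 1:  # I: anchored between ref_cursor-1 and ref_cursor
            if start0 <= ref_cursor - 1 < end0:
                bases.extend(seq[query_cursor:query_cursor + length])
                out_quals.extend(quals[query_cursor:query_cursor + length])
            query_cursor += length
        elif op in (2, 3):  # D, N consume reference only
            ref_cursor += length
        elif op == 4:  # S
            query_cursor += length
        # H (5) and P (6) consume neither
    return "".join(bases).upper(), out_quals


def pileup(
    alignments: pysam.AlignmentFile,
    site: PanelSite,
    min_base_q: int = 10,
    min_mapq: int = 20,
    exclude_duplicates: bool = True,
    indel_quality_cap: int = 45,
) -> PileupColumn:
    """Collect filtered read evidence over the full REF span of a site.

    Reads must be mapped, primary, non-duplicate (unless
    ``exclude_duplicates`` is off), have MAPQ >= ``min_mapq`` and span the
    whole REF interval; the spelled-out read sequence over the span is
    compared against REF and ALT to assign the allele index.  For SNVs the
    observation quality is the base quality at the site; for indels it is the
    minimum base quality over the span, capped at ``indel_quality_cap``.
    Observations below ``min_base_q`` are dropped.
    """
    start0 = site.pos - 1
    end0 = start0 + len(site.ref)
    if site.contig not in (alignments.references or ()):
        _log.warning("contig %r absent from alignments; empty pileup at %s", site.contig, site.locus)
        return PileupColumn(site.contig, site.pos, ())
    is_snv = len(site.ref) == 1 and len(site.alt) == 1
    observations: list[Observation] = []
    for read in alignments.fetch(site.contig, start0, end0):
        if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_qcfail:
            continue
        if exclude_duplicates and read.is_duplicate:
            continue
        if read.mapping_quality < min_mapq:
            continue
        if read.reference_start > start0 or (read.reference_end or 0) < end0:
            continue  # must span the whole REF interval
        if read.query_sequence is None or read.query_qualities is None:
            continue
        spelled, quals = _spell_read(read, start0, end0)
        if spelled == site.ref:
            allele_index = 0
        elif spelled == site.alt:
            allele_index = 1
        else:
            allele_index = -1
        if is_snv and len(quals) == 1:
            quality = int(quals[0])
        else:
            quality = min((int(q) for q in quals), default=min_base_q)
            quality = min(quality, indel_quality_cap)
        if quality < min_base_q:
            continue
        observations.append(Observation(allele_index, quality, read.mapping_quality))
    return PileupColumn(site.contig, site.pos, tuple(observations))


def genotype_given_alleles(column: PileupColumn, site: PanelSite) -> GenotypeCall:
    """Compute the diploid genotype call for one pileup column.

    PLs are rounded to the nearest integer (half away from zero) and capped
    at 2550; observation qualities are floored at phred 2 when converted to
    error probabilities.  When two genotypes tie at PL 0 the one with more
    REF alleles is called, with GQ 0 — conservative for a screen whose
    positives are homozygous-reference, since ties are then removed by the
    RGQ filter.  An empty column yields a no-call.
    """
    dp = column.depth
    ad = (
        sum(1 for o in column.observations if o.allele_index == 0),
        sum(1 for o in column.observations if o.allele_index == 1),
    )
    if dp == 0:
        return GenotypeCall(site=site, gt=None, dp=0, ad=(0, 0), pl=None, gq=None, rgq=None, site_quality=0.0)
    log10_likelihood = []
    for a1, a2 in GENOTYPES:
        total = 0.0
        for obs in column.observations:
            eps = phred_to_error_prob(max(obs.quality, MIN_PHRED))
            p1 = (1.0 - eps) if obs.allele_index == a1 else eps / 3.0
            p2 = (1.0 - eps) if obs.allele_index == a2 else eps / 3.0
            total += math.log10(0.5 * p1 + 0.5 * p2)
        log10_likelihood.append(total)
    best = max(log10_likelihood)
    pl = tuple(
        min(PL_CAP, int(math.floor(-10.0 * (l - best) + 0.5))) for l in log10_likelihood
    )
    gt = GENOTYPES[pl.index(0)]  # first zero = most REF alleles on ties
    ordered = sorted(pl)
    gq = min(GQ_CAP, ordered[1] - ordered[0])
    rgq = gq if gt == (0, 0) else None
    site_quality = 0.0 if gt == (0, 0) else float(pl[0])
    return GenotypeCall(site=site, gt=gt, dp=dp, ad=ad, pl=pl, gq=gq, rgq=rgq, site_quality=site_quality)


def open_alignments(path, scratch_dir=None) -> pysam.AlignmentFile:
    """Open alignments with random access, converting/indexing as needed.

    SAM input is sorted into a temporary BAM and indexed; BAM input lacking
    an index is indexed in place.
    """
    path = str(path)
    if path.endswith(".sam"):
        tmpdir = tempfile.mkdtemp(prefix="mrascreen_", dir=scratch_dir)
        bam = os.path.join(tmpdir, "alignments.bam")
        pysam.sort("-O", "bam", "-o", bam, path)
        pysam.index(bam)
        return pysam.AlignmentFile(bam)
    if not (os.path.exists(path + ".bai") or os.path.exists(path + ".csi")):
        pysam.index(path)
    return pysam.AlignmentFile(path)


def call_sites(
    alignments: Union[pysam.AlignmentFile, str, os.PathLike],
    sites: Iterable[PanelSite],
    min_base_q: int = 10,
    min_mapq: int = 20,
    exclude_duplicates: bool = True,
    indel_quality_cap: int = 45,
) -> tuple[list[GenotypeCall], dict[str, int]]:
    """Genotype every panel site, including hom-ref and no-call records.

    Returns exactly one call per site, in input order, plus a run summary of
    counts by genotype class.
    """
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = open_alignments(alignments)
    calls: list[GenotypeCall] = []
    summary = {"0/0": 0, "0/1": 0, "1/1": 0, "no_call": 0}
    for site in sites:
        column = pileup(
            alignments,
            site,
            min_base_q=min_base_q,
            min_mapq=min_mapq,
            exclude_duplicates=exclude_duplicates,
            indel_quality_cap=indel_quality_cap,
        )
        call = genotype_given_alleles(column, site)
        summary[call.gt_string if call.gt is not None else "no_call"] += 1
        calls.append(call)
    return calls, summary


def _calls_header(calls: list[GenotypeCall], sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.add_line(
        "##source=mrascreen genotype-given-alleles "
        "(symmetric-error diploid model, eps=10^(-q/10), mismatch mass eps/3)"
    )
    seen: dict[str, int] = {}
    for call in calls:
        needed = call.site.pos + len(call.site.ref) + 1000
        seen[call.site.contig] = max(seen.get(call.site.contig, 0), needed)
    for contig in sorted(seen):
        header.contigs.add(contig, length=seen[contig])
    header.info.add("REF_AF", 1, "Float", "Population frequency of the (minor) reference allele")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allele-supporting read counts")
    header.formats.add("DP", 1, "Integer", "Filtered read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("PL", "G", "Integer", "Phred-scaled normalized genotype likelihoods")
    header.formats.add("RGQ", 1, "Integer", "Reference genotype quality (hom-ref calls only)")
    header.add_sample(sample)
    return header


def write_calls_vcf(calls: list[GenotypeCall], path, sample: str = "SAMPLE") -> None:
    """Write calls as a single-sample VCF (GT:AD:DP:GQ:PL, RGQ for 0/0).

    QUAL is written as 0 for homozygous-reference records, matching the
    convention that reference-site QUAL carries no usable confidence.
    """
    header = _calls_header(calls, sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in calls:
            site = call.site
            rec = out.new_record(
                contig=site.contig,
                start=site.pos - 1,
                stop=site.pos - 1 + len(site.ref),
                alleles=(site.ref, site.alt),
                id=site.id or None,
            )
            rec.qual = call.site_quality
            rec.info["REF_AF"] = float(site.ref_af)
            sample_rec = rec.samples[sample]
            sample_rec["GT"] = call.gt if call.gt is not None else (None, None)
            sample_rec["DP"] = call.dp
            sample_rec["AD"] = call.ad
            if call.pl is not None:
                sample_rec["PL"] = call.pl
                sample_rec["GQ"] = call.gq
            if call.rgq is not None:
                sample_rec["RGQ"] = call.rgq
            out.write(rec)


def read_calls_vcf(path) -> list[GenotypeCall]:
    """Load calls written by :func:`write_calls_vcf`."""
    from .panel import classify_rarity

    calls: list[GenotypeCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0]
        for rec in vcf:
            ref_af = float(rec.info.get("REF_AF", 0.0))
            site = PanelSite(
                contig=rec.contig,
                pos=rec.pos,
                ref=str(rec.ref).upper(),
                alt=str((rec.alts or ("N",))[0]).upper(),
                ref_af=ref_af,
                alt_af=1.0 - ref_af,
                rarity=classify_rarity(ref_af),
                id=rec.id or "",
            )
            data = rec.samples[sample]
            gt_raw = data.get("GT")
            gt = None
            if gt_raw is not None and None not in gt_raw:
                gt = tuple(sorted(int(a) for a in gt_raw))
            pl_raw = data.get("PL")
            pl = tuple(int(p) for p in pl_raw) if pl_raw is not None else None
            ad_raw = data.get("AD")
            ad = tuple(int(a) for a in ad_raw) if ad_raw is not None else (0, 0)
            gq = data.get("GQ")
            rgq = data.get("RGQ")
            calls.append(
                GenotypeCall(
                    site=site,
                    gt=gt,
                    dp=int(data.get("DP") or 0),
                    ad=ad,
                    pl=pl,
                    gq=int(gq) if gq is not None else None,
                    rgq=int(rgq) if rgq is not None else None,
                    site_quality=float(rec.qual or 0.0),
                )
            )
    return calls
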