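"""Decomposition and normalization of population frequency-VCF records.

Population resources such as ExAC/gnomAD publish one VCF record per locus with
possibly several ALT alleles and per-ALT ``AF``/``AC`` INFO fields
(``Number=A``).  Minor-reference-allele selection needs per-allele frequencies
at canonical variant representations, so multi-allelic records are first split
into biallelic ones ("decomposition", subsetting the per-ALT fields) and each
biallelic variant is then left-aligned and trimmed against the reference
sequence ("normalization").

The normalization algorithm is the standard one: repeatedly strip a shared
trailing base (extending both alleles leftwards with the previous reference
base whenever one allele would become empty), then strip shared leading bases
while both alleles are at least two bases long.  SNVs are already minimal and
pass through unchanged; the result is unique for a given input haplotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterator, Mapping, Union

import pysam

__all__ = [
    "PopulationSiteRecord",
    "BiallelicVariant",
    "IngestStats",
    "MalformedRecordError",
    "ReferenceMismatchError",
    "CoordinateError",
    "NotAVariantError",
    "decompose",
    "normalize",
    "iter_population_records",
    "fetch_sequence",
    "get_contig_length",
]

_log = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGT")

#: A reference can be a pysam.FastaFile or a plain {contig: sequence} mapping.
Reference = Union[pysam.FastaFile, Mapping[str, str]]


class MalformedRecordError(ValueError):
    """A frequency-VCF record violates its own field contracts."""


class ReferenceMismatchError(ValueError):
    """A variant's REF allele disagrees with the reference sequence."""


class CoordinateError(ValueError):
    """A variant position lies outside its contig."""


class NotAVariantError(ValueError):
    """REF and ALT alleles encode the same sequence (degenerate record)."""


def _is_simple_allele(allele: str) -> bool:
    return bool(allele) and set(allele) <= _NUCLEOTIDES


def fetch_sequence(reference: Reference, contig: str, start0: int, end0: int) -> str:
    """Return the uppercased reference slice over 0-based half-open [start0, end0)."""
    if hasattr(reference, "fetch"):
        seq = reference.fetch(contig, max(start0, 0), end0)
    else:
        seq = reference[contig][max(start0, 0):end0]
    return seq.upper()


def get_contig_length(reference: Reference, contig: str) -> int:
    if hasattr(reference, "get_reference_length"):
        return reference.get_reference_length(contig)
    return len(reference[contig])


@dataclass(frozen=True)
class PopulationSiteRecord:
    """One locus from a population frequency VCF (possibly multi-allelic).

    ``pos`` is 1-based as in VCF; ``alt_freqs`` are the per-ALT population
    allele frequencies (``Number=A`` semantics).  Invariants are checked on
    construction and violations raise :class:`MalformedRecordError` naming
    the locus.
    """

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    alt_freqs: tuple[float, ...]
    alt_counts: tuple[int, ...] | None = None
    total_alleles: int | None = None
    id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alts", tuple(a.upper() for a in self.alts))
        object.__setattr__(self, "alt_freqs", tuple(float(f) for f in self.alt_freqs))
        if len(self.alts) != len(self.alt_freqs):
            raise MalformedRecordError(
                f"{self.locus}: {len(self.alts)} ALT allele(s) but "
                f"{len(self.alt_freqs)} frequency value(s)"
            )
        if self.alt_counts is not None and len(self.alt_counts) != len(self.alts):
            raise MalformedRecordError(f"{self.locus}: per-ALT AC length mismatch")
        if not _is_simple_allele(self.ref):
            raise MalformedRecordError(f"{self.locus}: REF {self.ref!r} is not a simple allele")
        for alt in self.alts:
            if not _is_simple_allele(alt):
                raise MalformedRecordError(f"{self.locus}: ALT {alt!r} is not a simple allele")
        for freq in self.alt_freqs:
            if not 0.0 <= freq <= 1.0:
                raise MalformedRecordError(f"{self.locus}: allele frequency {freq} outside [0, 1]")
        if sum(self.alt_freqs) > 1.0 + 1e-9:
            raise MalformedRecordError(
                f"{self.locus}: ALT frequencies sum to {sum(self.alt_freqs):.6g} > 1"
            )

    @property
    def locus(self) -> str:
        return f"{self.contig}:{self.pos}"


@dataclass(frozen=True)
class BiallelicVariant:
    """A decomposed biallelic variant carrying its own ALT frequency.

    ``origin_ref_freq`` is the frequency of the REF allele at the original
    (pre-split) locus, i.e. 1 minus the sum of *all* sibling ALT frequencies,
    clamped to [0, 1]; it is identical across siblings split from one record.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    alt_freq: float
    origin_ref_freq: float
    id: str = ""

    @property
    def locus(self) -> str:
        return f"{self.contig}:{self.pos}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def decompose(record: PopulationSiteRecord) -> list[BiallelicVariant]:
    """Split a (possibly multi-allelic) record into biallelic variants.

    One :class:`BiallelicVariant` is returned per ALT, in ALT order, each
    carrying its own frequency; all carry the same ``origin_ref_freq``
    computed before splitting.  Biallelic inputs pass through unchanged.
    """
    origin_ref = 1.0 - sum(record.alt_freqs)
    if origin_ref < 0.0:
        # Frequency rounding in source files can push the sum past 1.
        if origin_ref < -1e-9:
            _log.warning(
                "%s: ALT frequencies sum past 1 by %.3g; clamping REF frequency to 0",
                record.locus, -origin_ref,
            )
        origin_ref = 0.0
    origin_ref = min(origin_ref, 1.0)
    return [
        BiallelicVariant(
            contig=record.contig,
            pos=record.pos,
            ref=record.ref,
            alt=alt,
            alt_freq=freq,
            origin_ref_freq=origin_ref,
            id=record.id,
        )
        for alt, freq in zip(record.alts, record.alt_freqs)
    ]


def normalize(variant: BiallelicVariant, reference: Reference) -> BiallelicVariant:
    """Return the canonical (trimmed, left-aligned) representation of a variant.

    The returned variant applies to the reference exactly as the input does;
    SNVs are returned unchanged.  Raises :class:`ReferenceMismatchError` when
    the stated REF disagrees with the reference sequence (including IUPAC
    ambiguity codes in the reference), :class:`CoordinateError` for positions
    outside the contig, and :class:`NotAVariantError` when REF == ALT.
    """
    if variant.ref == variant.alt:
        raise NotAVariantError(f"{variant.locus}: REF == ALT ({variant.ref}); not a variant")
    if not _is_simple_allele(variant.ref) or not _is_simple_allele(variant.alt):
        raise MalformedRecordError(f"{variant.locus}: alleles must be A/C/G/T strings")
    contig_len = get_contig_length(reference, variant.contig)
    if variant.pos < 1 or variant.pos + len(variant.ref) - 1 > contig_len:
        raise CoordinateError(
            f"{variant.locus}: REF span [{variant.pos}, {variant.pos + len(variant.ref) - 1}] "
            f"outside contig of length {contig_len}"
        )
    observed = fetch_sequence(
        reference, variant.contig, variant.pos - 1, variant.pos - 1 + len(variant.ref)
    )
    if observed != variant.ref:
        raise ReferenceMismatchError(
            f"{variant.locus}: REF {variant.ref} does not match reference sequence {observed!r}"
        )

    pos, ref, alt = variant.pos, variant.ref, variant.alt
    # Right-trim shared trailing bases, left-extending when an allele would empty.
    while ref[-1] == alt[-1] and not (len(ref) == 1 and len(alt) == 1):
        if len(ref) == 1 or len(alt) == 1:
            if pos == 1:
                break  # cannot left-extend past the contig start
            pad = fetch_sequence(reference, variant.contig, pos - 2, pos - 1)
            if not _is_simple_allele(pad):
                raise ReferenceMismatchError(
                    f"{variant.contig}:{pos - 1}: ambiguous reference base {pad!r} "
                    "during left-alignment"
                )
            pos -= 1
            ref, alt = pad + ref, pad + alt
        ref, alt = ref[:-1], alt[:-1]
    # Left-trim shared leading bases, keeping at least one base per allele.
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return replace(variant, pos=pos, ref=ref, alt=alt)


def apply_variant(sequence: str, variant: BiallelicVariant) -> str:
    """Apply a variant to a contig sequence, returning the alternate haplotype.

    Used for equivalence checking: two representations of the same variant
    yield identical haplotype sequences.
    """
    start = variant.pos - 1
    if sequence[start:start + len(variant.ref)].upper() != variant.ref:
        raise ReferenceMismatchError(f"{variant.locus}: REF does not match sequence")
    return sequence[:start] + variant.alt + sequence[start + len(variant.ref):]


@dataclass
class IngestStats:
    """Counters accumulated while reading a frequency VCF."""

    records_read: int = 0
    symbolic_alts_skipped: int = 0
    missing_frequency_skipped: int = 0
    malformed_skipped: int = 0


def info_get(rec, key: str, default=None):
    """INFO lookup tolerant of keys missing from the VCF header."""
    try:
        return rec.info.get(key, default)
    except (KeyError, ValueError):
        return default


def _per_alt_values(value, n_alts: int):
    """Coerce a pysam INFO value with Number=A semantics to a tuple."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        vals = tuple(value)
    else:
        vals = (value,)
    if len(vals) != n_alts:
        return None
    return vals


def iter_population_records(
    path,
    af_key: str = "AF",
    ac_key: str = "AC",
    an_key: str = "AN",
    stats: IngestStats | None = None,
) -> Iterator[PopulationSiteRecord]:
    """Stream :class:`PopulationSiteRecord` objects from a frequency VCF.

    Frequency precedence follows the ExAC field layout: the per-ALT ``AF``
    INFO is used when present, otherwise frequencies are computed as AC/AN;
    records with AN == 0 or no usable frequency are skipped with a warning.
    Symbolic ALTs (``<DEL>``, breakends) and ``*`` alleles are dropped and
    counted; a record whose ALTs are all symbolic is skipped entirely.
    """
    stats = stats if stats is not None else IngestStats()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            stats.records_read += 1
            alts = rec.alts or ()
            keep = [i for i, a in enumerate(alts) if _is_simple_allele(str(a).upper())]
            n_dropped = len(alts) - len(keep)
            if n_dropped:
                stats.symbolic_alts_skipped += n_dropped
            if not keep:
                continue

            freqs = _per_alt_values(info_get(rec, af_key), len(alts))
            counts = _per_alt_values(info_get(rec, ac_key), len(alts))
            an = info_get(rec, an_key)
            if isinstance(an, (tuple, list)):
                an = an[0] if an else None
            if freqs is None:
                if counts is not None and an:
                    freqs = tuple(c / an for c in counts)
                else:
                    stats.missing_frequency_skipped += 1
                    _log.warning("%s:%d: no usable allele frequency; skipped", rec.contig, rec.pos)
                    continue
            try:
                yield PopulationSiteRecord(
                    contig=rec.contig,
                    pos=rec.pos,
                    ref=str(rec.ref).upper(),
                    alts=tuple(str(alts[i]).upper() for i in keep),
                    alt_freqs=tuple(float(freqs[i]) for i in keep),
                    alt_counts=(tuple(int(counts[i]) for i in keep) if counts is not None else None),
                    total_alleles=(int(an) if an is not None else None),
                    id=rec.id or "",
                )
            except MalformedRecordError as exc:
                stats.malformed_skipped += 1
                _log.warning("skipping malformed record: %s", exc)
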