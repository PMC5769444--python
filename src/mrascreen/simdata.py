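"""Seeded synthetic data: references, frequency VCFs, reads and truth sets.

The generator emulates the statistical structure the screening pipeline
assumes: a reference contig with embedded low-complexity tracts, a
population frequency VCF with a planted fraction of minor-reference-allele
(MRA) sites (some rare, some multi-allelic, optionally indels), and
single-end reads drawn from planted diploid genotypes with phred-consistent
base errors.  Every output is deterministic for a fixed seed and config:
each output stream derives its RNG from (seed, output name), so adding an
output never perturbs the others.

Coverage at a site is Poisson(depth_mean) by default; ``depth_mode="fixed"``
plants exactly ``depth_mean`` spanning reads per site, for experiments whose
design calls for a guaranteed depth rather than a depth distribution.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pysam

from .fixtures import Fixtures, bundled_fixtures  # noqa: F401  (re-exported)
from .genotyper import GENOTYPES, Observation, PileupColumn, phred_to_error_prob
from .panel import PanelSite, classify_rarity

__all__ = [
    "SimulationConfig",
    "SimulationError",
    "RepeatTract",
    "make_reference",
    "make_population_vcf",
    "assign_genotypes",
    "simulate_reads",
    "simulate_genotype_columns",
    "bundled_fixtures",
]

_BASES = "ACGT"


class SimulationError(ValueError):
    """Infeasible simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the synthetic-data generator.

    ``fraction_mra`` of the ``n_sites`` frequency records get a major ALT
    (reference allele frequency below 0.5); ``rare_fraction`` of those get a
    reference frequency below 0.01.  ``fraction_multiallelic`` records carry
    two ALTs.  ``planted_genotypes`` optionally fixes per-site diploid
    genotypes for read simulation (otherwise supplied per call).
    """

    seed: int = 0
    contig: str = "sim1"
    contig_length: int = 100_000
    n_sites: int = 100
    fraction_mra: float = 0.3
    fraction_multiallelic: float = 0.0
    rare_fraction: float = 0.1
    indel_fraction: float = 0.0
    depth_mean: float = 30.0
    depth_mode: str = "poisson"  # "poisson" | "fixed"
    base_quality: int = 30
    read_length: int = 100
    error_rate_override: float | None = None
    duplicate_fraction: float = 0.0
    low_mapq_fraction: float = 0.0
    n_repeat_tracts: int = 4
    min_site_spacing: int | None = None
    planted_genotypes: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        for name in ("fraction_mra", "fraction_multiallelic", "rare_fraction",
                     "indel_fraction", "duplicate_fraction", "low_mapq_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise SimulationError(f"{name}={value} outside [0, 1]")
        if self.depth_mean <= 0:
            raise SimulationError("depth_mean must be positive")
        if self.contig_length < 1000:
            raise SimulationError("contig_length must be >= 1000")
        if self.depth_mode not in ("poisson", "fixed"):
            raise SimulationError(f"unknown depth_mode {self.depth_mode!r}")
        if self.error_rate_override is not None and not 0.0 <= self.error_rate_override <= 1.0:
            raise SimulationError("error_rate_override outside [0, 1]")

    @property
    def spacing(self) -> int:
        return self.min_site_spacing if self.min_site_spacing is not None else 2 * self.read_length + 10


def _rng(seed: int, name: str) -> np.random.Generator:
    """One RNG stream per output file, derived from (seed, name)."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode()) & 0x7FFFFFFF])


@dataclass(frozen=True)
class RepeatTract:
    """An embedded low-complexity tract (0-based half-open coordinates)."""

    start: int
    end: int
    kind: str  # "homopolymer" | "dinucleotide"
    unit: str


def make_reference(config: SimulationConfig, fasta_path=None) -> tuple[str, list[RepeatTract]]:
    """Generate a random contig with embedded repeat tracts.

    Returns (sequence, tracts); when ``fasta_path`` is given the sequence is
    also written as an indexed FASTA.
    """
    rng = _rng(config.seed, "reference")
    seq = list(_BASES[i] for i in rng.integers(0, 4, size=config.contig_length))
    tracts: list[RepeatTract] = []
    n = config.n_repeat_tracts
    for k in range(n):
        anchor = (k + 1) * config.contig_length // (n + 2)
        if k % 2 == 0:
            base = _BASES[int(rng.integers(0, 4))]
            tract_seq = base * 8
            kind, unit = "homopolymer", base
        else:
            b1 = _BASES[int(rng.integers(0, 4))]
            b2 = _BASES[(int(rng.integers(1, 4)) + _BASES.index(b1)) % 4]
            tract_seq = (b1 + b2) * 5
            kind, unit = "dinucleotide", b1 + b2
        seq[anchor:anchor + len(tract_seq)] = tract_seq
        tracts.append(RepeatTract(anchor, anchor + len(tract_seq), kind, unit))
    sequence = "".join(seq)
    if fasta_path is not None:
        with open(fasta_path, "w") as out:
            out.write(f">{config.contig}\n")
            for i in range(0, len(sequence), 80):
                out.write(sequence[i:i + 80] + "\n")
        pysam.faidx(str(fasta_path))
    return sequence, tracts


def _site_positions(config: SimulationConfig, rng: np.random.Generator, max_span: int = 8) -> list[int]:
    """Choose 0-based site positions on a jittered grid with guaranteed spacing."""
    margin = 400
    spacing = config.spacing
    lo = margin
    hi = config.contig_length - margin - max_span
    candidates = np.arange(lo, hi, spacing)
    if len(candidates) < config.n_sites:
        raise SimulationError(
            f"contig_length {config.contig_length} cannot hold {config.n_sites} sites "
            f"at spacing {spacing}"
        )
    chosen = np.sort(rng.choice(candidates, size=config.n_sites, replace=False))
    jitter_max = max(1, min(spacing // 4, 50))
    jitter = rng.integers(0, jitter_max, size=config.n_sites)
    return [int(p + j) for p, j in zip(chosen, jitter)]


def _snv_alts(rng: np.random.Generator, ref_base: str, n: int) -> list[str]:
    others = [b for b in _BASES if b != ref_base]
    idx = rng.permutation(3)[:n]
    return [others[i] for i in idx]


def _indel_alleles(rng: np.random.Generator, sequence: str, pos0: int) -> tuple[str, str]:
    """Pick a pure indel at pos0 whose representation is already canonical.

    A pure indel with padding base b is canonical iff its last allele base
    differs from b (no shared trailing base), which is checked against the
    actual sequence so normalization is the identity on planted sites.
    """
    anchor = sequence[pos0]
    if rng.random() < 0.5:  # deletion
        for d in range(int(rng.integers(1, 4)), 7):
            ref = sequence[pos0:pos0 + 1 + d]
            if len(ref) == 1 + d and ref[-1] != anchor:
                return ref, anchor
    # insertion (also the fallback when a deletion can't be canonical here)
    length = int(rng.integers(1, 4))
    ins = [_BASES[i] for i in rng.integers(0, 4, size=length)]
    if ins[-1] == anchor:
        ins[-1] = _BASES[(_BASES.index(anchor) + 1 + int(rng.integers(0, 3))) % 4]
    return anchor, anchor + "".join(ins)


def make_population_vcf(
    config: SimulationConfig,
    sequence: str,
    vcf_path,
) -> list[PanelSite]:
    """Write a frequency VCF with planted MRA sites; return the planted truth.

    Deterministic allocation: exactly round(n_sites * fraction_mra) sites are
    MRA, of which round(* rare_fraction) have a rare (< 0.01) reference
    allele; round(n_sites * fraction_multiallelic) records carry two ALTs.
    Per-ALT AF plus AC/AN INFO fields are emitted; the sum of ALT
    frequencies never exceeds 1.
    """
    rng = _rng(config.seed, "population")
    positions = _site_positions(config, rng)
    n = config.n_sites
    n_mra = int(round(n * config.fraction_mra))
    n_rare = int(round(n_mra * config.rare_fraction))
    n_multi = int(round(n * config.fraction_multiallelic))
    n_indel = int(round(n * config.indel_fraction))

    order = rng.permutation(n)
    is_mra = np.zeros(n, dtype=bool)
    is_mra[order[:n_mra]] = True
    is_rare = np.zeros(n, dtype=bool)
    is_rare[order[:n_rare]] = True  # rare sites are a subset of MRA sites
    multi_pool = rng.permutation(n)
    is_multi = np.zeros(n, dtype=bool)
    is_multi[multi_pool[:n_multi]] = True
    indel_pool = [i for i in rng.permutation(n) if not is_multi[i]]
    is_indel = np.zeros(n, dtype=bool)
    for i in indel_pool[:n_indel]:
        is_indel[i] = True

    an = 100_000
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.contigs.add(config.contig, length=config.contig_length)
    header.info.add("AF", "A", "Float", "Alternate allele frequency")
    header.info.add("AC", "A", "Integer", "Alternate allele count")
    header.info.add("AN", 1, "Integer", "Total allele number")

    planted: list[PanelSite] = []
    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for i, pos0 in enumerate(positions):
            if is_indel[i]:
                ref, alt = _indel_alleles(rng, sequence, pos0)
                alts = [alt]
            else:
                ref = sequence[pos0]
                alts = _snv_alts(rng, ref, 2 if is_multi[i] else 1)

            if is_mra[i]:
                ref_af = float(rng.uniform(0.002, 0.008) if is_rare[i] else rng.uniform(0.02, 0.45))
                if is_multi[i]:
                    minor_alt_af = float(rng.uniform(0.003, 0.006))
                    major_af = 1.0 - ref_af - minor_alt_af
                    freqs = [major_af, minor_alt_af]
                else:
                    freqs = [1.0 - ref_af]
            else:
                if is_multi[i]:
                    freqs = [float(rng.uniform(0.05, 0.30)), float(rng.uniform(0.02, 0.19))]
                else:
                    freqs = [float(rng.uniform(0.02, 0.45))]

            # Shuffle ALT order at multi-allelic sites to exercise subsetting.
            if len(alts) == 2 and rng.random() < 0.5:
                alts, freqs = alts[::-1], freqs[::-1]

            rec = out.new_record(
                contig=config.contig,
                start=pos0,
                stop=pos0 + len(ref),
                alleles=tuple([ref] + alts),
                id=f"sim{i:05d}",
            )
            rec.info["AF"] = tuple(freqs)
            rec.info["AC"] = tuple(int(round(f * an)) for f in freqs)
            rec.info["AN"] = an
            out.write(rec)

            if is_mra[i]:
                major_idx = int(np.argmax(freqs))
                planted.append(
                    PanelSite(
                        contig=config.contig,
                        pos=pos0 + 1,
                        ref=ref,
                        alt=alts[major_idx],
                        ref_af=ref_af,
                        alt_af=freqs[major_idx],
                        rarity=classify_rarity(ref_af),
                        id=f"sim{i:05d}",
                    )
                )
    planted.sort(key=lambda s: s.key)
    return planted


def assign_genotypes(
    config: SimulationConfig,
    n_sites: int,
    counts: tuple[int, int, int],
) -> list[tuple[int, int]]:
    """Deterministically assign (hom-ref, het, hom-alt) genotypes to sites.

    ``counts`` must sum to ``n_sites``; the assignment order is shuffled by
    the seeded RNG so genotype classes are not position-correlated.
    """
    if sum(counts) != n_sites:
        raise SimulationError(f"genotype counts {counts} do not sum to {n_sites}")
    gts = [GENOTYPES[k] for k, c in enumerate(counts) for _ in range(c)]
    rng = _rng(config.seed, "genotypes")
    return [gts[i] for i in rng.permutation(n_sites)]


def _build_read(
    sequence: str,
    start: int,
    read_length: int,
    pos0: int,
    ref: str,
    alt: str,
    hap_allele: int,
) -> tuple[str, list[tuple[int, int]]]:
    """Spell one read from the chosen haplotype, with its CIGAR."""
    if hap_allele == 0 or ref == alt:
        return sequence[start:start + read_length], [(0, read_length)]
    lref, lalt = len(ref), len(alt)
    if lref == 1 and lalt == 1:  # SNV
        seq = sequence[start:pos0] + alt + sequence[pos0 + 1:start + read_length]
        return seq, [(0, read_length)]
    if lref == 1 and lalt > 1:  # insertion
        prefix = sequence[start:pos0 + 1]
        ins = alt[1:]
        rest = read_length - len(prefix) - len(ins)
        seq = prefix + ins + sequence[pos0 + 1:pos0 + 1 + rest]
        cigar = [(0, len(prefix)), (1, len(ins))] + ([(0, rest)] if rest > 0 else [])
        return seq, cigar
    if lalt == 1 and lref > 1:  # deletion
        prefix = sequence[start:pos0 + 1]
        rest = read_length - len(prefix)
        seq = prefix + sequence[pos0 + lref:pos0 + lref + rest]
        cigar = [(0, len(prefix)), (2, lref - 1)] + ([(0, rest)] if rest > 0 else [])
        return seq, cigar
    raise SimulationError(f"cannot simulate complex allele {ref}>{alt}")


def _inject_errors(seq: str, eps: float, rng: np.random.Generator) -> str:
    if eps <= 0.0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < eps)
    if len(hits) == 0:
        return seq
    out = list(seq)
    for i in hits:
        others = [b for b in _BASES if b != out[i]]
        out[i] = others[int(rng.integers(0, 3))]
    return "".join(out)


def simulate_reads(
    config: SimulationConfig,
    sequence: str,
    sites: list[tuple[PanelSite, tuple[int, int]]],
    sam_path,
    truth_vcf_path=None,
) -> None:
    """Emit coordinate-sorted single-end reads for planted diploid genotypes.

    Each of the ~depth_mean reads spanning a site is drawn from one of the
    two planted haplotypes at random; per-base errors are injected at rate
    10^(-base_quality/10) (or ``error_rate_override``), uniformly over the
    three other bases.  ``duplicate_fraction`` / ``low_mapq_fraction`` inject
    extra decoy reads (duplicate-flagged, MAPQ 5) without reducing real
    coverage.  When ``truth_vcf_path`` is given the planted genotypes —
    including explicit 0/0 — are written as a single-sample truth VCF.
    """
    rng = _rng(config.seed, "reads")
    eps = (
        config.error_rate_override
        if config.error_rate_override is not None
        else phred_to_error_prob(config.base_quality)
    )
    read_length = config.read_length
    entries: list[tuple[int, str, str, list[tuple[int, int]], int, int]] = []
    for i, (site, gt) in enumerate(sites):
        pos0 = site.pos - 1
        if pos0 < 0 or pos0 + len(site.ref) > len(sequence):
            raise SimulationError(f"site {site.locus} outside contig")
        max_ins = max(0, len(site.alt) - len(site.ref))
        lo = max(0, pos0 + len(site.ref) - read_length + max_ins)
        hi = min(pos0, len(sequence) - read_length)
        if hi < lo:
            raise SimulationError(f"site {site.locus} too close to contig end for spanning reads")
        depth = (
            int(round(config.depth_mean))
            if config.depth_mode == "fixed"
            else int(rng.poisson(config.depth_mean))
        )
        for j in range(depth):
            start = int(rng.integers(lo, hi + 1))
            hap_allele = gt[int(rng.integers(0, 2))]
            seq, cigar = _build_read(sequence, start, read_length, pos0, site.ref, site.alt, hap_allele)
            seq = _inject_errors(seq, eps, rng)
            if config.low_mapq_fraction and rng.random() < config.low_mapq_fraction:
                entries.append((start, f"r{i}_{j}lm", seq, cigar, 0, 5))
            entries.append((start, f"r{i}_{j}", seq, cigar, 0, 60))
            if config.duplicate_fraction and rng.random() < config.duplicate_fraction:
                entries.append((start, f"r{i}_{j}dup", seq, cigar, 0x400, 60))
    entries.sort(key=lambda e: e[0])

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": config.contig, "LN": len(sequence)}],
        }
    )
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        for start, name, seq, cigar, flag, mapq in entries:
            read = pysam.AlignedSegment(header)
            read.query_name = name
            read.query_sequence = seq
            read.flag = flag
            read.reference_id = 0
            read.reference_start = start
            read.mapping_quality = mapq
            read.cigartuples = cigar
            read.query_qualities = pysam.qualitystring_to_array(
                chr(config.base_quality + 33) * len(seq)
            )
            out.write(read)

    if truth_vcf_path is not None:
        vcf_header = pysam.VariantHeader()
        vcf_header.add_line("##fileformat=VCFv4.2")
        vcf_header.contigs.add(config.contig, length=len(sequence))
        vcf_header.formats.add("GT", 1, "String", "Planted genotype")
        vcf_header.add_sample("SIM")
        ordered = sorted(sites, key=lambda pair: pair[0].key)
        with pysam.VariantFile(str(truth_vcf_path), "w", header=vcf_header) as out:
            for site, gt in ordered:
                rec = out.new_record(
                    contig=site.contig,
                    start=site.pos - 1,
                    stop=site.pos - 1 + len(site.ref),
                    alleles=(site.ref, site.alt),
                    id=site.id or None,
                )
                rec.samples["SIM"]["GT"] = gt
                out.write(rec)


def simulate_genotype_columns(
    seed: int,
    n_sites: int,
    depth_mean: float,
    base_quality: int,
    genotype_prior: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    error_rate_override: float | None = None,
) -> list[tuple[tuple[int, int], PileupColumn]]:
    """Draw pileup columns directly from the read-observation model.

    A lightweight path for likelihood-calibration experiments: per site a
    genotype is drawn from ``genotype_prior``, depth from
    Poisson(depth_mean), and each read reports its haplotype's allele with a
    phred-``base_quality`` error to one of the three other bases.  Returns
    (planted genotype, column) pairs.
    """
    rng = _rng(seed, "columns")
    eps = error_rate_override if error_rate_override is not None else phred_to_error_prob(base_quality)
    prior = np.asarray(genotype_prior, dtype=float)
    prior = prior / prior.sum()
    ref_base, alt_base = "A", "C"
    out = []
    for i in range(n_sites):
        gt = GENOTYPES[int(rng.choice(3, p=prior))]
        depth = int(rng.poisson(depth_mean))
        observations = []
        for _ in range(depth):
            base = ref_base if gt[int(rng.integers(0, 2))] == 0 else alt_base
            if rng.random() < eps:
                others = [b for b in _BASES if b != base]
                base = others[int(rng.integers(0, 3))]
            allele_index = 0 if base == ref_base else (1 if base == alt_base else -1)
            observations.append(Observation(allele_index, base_quality, 60))
        out.append((gt, PileupColumn("simcol", i + 1, tuple(observations))))
    return out
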