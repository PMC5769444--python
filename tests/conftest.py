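"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from fractions import Fraction

import pysam
import pytest

from mrascreen.genotyper import GENOTYPES
from mrascreen.panel import PanelSite, classify_rarity


@pytest.fixture()
def toy_reference() -> dict[str, str]:
    """A contig whose positions 101-110 spell GGCACACACG (1-based)."""
    return {"chr_t": "A" * 100 + "GGCACACACG" + "T" * 40}


def make_site(contig="chr_t", pos=100, ref="A", alt="G", ref_af=0.1, id="") -> PanelSite:
    return PanelSite(
        contig=contig, pos=pos, ref=ref, alt=alt,
        ref_af=ref_af, alt_af=1.0 - ref_af,
        rarity=classify_rarity(ref_af), id=id,
    )


def write_bam(path, contig: str, length: int, reads: list[dict]) -> str:
    """Write reads as a coordinate-sorted, indexed BAM.

    Each read dict takes: name, start (0-based), seq, and optional qual
    (phred int applied to all bases), cigar (tuples), flag, mapq.
    """
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": contig, "LN": length}]}
    )
    path = str(path)
    with pysam.AlignmentFile(path, "wb", header=header) as out:
        for spec in sorted(reads, key=lambda r: r["start"]):
            read = pysam.AlignedSegment(header)
            read.query_name = spec["name"]
            read.query_sequence = spec["seq"]
            read.flag = spec.get("flag", 0)
            read.reference_id = 0
            read.reference_start = spec["start"]
            read.mapping_quality = spec.get("mapq", 60)
            read.cigartuples = spec.get("cigar", [(0, len(spec["seq"]))])
            read.query_qualities = [spec.get("qual", 30)] * len(spec["seq"])
            out.write(read)
    pysam.index(path)
    return path


# ---------------------------------------------------------------------------
# Independent oracles


def apply_representation(seq: str, pos: int, ref: str, alt: str) -> str:
    """Apply a (1-based pos, ref, alt) representation to a sequence."""
    assert seq[pos - 1:pos - 1 + len(ref)] == ref
    return seq[:pos - 1] + alt + seq[pos - 1 + len(ref):]


def brute_force_normalize(seq: str, pos: int, ref: str, alt: str,
                          max_allele_len: int = 14) -> tuple[int, str, str]:
    """Exhaustive minimal-representation search over a short contig.

    Enumerates every (pos, ref, alt) triple that produces the same alternate
    haplotype, then picks minimal total allele length, breaking ties by the
    smallest position.  Independent of the production left-align/trim code.
    """
    target = apply_representation(seq, pos, ref, alt)
    n = len(seq)
    best = None
    for cand_pos in range(1, n + 1):
        if seq[:cand_pos - 1] != target[:cand_pos - 1]:
            break  # a shared prefix is required; longer prefixes only shrink
        for ref_len in range(1, max_allele_len + 1):
            if cand_pos - 1 + ref_len > n:
                break
            alt_len = len(target) - (n - ref_len)
            if alt_len < 1 or alt_len > max_allele_len:
                continue
            cand_ref = seq[cand_pos - 1:cand_pos - 1 + ref_len]
            cand_alt = target[cand_pos - 1:cand_pos - 1 + alt_len]
            if cand_ref == cand_alt:
                continue
            if target[cand_pos - 1 + alt_len:] != seq[cand_pos - 1 + ref_len:]:
                continue
            key = (ref_len + alt_len, cand_pos)
            if best is None or key < best[0]:
                best = (key, cand_pos, cand_ref, cand_alt)
    assert best is not None, "no equivalent representation found"
    return best[1], best[2], best[3]


_EPS = {10: Fraction(1, 10), 20: Fraction(1, 100), 30: Fraction(1, 1000)}


def exact_pl_oracle(observations: list[tuple[int, int]]) -> tuple[int, int, int]:
    """Exact-rational genotype likelihoods for (allele_index, quality) pairs.

    Evaluates the diploid model with Fraction arithmetic (no log-space
    accumulation) and phred-scales at the end; an independent high-precision
    check on the production log-space implementation.
    """
    likelihoods = []
    for a1, a2 in GENOTYPES:
        L = Fraction(1)
        for allele_index, quality in observations:
            eps = _EPS[quality]
            p1 = (1 - eps) if allele_index == a1 else eps / 3
            p2 = (1 - eps) if allele_index == a2 else eps / 3
            L *= Fraction(1, 2) * (p1 + p2)
        likelihoods.append(L)
    l_max = max(likelihoods)
    pls = []
    for L in likelihoods:
        ratio = L / l_max
        phred = -10.0 * (math.log10(ratio.numerator) - math.log10(ratio.denominator))
        pls.append(min(2550, int(math.floor(phred + 0.5))))
    return tuple(pls)
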