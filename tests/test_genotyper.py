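"""Pileup collection and genotype-given-alleles likelihoods."""

import itertools

import pysam
import pytest

from mrascreen.genotyper import (
    GENOTYPES,
    Observation,
    PileupColumn,
    call_sites,
    genotype_given_alleles,
    phred_to_error_prob,
    pileup,
    read_calls_vcf,
    write_calls_vcf,
)
from mrascreen.simdata import SimulationConfig, make_population_vcf, make_reference, simulate_reads

from conftest import exact_pl_oracle, make_site, write_bam

CONTIG = "chr_t"
LENGTH = 400


@pytest.fixture()
def snv_site():
    return make_site(contig=CONTIG, pos=100, ref="A", alt="G")


def _read(name, start, seq, **kw):
    return dict(name=name, start=start, seq=seq, **kw)


class TestPileup:
    def test_no_overlapping_reads_gives_empty_column(self, tmp_path, snv_site):
        bam = write_bam(tmp_path / "a.bam", CONTIG, LENGTH,
                        [_read("r0", 200, "A" * 50)])
        with pysam.AlignmentFile(bam) as aln:
            assert pileup(aln, snv_site).observations == ()

    def test_reference_reads_all_support_ref(self, tmp_path, snv_site):
        reads = [_read(f"r{i}", 80, "C" * 19 + "A" + "C" * 30) for i in range(5)]
        bam = write_bam(tmp_path / "a.bam", CONTIG, LENGTH, reads)
        with pysam.AlignmentFile(bam) as aln:
            column = pileup(aln, snv_site)
        assert len(column.observations) == 5
        assert all(o.allele_index == 0 and o.quality == 30 for o in column.observations)

    def test_duplicate_and_low_mapq_reads_are_filtered(self, tmp_path, snv_site):
        seq = "C" * 19 + "A" + "C" * 30
        reads = [_read(f"r{i}", 80, seq) for i in range(3)]
        reads.append(_read("dup", 80, seq, flag=0x400))
        reads.append(_read("lowmq", 80, seq, mapq=5))
        bam = write_bam(tmp_path / "a.bam", CONTIG, LENGTH, reads)
        with pysam.AlignmentFile(bam) as aln:
            assert len(pileup(aln, snv_site).observations) == 3
            assert len(pileup(aln, snv_site, exclude_duplicates=False).observations) == 4
            assert len(pileup(aln, snv_site, min_mapq=0).observations) == 4

    def test_low_base_quality_observation_dropped(self, tmp_path, snv_site):
        reads = [
            _read("hi", 80, "C" * 19 + "G" + "C" * 30, qual=30),
            _read("lo", 80, "C" * 19 + "G" + "C" * 30, qual=5),
        ]
        bam = write_bam(tmp_path / "a.bam", CONTIG, LENGTH, reads)
        with pysam.AlignmentFile(bam) as aln:
            column = pileup(aln, snv_site)
        assert len(column.observations) == 1
        assert column.observations[0].allele_index == 1

    def test_partial_span_reads_excluded_for_indel_site(self, tmp_path):
        site = make_site(contig=CONTIG, pos=100, ref="GCA", alt="G")
        reads = [
            _read("spans", 90, "T" * 30),            # covers [90, 120) fully
            _read("partial", 100, "T" * 30),         # starts inside the REF span
        ]
        bam = write_bam(tmp_path / "a.bam", CONTIG, LENGTH, reads)
        with pysam.AlignmentFile(bam) as aln:
            column = pileup(aln, site)
        assert len(column.observations) == 1

    def test_deletion_read_supports_alt_with_capped_quality(self, tmp_path):
        site = make_site(contig=CONTIG, pos=100, ref="GCA", alt="G")
        # CIGAR 10M 2D 10M deletes the reference CA inside the span.
        reads = [
            _read("del", 90, "T" * 9 + "G" + "T" * 10, cigar=[(0, 10), (2, 2), (0, 10)], qual=50),
            _read("ref", 90, "T" * 9 + "GCA" + "T" * 10, qual=50),
        ]
        bam = write_bam(tmp_path / "a.bam", CONTIG, LENGTH, reads)
        with pysam.AlignmentFile(bam) as aln:
            column = pileup(aln, site)
        by_name = sorted(column.observations, key=lambda o: o.allele_index)
        assert [o.allele_index for o in by_name] == [0, 1]
        assert all(o.quality == 45 for o in by_name)  # indel quality ceiling

    def test_insertion_read_spells_alt_allele(self, tmp_path):
        site = make_site(contig=CONTIG, pos=100, ref="G", alt="GTT")
        reads = [
            _read("ins", 90, "A" * 10 + "TT" + "A" * 8, cigar=[(0, 10), (1, 2), (0, 8)]),
        ]
        # read base at ref pos 99 (0-based) is 'A'... make the anchor match:
        reads[0]["seq"] = "A" * 9 + "G" + "TT" + "A" * 8
        bam = write_bam(tmp_path / "a.bam", CONTIG, LENGTH, reads)
        with pysam.AlignmentFile(bam) as aln:
            column = pileup(aln, site)
        assert [o.allele_index for o in column.observations] == [1]

    def test_absent_contig_returns_empty_column_not_error(self, tmp_path, snv_site):
        bam = write_bam(tmp_path / "a.bam", "other", LENGTH, [_read("r0", 80, "A" * 50)])
        with pysam.AlignmentFile(bam) as aln:
            assert pileup(aln, snv_site).observations == ()


class TestGenotypeLikelihoods:
    def test_empty_column_is_no_call(self, snv_site):
        call = genotype_given_alleles(PileupColumn(CONTIG, 100, ()), snv_site)
        assert call.gt is None and call.dp == 0 and call.pl is None

    def test_ten_reference_reads_at_q30(self, snv_site):
        column = PileupColumn(CONTIG, 100, tuple(Observation(0, 30, 60) for _ in range(10)))
        call = genotype_given_alleles(column, snv_site)
        assert call.gt == (0, 0)
        assert call.pl == (0, 30, 348)
        assert call.gq == call.rgq == 30
        assert call.site_quality == 0.0

    def test_balanced_column_calls_het_with_symmetric_homs(self, snv_site):
        obs = tuple(Observation(i % 2, 30, 60) for i in range(10))
        call = genotype_given_alleles(PileupColumn(CONTIG, 100, obs), snv_site)
        assert call.gt == (0, 1) and call.pl[1] == 0
        assert call.pl[0] == call.pl[2]
        assert call.rgq is None and call.site_quality > 0

    def test_tie_prefers_reference_with_zero_gq(self, snv_site):
        call = genotype_given_alleles(PileupColumn(CONTIG, 100, ()), snv_site)
        assert call.gt is None  # no-data handled separately
        # One -1 observation: mismatch to every genotype, all PLs tie at 0.
        obs = (Observation(-1, 30, 60),)
        call = genotype_given_alleles(PileupColumn(CONTIG, 100, obs), snv_site)
        assert call.gt == (0, 0) and call.gq == 0 and call.rgq == 0

    def test_matches_exact_rational_oracle_exhaustively(self, snv_site):
        """Integer PLs equal exact-Fraction evaluation for all small columns."""
        obs_types = [(ai, q) for ai in (0, 1, -1) for q in (10, 20, 30)]
        checked = 0
        for n in range(1, 5):
            for combo in itertools.combinations_with_replacement(obs_types, n):
                column = PileupColumn(CONTIG, 100, tuple(Observation(ai, q, 60) for ai, q in combo))
                call = genotype_given_alleles(column, snv_site)
                assert call.pl == exact_pl_oracle(list(combo)), combo
                assert min(call.pl) == 0
                checked += 1
        assert checked == 714  # multisets of size 1..4 over 9 observation types

    def test_rgq_monotone_in_reference_evidence(self, snv_site):
        rgqs = []
        for n in range(1, 40):
            obs = tuple(Observation(0, 30, 60) for _ in range(n))
            call = genotype_given_alleles(PileupColumn(CONTIG, 100, obs), snv_site)
            assert call.gt == (0, 0)
            rgqs.append(call.rgq)
        assert rgqs == sorted(rgqs)
        assert max(rgqs) == 99  # GQ cap

    def test_phred_transform(self):
        assert phred_to_error_prob(30) == pytest.approx(0.001)
        assert phred_to_error_prob(10) == pytest.approx(0.1)


class TestCallSites:
    def test_one_call_per_site_including_no_call(self, tmp_path):
        sites = [make_site(contig=CONTIG, pos=p, ref="A", alt="G") for p in (100, 150, 300)]
        seq = "C" * 19 + "A" + "C" * 30
        reads = [_read(f"r{i}", 80, seq) for i in range(5)]
        reads += [_read(f"s{i}", 130, seq) for i in range(5)]
        bam = write_bam(tmp_path / "a.bam", CONTIG, LENGTH, reads)
        calls, summary = call_sites(bam, sites)
        assert [c.site.pos for c in calls] == [100, 150, 300]
        assert [c.gt for c in calls] == [(0, 0), (0, 0), None]
        assert summary == {"0/0": 2, "0/1": 0, "1/1": 0, "no_call": 1}

    def test_recovers_planted_genotypes_end_to_end(self, tmp_path):
        config = SimulationConfig(
            seed=11, contig_length=40_000, n_sites=100, fraction_mra=1.0,
            depth_mean=30, depth_mode="fixed", base_quality=30,
        )
        sequence, _ = make_reference(config)
        planted = make_population_vcf(config, sequence, tmp_path / "pop.vcf")
        genotypes = [GENOTYPES[i % 3] for i in range(len(planted))]
        sam = tmp_path / "reads.sam"
        simulate_reads(config, sequence, list(zip(planted, genotypes)), sam)
        calls, _ = call_sites(sam, planted)
        correct = sum(1 for call, gt in zip(calls, genotypes) if call.gt == gt)
        assert correct >= 99
        for call in calls:
            if call.gt == (0, 0):
                assert call.site_quality == 0.0 and call.rgq is not None

    def test_calls_vcf_round_trip(self, tmp_path, snv_site):
        obs = tuple(Observation(0, 30, 60) for _ in range(10))
        call = genotype_given_alleles(PileupColumn(CONTIG, 100, obs), snv_site)
        nocall = genotype_given_alleles(PileupColumn(CONTIG, 100, ()), snv_site)
        path = tmp_path / "calls.vcf"
        write_calls_vcf([call, nocall], path)
        loaded = read_calls_vcf(path)
        assert loaded[0].gt == (0, 0) and loaded[0].pl == (0, 30, 348)
        assert loaded[0].rgq == 30 and loaded[0].dp == 10
        assert loaded[1].gt is None
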