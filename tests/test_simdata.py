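"""Synthetic-data generator: determinism, planted structure, fixtures."""

import pytest

from mrascreen.fixtures import BLEEDING_DIATHESIS_GENES, bundled_fixtures, fixture_panel_sites
from mrascreen.genotyper import call_sites, pileup, open_alignments
from mrascreen.panel import build_panel
from mrascreen.simdata import (
    SimulationConfig,
    SimulationError,
    assign_genotypes,
    make_population_vcf,
    make_reference,
    simulate_genotype_columns,
    simulate_reads,
)
from mrascreen.vcfnorm import iter_population_records


SMALL = dict(contig_length=30_000, n_sites=40, fraction_mra=0.5,
             fraction_multiallelic=0.2, rare_fraction=0.2, indel_fraction=0.1,
             depth_mean=20, depth_mode="fixed", base_quality=30)


class TestDeterminism:
    def test_outputs_byte_identical_under_fixed_seed(self, tmp_path):
        for sub in ("a", "b"):
            config = SimulationConfig(seed=5, **SMALL)
            d = tmp_path / sub
            d.mkdir()
            seq, _ = make_reference(config, d / "ref.fasta")
            planted = make_population_vcf(config, seq, d / "pop.vcf")
            gts = assign_genotypes(config, len(planted), (len(planted), 0, 0))
            simulate_reads(config, seq, list(zip(planted, gts)), d / "reads.sam", d / "truth.vcf")
        for name in ("ref.fasta", "pop.vcf", "reads.sam", "truth.vcf"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        a, _ = make_reference(SimulationConfig(seed=1, **SMALL))
        b, _ = make_reference(SimulationConfig(seed=2, **SMALL))
        assert a != b


class TestReference:
    def test_repeat_tracts_present_at_recorded_loci(self):
        seq, tracts = make_reference(SimulationConfig(seed=7, **SMALL))
        assert len(tracts) == 4
        for tract in tracts:
            chunk = seq[tract.start:tract.end]
            if tract.kind == "homopolymer":
                assert chunk == tract.unit * 8
            else:
                assert chunk == tract.unit * 5
                assert tract.unit[0] != tract.unit[1]

    def test_contig_too_short_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(seed=1, contig_length=500)


class TestPopulationVcf:
    def test_planted_counts_are_deterministic(self, tmp_path):
        config = SimulationConfig(seed=9, contig_length=60_000, n_sites=100,
                                  fraction_mra=0.3, fraction_multiallelic=0.2,
                                  rare_fraction=0.1, min_site_spacing=100)
        seq, _ = make_reference(config)
        planted = make_population_vcf(config, seq, tmp_path / "pop.vcf")
        assert len(planted) == 30
        assert sum(1 for s in planted if s.rarity == "rare") == 3
        records = list(iter_population_records(tmp_path / "pop.vcf"))
        assert len(records) == 100
        assert sum(1 for r in records if len(r.alts) == 2) == 20
        for r in records:
            assert sum(r.alt_freqs) <= 1.0 + 1e-6
            assert len(r.alts) == len(r.alt_freqs)

    def test_panel_recovery_is_exact(self, tmp_path):
        config = SimulationConfig(seed=3, **SMALL)
        seq, _ = make_reference(config)
        planted = make_population_vcf(config, seq, tmp_path / "pop.vcf")
        recovered = build_panel(iter_population_records(tmp_path / "pop.vcf"), {config.contig: seq})
        assert {s.key for s in recovered} == {s.key for s in planted}

    def test_infeasible_site_density_is_a_config_error(self, tmp_path):
        config = SimulationConfig(seed=1, contig_length=1000, n_sites=500)
        with pytest.raises(SimulationError):
            make_population_vcf(config, "A" * 1000, tmp_path / "pop.vcf")


class TestReads:
    def test_zero_error_limit_gives_pure_pileups(self, tmp_path):
        config = SimulationConfig(seed=13, error_rate_override=0.0, **SMALL)
        seq, _ = make_reference(config)
        planted = make_population_vcf(config, seq, tmp_path / "pop.vcf")
        gts = [(0, 0) if i % 2 == 0 else (1, 1) for i in range(len(planted))]
        sam = tmp_path / "reads.sam"
        simulate_reads(config, seq, list(zip(planted, gts)), sam)
        alignments = open_alignments(sam)
        for site, gt in zip(planted, gts):
            column = pileup(alignments, site)
            wanted = 0 if gt == (0, 0) else 1
            assert column.observations, site.locus
            assert all(o.allele_index == wanted for o in column.observations)

    def test_planted_truth_vcf_matches_calls(self, tmp_path):
        from mrascreen.concordance import read_truth_vcf

        config = SimulationConfig(seed=4, error_rate_override=0.0, **SMALL)
        seq, _ = make_reference(config)
        planted = make_population_vcf(config, seq, tmp_path / "pop.vcf")
        gts = assign_genotypes(config, len(planted), (10, 5, 5))
        simulate_reads(config, seq, list(zip(planted, gts)), tmp_path / "r.sam", tmp_path / "t.vcf")
        truth = read_truth_vcf(tmp_path / "t.vcf")
        by_key = {(t.contig, t.pos, t.ref, t.alt): t.gt for t in truth}
        calls, _ = call_sites(tmp_path / "r.sam", planted)
        for call, gt in zip(calls, gts):
            assert by_key[call.site.key] == gt
            assert call.gt == gt

    def test_decoy_duplicates_and_low_mapq_do_not_change_filtered_depth(self, tmp_path):
        base = dict(SMALL)
        clean_cfg = SimulationConfig(seed=6, **base)
        noisy_cfg = SimulationConfig(seed=6, duplicate_fraction=0.5, low_mapq_fraction=0.5, **base)
        seq, _ = make_reference(clean_cfg)
        planted = make_population_vcf(clean_cfg, seq, tmp_path / "pop.vcf")
        pairs = [(s, (0, 0)) for s in planted]
        simulate_reads(clean_cfg, seq, pairs, tmp_path / "clean.sam")
        simulate_reads(noisy_cfg, seq, pairs, tmp_path / "noisy.sam")
        clean_calls, _ = call_sites(tmp_path / "clean.sam", planted)
        noisy_calls, _ = call_sites(tmp_path / "noisy.sam", planted)
        assert [c.dp for c in clean_calls] == [c.dp for c in noisy_calls]
        noisy_lines = (tmp_path / "noisy.sam").read_text().count("\n")
        clean_lines = (tmp_path / "clean.sam").read_text().count("\n")
        assert noisy_lines > clean_lines


class TestGenotypeColumns:
    def test_flat_prior_and_depth_distribution(self):
        columns = simulate_genotype_columns(seed=8, n_sites=3000, depth_mean=5.0, base_quality=30)
        from collections import Counter

        counts = Counter(gt for gt, _ in columns)
        assert set(counts) == {(0, 0), (0, 1), (1, 1)}
        for gt in counts:
            assert counts[gt] == pytest.approx(1000, abs=150)
        mean_depth = sum(c.depth for _, c in columns) / len(columns)
        assert mean_depth == pytest.approx(5.0, abs=0.2)

    def test_zero_error_columns_contain_only_planted_alleles(self):
        columns = simulate_genotype_columns(seed=8, n_sites=500, depth_mean=5.0,
                                            base_quality=30, error_rate_override=0.0)
        for gt, column in columns:
            allowed = set(gt)
            assert all(o.allele_index in allowed for o in column.observations)


class TestBundledFixtures:
    def test_clinvar_table_shape_and_key_rows(self):
        fx = bundled_fixtures()
        assert len(fx.panel_table) == 20
        row = fx.panel_table.set_index("rsid").loc["rs6025"]
        assert row["maf"] == 0.02
        assert row["significance"] == "pathogenic"
        assert row["phenotype"] == "Factor V Leiden"
        rare = fx.panel_table.set_index("rsid").loc["rs1169305"]
        assert rare["maf"] == 0.004 and rare["significance"] == "pathogenic"

    def test_thrombophilia_table_frequencies(self):
        fx = bundled_fixtures()
        table = fx.thrombophilia_table.set_index("rsid")
        assert table.loc["rs1799983", "maf_exac"] == 0.2470
        assert table.loc["rs1799983", "disease_allele"] == "T"
        assert table.loc["rs1799983", "gene"] == "NOS3"
        assert len(fx.thrombophilia_table) == 4

    def test_gene_list_contents(self):
        assert len(BLEEDING_DIATHESIS_GENES) == 51
        assert {"F5", "PLAU", "NOS3", "F13B"} <= set(BLEEDING_DIATHESIS_GENES)

    def test_fixture_panel_sites_are_valid(self):
        sites = fixture_panel_sites()
        assert len(sites) == 20
        for site in sites:
            assert site.ref != site.alt
            assert site.ref_af < 0.5
            assert site.clinical
        by_id = {s.id: s for s in sites}
        assert by_id["rs6003"].ref == "C" and by_id["rs6003"].ref_af == 0.13
        assert by_id["rs6025"].rarity == "common"
        assert by_id["rs1169305"].rarity == "rare"
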