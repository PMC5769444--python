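"""Bundled reference tables: known minor-reference-allele variants.

These fixtures capture published examples of clinically annotated variants
whose hg19 reference allele is the minor — and sometimes the
disease-associated — allele, plus a curated bleeding-diathesis /
thrombophilia gene list used for candidate prioritization.

Coordinates are SYNTHETIC: rsIDs, alleles, frequencies and clinical labels
are real published values, but positions are arbitrary fixed offsets on a
toy contig because genome-build coordinates cannot be verified here.  Use
the rsIDs to look up real coordinates when working with genuine data.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .panel import PanelSite, classify_rarity

__all__ = [
    "CLINVAR_MRA_TABLE",
    "THROMBOPHILIA_TABLE",
    "BLEEDING_DIATHESIS_GENES",
    "FIXTURE_CONTIG",
    "Fixtures",
    "bundled_fixtures",
    "fixture_panel_sites",
]

FIXTURE_CONTIG = "toy1"

# (rsid, minor reference allele, reference MAF, phenotype, clinical significance)
CLINVAR_MRA_TABLE: list[tuple[str, str, float, str, str]] = [
    ("rs1169305", "A", 0.004, "Maturity onset diabetes", "pathogenic"),
    ("rs4784677", "C", 0.006, "Bardet-biedl syndrome", "pathogenic"),
    ("rs497116", "C", 0.014, "Sepsis", "risk factor"),
    ("rs6025", "T", 0.02, "Factor V Leiden", "pathogenic"),
    ("rs283413", "A", 0.02, "Parkinson disease", "risk factor"),
    ("rs820878", "T", 0.03, "Sandhoff disease", "pathogenic"),
    ("rs2476601", "A", 0.07, "(multiple autoimmune diseases)", "risk factor"),
    ("rs450046", "C", 0.08, "Proline Dehydrogenase deficiency", "pathogenic"),
    ("rs12021720", "T", 0.09, "Maple syrup urine disease", "pathogenic"),
    ("rs6003", "C", 0.13, "Factor XII deficiency", "pathogenic"),
    ("rs1154510", "T", 0.15, "Hawkinsinuria", "pathogenic"),
    ("rs7076156", "A", 0.21, "Nephrolithiasis", "risk factor"),
    ("rs1801265", "G", 0.23, "Dihydropyrimidine dehydrogenase deficiency", "pathogenic"),
    ("rs1799983", "T", 0.25, "Ischemic heart disease", "risk factor"),
    ("rs2227564", "T", 0.25, "Alzheimer disease", "risk factor"),
    ("rs1061170", "C", 0.33, "Basal lamina drusen", "pathogenic"),
    ("rs1341667", "T", 0.38, "Pre-eclampsia", "risk factor"),
    ("rs2073711", "A", 0.43, "Lumbar disc disease", "risk factor"),
    ("rs237025", "G", 0.44, "Diabetes mellitus", "risk factor"),
    ("rs3733402", "G", 0.46, "Prekallikrein deficiency", "pathogenic"),
]

# Thrombophilia-gene variants whose disease-associated allele is the hg19
# reference allele: (gene, rsid, MAF 1000G, MAF ExAC, disease allele,
# ClinVar-style notation).
THROMBOPHILIA_TABLE: list[tuple[str, str, float, float, str, str]] = [
    ("F5", "rs6025", 0.0060, 0.0215, "T", "c.1601G>A, c.1601G="),
    ("F13B", "rs6003", 0.2382, 0.1280, "C", "c.344G>A"),
    ("PLAU", "rs2227564", 0.2246, 0.2454, "T", "c.371C>T"),
    ("NOS3", "rs1799983", 0.1763, 0.2470, "T", "c.894T>G"),
]

#: Curated bleeding-diathesis gene list (51 symbols), including genes with a
#: known thrombosis phenotype.
BLEEDING_DIATHESIS_GENES: list[str] = [
    "ACE", "ANGPT1", "ANGPTL4", "APOH", "AVPR2", "B4GALT1", "CCR2", "CD40LG",
    "CPB2", "F10", "F11", "F12", "F13A1", "F13B", "F2", "F3", "F5", "F7",
    "F8", "F9", "FGA", "FGB", "FGG", "GGCX", "GP1BA", "GP6", "HABP2", "HGF",
    "HRG", "ITGA2B", "JAK2", "LPA", "MMADHC", "MST1", "MTHFR", "MTR", "MTRR",
    "NOS3", "P2RY12", "PLAT", "PLAU", "PLG", "PROC", "PROS1", "RAPGEF1",
    "SERPINC1", "SERPIND1", "SERPINE1", "TFPI", "THBD", "VWF",
]

_BASE_ORDER = "ACGT"


def _toy_alt(ref: str) -> str:
    """Deterministic synthetic ALT base differing from the (real) REF base."""
    return _BASE_ORDER[(_BASE_ORDER.index(ref) + 1) % 4]


def fixture_panel_sites() -> list[PanelSite]:
    """Panel-like sites built from the ClinVar MRA table on the toy contig.

    REF alleles and frequencies are the published values; ALT bases and
    coordinates are synthetic stand-ins (positions 1000, 2000, ...).
    """
    sites = []
    for i, (rsid, ref, maf, phenotype, significance) in enumerate(CLINVAR_MRA_TABLE):
        sites.append(
            PanelSite(
                contig=FIXTURE_CONTIG,
                pos=1000 * (i + 1),
                ref=ref,
                alt=_toy_alt(ref),
                ref_af=maf,
                alt_af=1.0 - maf,
                rarity=classify_rarity(maf),
                clinical=((significance, phenotype),),
                id=rsid,
            )
        )
    return sites


@dataclass(frozen=True)
class Fixtures:
    """Bundled fixture set (synthetic coordinates; see module docstring)."""

    panel_table: pd.DataFrame
    thrombophilia_table: pd.DataFrame
    gene_list: tuple[str, ...]


def bundled_fixtures() -> Fixtures:
    panel_table = pd.DataFrame(
        CLINVAR_MRA_TABLE,
        columns=["rsid", "minor_reference_allele", "maf", "phenotype", "significance"],
    )
    panel_table.insert(0, "contig", FIXTURE_CONTIG)
    panel_table.insert(1, "pos", [1000 * (i + 1) for i in range(len(CLINVAR_MRA_TABLE))])
    thrombophilia_table = pd.DataFrame(
        THROMBOPHILIA_TABLE,
        columns=["gene", "rsid", "maf_1000g", "maf_exac", "disease_allele", "clinvar_notation"],
    )
    return Fixtures(
        panel_table=panel_table,
        thrombophilia_table=thrombophilia_table,
        gene_list=tuple(BLEEDING_DIATHESIS_GENES),
    )
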