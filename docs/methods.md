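# Methods

## Minor-reference-allele panel

A site enters the panel when, after decomposition and normalization, one of
its alternate alleles is commoner than the reference. Two selection rules
are offered because they differ subtly at multi-allelic loci:

* **alt mode (default):** a decomposed biallelic variant is selected when
  its own ALT frequency strictly exceeds the cutoff (default 0.5). At most
  one ALT per locus can qualify, so the panel key (contig, pos, REF, ALT) is
  unique by construction.
* **ref mode:** a locus is selected when its pre-split reference-allele
  frequency is strictly below the cutoff; the most frequent ALT is emitted.
  This matches the "reference allele frequency less than 0.5" phrasing but
  can select a multi-allelic locus where no single ALT is major — the emitted
  ALT is then not itself a majority allele.

Ties at exactly 0.5 are excluded in both modes (strict inequalities).
Frequency precedence on ingest is per-ALT `AF` INFO first, then `AC`/`AN`;
records with `AN` = 0 or no usable frequency are skipped and counted.
Symbolic ALTs (`<DEL>`, breakends) and `*` alleles are dropped with a
counter; their frequency mass is dropped with them, so the stored reference
frequency at such loci is slightly inflated (a documented limitation —
panel membership is decided by the remaining simple ALTs only).

The reference-allele frequency stored per panel site is
`origin_ref_freq = max(0, 1 − Σ ALT AFs)` of the *pre-split* record,
identical across siblings of one multi-allelic record. Sites with
`origin_ref_freq < 0.01` are classified *rare* (strict; 0.01 exactly is
*common*).

### Normalization

Variant representations are canonicalized by the standard left-align/trim
procedure: repeatedly strip a shared trailing base, prepending the previous
reference base whenever an allele would become empty; then strip shared
leading bases while both alleles have length ≥ 2. SNVs pass through
unchanged. The result is the unique representation with minimal total
allele length and minimal position among all equivalent (pos, REF, ALT)
triples — the test suite verifies this against an exhaustive
minimal-representation search on random 50 bp contigs, along with
idempotence and haplotype preservation. At the contig start, where no
further left-extension is possible, the partially trimmed representation is
returned as-is. IUPAC ambiguity codes encountered in the reference (either
under the REF allele or during left-extension) raise a reference-mismatch
error rather than passing silently.

## Genotype-given-alleles model

Each panel site is genotyped independently from reads that (a) are mapped,
primary, non-duplicate, (b) have MAPQ ≥ 20 (both configurable), and (c)
span the site's full REF interval. The read's sequence over that interval
is spelled out CIGAR-aware (insertions anchored on an in-span base are
included) and compared with REF and ALT; any other spelling contributes a
mismatch to both alleles. Observation quality is the base quality at an
SNV, and the minimum base quality over the span, capped at 45, at an indel
(observations below base quality 10 are dropped; the cap acknowledges that
indel support is a span-match, not a per-base event).

For diploid genotype (a₁, a₂) the per-read likelihood is
½·P(obs|a₁) + ½·P(obs|a₂) with P(obs|a) = 1 − ε on a match and ε/3
otherwise, ε = 10^(−q/10). Numerical conventions, fixed for
reproducibility:

* observation quality floored at phred 2 before conversion to ε;
* PLs rounded half-up to integers and capped at 2550; GQ capped at 99;
* when two genotypes tie at PL 0, the genotype with more REF alleles is
  called with GQ = 0. This is the conservative direction for a screen whose
  positives are 0/0: ties surface as hom-ref candidates and are then
  removed by the RGQ > 30 filter rather than disappearing into het calls;
* empty columns yield an explicit no-call; QUAL is written as 0 for 0/0
  records, and RGQ (= GQ of a 0/0 call) is the usable confidence there.

The implementation accumulates log₁₀-likelihoods; the test suite checks all
pileup columns of up to six observations over qualities {10, 20, 30}
against an exact rational-arithmetic evaluation of the same model, to the
integer PL. No base-quality recalibration is attempted — input qualities
are trusted.

## Screening

A call is a screen positive iff GT = 0/0, DP > 20 and RGQ > 30, all strict
(RGQ 30 ⇔ wrong-genotype probability 0.001). Failing calls keep an
auditable status: `fail_dp`, `fail_rgq`, `fail_genotype` (het/hom-alt —
reported in a companion table since they are standard-calling findings, not
screen positives), or `no_call`. Because the carried allele equals the
reference, passing records are annotated with reference-equals notation
(`contig:g.<pos><REF>=`) plus the allele-level genotype string; this is a
genotype-state note, not full transcript-level HGVS. Gene prioritization
intersects the REF span with a named BED; a record overlapping several gene
intervals is emitted once per gene.

## Concordance benchmarking

Calls are first restricted to confident regions (0-based half-open BED);
inside them, absence of a truth record implies truth genotype 0/0, and
outside them sites are excluded, never counted as discordant. Truth records
are normalized before lookup when a reference is available, so equivalent
indel representations agree before any mismatch is declared. Discordant
sites get exactly one class, in fixed priority order: `allele_mismatch`
(truth record at the position with different alleles), `position_mismatch`
(a truth indel within ±10 bp — configurable — that plausibly explains the
disagreement as a representation shift), else `genotype_mismatch`. The
published discordance taxonomy was a manual review; the window and the
low-complexity criteria here (homopolymer run ≥ 5 or dinucleotide repeat
≥ 4 units within ±10 bp) are explicit, configurable stand-ins, and the
low-complexity flag is kept orthogonal to the class rather than being a
class itself. Reported rates are rounded half-up to two decimals.

## Synthetic data: what it emulates, and what not

The generator reproduces the *statistical* structure the pipeline assumes:
per-ALT frequency bookkeeping with planted MRA/rare/multi-allelic
fractions (deterministic counts, e.g. 1000 sites × 0.3 = exactly 300 MRA),
indels planted in already-canonical representation, reads drawn per site
from the two planted haplotype alleles with uniform base errors at rate
10^(−q/10), uniform quality strings, MAPQ 60, and optional duplicate/
low-MAPQ decoys that never displace real coverage. One RNG stream per
output file, derived from (seed, file name), makes every output
byte-deterministic and mutually independent.

It does **not** model: indel sequencing-error modes, quality decay along
reads, GC/capture bias, mapping ambiguity, contamination, or linked
variation between nearby sites (planted sites are spaced at least two read
lengths apart by default so each site's reads are unambiguous). Passing
tests therefore demonstrate correctness of the *method* under its own
error model, not robustness to real-platform artifacts.

Coverage per site is Poisson(depth_mean) by default. `depth_mode="fixed"`
plants exactly `depth_mean` spanning reads; the end-to-end recovery
experiments use it because their design states a guaranteed depth
("depth ≥ 30"), and a Poisson(30) draw would put ~3.5% of sites at or
below the DP = 20 screening threshold — a property of the depth
distribution, not of the screen under test.

## Study conditions used by the tests and the acceptance script

* **Panel recovery:** 1000 sites on a 40 kb contig (30-bp grid spacing),
  30% MRA, 20% multi-allelic, 10% rare, 10% indels; recovery of the
  planted set must be exact (precision = recall = 1).
* **End-to-end screen:** 150 frequency sites on 60 kb, 80% MRA (= 120 panel
  sites); genotypes planted as 100 × 0/0, 10 × 0/1, 10 × 1/1; fixed depth
  30, Q30, 100 bp reads. Expectation: ≥ 99 of the 100 hom-ref sites pass
  DP > 20 / RGQ > 30, zero passes elsewhere; with the error rate overridden
  to 0, concordance against the planted truth is exactly 1.
* **RGQ calibration:** calibration is a posterior statement —
  P(genotype ≠ 0/0 | called 0/0 with RGQ q) ≈ 10^(−q/10) under a flat prior
  — so genotypes are planted uniformly over {0/0, 0/1, 1/1} at 10,000
  sites and the wrong fraction is measured among 0/0 calls with RGQ within
  ±2 of q, for q ∈ {10, 20}, against a 3-standard-error Monte-Carlo band.
  Conditions (depth Poisson(5), base quality 10) were derived analytically:
  RGQ of an all-reference column is ~2.85·depth at Q10, so the attainable
  RGQ lattice (≈ 8.6, 11.4, …, 20.0) places points inside both bands with
  posteriors averaging close to the nominal rate; at Q30 the lattice
  (≈ 9.0, 12.0, …) skews the RGQ-10 band average to ~0.084, which no
  sample size can reconcile with 0.1. Shallow depth is required for RGQ to
  land near 10–20 at all.
* **Worked-example arithmetic:** the concordance machinery is run on
  constructed call/truth sets of 692 compared / 58 discordant and
  627 / 40, the published benchmark counts, and must report 91.62% / 8.38%
  and 6.38%.

All experiment sizes were chosen so the whole suite runs in seconds on one
CPU while keeping the Monte-Carlo bands meaningful.

## Known limitations

* Single-sample, biallelic genotyping only; no haplotype assembly, gVCF
  blocks, somatic models, or multi-allelic (> 2 alleles) genotypes per site.
* Indel evidence is span-matching; partially overlapping reads are excluded
  rather than partially scored, and no local re-assembly is attempted.
* The clinical join is coordinate/allele-based and ignores rsIDs (which
  drift between builds); contig naming can be harmonized (`chr` prefix)
  but cross-assembly liftover is out of scope.
* Bundled fixture tables carry real published rsIDs, alleles, frequencies
  and significance labels but synthetic coordinates on a toy contig.
* The external caller the approach was originally validated with has its
  own read filters and likelihood details; integer-PL parity with it is not
  promised, only internal correctness of the model stated here.
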