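# mrascreen

Screening of clinically relevant variants whose pathogenic allele **is** the
genome reference allele.

## The problem

Variant calling reports differences from a reference genome. But the human
reference carries, at tens of thousands of sites, an allele that is *less
frequent* in the population than an alternate allele at the same position —
a **minor reference allele (MRA)**. The classic example is the Factor V
Leiden variant rs6025: the disease-associated allele is the hg19 reference
allele. An individual homozygous for such an allele shows *no variant at
all* in a standard call set, so the clinically relevant genotype is silently
missed, while carriers of the common (usually benign) alternate allele
produce conspicuous high-frequency "variants".

`mrascreen` implements a panel-based screen for these sites, aimed at
clinical and research exome/genome analysts:

1. **Panel construction** (`vcfnorm`, `panel`): multi-allelic records from a
   population frequency VCF (ExAC/gnomAD-style, per-ALT `AF` or `AC`/`AN`)
   are decomposed into biallelic variants with per-allele frequency
   subsetting, left-aligned and trimmed against the reference, and selected
   when an alternate allele frequency exceeds 0.5 (strict) — equivalently,
   the reference allele frequency is below 0.5. Sites with reference AF
   < 0.01 are classified *rare*; ClinVar-style significance records can be
   joined on normalized (contig, pos, REF, ALT); the panel is written as VCF
   and BED.
2. **Direct genotyping** (`genotyper`): every panel site is genotyped from
   the alignments in genotype-given-alleles fashion, *including* homozygous
   reference calls that ordinary callers omit. For a diploid genotype
   g = (a₁, a₂) and read observations b with phred quality q,

       L(g) = ∏ᵦ [ ½ P(b | a₁) + ½ P(b | a₂) ],
       P(b | a) = 1 − ε  if b matches a,  ε/3 otherwise,  ε = 10^(−q/10)

   Likelihoods are reported as normalized phred-scaled **PL** values
   (min PL = 0), genotype quality **GQ** = the gap between the two smallest
   PLs, and — for 0/0 calls — the **reference genotype quality RGQ** = GQ.
   RGQ is the screen's quality metric because VCF site quality (QUAL) is 0
   at reference sites.
3. **Screening** (`screen`): calls are filtered to confident homozygous
   reference findings with **DP > 20** and **RGQ > 30** (wrong-genotype
   probability 10^(−30/10) = 0.001), both strict and configurable. Passing
   records report the carried minor reference allele with reference-equals
   notation (e.g. `g.1882T=; T/T`); het/hom-alt calls go to a companion
   table; results can be prioritized against a named gene BED (a curated
   51-gene bleeding-diathesis/thrombophilia list ships as a fixture).
4. **Benchmarking** (`concordance`): screened calls are compared against a
   high-confidence truth set restricted to confident regions, where a
   missing truth record implies a 0/0 truth genotype. Discordant sites are
   classified (allele mismatch → position mismatch → genotype mismatch) and
   orthogonally flagged for low-complexity context (homopolymer ≥ 5 or
   dinucleotide repeat ≥ 4 units within ±10 bp).
5. **Synthetic data** (`simdata`): seeded, byte-deterministic generation of
   reference contigs with repeat tracts, frequency VCFs with planted MRA
   sites, and reads from planted diploid genotypes with phred-consistent
   errors — the substrate for every statistical test in the suite.

## Worked example

Simulate a 30 kb contig with 40 frequency-VCF sites (20 of them MRA), an
individual homozygous-reference at 16 panel sites (het at 2, hom-alt at 2),
then run the whole screen:

```bash
cat > sim.yaml <<EOF
seed: 7
contig_length: 30000
n_sites: 40
fraction_mra: 0.5
fraction_multiallelic: 0.2
rare_fraction: 0.2
depth_mean: 30
depth_mode: fixed
base_quality: 30
genotype_counts: [16, 2, 2]
EOF
mrascreen simulate --config sim.yaml --out-dir sim
mrascreen build-panel --pop-vcf sim/population.vcf --ref sim/reference.fasta --out-prefix demo
mrascreen genotype --bam sim/reads.sam --ref sim/reference.fasta \
    --panel demo.panel.vcf --out demo.calls.vcf
mrascreen screen --calls demo.calls.vcf --out-prefix demo
printf 'sim1\t0\t30000\n' > confident.bed
mrascreen concord --calls demo.calls.vcf --truth sim/truth.vcf \
    --confident confident.bed --ref sim/reference.fasta --out-prefix demo
```

which prints

```
wrote sim/reference.fasta, sim/population.vcf (40 sites, 20 MRA, 4 repeat tracts), sim/reads.sam, sim/truth.vcf
read 40 records (0 symbolic ALTs, 0 skipped); selected 20 panel sites (0 normalization failures)
genotyped 20 sites: 0/0=16, 0/1=2, 1/1=2, no_call=0
screened 20 calls; 16 pass (DP > 20, RGQ > 30)
excluded 0 calls outside confident regions
compared 20/20 calls: 20 concordant (100.0%), 0 discordant (0.0%)
```

All 20 planted MRA sites are recovered into the panel; the 16 planted
homozygous-reference genotypes — invisible to standard calling — pass the
DP/RGQ screen, the 4 planted variant genotypes are routed to the companion
table, and every call agrees with the planted truth. The screen report
(`demo.screen.tsv`) begins:

```
contig  pos   id        carried_minor_allele  ref_af  rarity  genotype  dp  rgq
sim1    1882  sim00001  T                     0.0023  rare    T/T       30  90
sim1    7774  sim00012  C                     0.0998  common  C/C       30  90
sim1    9648  sim00014  T                     0.1999  common  T/T       30  90
```

Each row is a confident carrier of a minor reference allele: `T/T` at a
site where the reference `T` has population frequency 0.0023 means this
individual is homozygous for an allele carried by ~0.2% of chromosomes —
a finding standard calling would report as "no change" (`g.1882T=`).

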