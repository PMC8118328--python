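# Methods

## Scope and model

`editome` re-implements, at desk scale, the downstream analysis used to ask
which A-to-I RNA editing sites depend on which ADAR enzyme: genome-wide site
identification from aligned RNA-seq reads, annotation against known editing
databases, per-site editing-ratio quantification, the *retention* statistic
contrasting knockout genotypes with wild type, and two orthogonal targeted
assays (amplicon deep sequencing and Sanger peak ratios). Because the
original study's inputs are organism-scale sequencing runs, the package
ships a synthetic editome generator that plays the role of the sequencing
data; every stage is exercised and tested against that generator's ground
truth.

### Editing model

Each site *i* carries a contribution c_e ∈ [0, 1] for each enzyme
e ∈ {ADAR1 p110, ADAR1 p150, ADAR2}. A genotype G (a subset of available
enzymes) realizes the editing ratio under an independent-action rule:

    ratio(i, G) = 1 − ∏_{e ∈ G} (1 − c_e(i))

This is a modeling choice, not an estimate of real kinetics: it is the
simplest rule under which (a) removing an enzyme never increases editing,
(b) a site whose only contributing enzyme is removed goes to zero, and
(c) two-enzyme sites remain substantially edited after losing one enzyme.
Note its quantitative consequence: for a site edited redundantly by p110
and ADAR2, retention in a single knockout is
c_other / (1 − (1−c_p110)(1−c_ADAR2)), which is high but strictly below 1.
The generator draws redundant contributions from U(0.6, 0.9), giving
truth-expected single-knockout retention around 0.8; tests compare measured
retention against this truth-table expectation rather than against an
idealized 1.

### Simulated study conditions (generator defaults)

These are fixed once and shared by the test suite and the acceptance
script; they are the package's definition of the study, not tuning knobs.

| parameter | default | rationale |
|---|---|---|
| read length | 100 bp, paired-end | matches the library design being emulated |
| base error rate | 0.001 / base | ~Q30 platform error |
| base quality | constant Q30 | matches the error rate; recalibration is out of scope |
| pre-mRNA fragment fraction | 0.30 | gives intronic sites ~30% of exonic coverage, enough to quantify the many intronic sites the analysis targets |
| per-sample depth | 60× mean template coverage | intronic sites then see ≳18×, clearing the 10-read ratio floor |
| fragment length | N(300, 30), clipped | typical RNA-seq insert size |
| sites per study | 300 (contrast study) | enough for per-class retention means at Monte-Carlo noise ~0.01 |
| region mix | intron 0.45 / 3'UTR 0.40 / CDS 0.15 | editing catalogs are dominated by intronic and 3'UTR sites |
| enzyme-class mix | p110-only 0.30 / ADAR2-only 0.30 / redundant 0.38 / p150-only 0.02 | the small p150-only class is what survives the double knockout |
| contributions | U(0.35, 0.9) single-enzyme; U(0.6, 0.9) redundant and p150-only | keeps wild-type ratios above the 5% retention floor so eligibility reflects biology, not noise |
| replicates | 2 per genotype | the retention rule is defined over two animals per group |

Planted sites keep 25 bp away from transcript span boundaries: fragment
sampling tapers coverage to zero at template ends (as real libraries do at
transcript 3' ends), so sites placed in the last few bases would be
unquantifiable at any depth.

The library is strand-preserving: read 1 carries the gene strand. Edits are
decided per cDNA fragment, so overlapping mates agree; sequencing errors
are independent per base.

What the generator does **not** emulate: hyper-editing clusters, PCR
duplication-rate realism (duplicates arise only by coincidence of fragment
coordinates), quality miscalibration, mappability artifacts, germline SNPs,
and expression-level variation between genes. Passing tests therefore
demonstrate correctness of the analysis logic under binomial sampling — not
robustness to alignment artifacts or SNP contamination in real data.

## Discovery stages

**Pileup.** CIGAR-aware: M/=/X bases are tallied, D/N/S contribute nothing,
insertions anchor to no column. Floors default to base quality ≥ Q20 and
mapping quality ≥ 20 (config-exposed; reads below the mapping floor are
dropped, which is also the multi-mapper policy). Duplicates are marked by
(chromosome, unclipped 5' position, strand, mate signature), keeping the
highest base-quality-sum copy; ties break on read name so marking is
order-independent and idempotent. Overlapping mates count once per
position: the higher-quality base wins, equal qualities keep the mate
encountered first in coordinate order.

**Calling.** Per column, the highest-depth alternate allele is scored with
a Phred-scaled likelihood ratio: the no-variant null (each read is
reference unless a sequencing error occurred; a specific wrong base has
probability e/3 with e from the base quality) against a variant model with
allele fraction at its maximum-likelihood value AD_alt/(AD_ref+AD_alt).
A call is emitted when QUAL ≥ 20 (call-confidence default) and DP ≥ 5.
This column-wise model replaces haplotype assembly deliberately: only
biallelic substitutions feed the editing analysis, and the transparent
model makes the caller provable against a closed-form oracle. A pure
"product of alternate error probabilities" score was rejected because any
single Q30 error would clear the 20-Phred bar regardless of coverage; the
likelihood ratio keeps isolated errors at ordinary depth well below it.

**Hard filters.** FS is the Phred-scaled two-sided Fisher exact probability
of the allele-by-strand 2×2 table, computed by exhaustive fixed-margin
hypergeometric enumeration in exact integer arithmetic (the two-sided sum
includes every table whose probability does not exceed the observed one;
exact comparisons make tie handling deterministic). QD is QUAL divided by
informative depth (AD_ref + AD_alt). Calls are removed when FS > 30.0 or
QD < 2.0; equality survives, mirroring the quoted inequalities. An
undefined QD (zero informative depth) fails by convention.

**Orientation and annotation.** A>G inside a '+'-strand gene or T>C inside
a '−'-strand gene becomes an A-to-I candidate in gene-strand coordinates;
everything else is rejected. A candidate consistent with genes on both
strands is flagged ambiguous and excluded — database strand misregistration
is a known failure mode. Region labels use precedence CDS > 3'UTR > 5'UTR >
intron across the assigned gene's isoforms (exon beats intron, as gene-based
annotators behave); positions in no transcript are "others". Candidates are
kept only when a known-site entry matches chromosome, position *and* gene
strand; sources are pooled across databases with provenance retained.
Databases published on another assembly are lifted point-wise through UCSC
chain files (highest-scoring covering chain wins; gap positions are
unmapped; '−'-strand destinations use reverse-coordinate arithmetic). Only
point lifting is implemented. No SNP mask is applied beyond database
intersection.

## Quantification

The editing ratio is AD_alt/DP on the gene strand, reported at DP ≥ 10
(config-exposed; the floor is an assumption, echoed as such in run
manifests). Replicate means are unweighted arithmetic means of ratios, not
pooled counts. Retention = mean(mutant)/mean(wild type), computed only when
the wild-type mean exceeds 5% (strictly) and the site is *detected* in both
replicates of each group. "Detected" means: passed discovery + database
intersection in that replicate with a defined ratio and AD_alt ≥ 1. A site
silenced by a knockout therefore usually leaves the retention table as
"not detected in both mutants" rather than contributing a zero;
`summarize_retention(undetected_as_zero=True)` provides the complementary
reading in which such loss counts as retention 0. Both are reported because
"not detected" is genuinely ambiguous between zero coverage, zero alternate
reads, and caller non-emission — the record flags distinguish all three.

Category counts reproduce the two-animal union/intersection bookkeeping per
region; ratio categories are high (> 60%), mid ([30%, 60%], closed on both
ends), low (< 30%). ΔΔCt relative expression is 2^−ΔΔCt.

## Targeted assays

Amplicon reads are anchored by prefix-matching the 5' adaptor and barcode
(≤ 1 mismatch each), then assigned to the design minimizing Hamming
distance over the 20 bases flanking the target on each side with the site
base masked, so the edited allele cannot bias assignment (the anchoring
algorithm is this package's design; the original counting program is
unpublished). Reads are rejected when the best normalized distance exceeds
0.1, when the insert does not cover the anchor window, or when two designs
tie. Alleles are counted at the designated offset from bases ≥ Q20; the
ratio is n_G/(n_A+n_G) with other bases reported separately and never in
the denominator. The Sanger estimate is 100·G/(G+A) from supplied peak
heights; trace-file parsing is out of scope.

## Numerical and degenerate-input choices

- Coordinates are 1-based inclusive in all user-facing structures; interval
  arithmetic internal to chain lifting is 0-based half-open.
- FS of an all-zero table is defined as 0; p-values ≥ 1 clip FS at 0.
- Multi-allelic columns evaluate only the deepest alternate (ties to the
  alphabetically first base); the rest are logged.
- Reference-N columns are skipped with a log notice.
- Empty SAM input produces empty tables without error.
- All randomness flows through one seeded NumPy generator per invocation;
  identical arguments and seed give byte-identical SAM output.

## Problem sizes used in tests and the acceptance script

The shipped checks run the contrast study at 4 chromosomes × 20 kb, 300
sites, depth 60, eight samples; pileup-conservation checks use 50
simulations of ≤ 500 reads; the Fisher-strand oracle is exhaustive over all
2×2 tables with total ≤ 60; amplicon recovery uses 10⁴ reads. These sizes
keep every Monte-Carlo band (3 binomial SD) far wider than the residual
noise while completing in minutes on one CPU.

## Known limitations

- The caller has no ploidy/genotype-likelihood model and no indel support;
  it is a substitution caller for editing analysis.
- Database-free (de novo) editing discovery is deliberately absent: the
  analysis is restricted to database-registered sites, so novel or
  hyper-edited sites outside the catalogs are invisible by design.
- Liftover does not split intervals or handle multi-block point ambiguity
  beyond best-chain selection.
- The independent-action combination rule is a stand-in for unknown enzyme
  kinetics; per-enzyme contributions are free simulator inputs, not
  estimates of any real editome.
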