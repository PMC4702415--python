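# Methods

## The problem

At some genomic loci two genes are transcribed from opposite strands of the
same DNA, with exons that physically overlap — for example a protein-coding
gene and an antisense long non-coding RNA. Conventional read counting cannot
attribute an RNA-seq read in the overlap to either gene, and annotation-led
transcript assembly misses unannotated exons entirely. `sjkit` reconstructs
the exon/isoform architecture of such loci directly from splice-junction
evidence, without using any gene annotation, and provides the two statistical
analyses used to interrogate the reconstructed locus genetically: exact
binomial allelic-expression-imbalance (AEI) tests and negative-binomial (NB)
genotype–expression regressions.

## Junction discovery and strand assignment

A gapped alignment (CIGAR `N` operation) spanning at least 20 nt is treated
as a candidate intron; shorter gaps are indel-scale and ignored. The 20 nt
floor is below any known spliceosomal intron and above common indel lengths;
it is exposed as `min_intron`.

The transcribed strand is assigned from the canonical spliceosomal
dinucleotides. An intron whose genomic sequence runs `GT…AG` was spliced
from a plus-strand transcript; `CT…AC` (the reverse complement) from a
minus-strand transcript. Gaps matching neither are discarded — the strictly
canonical rule — but a discard tally is kept so the cost of the filter is
auditable. Minor splice classes (`GC–AG`, `AT–AC`) are deliberately not
rescued: strand assignment is the point of the rule, and the minor classes
are rare enough that their loss does not change locus architecture. On a
genome pathological enough to satisfy both orientations at once, plus strand
wins deterministically and a warning would be the user's only recourse; the
two canonical patterns are mutually exclusive on real sequence.

A read crossing two introns contributes one count to each junction.
Mapping-quality and overhang filters are available but default off, since
the upstream aligner's filtering is unknown in general.

### Abundance tiers

Junctions are classified into ordered abundance tiers from two joint
minimums, total reads and number of samples with at least one read:

| tier   | min reads | min samples |
|--------|-----------|-------------|
| rare   | 1         | 1           |
| low    | 2         | 2           |
| medium | 25        | 25          |
| high   | 100       | 100         |

The highest tier whose two thresholds are both met applies, so (25 reads,
24 samples) is still low. Classification is monotone in both arguments.

## Exon inference

Junction boundaries are exact: every acceptor position opens an exon and
every donor position closes one, on both strands (the geometry is
strand-independent; only the 5'/3' interpretation flips). Exon ends that no
junction defines — first exons, terminal exons, retained introns — are
extended along contiguous coverage while per-base depth stays at or above
`coverage_floor_fraction` (default 0.1) of the exon's internal median depth.
The floor is a design choice: published descriptions of such extensions are
qualitative, and 10 % of internal depth separates genuine UTR read-through
from background in our simulations.

Roles follow transcription orientation: no incoming junction at the 5'
boundary → transcription-start (TSS) candidate; no outgoing junction at the
3' boundary → terminal candidate. TSS calling is purely structural; no
promoter-model scoring is performed (externally computed TSS scores can be
carried as annotations).

Terminal ends are refined with two signals: polyadenylation hexamers
(default set `AATAAA` + `ATTAAA`; the extended 12-hexamer catalogue is
available) scanned on the transcribed strand, and a coverage drop-off test —
mean depth in a 100 nt window downstream ≤ θ = 0.2 × the upstream window.
θ and the window are exposed; the published description of the drop
("precipitous") carries no number, so these defaults are the package's own,
validated on simulated 3' decay where the recovered terminus lands within
50 nt of truth. A terminal call without a supporting poly-A signal is
low-confidence.

De-novo discovered exons that overlap on the same strand and share one
splice boundary are grouped as variants of one exon locus (transitive
closure). For curated catalogues the grouping is taken from the table's
variant-group labels: the printed groupings encode biological judgement that
geometry alone cannot reproduce (two distinct first exons may share a 5'
end; an intron-retention variant shares its donor with the downstream exon).

## Isoform enumeration

Exons and classified junctions form a DAG in transcription order. Isoform
models are all paths from an allowed start (TSS candidates by default) to an
allowed end (terminal candidates, or an explicit list when prior knowledge
pins the 3' exons), under evidence constraints:

- rare edges are never used (a single read in a single sample is not
  assembly-grade evidence);
- at most `max_low_edges` low-tier edges per path (default 1);
- at most one member of each variant group per path — alternative boundary
  versions of one exon are mutually exclusive;
- a pure TSS-candidate exon cannot be entered mid-path unless
  `tss_as_internal` is set (the ambiguity between "start exon" and
  "internal exon with unseen upstream junctions" is real at low depth, so
  the switch exists, default off).

Enumeration is exhaustive depth-first search with deterministic ordering
(start coordinate, then lexicographic exon chain). Tightening constraints
can only remove isoforms. Equivalence with a brute-force path search is
enforced by test on random graphs up to 25 nodes.

Transcript sequences concatenate exon sequences in transcription order,
reverse-complemented for minus-strand genes. No isoform abundance estimation
is attempted: the evidence model supports existence claims, not
quantification.

## Coding-potential assessment

Three independent measures per transcript model:

1. **Longest ORF** (ATG-to-stop) over the three forward frames — the strand
   is known from assembly, so reverse frames are not scanned. ORFs running
   off the 3' end are flagged `open_ended` and excluded from the headline
   longest-ORF value.
2. **Transmembrane segments** by Kyte–Doolittle hydropathy: window 19,
   windowed mean > 1.6, merged within 5 residues. The classical sliding
   window is chosen for determinism and parameter transparency; all three
   constants are configurable. Counts from different TM predictors are not
   expected to agree exactly.
3. **TESTCODE (Fickett) statistic** from codon-position asymmetry and
   composition of each base, using the published probability/weight lookup
   tables; < 0.74 noncoding, > 0.95 coding, between: ambiguous. Defined for
   sequences ≥ 200 nt. The reverse complement of a sequence is scored
   independently; no symmetry is assumed.

A spliced transcript > 200 nt with no supported ORF and a noncoding
TESTCODE call is the operational signature of a long non-coding RNA.

## Allelic expression imbalance

At a heterozygous site, each sample's allele counts are tested with the
exact one-sided upper-tail binomial probability of the major allele,
P(X ≥ k_major | n, p₀), p₀ = 0.5 by default. The tail is summed from the
PMF in log space — not the incomplete-beta shortcut, which loses precision
at large n, and not a normal approximation. The one-sided-on-the-major-allele
convention is documented prominently because it is what published AEI tables
of this form print; it is symmetric in the two counts and effectively
doubles the nominal level relative to a two-sided test.

Bonferroni correction multiplies by the number of heterozygous samples
tested at the site (the factor can be overridden when the tested cohort is
known to be larger than the rows at hand). Samples need ≥ 10 reads to be
tested (configurable); at lower depth, counts are pooled across samples and
tested once. Fold differences are major/minor ratios reported to two
decimals; a zero minor count is flagged infinite rather than rounded.
p₀ can be moved off 0.5 to absorb reference-mapping bias; no bias model is
built in.

## Genotype–expression association

Each expression endpoint (a gene's unique reads, one exon's reads, one
junction's reads) is a per-sample count modelled as

    log E[count] = log(library_size) + covariates + genotype

with NB2 dispersion estimated by maximum likelihood per model. Genotype
enters as an unordered three-level factor (an additive coding is available);
the genotype p-value is a likelihood-ratio chi-square of the genotype term
(Wald optional). The published description of this model family says "logit
link", which is inconsistent with the stated log-linear count equation; the
log link is implemented as the only reading under which the model is a
count regression with a rate offset.

The covariate set per endpoint is chosen by exhaustive subset search over
the candidate roster {age, race, gender, diagnosis, alcohol use, smoking,
PMI, brain pH, RIN, suicide} (≤ 2¹⁰ fits), minimizing BIC with the genotype
term always present; ties break to the smaller, lexicographically earlier
subset. Missing data are removed per model (complete cases). Failed fits
skip their subset with a log entry; a singular design names the collinear
columns.

Multiplicity: Bonferroni over (number of endpoints) × (effective number of
independent SNPs), the eigenvalue-based Li–Ji count on the SNP correlation
matrix — f(λ) = 1{λ ≥ 1} + (λ − ⌊λ⌋) summed over eigenvalues — so two SNPs
in perfect LD count once and independent SNPs count fully. Experiment-wise
significance is declared at α = 0.2. The Li–Ji choice is pluggable; the
method behind published adjustment factors of this form is not always
recoverable, and ours is stated exactly so the factor is reproducible.

## The synthetic-data generator

`simulate` builds a fully-known 13 kb locus emulating the architecture the
pipeline targets: a six-exon sense gene on the minus strand (one chain of
high-tier junctions; terminal exon with a planted poly-A hexamer and an
exponentially decaying 3' tail, scale 20 nt over 250 nt) and a four-exon
antisense gene on the plus strand whose first three exons overlap sense
exons, wired with high/medium edges plus one low-tier exon-skip edge and one
rare edge. All planted introns carry `GT…AG` on their transcribed strand. A
designated sense isoform carries a planted ORF (stop-guarded ATG, chosen
codons, closing stop); optionally the ORF encodes N hydrophobic 21-residue
stretches separated by polar linkers to emulate a seven-transmembrane
receptor.

Reads are 100 nt single-end: junction reads with 50 nt anchors drawn Poisson
per sample at tier rates (low 0.08, medium 0.4, high 5.0 expected
reads/sample; a rare junction is planted as exactly one read in one sample —
its defining observation), and uniform exon-body reads at a configurable
per-sample depth. The tier rates are set so that at the default cohort of
150 samples the classifier recovers every planted tier with ≥ 95 %
probability. Sequencing error, GC bias and duplicates are not modelled;
passing tests therefore demonstrate the logic of discovery and assembly, not
robustness to alignment artefacts.

Allelic counts for heterozygotes are Binomial(n, θ/(1+θ)) at Poisson-depth
n, with the imbalance factor θ tied to genotype; homozygotes carry all reads
on one allele and are excluded downstream. Genotypes for two SNPs are drawn
from haplotypes with correlation √r² so the sample LD hits the target;
covariates mirror a two-diagnosis post-mortem brain cohort of ~211 subjects
(age 45.7 ± 13.8, pH 6.51 ± 0.25, RIN 8.15 ± 0.85, PMI ~35 ± 21 h, ~74 %
male, ~48 % smokers); endpoint counts are NB2 with log-normal library sizes.

All randomness flows from one integer seed through a single generator;
(spec, seed) yields byte-identical outputs, and the ground truth (including
per-sample junction draws) is serialized as JSON alongside.

## Problem sizes used in the checks

The test-suite and the acceptance script run: end-to-end isoform recovery
over 20 seeds at ~50× aggregate exon coverage (150 samples); brute-force
enumeration equivalence over 20 random graphs of 5–25 nodes; NB-GLM null
calibration over 1000 replicates at n = 200; BIC selection consistency over
100 replicates at n = 208 with a 3-covariate candidate set (RIN signal,
two decoys); binomial tails cross-checked against exact integer arithmetic
up to n = 10,000. These sizes were chosen as the smallest at which the
respective Monte-Carlo bands are meaningful.

## Known limitations

- Coverage is strand-agnostic, as in unstranded library preparations;
  boundary-less exon ends inside a region covered by the opposite-strand
  gene would extend into that gene's coverage. Junction-defined boundaries
  are immune.
- Terminal/TSS exon ends inferred from coverage carry ±tens-of-nt
  uncertainty by construction; only junction-defined boundaries are exact.
- The assembler proves path existence under evidence constraints; with
  permissive constraints the model count grows combinatorially and should
  be read as an upper envelope of isoform diversity, not a quantified
  transcriptome.
- The AEI test assumes independent reads; UMI-free PCR duplicates would
  overstate significance.
- NB dispersion is estimated per model with no shrinkage across endpoints;
  with few samples the LRT can be mildly anticonservative.
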