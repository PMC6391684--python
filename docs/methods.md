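# Methods

This note documents the models, defaults, and numerical choices behind
`vgenepop`, and what the synthetic cohort does and does not emulate.

## Reference database and operational grouping

Germline alleles are read from IMGT-dialect FASTA ('|'-separated header
fields; the field matching `SEGMENT*NN` is the allele name; an optional
`F`/`P`/`ORF` field is the functionality call; plain `>SEGMENT*NN` headers
are accepted). Non-functional records are retained but flagged and excluded
from grouping and every downstream statistic.

Grouping metric: global (end-gap-penalized) alignment identity,
matches / alignment columns, computed by the package's own Needleman–Wunsch.
Two segments join one group when **any** allele pair across them reaches the
identity threshold (default 0.95), and merging is single linkage: the listed
duplicated families are chained sets, so transitive merging is the behaviour
that reproduces them. Group ids are the lexicographically smallest member
plus `^`. The threshold and scoring are configurable because the exact
parameters behind "95% similarity" are a convention, not a derived quantity.

Reading frame: position 0 of the database sequence. This is forced by the
printed novel-allele names: in `ag168ND` the a→g substitution changes N to D
only if 168 is the first base of a codon, which holds for 0-based indexing
(168 ≡ 0 mod 3) and fails for 1-based; `cg27HD` and `gt234E_` check out the
same way.

## Pairwise alignment

Both aligners use the three-state Gotoh recursion with affine gaps; a gap of
length L costs `open + (L−1)·extend` (the open penalty covers the first
gapped column). Defaults: BLOSUM62 with open 11 / extend 1 for amino acids,
match 2 / mismatch −2 / open 3 / extend 1 for nucleotides. Identity is
counted over one optimal traceback (ties resolved diagonal-first); scores are
exact, and the test suite checks them against an independent memoized
recursion, exhaustive substring enumeration (local), and a second
implementation from a standard library. Kernels are JIT-compiled when numba
is importable, with an identical pure-Python fallback.

## Copy-number estimation

`CN = 2 · kmer_cov · r/(r−k+1) · L/(L−r+1) / genome_cov`. The k-mer factor
counts the `r−k+1` k-mers per read; the trapezoid factor is the plateau-to-
mean ratio for reads fully contained in a length-L contig (uniform starts on
`L−r+1` positions). The diploid constant 2 treats genome-wide coverage as the
two-copy baseline; mean (not median) genome coverage is used and
configurable. When base coverage is supplied directly the k-mer conversion is
skipped and a provenance flag records the path.

## CNV genotype calling

Polymorphism definitions (which groups co-vary and the candidate haploid
variants) are configuration inputs, not discovered de novo — the genomic
configurations come from prior knowledge, and fixing them makes calls
auditable. Two call methods:

- **cluster** (multi-gene insertion/deletion polymorphisms): agglomerative
  clustering, Ward linkage on Euclidean distance, with the cluster count set
  to the number of diploid classes having at least one nearest individual
  (capped by the class count). Each cluster is assigned the diploid class
  nearest its centroid; ties break toward lower total copy number, then
  lexicographic label. Ward is chosen because CN clusters are compact and
  roughly spherical at multiplicative noise; degenerate all-identical input
  collapses to one cluster with a warning.
- **round** (high-copy single-group sets): the diploid total is snapped to
  the nearest valid class sum (so noise cannot push calls outside the
  configured range), because the per-haplotype split of, say, 13 copies is
  not identifiable from depth; the balanced decomposition ⌈d/2⌉ gives the
  minimal possible largest haploid count, and relative abundances for these
  sets are distributions over diploid totals.

Regional distribution tests use the asymptotic chi-squared goodness-of-fit
against the global class distribution even at small regional n (warning
emitted when an expected count is below 5), flagging at p < 0.01 by default.
R² between groups is the squared Pearson correlation of estimate columns;
constant columns are reported NaN and excluded from averages. An
`exclude_groups` blocklist drops segments with anomalous coverage profiles
from CNV calling.

## Phasing and allele calling

The phaser is a deliberately simplified stand-in for a mapping + variant
calling + read-backed phasing chain, valid in the synthetic regime
(substitutions only, no indels). Pileup columns with two base states each
holding ≥ 20% of covering reads are heterozygous; more than two such states
is an ambiguity error. Phasing is greedy by position: mate reads share a
fragment id and vote jointly for state pairings; a site with no linkage to
previously phased sites gets a deterministic alphabetical phase and the
segment is flagged. Flagged segments are excluded from cohort calling by
default, because their arbitrary phase fabricates recurring chimeric
haplotypes that the two-individual rule cannot remove (the phase error
repeats identically across individuals). Uncovered positions render as `N`,
flag the segment truncated, and never count as mutations.

Matching minimizes substitutions against the group's alleles over the shared
prefix; equidistant candidates resolve to the lexicographically smallest
name with the tie recorded. Mutation amino acids compare the reference codon
with the codon carrying only that substitution. Names append `(P)` when any
alternative amino acid is a stop and `(T)` when the reconstruction is
truncated. The ≥2-individual rule counts distinct individuals (a homozygote
is one individual, two haplotypes); frequencies are over called haplotypes
per group. SNVs apply the same ≥2-individual rule per base state.

## Population statistics

- Pairwise bp difference: distinct called alleles, unweighted, over the
  shared prefix, as a percentage; averaged per segment then unweighted over
  segments (a frequency-weighted mode exists behind a flag). Segments with
  fewer than two called alleles are skipped with a warning.
- SNPs per segment divides total SNP positions by the full designated
  two-copy list, including zero-SNP segments.
- Private variants: every carrier from one region; regional frequency is
  carrier haplotypes over twice the region size.
- FST: Weir & Cockerham (1984) θ on haplotype allele counts, per allele and
  locus via the one-way ANOVA moments (MSP, MSG, n_c), combined as a ratio
  of sums over alleles and loci. Regions with fewer than two haplotypes at a
  locus drop out of that locus; monomorphic data leave θ undefined rather
  than zero.
- The KS comparison of allele-count distributions uses the asymptotic
  p-value by default (exact mode available).
- The segment-set difference probability counts unordered individual pairs
  whose present-segment sets differ, overall and per region.

## Population structure

The allele copy matrix encodes haplotype calls as 0/1/2 per allele column;
uncalled haplotypes contribute zero, leaving the per-segment row sum below 2
as a missingness signal (a complete-case mode can be had by filtering the
calls first). Metric MDS runs SMACOF initialized from the classical-scaling
(principal coordinates) solution plus seeded random restarts, keeping the
lowest-stress solution; the PCoA start makes exactly embeddable
configurations (e.g. a 3-4-5 triangle) reproduce their distances to machine
precision and the fixed seed makes embeddings deterministic. Regional
separation is the mean silhouette over embedded coordinates.

## Synthetic cohort

The generator draws, per individual: a region (fixed regional sizes,
defaulting to a seven-region worldwide panel of 286), a DNA source
(blood/saliva/cell-line at 0.25/0.13/0.62, so ~38% of individuals survive
the IGHV blood-and-saliva filter), a genome coverage (Gaussian, mean 42×,
sd 5, floored at 1), two independent haploid variants per polymorphism from
regional frequencies, and two alleles per two-copy group from regional
allele frequencies. Diploid copy number is the sum of the haploid draws.
Observed group coverage is `(CN/2) · genome_cov · (1 + N(0, cv))` truncated
at zero — multiplicative Gaussian noise with cv defaulting to 0.05 (noise is
not modelled mechanistically; this form degrades cluster separation smoothly,
which is what the calling stage must tolerate). Coverage is emitted in k-mer
units (100-bp reads, 21-mers) so the estimation chain is exercised end to
end and inverts exactly at cv = 0.

Reads for two-copy groups are paired-end: fragment starts uniform, lengths
Gaussian (mean 250, sd 60) clipped to [read length, template length], two
mates per fragment, i.i.d. substitution errors. Novel alleles are planted by
mutating database alleles at configured positions, with planted codons making
the headline names hand-checkable (`IGHV1-18*01_ag168ND`,
`TRBV10-1*02_gt234E_(P)`, `TRBV12-5*01_cg27HD`); each locus also plants one
region-private novel allele and one region-private database allele. The
synthetic reference mirrors real locus structure: 297-bp stop-free segments,
near-identical duplicate pairs and a chained four-member family for IGHV,
45 two-copy TRBV groups (50 groups in all), and one pseudogene per locus.

Not emulated: indels and structural breakpoints within segments, realistic
error profiles and quality scores, GC/mappability bias, linkage between
polymorphisms (off by default because measured correlations are negligible),
and the VDJ-truncation of cell-line IGHV (represented only through the DNA
source filter). Passing tests therefore demonstrate correctness of the
statistical machinery under a faithful abstraction of the data, not
robustness to alignment artifacts or assembly errors in real reads.

## Problem sizes and determinism

The default full run is 286 individuals over ~50 groups (TRBV shape), which
completes in a few minutes on one CPU; tests use cohorts of 40–200
individuals except for one full-size end-to-end check. All randomness flows
from one root seed (simulation from the config seed; read simulation and MDS
from fixed offsets of the pipeline seed), and reruns with the same
configuration are byte-identical for the deterministic stages. Pipeline
aborts remove partial outputs and name the failing stage.
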