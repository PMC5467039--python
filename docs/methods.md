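# Methods

## Overview

editml detects A-to-I RNA editing from coordinate-sorted RNA-seq alignments
in five stages: stranded pileup, minimal-evidence candidate extraction,
optional genotype filtering against matched DNA variants, 28-feature
extraction, and logistic-regression scoring with an adjustable confidence
threshold. A synthetic read generator with planted truth provides the
training and evaluation substrate.

## Pileup policies

Observations are retained when base quality >= 20 and mapping quality >= 20
(both configurable). Duplicate, secondary, supplementary and QC-fail records
are excluded. Overlapping mate pairs are counted once: the samtools overlap
correction zeroes the lower-quality mate base, which the base-quality filter
then removes (this requires `min_baseq >= 1`). Deletions and reference skips
contribute no observation. Coordinates are 0-based half-open internally;
1-based only in VCF and the calls TSV. There is no realignment step and no
indel calling.

## Candidate extraction

A candidate needs >= 3 variant reads, editing level >= 0.1 and coverage
>= 10 by default. The 0.1 level floor matches the lowest editing level the
classifier is trained on; the read-support defaults follow common practice
for editing detection and are configurable. All substitution types are
retained — the type is a feature, not a filter, and non-A-to-I candidates
are exactly what the negative training classes contain. Multi-allelic
columns yield one candidate (the most frequent non-reference allele; ties
broken A < C < G < T). Genotype filtering removes candidates at DNA-variant
positions regardless of allele: a genomic variant at the site undermines the
editing interpretation either way. dbSNP-style bulk removal is deliberately
not a hard filter (SNPs are a classifier class); it can be emulated by
passing a dbSNP VCF as the DNA-variant input.

## The 28 features

The fixed order is serialized with every model; scoring refuses mismatched
feature lists rather than silently reordering. Class 1 (3): variant reads,
coverage, editing level. Class 2 (13): mean MAPQ of variant reads and of all
reads, mean base quality of variant observations, mean and population SD of
the variant observations' relative read positions (measured in original read
orientation, in [0, 1]), fraction of variant observations within 5 bases of
a read end, two-sided Fisher-exact strand-bias p-value on the ref/alt x
strand table (all-zero table defined as p = 1), fraction of variant reads on
the + strand, simple-repeat membership, homopolymer run length at the site,
mean mismatch count (NM) and mean soft-clip fraction of variant reads, and a
near-splice flag (any overlapping read has an N-gap junction within 4
bases). Class 3 (12): A>G, T>C and A-to-I (= either) flags, Alu membership,
and 5'/3' neighbor one-hots read in reference orientation (all-zero group at
a contig edge, with a logged warning).

Choices worth noting: strand bias is a p-value rather than a ratio for
boundedness; the 5-base read-end and 4-base splice windows are conventional
artifact windows and configurable; no transcript-strand inference is
attempted — A>G and T>C are treated symmetrically as putative A-to-I.
Features are passed raw to the classifier; standardization (per-feature
location/scale) is learned at training time, inside each CV fold, and stored
in the model document.

## Training

Positives carry provenance `consensus-validated` or `two-method-validated`;
negatives come from seven per-criterion filter-fail pools, an
aligner-discordant pool, a SNP pool and an unvalidated pool. With the
canonical pool sizes (7x150 + 300 + 1200 + 375) the negative set has 2925
members; with 1475 positives the full set has 4400 examples at a ~1:2 mix.
All positives are kept; negatives are sampled per pool with a fixed seed,
and a site appearing in several pools keeps its first-listed provenance.

The classifier is logistic regression (liblinear) with positive-class weight
2.0. Model selection maximizes mean cross-validated F0.5 — the
precision-weighted F-measure, chosen because false positives are costlier
than false negatives in editing catalogs — over {L1, L2} x 7 regularization
strengths log-spaced in [1e-3, 1e3], with stratified five-fold CV. The
winning configuration is refit on all examples. The model document (JSON) is
versioned and human-readable: feature names, scaling, weights, intercept,
hyperparameters, seed and CV metadata.

## Evaluation conventions

ROC area equals the positive-negative pairwise-comparison probability with
ties counting one half. The PR area uses the step-wise convention in which
precision is held from the next-ranked point (average precision), so the
number is reproducible bit-for-bit. The cross-platform validation rate
counts a passing call as assessable when the second platform covers it with
>= 20 retained observations (>= 15 when assembling training positives, where
a larger positive set is worth a slightly laxer gate) and as validated when
the same substitution has >= 3 supporting observations there; rates are
reported overall and per coverage stratum.

## The synthetic generator

The generator emulates the study design, not a full transcriptome. A
reference genome is i.i.d. with configurable GC (default 0.41,
human-genome-like). Editing events sit on reference A (annotated + strand,
A>G) or T (annotated -, T>C); levels are `0.1 + 0.9 * Beta(1, 3)` (floor
0.1, median ~0.29), reflecting the low-skewed level distribution of real
editomes. SNPs are heterozygous with probability 2/3 (expressed allele
fraction 0.5) else homozygous (1.0), with the alt base uniform over the
three alternatives — substitution types are uniform over the 12 ordered
pairs rather than transition-biased, a simplicity choice. Reads are
single-end, uniformly placed, strand-random, and emitted pre-aligned with
exact placement (no aligner). At every event each overlapping read draws the
alt base independently with probability equal to the allele fraction, so
observed levels are binomial around the planted level.

Platform profiles: `illumina` (error 0.003, 100 bp, quality ~N(37, 4)) and
`proton` (error 0.012, 150 bp, quality ~N(28, 6)); both give 10% of reads a
mapping quality in [20, 50] (ambiguous placements) and soft-clip 5% of reads
at one end. Error bases get their quality shifted down by 10, making errors
quality-correlated. Indels are not simulated (homopolymer-specific error
modeling is out of scope); spliced N-gap reads are available behind
`splice_prob` and off by default. Read placement and planted-allele draws
use a seed-only RNG stream while the error process uses a profile-salted
stream, so two profiles with equal read length and seed plant variants
identically but err at different positions — the property the two-platform
validation logic relies on.

Annotations: an Alu-like interval (~250-350 bp, the length of a full Alu
element) is laid over a seeded 90% of editing sites — consistent with the
large majority of human A-to-I sites falling in Alu — and the track is then
split so it never covers planted SNPs or the held-out editing sites, making
Alu membership exactly Bernoulli(0.9) over editing sites and 0 over SNPs.
Simple-repeat intervals are random and avoid all planted events. The VCF
contains exactly the planted SNPs with genotypes.

What the generator does **not** model: expression-level variation and
isoforms, aligner-induced systematic misplacement, PCR duplicates,
position-dependent error profiles, indels, and linkage between nearby
events. Passing benchmarks therefore demonstrate that the pipeline's
machinery is correct and that the classifier can learn the intended
evidence structure — not that the same AUCs would be reached on real tissue
data, where negatives are harder and annotation is noisier.

## Benchmark study conditions

The classifier benchmark (also run by `scripts/acceptance.py`) uses an 80 kb
two-contig genome, 2400 editing events, 1500 SNPs, 30x coverage on both
platforms, Alu fraction 0.9. These sizes were chosen by capacity arithmetic:
at 30x, ~85% of planted edits pass the candidate thresholds and ~90% of
those are re-observed on the validation platform, leaving comfortably more
than the 1475 positives the canonical set needs; 1500 SNPs leave > 1200
expressed SNP candidates; and the Illumina-like error rate yields several
thousand sub-threshold error columns to fill the 1050 filter-fail, 300
discordant and 375 unvalidated negative slots. The seven filter-fail
criteria are class-2 artifact rules (one-sided strand, read-end clustering
>= 0.5, positional SD < 0.05, mean variant base quality < 30, mean variant
MAPQ < 50, mean mismatches >= 2, any soft-clip), and sub-threshold sites are
assigned to the least-filled pool among those whose criterion they fail.
Positives are subsampled to 1475 (consensus first) so that every replicate
trains on exactly 4400 examples. One replicate takes ~13 s on one CPU;
five-seed averages are reported.

## Numerical and degenerate-input conventions

All randomness flows through numpy Generators seeded from user seeds;
identical seeds give byte-identical FASTA/BAM/BED/VCF outputs and identical
trained weights. Empty pileup columns, single-class training sets, and
evaluation with a single label class raise typed errors rather than
returning NaN. The all-zero strand-bias table is defined as p = 1; an
all-reference column yields no candidate; a contig-edge context yields an
all-zero one-hot group. Tie-breaks (variant allele, thresholds at equality)
are documented in the relevant docstrings and covered by tests.

## Known limitations

The feature set is a careful reconstruction of the three documented feature
classes filled out with standard artifact statistics; an external model
trained on a different 28-feature itemization will not be interchangeable
(the feature-name list in the model document guards against silent misuse).
The pileup is single-threaded. The synthetic benchmark's absolute AUC values
are tied to its generator assumptions; they are floors-checked, not
calibrated to any external dataset.
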