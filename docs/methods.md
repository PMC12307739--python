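# Methods

This note documents the models, defaults and numerical choices behind the
package, and what the synthetic cohorts do and do not demonstrate.

## Mutation catalogs and f_deam

Somatic SBS are classified into the 96 trinucleotide channels under the
universal pyrimidine-strand convention: a purine-reference call is
reverse-complemented (flanks swap and complement, substitution maps to its
complement) so every mutation has one canonical channel. Channel order is
substitution-major (C>A, C>G, C>T, T>A, T>C, T>G), then 5' base A,C,G,T,
then 3' base A,C,G,T — the COSMIC matrix row layout, so signature files
align after label matching.

f_deam is the percentage of all SBS falling in the four CpG-site C>T
channels `A[C>T]G`, `C[C>T]G`, `G[C>T]G`, `T[C>T]G` ("CG>TG" is read as
C>T with 3' neighbour G; the 5' base is free). TMB is the plain SBS count
of the catalog. As a binomial proportion, f_deam/100 carries a sampling sd
of sqrt(f(1−f)/TMB); below `min_tmb = 10` mutations the estimate is too
noisy to act on and is reported as NA rather than a number. NA is a value,
not an error, and NA samples are excluded pairwise from rank statistics
with the exclusion counted in the log.

Parsing details: soft-masked (lowercase) reference bases are uppercased;
records with ambiguity codes (N) in alleles or context are skipped with a
logged warning; indels/MNVs are skipped and tallied separately. No VAF or
depth filter is applied by default (the calls are taken as the caller
emitted them); optional `min_vaf`/`min_depth` thresholds are exposed.

## Cause-of-HRD classes and the benchmark

Classes are assigned by strict precedence H1a > H1b > H2a > H2b > H3
(deleterious BRCA1/2 > deleterious other-HR > VUS BRCA1/2 > VUS other-HR >
nothing), taking the highest class among a tumor's alterations. A
monoallelic H1a outranks a biallelic H1b: precedence is by class only, and
the allelic suffix is derived afterwards from the alterations at the
achieved class (biallelic wins). The benchmark contrasts H1a\* (biallelic
deleterious BRCA1/2, or BRCA1 promoter hypermethylation) against H3;
intermediate classes are of mixed HR status and are excluded with a
recorded reason. Unknown methylation is treated as "not hypermethylated"
for classification but kept as unknown in the record, so cohorts without
methylation data can still be benchmarked; unknown allelic status is
treated as monoallelic for the H1a\* flag (conservative: not counted as
positive). The bundled HR gene list is a placeholder of well-known
HR-pathway genes, not a clinically authoritative list; real analyses should
supply their own.

## Scar scores

Thresholds follow the scarHRD conventions: LOH counts minor-allele-zero
segments strictly longer than 15 Mb that do not span a whole chromosome;
LST counts, per chromosome arm, transitions between adjacent segments of
differing allele state with both flanks ≥ 10 Mb, after iteratively removing
segments shorter than 3 Mb and merging identical neighbours to a fixed
point; TAI counts allele-imbalanced segments touching a telomere that
neither cross nor overlap the centromere and do not span the chromosome.
"Mb" is exactly 1e6 bp; segment length is end − start + 1 on 1-based
inclusive coordinates. All thresholds are `ScarConfig` keys.

Choices where conventions vary:

* Adjacent segments with identical allele state are merged across
  coverage gaps before LOH/TAI counting — an unprobed gap (e.g. the
  centromere) is not evidence of a state change. This is what makes a
  whole-chromosome LOH split by the centromere gap correctly excluded.
* No minimum-size filter is applied to TAI (none is part of the telomeric
  imbalance definition used here); the flag to add one would be a
  one-line config change.
* Sex chromosomes are excluded by default.
* No ploidy correction of LOH is applied; `ScarConfig` is the place a
  future flag would live.
* Telomere/centromere positions come from a genome-annotation table, so
  all scores are invariant under a coordinate translation of segments and
  annotation together.

## Purity dilution model

Mixing a fraction p/q of tumor reads with 1 − p/q of matched-normal reads
turns a tumor of purity q into one of purity p. At the variant level this
is exact: normal reads carry no somatic alternate allele, so a variant with
VAF v at purity q has expected VAF v·(p/q) after dilution. Detection is
resampled per variant: depth ~ Poisson(mean_depth) (negative binomial
optional via a dispersion parameter), alt reads ~ Binomial(depth, VAF), and
the variant survives if alt ≥ `min_alt_reads` (default 3) and alt/depth ≥
`min_vaf` (default 2%). With mean depth 100 these defaults put the
detection collapse between 10% and 5% purity: at p = 0.1 (from q = 0.8) a
clonal variant has expected VAF 0.05 and is usually recovered, at p = 0.05
roughly half the variants drop out. Sequencing-error false positives are
off by default (`base_error_rate = 0`). Because detection depends only on
VAF and depth — never on the channel — dilution thins the catalog without
biasing f_deam; only its sampling noise grows as TMB shrinks.

Copy-number attenuation works on two observables per segment: the
major-allele read fraction (p·a + (1−p)) / (p·(a+b) + 2(1−p)) and the
diploid-normalized total-copy ratio (p·(a+b) + 2(1−p))/2, each with
Gaussian noise of sd `noise_sd_at_unit_depth`/sqrt(mean_depth) (defaults
0.25 and 100, i.e. sd 0.025). A segment whose observed fraction deviates
from 1/2 by more than `calling_threshold` (default 0.075) is re-called to
the integer allele state with the nearest expected (fraction, ratio) pair
at purity p, ties broken toward lower total copy number; otherwise the
imbalance is indistinguishable from balanced and the segment collapses to
(1,1). The two-observable re-call is what lets (2,0) and (1,0) be
distinguished at high purity, as BAF+logR callers do. The defaults were
chosen from the mixture formula itself: a (2,1) imbalance drops below the
calling threshold near purity 0.4 and a (2,0) LOH near purity 0.1–0.2,
which reproduces the stepwise HRDsum degradation at 40%/20%/10% purity
while leaving both signals intact at 60–80%. The balanced (2,2) state is
invisible to this model at any purity (fraction exactly 1/2), which is the
model's statement that such segments carry no allelic scar signal.

## Synthetic cohorts

The generator emulates the statistical structure the analysis consumes,
not real genomes:

* class profiles put 8% (HR-deficient) vs 25% (HR-proficient) of mass on
  the four CpG-C>T channels, the remainder uniform — the direction and
  approximate magnitude of the ovarian-cancer contrast, without claiming
  its exact shape;
* TMB ~ round(LogNormal(meanlog 4.0, sdlog 0.8)) gives a median near 55
  SBS with >90% of samples at TMB ≥ 10;
* VAFs ~ Beta(8, 12) (mean 0.4): clonal heterozygous variants at the
  default source purity q = 0.8; no subclonality is modeled;
* HRDsum targets ~ Normal(55, 15) vs Normal(20, 10), rounded and clipped
  to [0, 80], split uniformly across LOH/LST/TAI; the clip is the planting
  capacity of the 44-arm synthetic genome (22 autosomes, lengths 240..60
  Mb, centromere at 40%);
* scar events are planted on disjoint chromosome arms with buffer
  segments sized so events cannot interact (an LOH block cannot create an
  LST, a TAI block cannot create an LOH, etc.); the actually-planted
  counts are recorded as ground truth and the scorer recovers them
  exactly — this is the generator's self-consistency oracle;
* default cohort size is 20+20, the size of a high-purity dilution
  subcohort.

What passing tests on these cohorts shows: the pipeline's statistics
recover the parameters the generator planted, at the sample sizes and
noise levels stated above. What they do not show: performance on real
tumors, where mutational processes beyond a two-component mixture, caller
artifacts, subclonality and segmentation error all act. The fixed
per-class channel profiles also mean within-class biological variance of
f_deam is understated relative to real cohorts.

## Evaluation protocol

AUC is the Mann-Whitney concordance probability (ties counted 1/2) after
orienting scores by their stated direction — f_deam is a negative
predictor (`lower_predicts_positive`), HRDsum a positive one. The paired
DeLong test uses the structural-components covariance estimator and a
two-sided normal p; the test suite checks it against R pROC's
`roc.test(paired, method="delong")` on a shared fixture (agreement to
1e-6 on the p-value). Cutpoints maximize balanced
accuracy by exhaustive search over midpoints of adjacent distinct scores
plus sentinels beyond the range; balanced-accuracy ties break toward
higher sensitivity. Calling conventions at the fixed clinical cutpoints:
HRD-positive iff f_deam < 13.1 (strict), HRD-positive iff HRDsum ≥ 42 —
both configurable, since boundary inclusion is a convention. The
96-channel differential analysis normalizes counts by TMB, tests each
channel with the two-sided Wilcoxon rank-sum (exact when the combined
sample is ≤ 50 and tie-free, normal approximation with continuity
correction otherwise) and adjusts across the 96 tests with
Benjamini-Hochberg at FDR 5%. Cohen's kappa uses marginal-product expected
agreement, defined as 0 when a call vector is constant (p_o = p_e
algebraically). Degenerate inputs fail loudly: single-class label sets,
mismatched sample sets, and sub-minimal group sizes raise validation
errors rather than returning numbers.

## Problem sizes and reproducibility

Test and acceptance runs use cohorts of 20–300 samples per class, 200–500
replicate catalogs for sampling-law checks, 20 replicate cohorts for the
purity asymmetry, and a 10000-resample paired bootstrap as the independent
check on DeLong's test (enough resamples to keep the oracle's own
Monte-Carlo error well below the comparison tolerance). Every stochastic
component takes a `numpy.random.Generator` or an integer seed; identical
config + seed reproduces cohorts, experiment tables and pipeline JSON
byte-for-byte.

## Known limitations

* The purity model treats all variants as clonal and all segments as
  independently observed; no segmentation error or caller-specific
  behaviour is modeled.
* The HR gene list shipped for classification is a placeholder.
* The CG>TG content of real COSMIC signatures depends slightly on the
  genome build of the supplied matrix; the package records only what it is
  given (see `data/cosmic/README.md`).
* Scar scoring assumes allele-specific copy numbers are already called;
  deriving them from BAF/logR or reads is out of scope.
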