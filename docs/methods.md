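# Methods

## Splice-site usage

A splice-site is anchored at the 1-based genomic coordinate of its
intron-terminal base (the G of the donor GT, the G of the acceptor AG);
relative positions run along the transcribed strand, intronic side positive
for donors and negative for acceptors. Usage is the empirical proportion
SSE = α/(α+β), where α counts junction reads splicing at the site and β all
other reads crossing its position (continuous spanning reads plus junction
reads splicing past it). This is a deliberately simple estimator: the
partner-weighted refinement of β used by dedicated junction quantifiers is
out of scope, so absolute usage values here are interpretable as raw
crossing-read fractions. A site/sample cell is missing, never zero, when no
read crosses.

Filtering retains a site when at least `min_genotypes` (default 100)
genotypes have `min_replicates` (3) replicates each with `min_reads` (10)
crossing reads; per-genotype usage is the mean over passing replicates,
requiring `min_passing` (2). Replicate-free cohorts set both replicate
thresholds to 1. Strata (sexes, tissues) are averaged separately.
Raising any threshold can only shrink the retained set (tested as a
monotonicity property). Missing genotypes are dropped from a site's
statistics, not imputed.

## Variability, heritability, site selection

Per site we report the range (max − min of per-genotype usage), the sample
variance, and — with replication — broad-sense heritability from one-way
ANOVA with genotype as the factor: σ²g = (MS_between − MS_within)/r̄, r̄ the
harmonic mean of per-genotype replicate counts, H² = σ²g/(σ²g+σ²e) clamped
to [0,1]. Genotypes need ≥ 2 passing replicates to enter; without any
replication H² is undefined and site selection falls back to variance
alone. Mappable sites are the intersection of the top variance and top H²
quartiles (quartiles computed on coverage-filtered sites only, matching the
order of operations of the quantification stage) with ≥ 100 observed
genotypes.

Note the binomial sampling term: observed usage variance is
σ²g + σ²e + p(1−p)/n for crossing depth n, so H² estimates approach the
σ²g/(σ²g+σ²e) target only at depth where p(1−p)/n is negligible. The
heritability recovery study therefore uses depth 200 with noise SDs of
0.15, where the binomial term biases H² down by only ~0.02.

## Association mapping

The engine is per-variant ordinary least squares of per-genotype usage on
dosage (0/1 inbred calls or 0/1/2 diploid), two-sided t-test on the slope,
p floored at 1e-300. This is a documented simplification of a mixed-model
engine: population structure can be handled by supplying a kinship matrix,
whose leading eigenvectors (default 5) are projected out of phenotype and
dosages before the fits. The engine choice is recorded in the run manifest.
Variants are filtered at minor allele frequency ≥ 0.05 (the boundary is
inclusive), computed on the analyzed individuals.

Peak calling groups significant variants (default threshold: Bonferroni
0.05/#variants, logged) within a 100 kb merge window per chromosome and
drops peaks with fewer than `min_peak_snps` members (50 for dense real
panels; simulations with unlinked variants use 1 since without LD a causal
signal is a single SNP). The noise gate takes the five lowest-p variants
genome-wide such that no two lie within 750 kb (peak members included —
whether to exclude them is unspecified in the procedure this follows, and
including them is the stricter choice), and requires the peak top SNP's
−log10 p to be ≥ 1.33× their mean. Top-SNP ties resolve to the member
nearest the site. The top SNP is classified cis iff it lies on the same
chromosome within 1 Mb; different chromosomes are trans by definition.
ΔSSE is the allele-count-weighted mean usage of minor-allele carriers minus
major-allele carriers (equal to the OLS slope up to sign for binary
dosage); PVE uses the standard single-SNP formula from effect size,
standard error, allele frequency and sample size.

## Position-wise nucleotide effects

Per-position analyses use donor windows −3..+7 and acceptor windows −7..+3.
The variance partition statistic is (TSS − RSS)/TSS with TSS the total sum
of squares of site usage and RSS the within-base sum; 0 by convention when
TSS = 0. Pairwise interactions compare the observed mean usage of a
(position, base)×(position, base) class with the additive expectation
grand + (m₁ − grand) + (m₂ − grand), capped to [0,1] before differencing;
site/sequence combinations are down-sampled to a configurable cap (default
2 million) with a seeded draw. Outliers among sorted deviations are called
by the elbow rule: the curve is normalized to the unit square (the two axes
have different units, so rank and value are each scaled to [0,1] — the
scaling is a design choice), each tail's elbow is the point farthest from
the chord joining the curve midpoint to that extreme, and the threshold is
the elbow value pushed outward by a conservative buffer of 0.1.

Splice-promoting/reducing nucleotides are inferred from associations whose
top SNP lies within 100 bp of its site, deduplicated so each SNP informs
only its closest site (ties: donor before acceptor, then lower coordinate —
an arbitrary but deterministic rule; ties are vanishingly rare). The allele
whose carriers use the site more (sign of the slope, equivalently of ΔSSE)
is promoting; each association votes once, unweighted by effect size, and
the modal base per relative position forms the profile. Best/worst
synthetic introns concatenate donor-side positions 0..49 with acceptor-side
−49..0, force GT/AG anchors and a branch-point adenosine 25 bp from the 3'
end, and fill positions beyond the profile's support from the per-position
mean-usage best/worst bases (association profiles only cover the
splice-site's vicinity, while the construct spans 100 bp). Optional
modifications overwrite the 3' region with a polypyrimidine tract and/or a
consensus branch point, or replace the terminal hexamers with the top-ranked
table entries.

## Hexamer ranking and choice explanation

k-mers are intron-anchored: donors GT + (k−2) intronic bases, acceptors
(k−2) bases + AG, k ∈ [2,8], so the key space is 4^(k−2). A site's strength
is its mean usage across genotypes (within-site first, then across sites,
to avoid coverage weighting; single-sample datasets use site values
directly); a key's strength is the mean over its sites, ranked descending
with ties broken by site count then lexicographically. Keys never observed
used are absent from tables, not zero-filled.

The choice statistic scans ±window (default 100, 200 available) around each
used site on the transcribed strand — splicing acts on the pre-mRNA, so the
opposite strand never competes — for GT (donors) or AG (acceptors) anchors,
extracts their keys and asks whether the used site's key is the best-ranked
and occurs exactly once among the candidates ("unique" is read as
occurs-once; with unduplicated keys this coincides with a single candidate
attaining the top rank). Keys absent from the table rank below all present
keys (a "skip such windows" mode is available). Sites with another used
site of the same type within the window are excluded — their competition is
genuine, not sequence-intrinsic. The adjusted percentage multiplies the raw
success rate by the fraction of possible keys observed; this multiplicative
reading penalizes long k-mers whose key space is mostly unobserved and
reproduces the k = 6 optimum, and the raw rate is always reported alongside
so alternative adjustments can be inspected.

p-distance between equal-length keys is the mismatch fraction (a metric);
profiles group keys by distance from a reference (GTAAGT for donors — the
U1 snRNA pairing consensus — and the strongest acceptor hexamer) and report
per-group mean strength and its correlation with distance. Cross-dataset
comparisons use squared Spearman correlations of ranks on ≥ 10 shared keys,
with the sign reported separately. Occurrence profiling partitions every
anchored k-mer occurrence in gene bodies into used-as-splice-site vs not
and correlates each partition's proportions with key strength.

Competing-pair analysis (two-donor minigene constructs): the winner is the
higher-usage site; a pair is explained when the winner's key has the higher
table strength; SSE or strength ties are excluded from both numerator and
denominator. Fractions are reported overall and stratified at a strength
gap of 0.25. The null shuffles the strength-to-key assignment (default
10,000 permutations, seeded, bit-reproducible) and reports its upper
quantile as the threshold.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, with
usage determined entirely by the intron-terminal hexamer through a strength
map (the default map decays with p-distance from GTAAGT/TTGCAG plus seeded
jitter, mirroring the observed consensus-distance gradient). Genes with
exons of 120–180 bp and introns of 150–300 bp (long enough that a ±100 bp
window never contains two annotated same-type sites) are laid on two
chromosomes on both strands; hexamers are drawn proportional to strength by
default — mirroring the observed strength–frequency correlation — with a
uniform mode for designs needing balanced per-hexamer counts. Genotypes are
inbred 0/1 panels by default (0/1/2 diploid available); a configured
fraction of sites receives one variant inside its hexamer whose alternate
allele switches the hexamer and hence the true strength, the rest is
neutral background outside hexamer footprints. Counts per site, genotype
and replicate draw a crossing total from a negative binomial (mean =
depth, dispersion θ = 10 — the depth distribution of real data is
unreported, so the dispersion is a free parameter — giving var = μ + μ²/θ)
and supporting reads from Binomial(n, clamp(truth + genotype effect +
replicate noise, 0, 1)); the genotype effect is shared across a genotype's
replicates, which is what makes broad-sense heritability identifiable.
Noise is additive on the probability scale and clamped — the simplest model
consistent with bounded usage. Minigene constructs carry two donors ≥ 6 bp
apart; reads split by sigmoid((s_A − s_B)/temperature + noise), with
temperature 0 the deterministic limit and ∞ a fair coin.

What the generator does **not** emulate: linkage disequilibrium (each
variant segregates independently, so simulated peaks are single SNPs and
peak-calling runs with `min_peak_snps=1`), alignment and mapping artifacts,
expression differences between genes, trans-regulatory networks beyond the
optional single-variant multiplicative effects, overlapping genes, and
non-canonical (U12-type) splice-sites. Passing recovery tests therefore
demonstrates the correctness of the statistical machinery under the model's
assumptions, not robustness to those real-data complications.

## Problem sizes and determinism

The bundled studies use 20 sites × 200 genotypes for causal-variant
recovery, 100 genotypes × 4 replicates at depth 200 for heritability, 3,000
donor sites for the k-mer sweep (10 seeded runs), 60 hexamers × 30 sites
for ranking recovery, and 2,000 pairs × 10,000 permutations for the
minigene null — sizes at which every recovery margin is wide while the full
suite runs in well under a minute. All randomness flows through
`numpy.random.default_rng` seeded from explicit (seed, stream) pairs, so
identical configurations produce byte-identical outputs, including written
FASTA/VCF/BED files and permutation thresholds.
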