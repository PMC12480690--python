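# splicehex

Tools for explaining **splice-site choice** from RNA-seq junction counts:
empirical splice-site usage quantification, heritability-gated per-site
genome-wide association with bespoke peak calling and cis/trans
classification, position-wise nucleotide effect analysis, and intronic
hexamer strength ranking with a "percentage of splice-site choices
explained" statistic — plus a synthetic-data generator that plants all of
the above as known ground truth.

It is written for transcriptomics researchers who want to treat individual
donor (GT...) and acceptor (...AG) splice-sites — not isoforms, exon
inclusion events or intron clusters — as quantitative molecular phenotypes.

## The quantities it computes

**Splice-site usage (SSE).** For a site with `α` junction reads splicing at
it and `β` other reads crossing its position,

    SSE = α / (α + β)  ∈ [0, 1]

missing where nothing crosses. Sites are kept when covered by ≥ 10 reads in
≥ 3 replicates of ≥ 100 genotypes, and usage is averaged per genotype over
replicates (all thresholds configurable; replicate-free cohorts use 1).

**Broad-sense heritability.** One-way ANOVA with genotype as factor:
σ²g = (MS_between − MS_within)/r̄ with r̄ the harmonic-mean replicate count,
and H² = σ²g/(σ²g + σ²e) clamped to [0, 1]. Sites in the top quartile of
both variance and H² (variance only, without replicates) go to GWAS.

**Per-site GWAS.** Usage ~ dosage per variant (MAF ≥ 0.05, optional
kinship pre-whitening), peaks called by merging significant SNPs with a
minimum member count, gated by requiring the top SNP's −log10 p to exceed
1.33× the mean of the five best mutually spread-out (>750 kb) SNPs in the
plot. Top SNPs are placed on a strand-normalized axis (position 0 = the
intron-terminal G), classified **cis** within 1 Mb (different chromosome =
trans), and summarised by ΔSSE (minor- minus major-allele mean usage) and
PVE = 2β²f(1−f) / (2β²f(1−f) + se²·2N·f(1−f)).

**Hexamer ranking and choice explanation.** Sites are grouped by their
intron-terminal hexamer (GT[N]₄ donors, [N]₄AG acceptors; ≤ 256 keys each),
ranked by mean usage. For every used site, all GT/AG-anchored k-mers within
±100 bp on the transcribed strand compete; a choice is *explained* when the
site's k-mer is the unique best-ranked candidate. The success rate times
the share of possible k-mers observed gives the adjusted percentage, which
peaks at hexamers (k = 6). Competing-donor minigene libraries are scored
the same way against a 10,000-shuffle permutation null.

## Worked example

`examples/03_hexamer_ranking.py` simulates a 3,000-donor transcriptome
whose true usage is exactly hexamer-determined, ranks the hexamers and
sweeps the k-mer length:

```
strongest donor hexamers (rank, key, n_sites, mean usage):
    1  GTAAGT    98  0.976
    2  GTCAGT    45  0.524
    3  GTAGGT    50  0.508
   k-mer length sweep (donor sites):
   n_tested  raw_rate  possible_fraction  adjusted_percent
4      3000     0.114              1.000            11.367
5      3000     0.179              1.000            17.867
6      3000     0.237              0.914            21.694
7      3000     0.242              0.745            18.057
8      3000     0.272              0.435            11.820
best length: k=6
correlation of hexamer strength with p-distance from GTAAGT
(the U1 snRNA pairing consensus): -0.91
```

The raw success rate rises with k (longer k-mers are easier to be unique),
but the adjustment for unobserved key space pulls k = 7, 8 down — the
hexamer is the optimum. `examples/02_map_splice_qtl.py` plants one
hexamer-switching SNP at each of 20 donor sites (200 genotypes, MAF 0.25,
usage gap 0.5) and recovers the causal variant as the cis top SNP of a
passing peak at 100% of sites. The other examples cover quantification and
heritability (01), the minigene permutation analysis (04), and
position-wise nucleotide effects with best/worst synthetic introns (05).

A thin CLI mirrors the pipeline:
`splicehex {simulate, sse, gwas, seqfx, hexrank, run}` (see `--help`).

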