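"""Predefined simulation studies with planted ground truth.

Each function wires the generator, the quantification and one analysis into
a self-contained experiment and returns the measured quantities next to the
planted truth, so that recovery can be assessed.  The study conditions
(sample sizes, depths, noise levels, effect sizes) are fixed by design; the
seed only moves the random draws.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from . import assoc, hexrank, sse, synthio
from .genome import DONOR

log = logging.getLogger(__name__)


def heritability_study(n_genotypes: int = 100, replicates: int = 4,
                       depth: float = 200.0, noise_sd: float = 0.15,
                       n_sites: int = 60, seed: int = 0) -> pd.Series:
    """Equal genotype and replicate noise: H-squared should centre on 0.5.

    Sites have true usage 0.5; genotype_sd == residual_sd so the
    between-genotype share of the (pre-binomial) variance is exactly one
    half.  Returns the per-site heritability estimates.
    """
    config = synthio.SynthConfig(
        n_genotypes=n_genotypes, replicates_per_genotype=replicates,
        read_depth_mean=depth, genotype_sd=noise_sd, residual_sd=noise_sd,
        seed=seed)
    individuals = [f"g{i:04d}" for i in range(n_genotypes)]
    truth = pd.DataFrame(0.5, index=[f"s{i:03d}" for i in range(n_sites)],
                         columns=individuals)
    matrix = synthio.simulate_junction_counts(truth, config)
    return sse.broad_sense_heritability(matrix)


def _spaced_hexamers(rng, keys: list[str], n: int, min_distance: int = 2) -> list[str]:
    """Greedily pick n keys pairwise differing at >= min_distance positions."""
    picked: list[str] = []
    for key in rng.permutation(keys):
        if all(sum(a != b for a, b in zip(key, q)) >= min_distance for q in picked):
            picked.append(str(key))
        if len(picked) == n:
            return picked
    raise RuntimeError(f"could not pick {n} spaced hexamers")


def causal_recovery_study(n_sites: int = 20, n_genotypes: int = 200,
                          maf: float = 0.25, strength_gap: float = 0.5,
                          depth: float = 50.0, replicates: int = 3,
                          n_background: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Plant one hexamer-switching SNP per donor site and map it back.

    Every donor carries a causal variant inside its hexamer whose alternate
    allele moves the true usage by ``strength_gap``.  Each site's GWAS runs
    genome-wide over the causal variants plus neutral background; the study
    reports, per site, whether the causal SNP is the top SNP of a passing
    peak and how its top association classifies.
    """
    rng = np.random.default_rng([seed, 0xEE])
    model = synthio.TrueStrengthModel.distance_decay(seed=seed)
    donors = _spaced_hexamers(rng, list(synthio.DONOR_HEXAMERS), n_sites)
    config = synthio.SynthConfig(
        n_genes=n_sites, introns_per_gene=1, n_genotypes=n_genotypes,
        replicates_per_genotype=replicates, read_depth_mean=depth,
        genotype_sd=0.03, residual_sd=0.03, causal_fraction=1.0,
        causal_maf_range=(maf, maf), seed=seed,
        donor_hexamers=tuple(donors), hexamer_weighting="uniform")
    genome, sites = synthio.generate_genome(config, model)
    variants, dosages = synthio.simulate_genotypes(config, sites, genome,
                                                   n_background=n_background)
    # force the planted strength gap: reference hexamer strong, alternate weak
    causal = variants.dropna(subset=["causal_site"])
    causal = causal[sites.loc[causal["causal_site"], "site_type"].to_numpy() == DONOR]
    hi, lo = 0.5 + strength_gap / 2, 0.5 - strength_gap / 2
    for _, v in causal.iterrows():
        site = sites.loc[v.causal_site]
        ref_hex = site.hexamer
        rel = int(v.rel_offset)
        alt_t = v.alt if site.strand == "+" else synthio.complement(v.alt)
        alt_hex = ref_hex[:rel] + alt_t + ref_hex[rel + 1:]
        model.donor_map[ref_hex] = hi
        model.donor_map[alt_hex] = lo
    truth = synthio.true_sse(sites, model, genome, variants, dosages)
    matrix = synthio.simulate_junction_counts(truth, config, sites)
    phenotypes = sse.genotype_average(matrix, min_passing=2)
    gmat = assoc.GenotypeMatrix(variants=variants, dosages=dosages)

    rows = []
    for _, v in causal.iterrows():
        site_id = v.causal_site
        rec = assoc.map_site(phenotypes.loc[site_id], gmat, sites.loc[site_id],
                             site_id=site_id, min_peak_snps=1)
        causal_vid = causal.index[causal["causal_site"] == site_id][0]
        rows.append({"site_id": site_id, "causal_variant": causal_vid,
                     "mapped": rec is not None,
                     "top_snp": rec["top_snp"] if rec else None,
                     "recovered": bool(rec and rec["top_snp"] == causal_vid),
                     "cis_trans": rec["cis_trans"] if rec else None,
                     "delta_sse": rec["delta_sse"] if rec else np.nan,
                     "pve": rec["pve"] if rec else np.nan})
    return pd.DataFrame(rows).set_index("site_id")


def hexamer_transcriptome(n_donor_sites: int = 3000, depth: float = 80.0,
                          n_genotypes: int = 4, noise_sd: float = 0.02,
                          seed: int = 0):
    """A transcriptome whose true usage is exactly hexamer-determined.

    Returns (genome, donor sites, per-site mean usage, strength model).
    """
    config = synthio.SynthConfig(
        n_genes=(n_donor_sites + 1) // 2, introns_per_gene=2,
        n_genotypes=n_genotypes, replicates_per_genotype=1,
        read_depth_mean=depth, genotype_sd=noise_sd, residual_sd=noise_sd,
        seed=seed)
    model = synthio.TrueStrengthModel.distance_decay(seed=seed)
    genome, sites = synthio.generate_genome(config, model)
    truth = synthio.true_sse(sites, model, genome,
                             individuals=[f"g{i:04d}" for i in range(n_genotypes)])
    matrix = synthio.simulate_junction_counts(truth, config, sites)
    strength = sse.genotype_average(matrix, min_passing=1).mean(axis=1).dropna()
    donors = sites[sites["site_type"] == DONOR]
    donors = donors.loc[donors.index.intersection(strength.index)]
    return genome, donors, strength, model


def kmer_length_sweep(ks=(4, 5, 6, 7, 8), window: int = 100, seed: int = 0,
                      **transcriptome_kwargs) -> pd.DataFrame:
    """Adjusted percent of donor choices explained across k-mer lengths."""
    genome, donors, strength, _ = hexamer_transcriptome(seed=seed,
                                                        **transcriptome_kwargs)
    rows = []
    for k in ks:
        table = hexrank.strength_table(donors, strength, genome, k=k)
        res = hexrank.choice_explained(genome, donors, table, k=k, window=window)
        rows.append({"k": k, "n_tested": res.n_sites_tested,
                     "raw_rate": res.raw_rate,
                     "possible_fraction": res.possible_fraction,
                     "adjusted_percent": res.adjusted_percent})
    return pd.DataFrame(rows).set_index("k")


def planted_ranking_study(n_hexamers: int = 60, sites_per_hexamer: int = 30,
                          depth: float = 60.0, seed: int = 0) -> float:
    """Spearman correlation between recovered hexamer strengths and the
    planted donor map, at >= ``sites_per_hexamer`` sites per hexamer."""
    rng = np.random.default_rng([seed, 0xF1])
    model = synthio.TrueStrengthModel.distance_decay(seed=seed)
    chosen = list(rng.choice(list(synthio.DONOR_HEXAMERS), size=n_hexamers,
                             replace=False))
    n_sites = n_hexamers * sites_per_hexamer
    config = synthio.SynthConfig(
        n_genes=(n_sites + 1) // 2, introns_per_gene=2, n_genotypes=4,
        replicates_per_genotype=1, read_depth_mean=depth,
        genotype_sd=0.02, residual_sd=0.02, seed=seed,
        donor_hexamers=tuple(chosen), hexamer_weighting="uniform")
    genome, sites = synthio.generate_genome(config, model)
    truth = synthio.true_sse(sites, model, genome,
                             individuals=[f"g{i:04d}" for i in range(4)])
    matrix = synthio.simulate_junction_counts(truth, config, sites)
    strength = sse.genotype_average(matrix, min_passing=1).mean(axis=1).dropna()
    donors = sites[sites["site_type"] == DONOR]
    donors = donors.loc[donors.index.intersection(strength.index)]
    table = hexrank.strength_table(donors, strength, genome, k=6)
    counts = table.set_index("key")["n_sites"]
    log.info("min sites per hexamer: %d", counts.min())
    truth_vals = table["key"].map(model.donor_map)
    return float(stats.spearmanr(table["mean_sse"], truth_vals).statistic)


def null_minigene_study(n_pairs: int = 2000, n_perm: int = 10_000,
                        seed: int = 0) -> hexrank.CompetingPairResult:
    """Coin-flip winners: the explained fraction should sit inside the
    permutation null's central interval around one half."""
    model = synthio.TrueStrengthModel.distance_decay(seed=seed)
    pairs = synthio.simulate_minigene_library(
        model, n_constructs=n_pairs, temperature=np.inf, seed=seed)
    table = pd.DataFrame({"key": list(model.donor_map),
                          "mean_sse": list(model.donor_map.values())})
    table["n_sites"] = 1
    table = table.sort_values("mean_sse", ascending=False, ignore_index=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return hexrank.competing_pair_analysis(pairs, table, n_perm=n_perm,
                                           seed=seed)


def minigene_recovery_study(n_pairs: int = 2000, temperature: float = 0.2,
                            noise_sd: float = 0.3, n_perm: int = 2000,
                            seed: int = 0) -> hexrank.CompetingPairResult:
    """Strength-driven winners: explained fraction should beat the null,
    and pairs with a strength gap > 0.25 should be explained more often."""
    model = synthio.TrueStrengthModel.distance_decay(seed=seed)
    pairs = synthio.simulate_minigene_library(
        model, n_constructs=n_pairs, temperature=temperature,
        noise_sd=noise_sd, seed=seed)
    table = pd.DataFrame({"key": list(model.donor_map),
                          "mean_sse": list(model.donor_map.values())})
    table["n_sites"] = 1
    table = table.sort_values("mean_sse", ascending=False, ignore_index=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return hexrank.competing_pair_analysis(pairs, table, n_perm=n_perm,
                                           seed=seed)
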