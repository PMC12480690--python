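"""k-mer tables, window-scan choice explanation, distances, competing pairs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splicehex import hexrank, scenarios, synthio
from splicehex.genome import ACCEPTOR, DONOR

from oracles import naive_choice_explained


def test_possible_kmer_counts():
    assert hexrank.n_possible_kmers(4) == 16
    assert hexrank.n_possible_kmers(6) == 256
    assert hexrank.n_possible_kmers(8) == 4096
    with pytest.raises(ValueError):
        hexrank.n_possible_kmers(9)


def site(chrom, pos, strand, stype):
    return pd.Series({"chrom": chrom, "position": pos, "strand": strand,
                      "site_type": stype})


def test_extract_kmer_plus_strand(toy_genome):
    assert hexrank.extract_site_kmer(toy_genome, site("chr1", 6, "+", DONOR)) == "GTAAGC"
    assert hexrank.extract_site_kmer(toy_genome, site("chr1", 20, "+", ACCEPTOR)) == "TTACAG"
    assert hexrank.extract_site_kmer(toy_genome, site("chr1", 6, "+", DONOR), k=2) == "GT"


def test_extract_kmer_minus_strand_reverse_complement(toy_genome):
    assert hexrank.extract_site_kmer(toy_genome, site("chr2", 8, "-", DONOR)) == "GTAAGC"


def test_extract_kmer_applies_substitutions(toy_genome):
    got = hexrank.extract_site_kmer(toy_genome, site("chr1", 6, "+", DONOR),
                                    substitutions={("chr1", 8): "C"})
    assert got == "GTCAGC"
    # minus strand: forward-strand substitution complements into the k-mer
    got = hexrank.extract_site_kmer(toy_genome, site("chr2", 8, "-", DONOR),
                                    substitutions={("chr2", 6): "G"})
    assert got == "GTCAGC"


def test_strength_table_means_and_ties(toy_genome):
    sites = pd.DataFrame({
        "chrom": ["chr1", "chr2", "chr1"],
        "position": [6, 8, 6],
        "strand": ["+", "-", "+"],
        "site_type": [DONOR] * 3,
    }, index=pd.Index(["a", "b", "c"], name="site_id"))
    strength = pd.Series([0.6, 0.8, np.nan], index=sites.index)
    table = hexrank.strength_table(sites, strength, toy_genome, k=6)
    assert len(table) == 1
    assert table.iloc[0]["key"] == "GTAAGC"
    assert table.iloc[0]["n_sites"] == 2
    assert table.iloc[0]["mean_sse"] == pytest.approx(0.7)
    # tie-break: equal strength ranks by site count, then lexicographic
    t = pd.DataFrame({"key": ["GTCC", "GTAA", "GTGG"], "n_sites": [5, 5, 9],
                      "mean_sse": [0.4, 0.4, 0.4]})
    t2 = t.sort_values(["mean_sse", "n_sites", "key"],
                       ascending=[False, False, True], ignore_index=True)
    assert list(t2["key"]) == ["GTGG", "GTAA", "GTCC"]


def test_strength_table_row_bound(small_cohort):
    from splicehex import sse as sse_mod

    strength = sse_mod.genotype_average(small_cohort["matrix"],
                                        min_passing=2).mean(axis=1).dropna()
    sites = small_cohort["sites"]
    donors = sites[sites.site_type == DONOR]
    table = hexrank.strength_table(donors.loc[donors.index.intersection(strength.index)],
                                   strength, small_cohort["genome"], k=6)
    assert len(table) <= 256
    assert sorted(table["rank"]) == list(range(1, len(table) + 1))


def test_choice_explained_unique_best(toy_genome):
    # single eligible donor whose hexamer is the only table entry -> success
    sites = pd.DataFrame({"chrom": ["chr1"], "position": [6], "strand": ["+"],
                          "site_type": [DONOR]},
                         index=pd.Index(["a"], name="site_id"))
    table = pd.DataFrame({"key": ["GTAAGC"], "n_sites": [1],
                          "mean_sse": [0.9], "rank": [1]})
    res = hexrank.choice_explained(toy_genome, sites, table, k=6, window=10)
    assert (res.n_sites_tested, res.n_success) == (1, 1)
    assert res.adjusted_percent == pytest.approx(100 / 256)


def test_choice_explained_duplicate_key_fails():
    # the used site's hexamer occurs twice in the window -> uniqueness fails
    genome = {"c": "A" * 30 + "GTAAGC" + "TTTT" + "GTAAGC" + "A" * 30}
    sites = pd.DataFrame({"chrom": ["c"], "position": [31], "strand": ["+"],
                          "site_type": [DONOR]},
                         index=pd.Index(["a"], name="site_id"))
    table = pd.DataFrame({"key": ["GTAAGC"], "n_sites": [1],
                          "mean_sse": [0.9], "rank": [1]})
    res = hexrank.choice_explained(genome, sites, table, k=6, window=20)
    assert (res.n_sites_tested, res.n_success) == (1, 0)


def test_choice_explained_excludes_nearby_used_sites():
    genome = {"c": "A" * 30 + "GTAAGC" + "T" * 10 + "GTCCGC" + "A" * 30}
    sites = pd.DataFrame({"chrom": ["c", "c"], "position": [31, 47],
                          "strand": ["+", "+"], "site_type": [DONOR, DONOR]},
                         index=pd.Index(["a", "b"], name="site_id"))
    table = pd.DataFrame({"key": ["GTAAGC", "GTCCGC"], "n_sites": [1, 1],
                          "mean_sse": [0.9, 0.1], "rank": [1, 2]})
    res = hexrank.choice_explained(genome, sites, table, k=6, window=100)
    assert res.n_sites_tested == 0


def test_choice_explained_matches_naive_oracle():
    genome, donors, strength, _ = scenarios.hexamer_transcriptome(
        n_donor_sites=260, seed=17)
    sample = donors.sample(n=220, random_state=0)
    for k in (4, 6, 8):
        table = hexrank.strength_table(donors, strength, genome, k=k)
        res = hexrank.choice_explained(genome, sample, table, k=k, window=100)
        tested, success = naive_choice_explained(genome, sample, table, k, 100)
        assert (res.n_sites_tested, res.n_success) == (tested, success)


def test_rank_correlation_identity_and_reversal(model):
    t = pd.DataFrame({"key": list(model.donor_map)[:40],
                      "mean_sse": np.linspace(0.9, 0.1, 40)})
    t["rank"] = np.arange(1, 41)
    r2, sign = hexrank.rank_correlation(t, t)
    assert r2 == pytest.approx(1.0) and sign == 1
    rev = t.assign(rank=t["rank"].to_numpy()[::-1])
    r2, sign = hexrank.rank_correlation(t, rev)
    assert r2 == pytest.approx(1.0) and sign == -1
    small = t.head(5)
    r2, sign = hexrank.rank_correlation(small, small)
    assert np.isnan(r2) and sign == 0


def test_rank_correlation_noisy_replicates(model):
    # one planted truth, two independent count draws
    import dataclasses

    from splicehex import sse as sse_mod

    base = synthio.SynthConfig(n_genes=300, introns_per_gene=2, n_genotypes=4,
                               replicates_per_genotype=1, read_depth_mean=80,
                               genotype_sd=0.02, residual_sd=0.02, seed=31)
    genome, sites = synthio.generate_genome(base, model)
    truth = synthio.true_sse(sites, model, genome,
                             individuals=[f"g{i}" for i in range(4)])
    donors = sites[sites.site_type == DONOR]
    tables = {}
    for seed in (31, 32):
        cfg = dataclasses.replace(base, seed=seed)
        matrix = synthio.simulate_junction_counts(truth, cfg, sites)
        strength = sse_mod.genotype_average(matrix, min_passing=1).mean(axis=1)
        tables[seed] = hexrank.strength_table(donors, strength.dropna(),
                                              genome, k=6)
    r2, sign = hexrank.rank_correlation(tables[31], tables[32])
    assert sign == 1 and r2 > 0.8
    mat = hexrank.rank_correlation_matrix(tables)
    assert mat.loc[31, 31] == 1.0
    assert mat.loc[31, 32] == mat.loc[32, 31] == pytest.approx(r2)


def test_p_distance_values():
    assert hexrank.p_distance("GTAAGT", "GTAAGT") == 0
    assert hexrank.p_distance("GTAAGT", "GTCAGT") == pytest.approx(1 / 6)
    with pytest.raises(ValueError):
        hexrank.p_distance("GT", "GTA")


def test_p_distance_is_a_metric():
    rng = np.random.default_rng(8)
    keys = ["".join(p) for p in itertools.product("ACGT", repeat=3)]
    for _ in range(300):
        a, b, c = rng.choice(keys, 3)
        dab = hexrank.p_distance(a, b)
        assert dab == hexrank.p_distance(b, a)
        assert (dab == 0) == (a == b)
        assert dab <= hexrank.p_distance(a, c) + hexrank.p_distance(c, b) + 1e-12


def test_p_distance_profile_recovers_decay(model):
    table = pd.DataFrame({"key": list(model.donor_map),
                          "mean_sse": list(model.donor_map.values())})
    prof, corr = hexrank.p_distance_profile(table, "GTAAGT")
    assert corr < -0.9  # strengths decay away from the consensus
    assert prof["distance"].min() == 0
    assert prof.loc[prof["distance"].idxmin(), "mean_strength"] > \
        prof.loc[prof["distance"].idxmax(), "mean_strength"]


def test_occurrence_profile_partitions():
    genome, donors, strength, _ = scenarios.hexamer_transcriptome(
        n_donor_sites=1000, seed=23)
    table = hexrank.strength_table(donors, strength, genome, k=6)
    genes = (donors.groupby("gene_id")
             .agg(chrom=("chrom", "first"), start=("gene_start", "first"),
                  end=("gene_end", "first"), strand=("strand", "first"))
             .reset_index())
    prof, corr = hexrank.occurrence_profile(genome, genes, donors, table)
    # every annotated donor hexamer is found and counted as used
    used_total = prof["used"].sum()
    assert used_total == len(donors)
    assert (prof["used"] + prof["unused"] > 0).all()
    # strength-weighted placement: used proportions track strength better
    assert corr["used_proportion"] > corr["unused_proportion"]


def make_table(mapping):
    t = pd.DataFrame({"key": list(mapping), "mean_sse": list(mapping.values())})
    t["n_sites"] = 1
    t = t.sort_values("mean_sse", ascending=False, ignore_index=True)
    t["rank"] = np.arange(1, len(t) + 1)
    return t


def test_competing_pairs_concordant_discordant():
    table = make_table({"GTAAGT": 0.7, "GTCCCC": 0.2, "GTGGGG": 0.5})
    pairs = pd.DataFrame({
        "hexamer_a": ["GTAAGT", "GTCCCC", "GTAAGT"],
        "hexamer_b": ["GTCCCC", "GTAAGT", "GTGGGG"],
        "sse_a": [0.9, 0.9, 0.5],
        "sse_b": [0.1, 0.1, 0.5],  # last pair ties on SSE -> excluded
    })
    res = hexrank.competing_pair_analysis(pairs, table, n_perm=100, seed=0)
    assert res.n_pairs == 2
    assert res.explained_fraction == pytest.approx(0.5)


def test_competing_pairs_null_calibrated():
    res = scenarios.null_minigene_study(n_pairs=800, n_perm=2000, seed=5)
    lo, hi = res.central_interval
    assert lo <= res.explained_fraction <= hi
    assert abs(res.explained_fraction - 0.5) < 0.06


def test_competing_pairs_threshold_reproducible():
    a = scenarios.null_minigene_study(n_pairs=300, n_perm=500, seed=7)
    b = scenarios.null_minigene_study(n_pairs=300, n_perm=500, seed=7)
    assert a.threshold == b.threshold
    assert np.array_equal(a.null_fractions, b.null_fractions)


def test_competing_pairs_signal_beats_null():
    res = scenarios.minigene_recovery_study(n_pairs=1500, n_perm=1000, seed=9)
    assert res.explained_fraction > res.threshold
    by_gap = res.by_gap.set_index("gap_bin")
    assert by_gap.loc["> 0.25", "explained_fraction"] > \
        by_gap.loc["<= 0.25", "explained_fraction"]


def test_hexamer_adjustment_penalizes_extreme_k():
    # hexamer-determined truth: k=6 beats the shorter k=4 (coarser groups)
    # and the longer k=8 (mostly unobserved key space) after adjustment
    sweep = scenarios.kmer_length_sweep(ks=(4, 6, 8),
                                        n_donor_sites=1500, seed=3)
    best = sweep.loc[6, "adjusted_percent"]
    assert best > sweep.loc[4, "adjusted_percent"]
    assert best > sweep.loc[8, "adjusted_percent"]
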