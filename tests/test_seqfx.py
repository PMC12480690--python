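"""Position-wise nucleotide effects, interactions, elbows, synthetic introns."""

import numpy as np
import pandas as pd
import pytest

from splicehex import seqfx, synthio
from splicehex.genome import ACCEPTOR, DONOR

from oracles import two_pass_proportion


def test_proportion_of_variance_examples():
    # equal group means -> 0; zero within-group variance -> 1
    assert seqfx.proportion_of_variance([1, 2, 1, 2], ["a", "a", "b", "b"]) == 0
    assert seqfx.proportion_of_variance([1, 1, 2, 2], ["a", "a", "b", "b"]) == 1
    got = seqfx.proportion_of_variance([0.2, 0.4, 0.6, 0.8],
                                       ["A", "A", "G", "G"])
    assert got == pytest.approx(0.8)


def test_proportion_of_variance_matches_two_pass_oracle():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = rng.integers(6, 40)
        values = rng.uniform(0, 1, n)
        labels = rng.choice(list("ACGT"), n)
        if len(set(labels)) < 2:
            continue
        assert seqfx.proportion_of_variance(values, labels) == pytest.approx(
            two_pass_proportion(values, labels), abs=1e-12)


def test_proportion_of_variance_degenerate():
    assert seqfx.proportion_of_variance([0.5, 0.5, 0.5], ["a", "b", "a"]) == 0.0
    with pytest.raises(ValueError):
        seqfx.proportion_of_variance([1.0, 2.0], ["a", "a"])


@pytest.fixture(scope="module")
def donor_context():
    """Six donors on a toy genome with known window bases."""
    rng = np.random.default_rng(3)
    seqs, sites = [], []
    offset = 0
    chrom_parts = []
    for i in range(6):
        pad = "".join(rng.choice(list("ACGT"), 20))
        core = "GTAAGT" if i % 2 else "GTCCGT"
        chrom_parts.append(pad + core)
        pos = offset + 21
        sites.append({"site_id": f"d{i}", "chrom": "c", "position": pos,
                      "strand": "+", "site_type": DONOR, "gene_id": f"g{i}"})
        offset += 26
    chrom_parts.append("A" * 20)
    genome = {"c": "".join(chrom_parts)}
    return genome, pd.DataFrame(sites).set_index("site_id")


def test_position_nucleotide_means(donor_context):
    genome, sites = donor_context
    strength = pd.Series([0.2, 0.8, 0.2, 0.8, 0.2, 0.8], index=sites.index)
    prof = seqfx.position_nucleotide_means(sites, genome, strength,
                                           windows={DONOR: (0, 5)})
    at3 = prof[(prof.position == 2)]
    # A at +2 only in the strong sites, C only in the weak ones
    assert at3[at3.base == "A"].mean_sse.iloc[0] == pytest.approx(0.8)
    assert at3[at3.base == "C"].mean_sse.iloc[0] == pytest.approx(0.2)
    assert at3[at3.base == "G"].mean_sse.isna().all()
    assert at3[at3.base == "A"].best_base.iloc[0] == "A"
    # counts at any position sum to the number of scored sites
    assert prof.groupby("position").n_sites.sum().eq(6).all()


def test_pairwise_interactions_additive_and_cap():
    # deterministic contexts: base at p0 and p1 shift the mean additively
    rng = np.random.default_rng(1)
    n = 4000
    b0 = rng.choice(["A", "G"], n)
    b1 = rng.choice(["C", "T"], n)
    y = 0.5 + np.where(b0 == "A", -0.1, 0.1) + np.where(b1 == "C", -0.05, 0.05)
    ctx = pd.DataFrame({0: b0, 1: b1}, index=[f"s{i}" for i in range(n)])
    recs = seqfx.pairwise_interactions(ctx, pd.Series(y, index=ctx.index),
                                       max_combinations=None)
    assert np.abs(recs.deviation).max() < 0.02  # additive data: no deviation
    # cap rule: expectation cannot leave [0, 1]
    y2 = np.where((b0 == "A") & (b1 == "C"), 0.0, np.where(b0 == "A", 0.02, 0.9))
    recs2 = seqfx.pairwise_interactions(ctx, pd.Series(y2, index=ctx.index),
                                        max_combinations=None)
    assert (recs2.expected >= 0).all() and (recs2.expected <= 1).all()


def test_pairwise_interactions_planted_epistasis():
    rng = np.random.default_rng(2)
    n = 6000
    b0 = rng.choice(list("ACGT"), n)
    b1 = rng.choice(list("ACGT"), n)
    y = 0.4 + rng.normal(0, 0.01, n)
    y = np.where((b0 == "A") & (b1 == "G"), y + 0.3, y)
    ctx = pd.DataFrame({-1: b0, 3: b1}, index=[f"s{i}" for i in range(n)])
    recs = seqfx.pairwise_interactions(ctx, pd.Series(np.clip(y, 0, 1),
                                                      index=ctx.index),
                                       max_combinations=None)
    recs = recs.set_index(["base1", "base2"])
    planted = recs.loc[("A", "G"), "deviation"]
    others = recs.drop(index=("A", "G"))["deviation"]
    # the naive additive expectation spreads the planted shift across the
    # marginal means, so the pair deviation is attenuated but dominant
    assert planted > 0.15
    assert planted > np.abs(others).max() + 0.1


def test_elbow_outliers_flags_single_extreme():
    rng = np.random.default_rng(4)
    dev = pd.Series(rng.normal(0, 0.01, 99).tolist() + [0.5])
    flagged = seqfx.elbow_outliers(dev, buffer=0.1)
    assert flagged.sum() == 1 and bool(flagged.iloc[-1])


def test_elbow_outliers_buffer_and_degenerate():
    assert not seqfx.elbow_outliers(pd.Series([0.0] * 10)).any()
    rng = np.random.default_rng(5)
    dev = pd.Series(rng.normal(0, 0.01, 99).tolist() + [0.08])
    # beyond the elbow but within the 0.1 buffer -> not flagged
    assert not seqfx.elbow_outliers(dev, buffer=0.1).iloc[-1]
    with pytest.raises(ValueError):
        seqfx.elbow_outliers(pd.Series([0.1, 0.2]))


def test_infer_promoting_nucleotides_rules():
    sites = pd.DataFrame({
        "chrom": ["c", "c"], "position": [100, 500], "strand": ["+", "-"],
        "site_type": [DONOR, DONOR], "gene_id": ["g1", "g2"],
    }, index=pd.Index(["s1", "s2"], name="site_id"))
    assoc_table = pd.DataFrame({
        "site_id": ["s1", "s1", "s2"],
        "top_snp": ["v1", "v2", "v3"],
        "distance": [3, 150, 4],  # 150 bp association must be excluded
        "beta": [0.2, 0.2, -0.3],
        "ref": ["A", "A", "C"], "alt": ["G", "G", "T"],
    })
    prof = seqfx.infer_promoting_nucleotides(assoc_table, sites)
    row3 = prof[(prof.position == 3)].iloc[0]
    assert row3.promoting_base == "G" and row3.reducing_base == "A"
    # minus-strand SNP: beta<0 means the (transcribed) ref base promotes
    row4 = prof[(prof.position == 4)].iloc[0]
    assert row4.promoting_base == "G"  # complement of forward C
    assert row4.reducing_base == "A"  # complement of forward T
    assert 150 not in set(prof.position)


def test_promoting_profile_recovery_from_planted_truth():
    # many associations per position, each voting for the planted best base
    rng = np.random.default_rng(6)
    planted = {p: rng.choice(list("ACGT")) for p in range(-2, 7)}
    sites, rows = [], []
    for i in range(200):
        pos = int(rng.integers(-2, 7))
        site_id = f"s{i}"
        sites.append({"site_id": site_id, "chrom": "c", "position": 1000 + i * 300,
                      "strand": "+", "site_type": DONOR, "gene_id": f"g{i}"})
        best = planted[pos]
        other = rng.choice([b for b in "ACGT" if b != best])
        promoted_is_alt = bool(rng.integers(0, 2))
        rows.append({"site_id": site_id, "top_snp": f"v{i}", "distance": pos,
                     "beta": 0.2 if promoted_is_alt else -0.2,
                     "ref": other if promoted_is_alt else best,
                     "alt": best if promoted_is_alt else other})
    prof = seqfx.infer_promoting_nucleotides(
        pd.DataFrame(rows), pd.DataFrame(sites).set_index("site_id"))
    prof = prof[prof.n_support >= 5]
    for _, r in prof.iterrows():
        assert r.promoting_base == planted[r.position]


def make_profile():
    rows = []
    for p in range(0, 7):
        rows.append({"site_type": DONOR, "position": p, "promoting_base": "A",
                     "reducing_base": "G", "n_support": 10})
    for p in range(-6, 1):
        rows.append({"site_type": ACCEPTOR, "position": p, "promoting_base": "T",
                     "reducing_base": "C", "n_support": 10})
    return pd.DataFrame(rows)


def test_build_synthetic_intron_contracts():
    prof = make_profile()
    best = seqfx.build_synthetic_intron(prof, "best")
    worst = seqfx.build_synthetic_intron(prof, "worst")
    for seq in (best, worst):
        assert len(seq) == 100
        assert seq.startswith("GT") and seq.endswith("AG")
        assert "A" in seq[60:95]  # branch-point adenosine present
    gc = lambda s: (s.count("G") + s.count("C")) / len(s)
    assert gc(worst) > 0.5 > gc(best)  # reducing profile is GC-biased here


def test_build_synthetic_intron_modifications(model):
    from splicehex import hexrank

    prof = make_profile()
    tables = {}
    for stype, mapping in ((DONOR, model.donor_map),
                           (ACCEPTOR, model.acceptor_map)):
        t = pd.DataFrame({"key": list(mapping), "mean_sse": list(mapping.values())})
        t["n_sites"] = 1
        t = t.sort_values("mean_sse", ascending=False, ignore_index=True)
        t["rank"] = np.arange(1, len(t) + 1)
        tables[stype] = t
    seq = seqfx.build_synthetic_intron(prof, "worst",
                                       modifications={"ppt", "strong_hexamers"},
                                       strength_tables=tables)
    assert seq[:6] == tables[DONOR].iloc[0]["key"]
    assert seq[-6:] == tables[ACCEPTOR].iloc[0]["key"]
    ppt = seq[80:94]
    assert sum(b in "CT" for b in ppt) == len(ppt)
    with pytest.raises(ValueError):
        seqfx.build_synthetic_intron(prof, "best", modifications={"bogus"})
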