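"""Intronic k-mer strength tables, rankings and splice-site choice analysis.

Splice-sites are grouped by their intron-anchored k-mer (donor: GT plus the
next k-2 intronic bases; acceptor: k-2 intronic bases ending in AG), the
average usage of each k-mer across the sites carrying it defines its
strength, and k-mers are ranked by strength.  The "percentage of splice-site
choices explained" statistic asks, for every used site, whether its k-mer is
the unique best-ranked one among all candidate GT/AG occurrences within a
+/-window on the transcribed strand, adjusting the success rate by the share
of possible k-mers actually observed at splice-sites.  The module also
provides p-distance profiling against a reference k-mer, cross-table rank
correlations, used/unused occurrence profiling in gene bodies, and the
competing-pair permutation analysis for two-donor minigene libraries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import ACCEPTOR, DONOR, revcomp, transcribed_window

log = logging.getLogger(__name__)


def n_possible_kmers(k: int) -> int:
    """Number of possible intron-anchored k-mers: 4**(k-2)."""
    if not 2 <= k <= 8:
        raise ValueError("k must lie in [2, 8]")
    return 4 ** (k - 2)


def extract_site_kmer(genome: dict[str, str], site, k: int = 6,
                      substitutions: dict | None = None) -> str | None:
    """The intron-anchored k-mer of a site on its transcribed strand.

    ``substitutions`` optionally maps (chrom, 1-based pos) to an alternate
    forward-strand base, applied before extraction (an individual's alleles).
    Returns None when the window leaves the contig.
    """
    if not 2 <= k <= 8:
        raise ValueError("k must lie in [2, 8]")
    chrom, position, strand = site["chrom"], int(site["position"]), site["strand"]
    if site["site_type"] == DONOR:
        lo, hi = 0, k - 1
    else:
        lo, hi = -(k - 1), 0
    if substitutions:
        g0 = position + lo if strand == "+" else position - hi
        g1 = position + hi if strand == "+" else position - lo
        seq = genome[chrom]
        if g0 < 1 or g1 > len(seq):
            return None
        window = list(seq[g0 - 1:g1])
        for (c, p), base in substitutions.items():
            if c == chrom and g0 <= p <= g1:
                window[p - g0] = base
        fwd = "".join(window)
        return fwd if strand == "+" else revcomp(fwd)
    return transcribed_window(genome, chrom, position, strand, lo, hi)


def strength_table(sites: pd.DataFrame, site_strength: pd.Series,
                   genome: dict[str, str], k: int = 6,
                   site_type: str | None = None) -> pd.DataFrame:
    """Average strength and rank of every observed k-mer of one site type.

    Site strength is the per-site mean SSE (averaged across genotypes first,
    so every site counts once); a k-mer's strength is the mean over its
    sites.  Rank 1 is strongest; ties break to larger n_sites then
    lexicographic key.  Sites whose extracted k-mer violates the GT/AG
    anchor are excluded (annotation/genome mismatch, logged).
    """
    if site_type is None:
        types = sites["site_type"].unique()
        if len(types) != 1:
            raise ValueError("pass sites of a single type or site_type=...")
        site_type = types[0]
    sub = sites[sites["site_type"] == site_type]
    strengths: dict[str, list] = {}
    n_flagged = 0
    for site_id, row in sub.iterrows():
        y = site_strength.get(site_id, np.nan)
        if pd.isna(y):
            continue
        key = extract_site_kmer(genome, row, k)
        if key is None:
            continue
        anchored = key.startswith("GT") if site_type == DONOR else key.endswith("AG")
        if not anchored:
            n_flagged += 1
            continue
        strengths.setdefault(key, []).append(float(y))
    if n_flagged:
        log.warning("%d sites had non-canonical %s k-mers and were excluded",
                    n_flagged, site_type)
    rows = [{"key": key, "n_sites": len(vals), "mean_sse": float(np.mean(vals))}
            for key, vals in strengths.items()]
    table = pd.DataFrame(rows, columns=["key", "n_sites", "mean_sse"])
    if table.empty:
        table["rank"] = []
        return table
    table = table.sort_values(["mean_sse", "n_sites", "key"],
                              ascending=[False, False, True],
                              ignore_index=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table.attrs["site_type"] = site_type
    table.attrs["k"] = k
    return table


def window_candidates(genome: dict[str, str], site, k: int, window: int) -> list[tuple[int, str]]:
    """All candidate (relative position, k-mer) anchors within +/-window.

    Candidates are GT occurrences (donors) or AG occurrences (acceptors) on
    the transcribed strand whose full k-mer fits in the contig; the relative
    position is that of the anchor's intron-terminal base.
    """
    stype = site["site_type"]
    lo, hi = -window, window
    seq = transcribed_window(genome, site["chrom"], int(site["position"]),
                             site["strand"], lo - (k + 1), hi + (k + 1))
    pad = 0
    if seq is None:  # fall back to a clipped window near contig ends
        chrom_len = len(genome[site["chrom"]])
        pos = int(site["position"])
        if site["strand"] == "+":
            g0 = max(1, pos + lo - (k + 1))
            g1 = min(chrom_len, pos + hi + (k + 1))
            seq = genome[site["chrom"]][g0 - 1:g1]
            pad = (pos + lo - (k + 1)) - g0
        else:
            g0 = max(1, pos - hi - (k + 1))
            g1 = min(chrom_len, pos - lo + (k + 1))
            seq = revcomp(genome[site["chrom"]][g0 - 1:g1])
            pad = g1 - (pos - lo + (k + 1))
    out = []
    offset0 = lo - (k + 1) - pad  # relative position of seq[0]
    if stype == DONOR:
        for i in range(len(seq) - k + 1):
            if seq[i] == "G" and seq[i + 1] == "T":
                rel = offset0 + i
                if lo <= rel <= hi:
                    out.append((rel, seq[i:i + k]))
    else:
        for i in range(k - 1, len(seq)):
            if seq[i - 1] == "A" and seq[i] == "G":
                rel = offset0 + i
                if lo <= rel <= hi:
                    out.append((rel, seq[i - k + 1:i + 1]))
    return out


@dataclass
class ChoiceResult:
    """Outcome of the window-scan choice-explanation statistic."""

    k: int
    window: int
    n_sites_tested: int
    n_success: int
    possible_fraction: float

    @property
    def raw_rate(self) -> float:
        return self.n_success / self.n_sites_tested if self.n_sites_tested else np.nan

    @property
    def adjusted_percent(self) -> float:
        return self.raw_rate * self.possible_fraction * 100


def choice_explained(genome: dict[str, str], sites: pd.DataFrame,
                     table: pd.DataFrame, k: int = 6, window: int = 100,
                     absent_policy: str = "worst") -> ChoiceResult:
    """Fraction of used sites whose k-mer is the strongest and unique
    candidate in its +/-window, adjusted by the observed k-mer share.

    Sites with another used site of the same type within ``window`` bp are
    excluded (their competition is real, not sequence-intrinsic).  Keys
    absent from the strength table rank below every present key
    (``absent_policy='worst'``); with ``'skip'`` such windows are dropped.
    """
    if absent_policy not in ("worst", "skip"):
        raise ValueError("absent_policy must be 'worst' or 'skip'")
    types = sites["site_type"].unique()
    if len(types) != 1:
        raise ValueError("pass sites of a single type")
    ranks = dict(zip(table["key"], table["rank"]))
    worst = len(ranks) + 1
    n_tested = n_success = 0
    by_chrom = {c: g["position"].to_numpy() for c, g in sites.groupby("chrom")}
    for _, site in sites.iterrows():
        positions = by_chrom[site["chrom"]]
        near = np.abs(positions - site["position"]) <= window
        if near.sum() > 1:  # another used site of this type in the window
            continue
        cands = window_candidates(genome, site, k, window)
        rels = [rel for rel, _ in cands]
        if 0 not in rels:
            raise RuntimeError("used site missing from its own candidate set")
        keys = [key for _, key in cands]
        if absent_policy == "skip" and any(key not in ranks for key in keys):
            continue
        n_tested += 1
        kranks = [ranks.get(key, worst) for key in keys]
        best = min(kranks)
        best_keys = [key for key, kr in zip(keys, kranks) if kr == best]
        site_key = keys[rels.index(0)]
        if len(best_keys) == 1 and ranks.get(site_key, worst) == best:
            n_success += 1
    possible_fraction = len(ranks) / n_possible_kmers(k)
    return ChoiceResult(k=k, window=window, n_sites_tested=n_tested,
                        n_success=n_success, possible_fraction=possible_fraction)


def rank_correlation(table_a: pd.DataFrame, table_b: pd.DataFrame,
                     min_shared: int = 10):
    """Squared Spearman correlation of two k-mer rankings on shared keys.

    Returns (r_squared, sign of the underlying correlation); (nan, 0) with a
    warning when fewer than ``min_shared`` keys are shared.
    """
    merged = table_a.merge(table_b, on="key", suffixes=("_a", "_b"))
    if len(merged) < min_shared:
        log.warning("only %d shared keys; rank correlation undefined", len(merged))
        return np.nan, 0
    rho = stats.spearmanr(merged["rank_a"], merged["rank_b"]).statistic
    return float(rho ** 2), int(np.sign(rho))


def rank_correlation_matrix(tables: dict[str, pd.DataFrame],
                            min_shared: int = 10) -> pd.DataFrame:
    """Symmetric matrix of squared rank correlations across datasets."""
    names = list(tables)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r2, _ = rank_correlation(tables[a], tables[b], min_shared)
            out.loc[a, b] = out.loc[b, a] = r2
    return out


def p_distance(a: str, b: str) -> float:
    """Proportion of mismatching positions between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b)) / len(a)


def p_distance_profile(table: pd.DataFrame, reference: str):
    """Group k-mers by p-distance from ``reference`` and average strengths.

    Returns (per-group DataFrame, Pearson correlation of distance vs group
    mean strength).
    """
    dist = table["key"].map(lambda key: p_distance(key, reference))
    grp = table.assign(distance=dist).groupby("distance")
    prof = pd.DataFrame({"n_keys": grp.size(),
                         "mean_strength": grp["mean_sse"].mean()}).reset_index()
    corr = (float(stats.pearsonr(prof["distance"], prof["mean_strength"]).statistic)
            if len(prof) > 1 else np.nan)
    return prof, corr


def occurrence_profile(genome: dict[str, str], genes: pd.DataFrame,
                       sites: pd.DataFrame, table: pd.DataFrame,
                       k: int = 6) -> tuple[pd.DataFrame, dict]:
    """Used vs unused occurrences of each k-mer in gene bodies.

    ``genes`` needs chrom, start, end (1-based inclusive) and strand.  Every
    GT/AG-anchored k-mer occurrence on the transcribed strand is tallied as
    used when its anchor coincides with a used splice-site of that type.
    Returns the per-key table joined to mean strength plus the Pearson
    correlations of the used and unused occurrence proportions with strength.
    """
    site_type = table.attrs.get("site_type", DONOR)
    used_positions = {(r.chrom, int(r.position))
                      for _, r in sites[sites["site_type"] == site_type].iterrows()}
    counts: dict[str, list] = {}
    for _, g in genes.iterrows():
        seq = genome[g.chrom][int(g.start) - 1:int(g.end)]
        if g.strand == "-":
            seq = revcomp(seq)
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if site_type == DONOR:
                if not kmer.startswith("GT"):
                    continue
                off = i  # transcribed offset of the anchor G
            else:
                if not kmer.endswith("AG"):
                    continue
                off = i + k - 1
            if g.strand == "+":
                pos = int(g.start) + off
            else:
                pos = int(g.end) - off
            used = (g.chrom, pos) in used_positions
            cell = counts.setdefault(kmer, [0, 0])
            cell[0 if used else 1] += 1
    rows = [{"key": key, "used": u, "unused": nu} for key, (u, nu) in counts.items()]
    prof = pd.DataFrame(rows).merge(table[["key", "mean_sse"]], on="key", how="left")
    tot_used = max(prof["used"].sum(), 1)
    tot_unused = max(prof["unused"].sum(), 1)
    prof["used_proportion"] = prof["used"] / tot_used
    prof["unused_proportion"] = prof["unused"] / tot_unused
    ok = prof["mean_sse"].notna()
    corr = {}
    for col in ("used_proportion", "unused_proportion"):
        if ok.sum() > 2 and prof.loc[ok, col].nunique() > 1:
            corr[col] = float(stats.pearsonr(prof.loc[ok, col],
                                             prof.loc[ok, "mean_sse"]).statistic)
        else:
            corr[col] = np.nan
    return prof, corr


@dataclass
class CompetingPairResult:
    """Explained fractions and the permutation null for competing pairs."""

    n_pairs: int
    n_excluded: int
    explained_fraction: float
    by_gap: pd.DataFrame
    null_fractions: np.ndarray
    threshold: float
    central_interval: tuple[float, float]


def competing_pair_analysis(pairs: pd.DataFrame, table: pd.DataFrame,
                            gap_threshold: float = 0.25, n_perm: int = 10_000,
                            upper_quantile: float = 0.95,
                            seed: int = 0) -> CompetingPairResult:
    """Fraction of competing pairs whose winner carries the stronger k-mer.

    ``pairs`` needs hexamer_a/hexamer_b and sse_a/sse_b columns; the winner
    is the higher-SSE site and a pair is explained when the winner's k-mer
    has the higher table strength.  Pairs with an SSE or strength tie are
    excluded.  The null shuffles the strength-to-key assignment ``n_perm``
    times; ``threshold`` is the null's ``upper_quantile`` and
    ``central_interval`` its central 99% range.
    """
    strength = dict(zip(table["key"], table["mean_sse"]))
    keys = table["key"].to_numpy()
    values = table["mean_sse"].to_numpy()
    key_index = {key: i for i, key in enumerate(keys)}

    known = pairs[pairs["hexamer_a"].isin(strength) & pairs["hexamer_b"].isin(strength)]
    ia = known["hexamer_a"].map(key_index).to_numpy()
    ib = known["hexamer_b"].map(key_index).to_numpy()
    sse_a = known["sse_a"].to_numpy(float)
    sse_b = known["sse_b"].to_numpy(float)
    s_a, s_b = values[ia], values[ib]
    usable = (sse_a != sse_b) & (s_a != s_b) & ~np.isnan(sse_a) & ~np.isnan(sse_b)
    n_excluded = int(len(pairs) - usable.sum())
    if n_excluded:
        log.info("excluded %d tied/unknown pairs", n_excluded)
    a_wins = sse_a[usable] > sse_b[usable]
    gap = np.abs(s_a - s_b)[usable]
    explained = np.where(a_wins, s_a[usable] > s_b[usable], s_b[usable] > s_a[usable])
    frac = float(explained.mean()) if len(explained) else np.nan

    bins = pd.cut(gap, [0, gap_threshold, 1.0], labels=[f"<= {gap_threshold}",
                                                        f"> {gap_threshold}"],
                  include_lowest=True)
    by_gap = (pd.DataFrame({"gap_bin": bins, "explained": explained})
              .groupby("gap_bin", observed=False)
              .agg(n_pairs=("explained", "size"),
                   explained_fraction=("explained", "mean"))
              .reset_index())

    rng = np.random.default_rng(seed)
    iau, ibu = ia[usable], ib[usable]
    wins = a_wins
    null = np.empty(n_perm)
    for j in range(n_perm):
        perm = rng.permutation(values)
        pa, pb = perm[iau], perm[ibu]
        ok = pa != pb
        expl = np.where(wins[ok], pa[ok] > pb[ok], pb[ok] > pa[ok])
        null[j] = expl.mean() if len(expl) else np.nan
    threshold = float(np.quantile(null, upper_quantile))
    interval = (float(np.quantile(null, 0.005)), float(np.quantile(null, 0.995)))
    return CompetingPairResult(n_pairs=int(usable.sum()), n_excluded=n_excluded,
                               explained_fraction=frac, by_gap=by_gap,
                               null_fractions=null, threshold=threshold,
                               central_interval=interval)
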