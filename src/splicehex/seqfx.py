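"""Position-wise nucleotide effects on splice-site usage.

Covers the per-position nucleotide means around donors and acceptors, the
(TSS - RSS)/TSS proportion-of-variance statistic, second-order (pairwise)
nucleotide interactions against a capped additive expectation with
elbow-based outlier calling, inference of splice-promoting/reducing
nucleotides from high-resolution association results, and the construction
of 100 bp best/worst synthetic introns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import ACCEPTOR, DONOR, complement, transcribed_window

log = logging.getLogger(__name__)

BASES = "ACGT"
DEFAULT_WINDOWS = {DONOR: (-3, 7), ACCEPTOR: (-7, 3)}
PROMOTING_WINDOWS = {DONOR: (-2, 6), ACCEPTOR: (-6, 2)}


def site_context_frame(sites: pd.DataFrame, genome: dict[str, str],
                       window: tuple[int, int]) -> pd.DataFrame:
    """Transcribed-strand base at each relative position, one row per site.

    Sites whose window runs off the contig are dropped (logged).
    """
    lo, hi = window
    rows, kept = [], []
    for site_id, r in sites.iterrows():
        seq = transcribed_window(genome, r.chrom, int(r.position), r.strand, lo, hi)
        if seq is None:
            log.info("site %s window extends past contig end; skipped", site_id)
            continue
        rows.append(list(seq))
        kept.append(site_id)
    return pd.DataFrame(rows, index=pd.Index(kept, name="site_id"),
                        columns=range(lo, hi + 1))


def proportion_of_variance(values, labels) -> float:
    """(TSS - RSS)/TSS for values grouped by ``labels``.

    TSS is the total sum of squares around the grand mean and RSS the sum of
    within-group sums of squares; returns 0 by convention when TSS is 0.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    ok = ~np.isnan(values)
    values, labels = values[ok], labels[ok]
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two non-empty groups")
    tss = float(np.sum((values - values.mean()) ** 2))
    if tss == 0:
        log.info("zero total variance; proportion set to 0")
        return 0.0
    rss = 0.0
    for g in np.unique(labels):
        grp = values[labels == g]
        rss += float(np.sum((grp - grp.mean()) ** 2))
    return (tss - rss) / tss


def position_nucleotide_means(sites: pd.DataFrame, genome: dict[str, str],
                              site_strength: pd.Series,
                              windows: dict | None = None) -> pd.DataFrame:
    """Mean site strength per (site_type, relative position, base), with the
    per-position proportion of variance and best base."""
    windows = windows or DEFAULT_WINDOWS
    out = []
    for stype, win in windows.items():
        sub = sites[sites["site_type"] == stype]
        if sub.empty:
            continue
        ctx = site_context_frame(sub, genome, win)
        y = site_strength.reindex(ctx.index)
        ok = y.notna()
        ctx, y = ctx[ok], y[ok]
        for pos in ctx.columns:
            col = ctx[pos]
            means = {b: y[col == b].mean() for b in BASES}
            counts = {b: int((col == b).sum()) for b in BASES}
            pov = (proportion_of_variance(y.to_numpy(), col.to_numpy())
                   if col.nunique() > 1 else 0.0)
            present = {b: m for b, m in means.items() if counts[b] > 0}
            best = max(present, key=present.get) if present else None
            for b in BASES:
                out.append({"site_type": stype, "position": pos, "base": b,
                            "mean_sse": means[b] if counts[b] else np.nan,
                            "n_sites": counts[b], "best_base": best,
                            "proportion_of_variance": pov})
    return pd.DataFrame(out)


def pairwise_interactions(ctx: pd.DataFrame, site_strength: pd.Series,
                          max_combinations: int | None = 2_000_000,
                          seed: int = 0) -> pd.DataFrame:
    """Deviation of each (position, base) pair's mean usage from the capped
    additive expectation built from the single-position means.

    ``max_combinations`` bounds the number of site/sequence combinations by
    down-sampling sites with a seeded draw.
    """
    y = site_strength.reindex(ctx.index)
    ok = y.notna()
    ctx, y = ctx[ok], y[ok]
    positions = list(ctx.columns)
    n_pairs = len(positions) * (len(positions) - 1) // 2
    if max_combinations is not None and len(ctx) * n_pairs > max_combinations:
        keep = max(2, max_combinations // n_pairs)
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(ctx), size=keep, replace=False)
        ctx, y = ctx.iloc[idx], y.iloc[idx]
    yv = y.to_numpy()
    grand = float(yv.mean())
    single = {(p, b): float(yv[(ctx[p] == b).to_numpy()].mean())
              for p in positions for b in BASES
              if (ctx[p] == b).any()}
    records = []
    for i, p1 in enumerate(positions):
        for p2 in positions[i + 1:]:
            c1, c2 = ctx[p1].to_numpy(), ctx[p2].to_numpy()
            for b1 in BASES:
                m1 = single.get((p1, b1))
                if m1 is None:
                    continue
                sel1 = c1 == b1
                for b2 in BASES:
                    m2 = single.get((p2, b2))
                    if m2 is None:
                        continue
                    sel = sel1 & (c2 == b2)
                    n = int(sel.sum())
                    if n == 0:
                        continue
                    expected = float(np.clip(grand + (m1 - grand) + (m2 - grand), 0, 1))
                    observed = float(yv[sel].mean())
                    records.append({"position1": p1, "base1": b1,
                                    "position2": p2, "base2": b2,
                                    "expected": expected, "observed": observed,
                                    "deviation": observed - expected, "n_sites": n})
    return pd.DataFrame.from_records(records)


def elbow_outliers(deviations: pd.Series, buffer: float = 0.1) -> pd.Series:
    """Flag deviations beyond the elbows of the sorted-deviation curve.

    The curve is normalized to the unit square (rank vs value); each tail's
    elbow is the point farthest from the chord joining the curve midpoint to
    that extreme, and the outlier threshold is the elbow value pushed outward
    by ``buffer``.
    """
    dev = pd.Series(deviations).astype(float)
    if len(dev) < 3:
        raise ValueError("need at least three deviations")
    order = dev.sort_values()
    vals = order.to_numpy()
    if vals[0] == vals[-1]:
        return pd.Series(False, index=dev.index)
    x = np.linspace(0, 1, len(vals))
    span = vals[-1] - vals[0]
    ynorm = (vals - vals[0]) / span
    mid = len(vals) // 2

    def elbow_value(i0, i1):
        p0 = np.array([x[i0], ynorm[i0]])
        p1 = np.array([x[i1], ynorm[i1]])
        seg = p1 - p0
        norm = np.hypot(*seg)
        lo, hi = min(i0, i1), max(i0, i1)
        px = x[lo:hi + 1] - p0[0]
        py = ynorm[lo:hi + 1] - p0[1]
        dist = np.abs(seg[0] * py - seg[1] * px) / norm
        return vals[lo + int(np.argmax(dist))]

    upper = elbow_value(mid, len(vals) - 1) + buffer
    lower = elbow_value(mid, 0) - buffer
    return (dev > upper) | (dev < lower)


def infer_promoting_nucleotides(associations: pd.DataFrame, sites: pd.DataFrame,
                                max_distance: int = 100,
                                windows: dict | None = None) -> pd.DataFrame:
    """Modal splice-promoting and splice-reducing base per relative position.

    ``associations`` needs site_id, top_snp, distance (site-normalized),
    beta (slope of SSE on alternate-allele dosage), ref and alt columns.
    Associations farther than ``max_distance`` from the site are discarded;
    each SNP informs only its closest site (ties: donors first, then the
    lower-coordinate site).  The allele whose carriers use the site more is
    the promoting base at that SNP's position, judged by the sign of beta.
    """
    windows = windows or PROMOTING_WINDOWS
    df = associations.dropna(subset=["distance"]).copy()
    df = df[df["distance"].abs() <= max_distance]
    if df.empty:
        return pd.DataFrame(columns=["site_type", "position", "promoting_base",
                                     "reducing_base", "n_support"])
    df["site_type"] = sites.loc[df["site_id"], "site_type"].to_numpy()
    df["strand"] = sites.loc[df["site_id"], "strand"].to_numpy()
    df["site_pos"] = sites.loc[df["site_id"], "position"].to_numpy()
    # one site per SNP: the closest, donors first, then lower coordinate
    df["_type_rank"] = (df["site_type"] != DONOR).astype(int)
    df = (df.sort_values(["top_snp", "distance", "_type_rank", "site_pos"],
                         key=lambda s: s.abs() if s.name == "distance" else s)
            .drop_duplicates("top_snp", keep="first"))
    tallies: dict[tuple, dict] = {}
    for _, r in df.iterrows():
        alt_t = r["alt"] if r["strand"] == "+" else complement(r["alt"])
        ref_t = r["ref"] if r["strand"] == "+" else complement(r["ref"])
        promoting, reducing = (alt_t, ref_t) if r["beta"] > 0 else (ref_t, alt_t)
        key = (r["site_type"], int(r["distance"]))
        cell = tallies.setdefault(key, {"promote": {}, "reduce": {}, "n": 0})
        cell["promote"][promoting] = cell["promote"].get(promoting, 0) + 1
        cell["reduce"][reducing] = cell["reduce"].get(reducing, 0) + 1
        cell["n"] += 1
    rows = []
    for (stype, pos), cell in sorted(tallies.items()):
        lo, hi = windows.get(stype, (-max_distance, max_distance))
        if not lo <= pos <= hi:
            continue
        rows.append({"site_type": stype, "position": pos,
                     "promoting_base": _modal(cell["promote"]),
                     "reducing_base": _modal(cell["reduce"]),
                     "n_support": cell["n"]})
    return pd.DataFrame(rows)


def _modal(counter: dict) -> str:
    return max(sorted(counter), key=counter.get)


def build_synthetic_intron(profile: pd.DataFrame, variant: str = "best",
                           fill_means: pd.DataFrame | None = None,
                           modifications: frozenset | set = frozenset(),
                           strength_tables: dict | None = None,
                           length: int = 100) -> str:
    """A synthetic intron from the promoting (best) or reducing (worst)
    profile: donor-side positions 0..len/2-1 joined to acceptor-side
    positions -(len/2-1)..0, with GT/AG anchors and a branch-point adenosine.

    Positions the profile does not cover are filled from the per-position
    mean-usage best/worst bases (``fill_means``, as returned by
    ``position_nucleotide_means``) and finally from a neutral default.
    ``modifications`` may include "ppt" (polypyrimidine tract), "branchpoint"
    (consensus CTAAC block) and "strong_hexamers" (terminal hexamers replaced
    by the rank-1 keys of ``strength_tables['donor'/'acceptor']``).
    """
    if variant not in ("best", "worst"):
        raise ValueError("variant must be 'best' or 'worst'")
    bad = set(modifications) - {"ppt", "branchpoint", "strong_hexamers"}
    if bad:
        raise ValueError(f"unknown modifications: {sorted(bad)}")
    half = length // 2
    col = "promoting_base" if variant == "best" else "reducing_base"

    def lookup(stype, pos):
        row = profile[(profile["site_type"] == stype) & (profile["position"] == pos)]
        if len(row) and pd.notna(row.iloc[0][col]):
            return row.iloc[0][col]
        if fill_means is not None:
            sub = fill_means[(fill_means["site_type"] == stype)
                             & (fill_means["position"] == pos)
                             & (fill_means["n_sites"] > 0)]
            if len(sub):
                ordered = sub.sort_values("mean_sse", ascending=(variant == "worst"))
                return ordered.iloc[0]["base"]
        return "T" if variant == "best" else "G"

    donor_side = [lookup(DONOR, p) for p in range(0, half)]
    acceptor_side = [lookup(ACCEPTOR, p) for p in range(-(length - half - 1), 1)]
    seq = donor_side + acceptor_side
    seq[0], seq[1] = "G", "T"
    seq[-2], seq[-1] = "A", "G"
    bp_at = length - 25  # branch point ~25 bp from the 3' end
    seq[bp_at] = "A"
    if "branchpoint" in modifications:
        seq[bp_at - 3:bp_at + 2] = list("CTAAC")
    if "ppt" in modifications:
        seq[length - 20:length - 6] = list("TTTTCTTTTTCTTT")
    if "strong_hexamers" in modifications:
        if not strength_tables:
            raise ValueError("strong_hexamers needs strength_tables")
        d_top = strength_tables[DONOR].sort_values("rank").iloc[0]["key"]
        a_top = strength_tables[ACCEPTOR].sort_values("rank").iloc[0]["key"]
        if not d_top.startswith("GT") or not a_top.endswith("AG"):
            raise ValueError("top hexamers conflict with the GT/AG anchors")
        seq[:6] = list(d_top)
        seq[-6:] = list(a_top)
    out = "".join(seq)
    assert out.startswith("GT") and out.endswith("AG") and len(out) == length
    return out
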