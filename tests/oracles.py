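"""Independent brute-force oracles used to cross-check the library.

These deliberately avoid the library's code paths: plain string scanning and
explicit accumulation loops only.
"""

from splicehex.genome import DONOR, revcomp


def two_pass_proportion(values, labels):
    """Explicit TSS and RSS accumulation for the variance-partition ratio."""
    values = [float(v) for v in values]
    grand = sum(values) / len(values)
    tss = sum((v - grand) ** 2 for v in values)
    rss = 0.0
    for g in set(labels):
        grp = [v for v, l in zip(values, labels) if l == g]
        m = sum(grp) / len(grp)
        rss += sum((v - m) ** 2 for v in grp)
    return (tss - rss) / tss if tss else 0.0


def naive_choice_explained(genome, sites, table, k, window):
    """Brute-force window-scan statistic: enumerate every relative position,
    read the k-mer off the forward strand, reverse-complement by hand."""
    ranks = {row["key"]: row["rank"] for _, row in table.iterrows()}
    worst = len(ranks) + 1
    tested = success = 0
    positions = {}
    for _, s in sites.iterrows():
        positions.setdefault(s["chrom"], []).append(int(s["position"]))
    for _, s in sites.iterrows():
        pos, chrom, strand = int(s["position"]), s["chrom"], s["strand"]
        stype = s["site_type"]
        if sum(abs(p - pos) <= window for p in positions[chrom]) > 1:
            continue
        seq = genome[chrom]
        cands = []  # (rel, key)
        for rel in range(-window, window + 1):
            if strand == "+":
                g = pos + rel  # 1-based anchor
                lo, hi = (g, g + k - 1) if stype == DONOR else (g - k + 1, g)
                if lo < 1 or hi > len(seq):
                    continue
                key = seq[lo - 1:hi]
            else:
                g = pos - rel
                lo, hi = (g - k + 1, g) if stype == DONOR else (g, g + k - 1)
                if lo < 1 or hi > len(seq):
                    continue
                key = revcomp(seq[lo - 1:hi])
            anchored = (key.startswith("GT") if stype == DONOR
                        else key.endswith("AG"))
            if anchored:
                cands.append((rel, key))
        assert any(rel == 0 for rel, _ in cands)
        tested += 1
        best = min(ranks.get(key, worst) for _, key in cands)
        winners = [(rel, key) for rel, key in cands
                   if ranks.get(key, worst) == best]
        if len(winners) == 1 and winners[0][0] == 0:
            success += 1
    return tested, success
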