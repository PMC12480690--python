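"""Position-wise nucleotide effects and best/worst synthetic introns.

Computes per-position nucleotide means and the variance-partition statistic
around donors on a simulated transcriptome, then assembles 100 bp synthetic
introns from the splice-promoting and splice-reducing bases.
"""

import pandas as pd

from splicehex import scenarios, seqfx
from splicehex.genome import ACCEPTOR, DONOR

genome, donors, strength, model = scenarios.hexamer_transcriptome(
    n_donor_sites=1500, seed=4)

profile = seqfx.position_nucleotide_means(donors, genome, strength)
pov = (profile.groupby("position")["proportion_of_variance"].first())
print("share of usage variance explained per donor position "
      "(0 = G of GT, intronic side positive):")
print(pov.round(3).to_string())
print("intronic positions inside the hexamer (+2..+5) dominate; "
      "positions outside carry none by construction here.")

# promoting/reducing bases straight from the per-position means
best_rows, worst_rows = [], []
for stype, lo, hi in ((DONOR, 0, 6), (ACCEPTOR, -6, 0)):
    for p in range(lo, hi + 1):
        sub = profile[(profile.site_type == stype) & (profile.position == p)
                      & (profile.n_sites > 0)]
        if sub.empty:
            continue
        ordered = sub.sort_values("mean_sse", ascending=False)
        best_rows.append({"site_type": stype, "position": p,
                          "promoting_base": ordered.iloc[0]["base"],
                          "reducing_base": ordered.iloc[-1]["base"],
                          "n_support": int(sub.n_sites.sum())})
prof = pd.DataFrame(best_rows)
best = seqfx.build_synthetic_intron(prof, "best", fill_means=profile)
worst = seqfx.build_synthetic_intron(prof, "worst", fill_means=profile)
gc = lambda s: (s.count("G") + s.count("C")) / len(s)
print(f"\nbest  intron ({gc(best):.0%} GC): {best}")
print(f"worst intron ({gc(worst):.0%} GC): {worst}")
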