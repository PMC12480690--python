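"""Competing-donor minigene library against a permutation null.

Each reporter construct carries two candidate donors; reads split between
the two junctions according to their true hexamer strengths.  The analysis
asks how often the winning site carries the stronger hexamer, stratifies by
the strength gap, and compares against a null that shuffles the
strength-to-hexamer assignment 10,000 times.
"""

from splicehex import scenarios

res = scenarios.minigene_recovery_study(n_pairs=2000, n_perm=10_000, seed=1)

print(f"pairs analysed: {res.n_pairs} (excluded ties: {res.n_excluded})")
print(f"choices explained by hexamer ranking: {res.explained_fraction:.1%}")
print(res.by_gap.to_string(index=False,
                           float_format=lambda v: f"{v:.3f}"))
print(f"permutation threshold (95th percentile of the null): "
      f"{res.threshold:.3f}")
print("an explained fraction above the threshold means the ranking carries "
      "real signal; pairs with a strength gap > 0.25 are explained more often.")
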