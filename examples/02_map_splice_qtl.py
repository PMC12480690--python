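"""Map planted splice-site variants by per-site GWAS.

Twenty donor sites each carry one SNP inside their hexamer whose alternate
allele shifts the true usage by 0.5.  Each site's per-genotype mean usage is
regressed on every variant genome-wide; peaks are called, gated against the
plot noise, and the top SNP is classified cis or trans.
"""

from splicehex import scenarios

result = scenarios.causal_recovery_study(
    n_sites=20, n_genotypes=200, maf=0.25, strength_gap=0.5,
    depth=50, replicates=3, seed=2024)

print(result[["causal_variant", "top_snp", "recovered", "cis_trans",
              "delta_sse", "pve"]].to_string(float_format="%.3f"))
print()
print(f"causal variant is the top SNP of a passing peak: "
      f"{result['recovered'].mean():.0%} of sites")
mapped = result[result["mapped"]]
print(f"top associations classified cis: "
      f"{(mapped['cis_trans'] == 'cis').mean():.0%}")
print("delta_sse is the usage shift carried by the minor allele; "
      "pve the variance it explains.")
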