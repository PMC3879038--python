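"""Transmission disequilibrium test on a cohort with one distorted locus.

A causal gene's SNPs transmit the risk allele from heterozygous parents
with probability tau = 0.75 instead of 0.5; the TDT ranks SNPs by how
asymmetric their transmission counts (b vs c) are.
"""

from triopba import SimConfig, generate_annotation, generate_cohort, run_qc, run_tdt

cfg = SimConfig(
    n_trios=200, n_snps=1000, n_genes=250, n_terms=20, tau=0.75,
    causal_term_ids=("T001",),
    causal_genes_per_population={"demo": ("G0000",)},
    seed=2,
)
ann = generate_annotation(cfg)
cohort, truth = generate_cohort(cfg, "demo", ann)
clean, _ = run_qc(cohort)
results = run_tdt(clean)

print(results.head(5).to_string(index=False))
top = set(results["snp_id"].head(5))
print(
    f"\ncausal SNPs {sorted(truth.causal_snp_ids)} "
    f"(in top 5: {sorted(top & set(truth.causal_snp_ids))})"
)
print(
    "b and c count transmissions/non-transmissions of the tested (minor) "
    "allele from heterozygous parents; chi2 = (b-c)^2/(b+c) with 1 df. "
    "The planted locus shows b far above c and heads the ranking."
)
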