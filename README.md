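# triopba

Trio-based pathway and network association analysis for complex disease,
with a synthetic study generator for end-to-end validation.

Rare complex diseases such as Hirschsprung's disease resist single-locus
association: cohorts are small, effects are weak, and the implicated genes
differ between populations even when the disrupted biology is the same.
`triopba` implements the module-level strategy for family-trio genotype
data: test each SNP for transmission distortion, project SNP evidence
onto genes, then ask whether *functional modules* (GO-style gene sets) or
*interactome neighbourhoods* — rather than individual genes — are
enriched for association. It is a library for statistical geneticists
and methods developers; every stage is importable, scriptable, and comes
with a thin `triopba` command-line wrapper.

## The statistics

**Transmission disequilibrium test (TDT).** For each SNP, count
transmissions *b* and non-transmissions *c* of the tested (minor) allele
from heterozygous parents to the affected child across complete,
Mendelian-consistent trios:

```
chi2 = (b - c)^2 / (b + c),   1 df
```

Trio QC precedes the test: SNP call rate > 80%, sample missingness < 5%,
complete trios only, founder MAF >= 0.5%, no Mendelian-error SNPs,
founder HWE exact p >= 1e-5.

**Gene scores.** A SNP belongs to a gene if it lies within the gene
limits ±500 bp (configurable, boundary-inclusive). A gene's score is the
minimum p-value over its SNPs (`best_p`), giving a ranked gene list.

**Pathway association (PBA).** For each term of a GO-like hierarchy
(levels 3–13, 5–600 scored member genes), fit

```
logit P(gene in term) = b0 + b1 * x(gene)
```

where `x` is the percentile rank of −log10(best_p). The one-sided
likelihood-ratio p-value for `b1 > 0` asks whether term members
concentrate among the most associated genes — none of them needs to be
individually significant. Benjamini–Hochberg FDR is applied over *all*
tests pooled across populations/chips.

**Network scan.** Map the N most associated genes onto an interactome,
join them by direct interactions or a single external node, and compare
the average degree of the connected genes with an empirical null from
random N-gene draws. Starting at N = 10, grow the list until the add-one
empirical p ≤ 0.05 or N = 200.

**Cross-population convergence.** For each SNP-rank cutoff k, count the
genes and the annotated terms shared by every population's top-k SNPs.
Shared terms without shared genes is the signature of different genes of
common functionality.

## Worked example

`examples/03_pathway_association.py` simulates 200 trios × 3,000 SNPs on
1,000 genes with 10 genes of one 20-gene term carrying τ = 0.75
transmission distortion, then runs QC → TDT → gene scoring → PBA:

```
793 genes scored; 258 extra-genic SNPs set aside
term_id  level  size_tested  coefficient    p_raw    q_fdr
   T001      3           18     4.545762 0.000003 0.000147
   T017      6            8     2.597114 0.025324 0.538144
   T033      6            6     2.712274 0.039338 0.538144
   ...
planted term T001 q = 1.47e-04 (BH-adjusted, significant below 0.05)
```

The planted term tops the table at q ≈ 1e-4 while every null term stays
far from significance. `examples/04_network_scan.py` does the same for
the interactome route:

```
scan stopped at N = 10: avg connectivity 23.7 vs null mean 4.8
(95th pct 10.7), empirical p = 0.000999
```

The other examples cover simulation + QC, TDT ranking, and the
cross-population overlap curves.

A full multi-population run (simulate → QC → TDT → scores → pooled-FDR
PBA → size-bias check → network scan → cross-population curves) is one
call — `run_pipeline(RunConfig(...))` — or from the shell:

```bash
triopba run-all --config config.yaml --seed 1 --out runs/demo
```

Outputs are plain TSV/JSON plus a manifest; reruns with the same config
and seed are byte-identical.

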