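# Methods

This note documents the models, conventions and design choices behind
`triopba`, in the order data flows through the pipeline.

## Synthetic study generator

The generator (`triopba.sim`) emulates the data-generating process the
analysis assumes, so that every stage can be validated against ground
truth.

**Genotypes.** Each SNP gets a minor-allele frequency drawn uniformly
from `maf_range` (default 0.1–0.4, a typical genotyping-array band) and
two allele symbols. Parental genotypes are drawn allele-wise, i.e. from
exact Hardy–Weinberg proportions. Each parent transmits one allele to
the affected child: homozygous parents transmit their only allele;
heterozygous parents transmit the risk (minor) allele with probability
τ — 0.5 everywhere except at causal SNPs, where τ ∈ [0.5, 1) is the
transmission-distortion parameter (default 0.7 when a signal is
planted). τ acts only through heterozygous parents, which makes it the
exact estimand of the TDT ratio b/(b+c) and yields a closed-form power
oracle: b | n_het ~ Binomial(n_het, τ) with E[n_het] = 2·n_trios·2m(1−m),
so the TDT statistic is approximately noncentral χ²(1) with
ncp = 2·n_trios·2m(1−m)·(2τ−1)².

Every SNP inside a causal gene carries the distortion — operationally
the SNPs act as perfect proxies of the causal variant — which matches
the min-p gene score's assumption and keeps the power oracle exact.

**Corruption.** Missingness zeroes genotype cells independently at
`missing_rate` (default 1%). Mendelian errors re-draw the child genotype
uniformly from the genotypes *inconsistent* with its parents at a random
subset of (trio, SNP) cells (`mendel_error_rate`, default 0.1%);
double-heterozygous parents admit no inconsistent child genotype and are
skipped, so every injected error is detectable by the QC check.

**Annotation.** Genes are non-overlapping intervals on synthetic
chromosomes (lengths uniform in `gene_length_range`, default 2–120 kb)
separated by gaps wider than twice the 500 bp flank, so positional
SNP→gene mapping is unambiguous. Genic SNPs are allocated
length-proportionally (after one guaranteed SNP per causal gene);
`extra_genic_fraction` (default 10%) land in the gaps beyond any flank.
The term hierarchy is a rooted DAG: a spine guarantees levels 1 through
`dag_depth` (default 6), remaining terms attach to random parents with
occasional second parents, and membership propagates upward in reverse
topological order. Causal terms are created as *leaves* at level 3
containing the planted genes plus one base draw, so their tested size is
controlled. Per-population cohorts share the annotation but carry
disjoint causal gene sets drawn from the same causal term — the
different-genes-common-function scenario.

**Interactome.** The graph grows by preferential attachment (m =
`interactome_degree_param`, default 2), giving a heavy-tailed degree
distribution. Planted module nodes are placed first in the growth
order, so they become well-connected hubs — as in curated interactomes,
where disease modules sit on well-studied, highly connected proteins —
and internal module edges are topped up until the within-module density
reaches `module_density_multiple` (default 5) times the background
density. Placing the module on background-degree nodes instead would
make the average-degree statistic blind to it by construction: the
alternative hypothesis of the connectivity scan *is* elevated
connectivity.

All randomness flows from one integer seed through named substreams
(`rng_for(seed, *tags)`), so every artefact is bytewise reproducible.

**What the generator does not model:** linkage disequilibrium between
SNPs, X-chromosome/sex-specific transmission, population stratification,
genotyping batch effects, or annotation errors. Passing tests therefore
demonstrate correctness of the statistics under the stated model, not
robustness to those real-data features.

## Quality control

Filters run in a fixed order, and the attrition report depends on it:
(1) SNP call rate ≤ 20% missing, (2) sample missingness ≤ 5%,
(3) removal of samples outside complete trios, (4) founder MAF ≥ 0.5%,
(5) removal of SNPs with any Mendelian-inconsistent trio, (6) founder
HWE exact p ≥ 1e-5. MAF and HWE use parents only: transmission
distortion at a true risk locus would otherwise masquerade as a
frequency or equilibrium violation in the children. The HWE test is the
exact conditional test (enumeration over heterozygote counts given
allele totals); a χ² variant is available behind `hwe_chi2=True`.
A SNP with any Mendelian error is dropped entirely (rather than zeroing
the offending genotype) — the conservative reading of array-era trio QC.

## TDT

Classical allele-based TDT without continuity correction. The tested
allele is the founder minor allele (ties break toward the smaller
allele symbol) and results are allele-labelled. Trios missing a
genotype or Mendelian-inconsistent at a SNP are skipped for that SNP.
When both parents and the child are heterozygous, one transmission of
each allele is counted. Ranking is by (p, snp_id) for determinism.
The p-value is discrete (it is a function of integer counts), with an
atom at p = 1 from b = c ties; calibration tests use the randomized
probability integral transform, which is exactly uniform iff the test
is calibrated.

## Gene scoring

SNP→gene assignment uses closed 1-based intervals `[start − 500,
end + 500]`; the boundary is inclusive (the flank convention is
documented rather than prescribed by the method). A SNP inside several
gene windows contributes to each — information-preserving and
symmetric. The gene score is min-p with deterministic tie-breaks; no LD
or permutation correction is attempted, which is why the length-bias
diagnostic exists downstream.

## Pathway association

Terms are tested only if their shortest-path level from the root (root
= 1) lies in [3, 13] and their *scored* member count in [5, 600]; both
bounds are configurable. The association model regresses binary term
membership on the percentile rank of −log10(best_p) (mid-ranks for
ties; a raw `neg_log10_p` transform is available but is sensitive to
monotone rescaling of p, which the rank transform is not). The reported
p-value is the one-sided *likelihood-ratio* test for a positive slope:
the Wald version loses power exactly in the strong-enrichment regime it
is meant to detect (the Hauck–Donner effect — the standard error grows
faster than the estimate as fits approach separation), while the LR
test is identically calibrated under the null (verified by simulation)
and substantially more sensitive under the alternative. Under complete
separation the MLE does not exist; the fit falls back to a weakly
ridge-penalised likelihood-ratio test (λ = 1e-3 on the slope) and the
row is flagged `separated`.

FDR control is Benjamini–Hochberg. In multi-population or multi-chip
studies all individual tests enter a single pooled adjustment (the
default in the pipeline); per-run adjustment is available for
single-cohort use.

## Gene-length bias diagnostic

Min-p gene scores favour long genes (more SNPs, more chances of a small
p by luck). For each significant term the median genomic span of its
scored member genes is compared with the third quartile — linear
interpolation quantile, type 7 — of the per-term medians over *all*
tested terms; a strictly larger median flags the term. The report
inspects, it does not correct.

## Network scan

"Minimum connecting network" is formalised as the union over seed pairs
of connecting paths of length ≤ 2: a direct interaction or exactly one
external (non-seed) intermediate. This matches the one-external-node
rule, is deterministic, and is checkable against exhaustive path
enumeration (which the tests do on all small graphs). When several
components arise, the largest is kept. Only
`max_intermediates_per_link` of 0 or 1 is supported — the published
form of the method uses 1, and longer relays would change the
statistic's meaning.

The connectivity statistic is the mean full-interactome degree of the
*linked seed genes* (scan default). The variant averaging over all
subnetwork nodes including intermediates is available
(`seeds_only_connectivity=False`) but has essentially no power against
a planted module: low-degree intermediates dilute the observed value
while single-hub triples fatten the null tail — measured recovery 0/20
versus 20/20 for the seeds-only form under identical conditions.

The null redraws N nodes uniformly without replacement from the
interactome and applies the identical construction; empty subnetworks
score 0 (the least-connected outcome). Significance is the add-one
empirical p = (1 + #{null ≥ obs}) / (1 + n_null), never smaller than
1/(1+n_null). The scan tests N = 10 … 200 with no multiplicity
correction across N (stated in the output metadata); the false-stop
rate of a fully null scan is therefore appreciable (≈0.2 over 51 N
values in simulation) and the scan should be read as hypothesis
generation, not confirmatory testing.

## Cross-population overlap

For each cutoff k, a population contributes the union of genes mapped
by its k lowest-p SNPs and the terms annotating those genes, restricted
to the PBA-tested term universe (so near-root umbrella terms do not
inflate the term curve). The curves report the sizes of the across-
population intersections; both are monotone non-decreasing in k by
construction. Counting terms from top-gene annotation (rather than
intersecting per-population significant-term lists) is deliberate: it
measures functional convergence without requiring per-population
significance.

## Pipeline and reproducibility

`run_pipeline` executes simulate/load → QC → TDT → gene scoring →
PBA (pooled FDR) → size-bias → network scan → cross-population curves,
writing TSV/JSON outputs and a manifest (package version, seed,
thresholds, per-step attrition; no timestamps). Every stage is
deterministic given the config seed, so reruns are byte-identical —
asserted by a test and by the acceptance script.

## Problem sizes used in validation

The statistical tests run at deliberately scaled study sizes chosen to
give the relevant checks high power while keeping the suite quick:
null calibration at 2,000 SNPs × 100 trios; power at 300 trios against
the closed form; pathway recovery at 200 trios, 1,000 genes, 50 terms
with 20 replicates (50 null replicates for FDR control); network
recovery at 500 nodes with 1,000-draw nulls and 20 replicates;
convergence at five populations × 2,000 SNPs with 10 replicates. The
acceptance script repeats the same measurements at reduced replicate
counts.

## Known limitations

- No LD model: power formulas and calibration assume independent SNPs.
- Min-p gene scores are biased toward long genes by design; the bias is
  diagnosed, not corrected.
- The GESBAP-style regression direction and transform are inferences
  from the method family, exposed as configuration rather than fixed.
- The interactome null treats the graph as the gene universe; genes
  absent from the interactome are invisible to the scan.
- The term-level convention (shortest path from root, root = 1) is one
  of several in use; level bounds are configurable for other choices.
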