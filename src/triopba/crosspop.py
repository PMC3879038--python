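"""Cross-population convergence: common genes versus common functions.

For each SNP-rank cutoff k, each population contributes the genes hit by
its k most associated SNPs and the terms annotating those genes; the
curves count the genes and the terms shared by every population.  When
disease genes differ between populations but belong to the same
functional modules, the term curve rises while the gene curve stays
flat — different genes, common functionality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneSetCollection

logger = logging.getLogger("triopba")


def default_cutoffs(k_min: int = 10, k_max: int = 1000, n: int = 25) -> list[int]:
    """Log-spaced rank cutoffs (matches a log-scale axis)."""
    grid = np.unique(np.geomspace(k_min, k_max, num=n).round().astype(int))
    return [int(k) for k in grid]


@dataclass
class OverlapCurve:
    curve: pd.DataFrame  # cutoff, n_common_genes, n_common_terms
    common_genes: dict[int, set[str]]
    common_terms: dict[int, set[str]]
    per_population_genes: dict[str, dict[int, set[str]]]  # audit trail

    def write_tsv(self, path) -> None:
        self.curve.to_csv(path, sep="\t", index=False)


def overlap_curves(
    ranked_snps_per_population: dict[str, list[str]],
    snp_to_genes: dict[str, set[str]],
    collection: GeneSetCollection,
    cutoffs: list[int] | None = None,
    term_universe=None,
) -> OverlapCurve:
    """Shared-gene and shared-term counts across populations by cutoff.

    ``ranked_snps_per_population`` maps each population to its SNP ids
    sorted by ascending TDT p-value.  Terms are counted from the
    annotation of the top-k genes, restricted to ``term_universe`` (the
    tested term list; defaults to every term except the hierarchy root).
    Cutoffs beyond a population's SNP count are truncated with a warning.
    """
    if len(ranked_snps_per_population) < 2:
        raise ValueError("need at least 2 populations")
    cutoffs = sorted(cutoffs or default_cutoffs())
    if term_universe is None:
        term_universe = [t for t in collection.term_ids() if t != collection.root]
    universe = set(term_universe)

    gene_to_terms: dict[str, set[str]] = {}
    for term_id in universe:
        for g in collection.members(term_id):
            gene_to_terms.setdefault(g, set()).add(term_id)

    per_pop_genes: dict[str, dict[int, set[str]]] = {}
    per_pop_terms: dict[str, dict[int, set[str]]] = {}
    for pop, snps in ranked_snps_per_population.items():
        snps = list(snps)
        per_pop_genes[pop] = {}
        per_pop_terms[pop] = {}
        for k in cutoffs:
            if k > len(snps):
                logger.warning(
                    "population %s has %d SNPs; cutoff %d truncated", pop, len(snps), k
                )
            genes: set[str] = set()
            for sid in snps[: min(k, len(snps))]:
                genes |= snp_to_genes.get(sid, set())
            terms: set[str] = set()
            for g in genes:
                terms |= gene_to_terms.get(g, set())
            per_pop_genes[pop][k] = genes
            per_pop_terms[pop][k] = terms

    common_genes, common_terms, rows = {}, {}, []
    pops = list(ranked_snps_per_population)
    for k in cutoffs:
        cg = set.intersection(*(per_pop_genes[p][k] for p in pops))
        ct = set.intersection(*(per_pop_terms[p][k] for p in pops))
        common_genes[k] = cg
        common_terms[k] = ct
        rows.append((k, len(cg), len(ct)))

    curve = pd.DataFrame(rows, columns=["cutoff", "n_common_genes", "n_common_terms"])
    return OverlapCurve(
        curve=curve,
        common_genes=common_genes,
        common_terms=common_terms,
        per_population_genes=per_pop_genes,
    )
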