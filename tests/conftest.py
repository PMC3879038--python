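import numpy as np
import pandas as pd
import pytest

import triopba as tp
from triopba.io import SAMPLE_COLUMNS, ALLELE_TO_CODE, TrioCohort, SnpRecord


def make_cohort(sample_rows, genotype_strings, snps=None):
    """Hand-build a cohort from PED-style rows and per-sample genotype
    strings like 'AG AA GG' (one token per SNP)."""
    samples = pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS)
    geno = []
    for s in genotype_strings:
        tokens = s.split()
        geno.append([[ALLELE_TO_CODE[a] for a in tok] for tok in tokens])
    genotypes = np.asarray(geno, dtype=np.int8)
    n_snps = genotypes.shape[1]
    if snps is None:
        snps = [SnpRecord(f"snp{j}", "chr1", 1000 * (j + 1)) for j in range(n_snps)]
    cohort = TrioCohort(samples=samples, snps=snps, genotypes=genotypes)
    cohort.rebuild_trio_index()
    return cohort


@pytest.fixture
def one_trio_rows():
    return [
        ["F1", "1", "0", "0", 1, 1],
        ["F1", "2", "0", "0", 2, 1],
        ["F1", "3", "1", "2", 1, 2],
    ]


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study shared by read-only tests."""
    cfg = tp.default_causal_config(
        n_populations=2,
        genes_per_population=5,
        n_trios=60,
        n_snps=800,
        n_genes=200,
        n_terms=40,
        term_size_range=(8, 20),
        tau=0.75,
        seed=42,
    )
    annotation, cohorts, interactome = tp.simulate_study(cfg)
    return cfg, annotation, cohorts, interactome


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

BIALLELIC_GENOTYPES = [("A", "A"), ("A", "G"), ("G", "G")]


def gamete_consistent(father_gt, mother_gt, child_gt) -> bool:
    """Brute-force Mendelian consistency by enumerating gamete pairs."""
    for fa in father_gt:
        for ma in mother_gt:
            if sorted((fa, ma)) == sorted(child_gt):
                return True
    return False


def gamete_transmissions(father_gt, mother_gt, child_gt, tested):
    """All (b, c) outcomes over gamete pairs producing this child."""
    outcomes = set()
    het = [gt for gt in (father_gt, mother_gt) if len(set(gt)) == 2]
    for fa in father_gt:
        for ma in mother_gt:
            if sorted((fa, ma)) != sorted(child_gt):
                continue
            b = 0
            if len(set(father_gt)) == 2:
                b += fa == tested
            if len(set(mother_gt)) == 2:
                b += ma == tested
            outcomes.add((b, len(het) - b))
    return outcomes


def bh_stepup_oracle(pvals):
    """Literal Benjamini-Hochberg step-up with monotonicity enforcement."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        candidate = p[i] * m / rank_from_end
        running_min = min(running_min, candidate)
        q[i] = min(running_min, 1.0)
    return q


def subnetwork_oracle(seeds, graph_edges, max_inter=1):
    """Exhaustive path-<=2 subnetwork construction on a tiny graph.

    Enumerates, for every seed pair, all connecting paths of length 1
    (direct edge) and length 2 (via a single non-seed intermediate),
    unions their edges, then keeps the largest connected component.
    Returns (node set, edge set).
    """
    import itertools

    adj = {}
    for a, b in graph_edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seeds = [s for s in seeds if s in adj]
    edges = set()
    for s1, s2 in itertools.combinations(sorted(seeds), 2):
        if s2 in adj[s1]:
            edges.add((min(s1, s2), max(s1, s2)))
        if max_inter >= 1:
            for x in adj:
                if x in seeds:
                    continue
                if s1 in adj[x] and s2 in adj[x]:
                    edges.add((min(s1, x), max(s1, x)))
                    edges.add((min(s2, x), max(s2, x)))
    if not edges:
        return set(), set()
    # connected components by flood fill
    local = {}
    for a, b in edges:
        local.setdefault(a, set()).add(b)
        local.setdefault(b, set()).add(a)
    comps = []
    todo = set(local)
    while todo:
        start = min(todo)
        comp = {start}
        stack = [start]
        while stack:
            for nb in local[stack.pop()]:
                if nb not in comp:
                    comp.add(nb)
                    stack.append(nb)
        comps.append(comp)
        todo -= comp
    best = max(comps, key=len)
    kept = {e for e in edges if e[0] in best}
    return best, kept
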