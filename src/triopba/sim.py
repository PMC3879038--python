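"""Synthetic trio-cohort study generator.

Emulates the data-generating process a family-based SNP association study
assumes: parents drawn from Hardy-Weinberg proportions at each marker,
Mendelian transmission to the affected child with an optional
transmission distortion ``tau`` at causal SNPs, genes of variable length
carrying length-proportional SNP counts, a rooted GO-style term hierarchy
with planted disease modules, and a scale-free-ish interactome with a
planted dense module.

``tau`` is the probability that a heterozygous parent transmits the risk
(minor) allele; ``tau = 0.5`` is the null of no association and is the
exact quantity the transmission disequilibrium test estimates through
``b / (b + c)``.  Homozygous parents transmit their only allele and are
untouched by the distortion.

All randomness flows from the single integer ``SimConfig.seed`` through
named substreams, so every artefact is reproducible byte-for-byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    GeneSetCollection,
    Interactome,
    SnpRecord,
    TrioCohort,
    SAMPLE_COLUMNS,
    ALLELE_TO_CODE,
)

__all__ = [
    "SimConfig",
    "TruthSet",
    "Annotation",
    "generate_annotation",
    "generate_cohort",
    "generate_interactome",
    "simulate_study",
]


def rng_for(seed: int, *tags) -> np.random.Generator:
    """Deterministic named substream of the global seed.

    Tags are folded in through CRC32 so the same (seed, tags) pair always
    yields the same stream regardless of call order.
    """
    keys = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        keys.append(zlib.crc32(str(t).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(keys))


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort generator."""

    n_trios: int = 100
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.1, 0.4)
    n_genes: int = 500
    gene_length_range: tuple[int, int] = (2_000, 120_000)
    flank_bp: int = 500
    n_terms: int = 50
    term_size_range: tuple[int, int] = (5, 40)
    dag_depth: int = 6
    causal_term_ids: tuple[str, ...] = ()
    causal_genes_per_population: dict[str, tuple[str, ...]] = field(default_factory=dict)
    tau: float = 0.7
    missing_rate: float = 0.01
    mendel_error_rate: float = 0.001
    extra_genic_fraction: float = 0.10
    interactome_degree_param: float = 2.0
    module_density_multiple: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.5 <= self.tau < 1.0):
            raise ValueError(f"tau must lie in [0.5, 1), got {self.tau}")
        for name in ("maf_range", "gene_length_range", "term_size_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered low <= high")
        lo, hi = self.maf_range
        if not (0.0 < lo and hi < 1.0):
            raise ValueError("maf_range must lie inside (0, 1)")
        for name in ("missing_rate", "mendel_error_rate", "extra_genic_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.n_terms < 2:
            raise ValueError("need at least 2 terms (root + one child)")
        if self.term_size_range[1] > self.n_genes:
            raise ValueError("term_size_range exceeds n_genes")
        if self.interactome_degree_param <= 0:
            raise ValueError("interactome_degree_param must be positive")
        if self.module_density_multiple < 1:
            raise ValueError("module_density_multiple must be >= 1")
        n_genic = round(self.n_snps * (1.0 - self.extra_genic_fraction))
        if n_genic < self.n_genes:
            raise ValueError(
                "fewer genic SNPs than genes: need at least 1 SNP per gene on average"
            )

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    def all_causal_genes(self) -> tuple[str, ...]:
        out: set[str] = set()
        for genes in self.causal_genes_per_population.values():
            out.update(genes)
        return tuple(sorted(out))


@dataclass
class TruthSet:
    """Ground truth of one simulated cohort, for power/recovery checks."""

    causal_snp_ids: list[str]
    causal_gene_ids: list[str]
    causal_term_ids: list[str]
    planted_module_nodes: list[str]

    def to_dict(self) -> dict:
        return {
            "causal_snp_ids": list(self.causal_snp_ids),
            "causal_gene_ids": list(self.causal_gene_ids),
            "causal_term_ids": list(self.causal_term_ids),
            "planted_module_nodes": list(self.planted_module_nodes),
        }


@dataclass
class Annotation:
    """Shared gene coordinates, SNP map, and term hierarchy of a study."""

    genes: pd.DataFrame  # chrom, start, end, gene_id (BED convention)
    snps: list[SnpRecord]  # positions 1-based, ordered by (chrom, position)
    snp_gene: dict[str, str | None]  # generating assignment (None = extra-genic)
    collection: GeneSetCollection

    def gene_lengths(self) -> dict[str, int]:
        return {
            g: int(e - s)
            for g, s, e in zip(self.genes["gene_id"], self.genes["start"], self.genes["end"])
        }


def default_causal_config(
    n_populations: int = 1,
    genes_per_population: int = 10,
    causal_term: str | None = None,
    **kwargs,
) -> SimConfig:
    """Convenience constructor planting one causal term whose member genes
    are split disjointly across populations (different genes, common
    functionality)."""
    cfg = SimConfig(**kwargs)
    term = causal_term or "T001"
    n_needed = n_populations * genes_per_population
    gene_ids = [f"G{i:04d}" for i in range(n_needed)]
    per_pop = {
        f"pop{p + 1}": tuple(gene_ids[p * genes_per_population : (p + 1) * genes_per_population])
        for p in range(n_populations)
    }
    return cfg.with_(causal_term_ids=(term,), causal_genes_per_population=per_pop)


# ---------------------------------------------------------------------------
# Annotation: genes, SNP positions, term hierarchy
# ---------------------------------------------------------------------------

_GENES_PER_CHROM = 50
_GAP_PAD = 1000  # bp of SNP-free buffer beyond the two flanks between genes


def generate_annotation(config: SimConfig) -> Annotation:
    """Gene intervals, SNP positions, and a rooted term DAG.

    Genes are non-overlapping on synthetic chromosomes with gaps wider
    than twice the flank, so the positional SNP->gene mapping is
    unambiguous.  Genic SNPs are distributed length-proportionally (after
    one guaranteed SNP per causal gene); a configurable fraction is
    placed extra-genically, farther than ``flank_bp`` from any gene.
    Term membership is propagated upward so the root annotates every
    annotated gene.
    """
    rng = rng_for(config.seed, "annotation")
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)

    gene_rows = []
    gap = 2 * config.flank_bp + _GAP_PAD
    pos = 0
    for i in range(config.n_genes):
        chrom = f"chr{i // _GENES_PER_CHROM + 1}"
        if i % _GENES_PER_CHROM == 0:
            pos = gap  # reset at the start of each chromosome
        start = pos
        end = start + int(lengths[i])
        gene_rows.append((chrom, start, end, f"G{i:04d}"))
        pos = end + gap
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "gene_id"])

    n_extra = round(config.n_snps * config.extra_genic_fraction)
    n_genic = config.n_snps - n_extra
    causal_genes = config.all_causal_genes()
    unknown = set(causal_genes) - set(genes["gene_id"])
    if unknown:
        raise ValueError(f"causal genes not among generated genes: {sorted(unknown)}")
    if n_genic < len(causal_genes):
        raise ValueError("not enough genic SNPs to cover every causal gene")

    # one guaranteed SNP per causal gene, remainder length-proportional
    gene_ids = genes["gene_id"].tolist()
    weights = lengths / lengths.sum()
    counts = np.zeros(config.n_genes, dtype=int)
    causal_idx = [gene_ids.index(g) for g in causal_genes]
    counts[causal_idx] += 1
    extra_counts = rng.multinomial(n_genic - len(causal_genes), weights)
    counts += extra_counts

    raw = []  # (chrom, position 1-based, gene_id or None)
    for i, n_in_gene in enumerate(counts):
        if n_in_gene == 0:
            continue
        chrom, start, end, gid = gene_rows[i]
        positions = rng.integers(start + 1, end + 1, size=n_in_gene)
        raw += [(chrom, int(p), gid) for p in positions]

    # extra-genic SNPs live in inter-gene gaps, beyond both flanks
    if n_extra:
        windows = []
        for i in range(config.n_genes):
            chrom, _s, end, _g = gene_rows[i]
            lo_w = end + config.flank_bp + 2  # 1-based, just past the flank
            hi_w = end + gap - config.flank_bp  # before the next gene's flank
            windows.append((chrom, lo_w, hi_w))
        picks = rng.integers(0, len(windows), size=n_extra)
        for w in picks:
            chrom, lo_w, hi_w = windows[w]
            raw.append((chrom, int(rng.integers(lo_w, hi_w + 1)), None))

    # de-duplicate positions, then name SNPs in genomic order
    seen: set[tuple[str, int]] = set()
    uniq = []
    for chrom, p, gid in raw:
        while (chrom, p) in seen:
            p += 1
        seen.add((chrom, p))
        uniq.append((chrom, p, gid))
    uniq.sort(key=lambda t: (_chrom_sort_key(t[0]), t[1]))
    snps = []
    snp_gene: dict[str, str | None] = {}
    for k, (chrom, p, gid) in enumerate(uniq):
        sid = f"snp{k:06d}"
        snps.append(SnpRecord(snp_id=sid, chrom=chrom, position=p))
        snp_gene[sid] = gid

    collection = _generate_hierarchy(config, gene_ids, rng)
    return Annotation(genes=genes, snps=snps, snp_gene=snp_gene, collection=collection)


def _chrom_sort_key(chrom: str):
    tail = chrom.removeprefix("chr")
    return (0, int(tail)) if tail.isdigit() else (1, tail)


def _generate_hierarchy(
    config: SimConfig, gene_ids: list[str], rng: np.random.Generator
) -> GeneSetCollection:
    """Rooted DAG of ``n_terms`` terms with shortest-path levels spanning
    at least 1..min(dag_depth, n_terms).  Causal terms are attached at
    level 3 and always contain their causal genes."""
    n = config.n_terms
    term_ids = [f"T{i:03d}" for i in range(n)]
    root = term_ids[0]
    depth = max(5, config.dag_depth)
    causal = [t for t in config.causal_term_ids]
    unknown = set(causal) - set(term_ids)
    if unknown:
        raise ValueError(f"causal term(s) not among generated terms: {sorted(unknown)}")
    if root in causal:
        raise ValueError("the root term cannot be a causal term")

    edges: list[tuple[str, str]] = []
    level: dict[str, int] = {root: 1}
    # spine of non-causal terms guaranteeing the requested depth
    spine_pool = [t for t in term_ids[1:] if t not in causal]
    spine = spine_pool[: min(depth, n) - 1]
    if len(spine) < 2:
        raise ValueError("too few non-causal terms to build the hierarchy spine")
    prev = root
    for t in spine:
        edges.append((prev, t))
        level[t] = level[prev] + 1
        prev = t
    # causal terms sit at level 3, under the level-2 spine node
    for t in causal:
        edges.append((spine[0], t))
        level[t] = 3
    # remaining terms hang off random parents (never deeper than depth)
    # causal terms stay leaves so their membership is exactly the planted
    # genes plus their own base draw (no inherited descendants)
    placed = [t for t in term_ids if t in level and t not in causal]
    rest = [t for t in term_ids if t not in level]
    for t in rest:
        candidates = [p for p in placed if level[p] < depth]
        parent = candidates[rng.integers(0, len(candidates))]
        edges.append((parent, t))
        level[t] = level[parent] + 1
        # occasional second parent makes it a DAG rather than a tree
        if rng.random() < 0.2:
            shallower = [p for p in placed if level[p] <= level[t] - 1 and p != parent]
            if shallower:
                edges.append((shallower[rng.integers(0, len(shallower))], t))
        placed.append(t)

    # base membership: every non-root term draws genes from the pool
    lo, hi = config.term_size_range
    terms: dict[str, tuple[str, set[str]]] = {root: (f"{root} root", set())}
    pool = np.asarray(gene_ids)
    for t in term_ids[1:]:
        size = int(rng.integers(lo, hi + 1))
        members = set(pool[rng.choice(len(pool), size=size, replace=False)])
        terms[t] = (f"{t} synthetic term", members)

    collection = GeneSetCollection(terms=terms, dag=edges)
    collection.compute_levels()

    # plant the causal genes into every causal term
    causal_genes = set(config.all_causal_genes())
    for ct in config.causal_term_ids:
        name, members = collection.terms[ct]
        collection.terms[ct] = (name, members | causal_genes)
    collection.propagate_up()
    return collection


# ---------------------------------------------------------------------------
# Trio genotypes
# ---------------------------------------------------------------------------

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


def generate_cohort(
    config: SimConfig,
    population_label: str = "pop1",
    annotation: Annotation | None = None,
) -> tuple[TrioCohort, TruthSet]:
    """Simulate one population's trio cohort.

    Parents are drawn genotype-wise from Hardy-Weinberg proportions at
    each SNP's MAF; each heterozygous parent transmits the risk (minor)
    allele with probability ``tau`` at this population's causal SNPs and
    0.5 elsewhere.  Missingness and Mendelian-error corruption are
    applied after transmission.  Deterministic given the seed and the
    population label.
    """
    if annotation is None:
        annotation = generate_annotation(config)
    rng = rng_for(config.seed, "cohort", population_label)
    n_trios, n_snps = config.n_trios, len(annotation.snps)

    causal_genes = set(config.causal_genes_per_population.get(population_label, ()))
    causal_snps = sorted(
        sid for sid, gid in annotation.snp_gene.items() if gid in causal_genes
    )
    if causal_genes and not causal_snps:
        raise ValueError(
            f"causal genes of population {population_label!r} carry no SNPs"
        )
    snp_ids = [s.snp_id for s in annotation.snps]
    causal_mask = np.isin(snp_ids, causal_snps)

    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=n_snps)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_snps)
    # risk (minor) allele code and major allele code per SNP
    risk_code = np.array(
        [ALLELE_TO_CODE[_ALLELE_PAIRS[k][0]] for k in pair_idx], dtype=np.int8
    )
    major_code = np.array(
        [ALLELE_TO_CODE[_ALLELE_PAIRS[k][1]] for k in pair_idx], dtype=np.int8
    )

    # parental alleles: True = risk allele; HWE by independent draws
    father = rng.random((n_trios, n_snps, 2)) < maf[None, :, None]
    mother = rng.random((n_trios, n_snps, 2)) < maf[None, :, None]

    tau_vec = np.where(causal_mask, config.tau, 0.5)
    child_f = _transmit(father, tau_vec, rng)
    child_m = _transmit(mother, tau_vec, rng)
    child = np.stack([child_f, child_m], axis=2)  # (trio, snp, 2) boolean risk

    # dosage of the risk allele, for corruption bookkeeping
    def to_codes(risk_bool: np.ndarray) -> np.ndarray:
        return np.where(risk_bool, risk_code[None, :, None], major_code[None, :, None]).astype(np.int8)

    geno_f, geno_m, geno_c = to_codes(father), to_codes(mother), to_codes(child)

    # Mendelian-error corruption: redraw the child genotype uniformly from
    # the genotypes inconsistent with its parents (only where one exists)
    if config.mendel_error_rate > 0:
        err_cells = rng.random((n_trios, n_snps)) < config.mendel_error_rate
        df = father.sum(axis=2)  # parental risk dosages
        dm = mother.sum(axis=2)
        for t, j in zip(*np.nonzero(err_cells)):
            bad = _inconsistent_dosages(int(df[t, j]), int(dm[t, j]))
            if not bad:
                continue
            d = bad[rng.integers(0, len(bad))]
            geno_c[t, j, 0] = risk_code[j] if d >= 1 else major_code[j]
            geno_c[t, j, 1] = risk_code[j] if d == 2 else major_code[j]

    # assemble sample table: father, mother, child per family
    rows, geno_rows = [], []
    for t in range(n_trios):
        fam = f"{population_label}_F{t:04d}"
        rows.append([fam, "1", "0", "0", 1, 1])
        rows.append([fam, "2", "0", "0", 2, 1])
        rows.append([fam, "3", "1", "2", 1, 2])
        geno_rows += [geno_f[t], geno_m[t], geno_c[t]]
    samples = pd.DataFrame(rows, columns=SAMPLE_COLUMNS)
    genotypes = np.stack(geno_rows)

    if config.missing_rate > 0:
        miss = rng.random((genotypes.shape[0], n_snps)) < config.missing_rate
        genotypes[miss, :] = 0

    snps = [
        SnpRecord(
            s.snp_id,
            s.chrom,
            s.position,
            alleles=tuple(
                sorted(("0ACGT"[risk_code[j]], "0ACGT"[major_code[j]]))
            ),
        )
        for j, s in enumerate(annotation.snps)
    ]
    cohort = TrioCohort(samples=samples, snps=snps, genotypes=genotypes)
    cohort.rebuild_trio_index()

    truth = TruthSet(
        causal_snp_ids=causal_snps,
        causal_gene_ids=sorted(causal_genes),
        causal_term_ids=list(config.causal_term_ids),
        planted_module_nodes=list(config.all_causal_genes()),
    )
    return cohort, truth


def _transmit(parent: np.ndarray, tau_vec: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Transmitted allele (True = risk) from each parent.

    Homozygous parents transmit their only allele; heterozygous parents
    transmit the risk allele with per-SNP probability ``tau``."""
    dosage = parent.sum(axis=2)
    het = dosage == 1
    draw = rng.random(parent.shape[:2]) < tau_vec[None, :]
    return np.where(het, draw, dosage == 2)


def _inconsistent_dosages(df: int, dm: int) -> list[int]:
    """Child risk-allele dosages impossible under Mendelian transmission."""
    tr = {0: {0}, 1: {0, 1}, 2: {1}}
    ok = {a + b for a in tr[df] for b in tr[dm]}
    return [d for d in (0, 1, 2) if d not in ok]


# ---------------------------------------------------------------------------
# Interactome
# ---------------------------------------------------------------------------

def generate_interactome(
    config: SimConfig,
    truth: TruthSet | None = None,
    gene_ids: list[str] | None = None,
) -> Interactome:
    """Scale-free-ish interactome with an optional planted dense module.

    The graph grows by preferential attachment (``m`` edges per new node,
    ``m`` = round(interactome_degree_param)).  Planted module nodes are
    placed first in the growth order, so — as in curated interactomes,
    where disease modules sit on well-studied, highly connected proteins —
    they end up among the best-connected nodes; internal module edges are
    then topped up until the within-module density reaches
    ``module_density_multiple`` times the background density.
    """
    if gene_ids is None:
        gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    module = list(truth.planted_module_nodes) if truth is not None else []
    unknown = set(module) - set(gene_ids)
    if unknown:
        raise ValueError(f"planted module nodes not among genes: {sorted(unknown)}")

    rng = rng_for(config.seed, "interactome")
    m = max(1, round(config.interactome_degree_param))
    n = len(gene_ids)
    if n <= m:
        raise ValueError("need more genes than the attachment parameter")

    others = [g for g in gene_ids if g not in set(module)]
    order = module + list(np.asarray(others)[rng.permutation(len(others))])

    ba_seed = int(rng.integers(0, 2**31 - 1))
    g = nx.barabasi_albert_graph(n, m, seed=ba_seed)
    g = nx.relabel_nodes(g, {i: order[i] for i in range(n)})

    if len(module) >= 2:
        k = len(module)
        pairs_mod = k * (k - 1) // 2
        pairs_all = n * (n - 1) // 2
        internal = sum(1 for a, b in g.edges if a in set(module) and b in set(module))
        external = g.number_of_edges() - internal
        bg_density = external / (pairs_all - pairs_mod)
        target = config.module_density_multiple * bg_density
        candidates = [
            (a, b)
            for i, a in enumerate(module)
            for b in module[i + 1 :]
            if not g.has_edge(a, b)
        ]
        need = int(np.ceil(target * pairs_mod)) - internal
        if need > 0:
            if need > len(candidates):
                need = len(candidates)
            picks = rng.choice(len(candidates), size=need, replace=False)
            g.add_edges_from(candidates[i] for i in picks)

    return Interactome.from_edges(g.edges())


# ---------------------------------------------------------------------------
# Whole-study convenience
# ---------------------------------------------------------------------------

def simulate_study(config: SimConfig, populations: list[str] | None = None):
    """Generate the shared annotation, one cohort per population, and the
    interactome.  Returns (annotation, {pop: (cohort, truth)}, interactome)."""
    if populations is None:
        populations = sorted(config.causal_genes_per_population) or ["pop1"]
    annotation = generate_annotation(config)
    cohorts = {
        pop: generate_cohort(config, pop, annotation=annotation) for pop in populations
    }
    any_truth = next(iter(cohorts.values()))[1]
    interactome = generate_interactome(
        config, truth=any_truth, gene_ids=annotation.genes["gene_id"].tolist()
    )
    return annotation, cohorts, interactome
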