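"""Readers and writers for the text formats the pipeline touches.

Genotypes travel as PLINK PED/MAP text, gene coordinates as BED
(0-based half-open), gene-set membership as GMT, the term hierarchy as a
parent/child two-column table, and the interactome as a two-column edge
list.  All readers validate their input and fail loudly; deduplicated or
dropped records are counted in the module logger rather than silently
discarded.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("triopba")

#: genotype allele codes used throughout the package
MISSING_CODE = 0
CODE_TO_ALLELE = "0ACGT"
ALLELE_TO_CODE = {a: i for i, a in enumerate(CODE_TO_ALLELE)}

SAMPLE_COLUMNS = [
    "family_id",
    "individual_id",
    "father_id",
    "mother_id",
    "sex",
    "phenotype",
]


@dataclass(frozen=True)
class SnpRecord:
    """One marker: identifier, chromosome, 1-based position, observed alleles."""

    snp_id: str
    chrom: str
    position: int
    alleles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"SNP {self.snp_id}: position must be >= 1")


@dataclass
class TrioCohort:
    """Father/mother/child genotypes for a set of trios.

    ``genotypes`` is an ``(n_samples, n_snps, 2)`` int8 array of allele
    codes (0 missing, 1..4 = A,C,G,T); allele order within a genotype is
    not meaningful.  ``trio_index`` holds ``(father_row, mother_row,
    child_row)`` triples; samples not belonging to any complete trio are
    retained and listed in ``unassigned_rows``.
    """

    samples: pd.DataFrame
    snps: list[SnpRecord]
    genotypes: np.ndarray
    trio_index: list[tuple[int, int, int]] = field(default_factory=list)
    unassigned_rows: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_samples = len(self.samples)
        if self.genotypes.shape != (n_samples, len(self.snps), 2):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{n_samples} samples x {len(self.snps)} SNPs"
            )
        for f, m, c in self.trio_index:
            if len({f, m, c}) != 3:
                raise ValueError("trio rows must be three distinct samples")

    # -- basic dimensions ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_trios(self) -> int:
        return len(self.trio_index)

    def founder_rows(self) -> np.ndarray:
        """Rows of parents in complete trios (the 'unaffected samples')."""
        rows = sorted({r for f, m, _ in self.trio_index for r in (f, m)})
        return np.asarray(rows, dtype=int)

    def child_rows(self) -> np.ndarray:
        return np.asarray(sorted({c for _, _, c in self.trio_index}), dtype=int)

    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    # -- subsetting ------------------------------------------------------
    def subset_snps(self, keep: np.ndarray) -> "TrioCohort":
        """New cohort with the boolean/int-indexed subset of SNPs."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        snps = [self.snps[i] for i in keep]
        return TrioCohort(
            samples=self.samples.copy(),
            snps=snps,
            genotypes=self.genotypes[:, keep, :].copy(),
            trio_index=list(self.trio_index),
            unassigned_rows=list(self.unassigned_rows),
        )

    def subset_samples(self, keep_rows: np.ndarray) -> "TrioCohort":
        """New cohort with a subset of sample rows; trios are rebuilt."""
        keep_rows = np.asarray(keep_rows)
        if keep_rows.dtype == bool:
            keep_rows = np.flatnonzero(keep_rows)
        samples = self.samples.iloc[keep_rows].reset_index(drop=True)
        geno = self.genotypes[keep_rows, :, :].copy()
        cohort = TrioCohort(samples=samples, snps=list(self.snps), genotypes=geno)
        cohort.rebuild_trio_index()
        return cohort

    def rebuild_trio_index(self) -> None:
        """Recompute trio_index/unassigned_rows from the pedigree pointers."""
        self.trio_index, self.unassigned_rows = _assemble_trios(self.samples)

    def equals(self, other: "TrioCohort") -> bool:
        return (
            self.samples.equals(other.samples)
            and self.snps == other.snps
            and np.array_equal(self.genotypes, other.genotypes)
            and self.trio_index == other.trio_index
        )


def _assemble_trios(samples: pd.DataFrame) -> tuple[list[tuple[int, int, int]], list[int]]:
    """Pair each child with its parents via (family_id, individual_id)."""
    key_to_row = {
        (fam, iid): row
        for row, (fam, iid) in enumerate(
            zip(samples["family_id"], samples["individual_id"])
        )
    }
    trios: list[tuple[int, int, int]] = []
    in_trio: set[int] = set()
    for row in range(len(samples)):
        fam = samples["family_id"].iat[row]
        fid = samples["father_id"].iat[row]
        mid = samples["mother_id"].iat[row]
        if str(fid) == "0" or str(mid) == "0":
            continue
        f_row = key_to_row.get((fam, fid))
        m_row = key_to_row.get((fam, mid))
        if f_row is None or m_row is None:
            continue
        trios.append((f_row, m_row, row))
        in_trio.update((f_row, m_row, row))
    unassigned = [r for r in range(len(samples)) if r not in in_trio]
    if unassigned:
        logger.info("%d sample(s) not part of a complete trio", len(unassigned))
    return trios, unassigned


# ---------------------------------------------------------------------------
# PLINK PED/MAP
# ---------------------------------------------------------------------------

def read_ped_map(ped_path, map_path) -> TrioCohort:
    """Read a PLINK text pedigree (PED) and marker map (MAP) into a cohort.

    The MAP file has 4 whitespace-separated columns (chrom, snp_id,
    genetic distance, bp position); the PED file has 6 pedigree columns
    followed by two allele symbols per SNP (A/C/G/T, 0 = missing).
    """
    snps: list[SnpRecord] = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise ValueError(f"{map_path}: line {ln}: expected 3 or 4 columns")
            chrom, snp_id = parts[0], parts[1]
            pos = int(parts[-1])
            snps.append(SnpRecord(snp_id=snp_id, chrom=chrom, position=pos))
    ids = [s.snp_id for s in snps]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{map_path}: duplicate SNP identifiers")

    rows = []
    geno_rows = []
    n_snps = len(snps)
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * n_snps} fields, "
                    f"found {len(parts)}"
                )
            rows.append(parts[:6])
            alleles = parts[6:]
            try:
                codes = [ALLELE_TO_CODE[a] for a in alleles]
            except KeyError as exc:
                raise ValueError(
                    f"{ped_path}: line {ln}: invalid allele symbol {exc.args[0]!r}"
                ) from None
            geno_rows.append(np.asarray(codes, dtype=np.int8).reshape(n_snps, 2))

    samples = pd.DataFrame(rows, columns=SAMPLE_COLUMNS)
    samples["sex"] = samples["sex"].astype(int)
    samples["phenotype"] = samples["phenotype"].astype(int)
    genotypes = (
        np.stack(geno_rows) if geno_rows else np.empty((0, n_snps, 2), dtype=np.int8)
    )
    cohort = TrioCohort(samples=samples, snps=snps, genotypes=genotypes)
    cohort.rebuild_trio_index()

    # record the allele symbols actually observed at each marker
    observed = _observed_alleles(cohort.genotypes)
    cohort.snps = [
        SnpRecord(s.snp_id, s.chrom, s.position, alleles=observed[j])
        for j, s in enumerate(cohort.snps)
    ]
    return cohort


def _observed_alleles(genotypes: np.ndarray) -> list[tuple[str, ...]]:
    out = []
    for j in range(genotypes.shape[1]):
        codes = np.unique(genotypes[:, j, :])
        out.append(tuple(CODE_TO_ALLELE[c] for c in codes if c != MISSING_CODE))
    return out


def write_ped_map(cohort: TrioCohort, ped_path, map_path) -> None:
    """Write the cohort back out as PLINK PED/MAP text."""
    with open(map_path, "w") as fh:
        for s in cohort.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.position}\n")
    lut = np.array(list(CODE_TO_ALLELE))
    flat = lut[cohort.genotypes.reshape(cohort.n_samples, -1)]
    with open(ped_path, "w") as fh:
        for row in range(cohort.n_samples):
            ped_cols = [str(v) for v in cohort.samples.iloc[row].tolist()]
            fh.write(" ".join(ped_cols + list(flat[row])) + "\n")


# ---------------------------------------------------------------------------
# Gene sets and hierarchy
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Term membership plus (optionally) a rooted DAG with computed levels.

    ``terms`` maps term_id -> (name, member gene set).  ``dag`` is the
    parent->child edge list; ``levels`` assigns each term 1 + the length
    of the shortest path from the unique root (root level 1), computed —
    never read from the source file.
    """

    terms: dict[str, tuple[str, set[str]]]
    dag: list[tuple[str, str]] = field(default_factory=list)
    levels: dict[str, int] = field(default_factory=dict)
    root: str | None = None

    def term_ids(self) -> list[str]:
        return sorted(self.terms)

    def members(self, term_id: str) -> set[str]:
        return self.terms[term_id][1]

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for _, genes in self.terms.values():
            out |= genes
        return out

    def children(self) -> dict[str, list[str]]:
        ch: dict[str, list[str]] = {t: [] for t in self.terms}
        for p, c in self.dag:
            ch.setdefault(p, []).append(c)
        return ch

    def propagate_up(self) -> None:
        """Make membership consistent with the DAG: a gene annotated to a
        child term is annotated to all its ancestors."""
        if not self.dag:
            return
        parents: dict[str, list[str]] = {}
        for p, c in self.dag:
            parents.setdefault(c, []).append(p)
        # children before parents: each term's membership is final before
        # it is handed upward (levels alone cannot order a DAG)
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.dag)
        order = reversed(list(nx.topological_sort(g)))
        for term in order:
            name, genes = self.terms[term]
            for p in parents.get(term, []):
                pname, pgenes = self.terms[p]
                self.terms[p] = (pname, pgenes | genes)

    def compute_levels(self) -> None:
        """BFS levels from the unique root; root has level 1."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.dag)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("term hierarchy contains a cycle")
        roots = [n for n in g.nodes if g.in_degree(n) == 0]
        if len(roots) != 1:
            raise ValueError(
                f"term hierarchy must have exactly one root, found {len(roots)}"
            )
        self.root = roots[0]
        self.levels = {}
        q = deque([(self.root, 1)])
        while q:
            node, lev = q.popleft()
            if node in self.levels:
                continue
            self.levels[node] = lev
            for child in g.successors(node):
                if child not in self.levels:
                    q.append((child, lev + 1))
        unreachable = set(self.terms) - set(self.levels)
        if unreachable:
            raise ValueError(
                f"{len(unreachable)} term(s) unreachable from root {self.root!r}"
            )


def read_gmt(path) -> GeneSetCollection:
    """Read GMT (term_id <TAB> description <TAB> gene ...), deduplicating
    repeated members with a logged count."""
    terms: dict[str, tuple[str, set[str]]] = {}
    n_dupes = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: expected >= 3 tab-separated fields")
            term_id, name = parts[0], parts[1]
            if term_id in terms:
                raise ValueError(f"{path}: line {ln}: duplicate term {term_id!r}")
            genes = [g for g in parts[2:] if g]
            n_dupes += len(genes) - len(set(genes))
            terms[term_id] = (name, set(genes))
    if n_dupes:
        logger.info("read_gmt: deduplicated %d repeated member(s)", n_dupes)
    return GeneSetCollection(terms=terms)


def read_hierarchy(path, collection: GeneSetCollection) -> GeneSetCollection:
    """Attach a parent->child edge table to a membership collection and
    compute levels.  Cycles or multiple roots are errors."""
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dupes = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: line {ln}: expected 2 columns")
            edge = (parts[0], parts[1])
            if edge in seen:
                n_dupes += 1
                continue
            seen.add(edge)
            edges.append(edge)
    if n_dupes:
        logger.info("read_hierarchy: deduplicated %d repeated edge(s)", n_dupes)
    for p, c in edges:
        for t in (p, c):
            if t not in collection.terms:
                collection.terms[t] = (t, set())
    collection.dag = edges
    collection.compute_levels()
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term_id in collection.term_ids():
            name, genes = collection.terms[term_id]
            fh.write("\t".join([term_id, name] + sorted(genes)) + "\n")


def write_hierarchy(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        fh.write("#parent_id\tchild_id\n")
        for p, c in sorted(collection.dag):
            fh.write(f"{p}\t{c}\n")


# ---------------------------------------------------------------------------
# Interactome
# ---------------------------------------------------------------------------

@dataclass
class Interactome:
    """Undirected protein-interaction graph over gene identifiers.

    The connectivity of a node is its degree: the number of partners of
    direct interaction.  No self-loops, no parallel edges.
    """

    adj: dict[str, set[str]]

    @classmethod
    def from_edges(cls, edges) -> "Interactome":
        adj: dict[str, set[str]] = {}
        n_dupes = 0
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                raise ValueError(f"self-loop edge {a!r}-{b!r} rejected")
            if b in adj.get(a, ()):  # already present
                n_dupes += 1
                continue
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        if n_dupes:
            logger.info("interactome: deduplicated %d repeated edge(s)", n_dupes)
        return cls(adj=adj)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.adj)

    @property
    def n_nodes(self) -> int:
        return len(self.adj)

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self.adj.values()) // 2

    def degree(self, node: str) -> int:
        return len(self.adj[node])

    def edges(self) -> list[tuple[str, str]]:
        out = []
        for a, nbrs in self.adj.items():
            for b in nbrs:
                if a < b:
                    out.append((a, b))
        return sorted(out)

    def density(self) -> float:
        n = self.n_nodes
        return 0.0 if n < 2 else 2.0 * self.n_edges / (n * (n - 1))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges())
        return g


def read_interactome(path) -> Interactome:
    """Read a 2-column undirected edge list (TSV/SIF-like).  Self-loops
    are rejected; duplicate edges are deduplicated with a logged count."""
    edges = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 3:  # SIF: node relation node
                a, b = parts[0], parts[2]
            elif len(parts) == 2:
                a, b = parts
            else:
                raise ValueError(f"{path}: line {ln}: expected 2 or 3 columns")
            if a == b:
                raise ValueError(f"{path}: line {ln}: self-loop {a!r} rejected")
            edges.append((a, b))
    return Interactome.from_edges(edges)


def write_interactome(interactome: Interactome, path) -> None:
    with open(path, "w") as fh:
        fh.write("#node_a\tnode_b\n")
        for a, b in interactome.edges():
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# BED gene intervals
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read gene intervals from BED (0-based half-open).  Returns a frame
    with columns chrom, start, end, gene_id."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: line {ln}: expected >= 4 columns")
            chrom, start, end, gene_id = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start >= end:
                raise ValueError(
                    f"{path}: line {ln}: start {start} >= end {end}"
                )
            rows.append((chrom, start, end, gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def write_bed(genes: pd.DataFrame, path) -> None:
    genes[["chrom", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )
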