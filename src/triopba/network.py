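"""Interactome connectivity scan over a ranked gene list.

The N most associated genes are mapped onto the interactome and joined
into a minimum connecting subnetwork: the union, over all seed pairs, of
connecting paths of length <= 2 — a direct interaction, or one external
(non-seed) intermediate node.  When several components arise only the
largest is kept.  The subnetwork's connectivity is the average, in the
full interactome, of the degrees of the connected genes — by default the
linked seed genes (a variant including intermediates sits behind
``seeds_only_connectivity=False``) — and its significance is the
empirical upper-tail probability of that average under repeated random
draws of N genes put through the same construction.  Starting from N = n_start the scan grows the seed list by
one gene until the connectivity is significant or n_max is reached.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .io import Interactome
from .sim import rng_for

logger = logging.getLogger("triopba")


@dataclass
class NetworkScanConfig:
    n_start: int = 10
    n_max: int = 200
    max_intermediates_per_link: int = 1
    n_null_samples: int = 1000
    alpha: float = 0.05
    seeds_only_connectivity: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_start > self.n_max:
            raise ValueError("n_start must be <= n_max")
        if self.n_null_samples < 100:
            raise ValueError("n_null_samples must be >= 100")
        if self.max_intermediates_per_link not in (0, 1):
            raise ValueError(
                "max_intermediates_per_link supports 0 (direct edges only) or "
                "1 (one external node per link)"
            )


@dataclass
class Subnetwork:
    """Largest component of the union of length-<=2 seed-connecting paths."""

    nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)
    seeds_linked: set[str] = field(default_factory=set)
    intermediates: set[str] = field(default_factory=set)
    seeds_unlinked: set[str] = field(default_factory=set)

    @property
    def is_empty(self) -> bool:
        return not self.nodes


@dataclass
class NetworkResult:
    n_final: int
    significant: bool
    observed_avg_connectivity: float
    empirical_p: float
    subnetwork: Subnetwork
    null_mean: float
    null_q95: float
    trace: list[tuple[int, float, float]]  # (N, statistic, empirical p)

    def to_dict(self) -> dict:
        return {
            "n_final": self.n_final,
            "significant": self.significant,
            "observed_avg_connectivity": self.observed_avg_connectivity,
            "empirical_p": self.empirical_p,
            "null_mean": self.null_mean,
            "null_q95": self.null_q95,
            "n_nodes": len(self.subnetwork.nodes),
            "n_edges": len(self.subnetwork.edges),
            "seeds_linked": sorted(self.subnetwork.seeds_linked),
            "intermediates": sorted(self.subnetwork.intermediates),
            "seeds_unlinked": sorted(self.subnetwork.seeds_unlinked),
            "trace": [
                {"n": n, "statistic": s, "empirical_p": p} for n, s, p in self.trace
            ],
            "note": "no multiplicity correction is applied across the N-scan",
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def write_edges_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#node_a\tnode_b\n")
            for a, b in sorted(self.subnetwork.edges):
                fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def _connect(seed_set: set, adj: dict, max_inter: int):
    """Edge set of the union of length-<=2 connecting paths between seeds."""
    edges: set[tuple[str, str]] = set()
    present = [s for s in seed_set if s in adj]
    present_set = set(present)
    for s in present:
        for nb in adj[s]:
            if nb in present_set and s < nb:
                edges.add((s, nb))
    if max_inter >= 1:
        counts: dict[str, int] = {}
        for s in present:
            for nb in adj[s]:
                if nb not in present_set:
                    counts[nb] = counts.get(nb, 0) + 1
        for x, cnt in counts.items():
            if cnt >= 2:  # on a path s1 - x - s2 for some seed pair
                for s in adj[x]:
                    if s in present_set:
                        edges.add((min(s, x), max(s, x)))
    return edges, present_set


def _largest_component(edges: set) -> tuple[set, set]:
    """Nodes and edges of the largest connected component (ties break on
    the lexicographically smallest node set)."""
    if not edges:
        return set(), set()
    adj: dict[str, set[str]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen: set[str] = set()
    best: set[str] = set()
    for start in sorted(adj):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in comp:
                    comp.add(nb)
                    stack.append(nb)
        seen |= comp
        if len(comp) > len(best):
            best = comp
    kept_edges = {e for e in edges if e[0] in best}
    return best, kept_edges


def minimal_connected_network(
    seeds, interactome: Interactome, max_intermediates_per_link: int = 1
) -> Subnetwork:
    """Minimum connecting subnetwork of the seed genes.

    Seeds absent from the interactome are dropped with a warning.  With
    ``max_intermediates_per_link = 1`` (the default) seed pairs may be
    joined through at most one external node; 0 allows direct
    interactions only.
    """
    if max_intermediates_per_link not in (0, 1):
        raise ValueError("max_intermediates_per_link supports only 0 or 1")
    seeds = list(dict.fromkeys(seeds))
    missing = [s for s in seeds if s not in interactome.adj]
    if missing:
        logger.warning(
            "%d seed(s) absent from the interactome: %s%s",
            len(missing),
            ", ".join(missing[:5]),
            "..." if len(missing) > 5 else "",
        )
    edges, present = _connect(set(seeds), interactome.adj, max_intermediates_per_link)
    nodes, edges = _largest_component(edges)
    sub = Subnetwork(
        nodes=nodes,
        edges=edges,
        seeds_linked=nodes & present,
        intermediates=nodes - present,
        seeds_unlinked=set(seeds) - nodes,
    )
    if sub.is_empty:
        logger.info("no seed pair connectable within the allowed path length")
    return sub


def avg_connectivity(
    subnetwork: Subnetwork, interactome: Interactome, seeds_only: bool = False
) -> float:
    """Mean full-interactome degree over the subnetwork's nodes."""
    nodes = subnetwork.seeds_linked if seeds_only else subnetwork.nodes
    if not nodes:
        raise ValueError("average connectivity of an empty subnetwork is undefined")
    return float(np.mean([len(interactome.adj[v]) for v in nodes]))


def _statistic(seed_set: set, interactome: Interactome, max_inter: int, seeds_only: bool) -> float:
    """Construction + statistic in one pass; empty subnetwork scores 0."""
    edges, present = _connect(seed_set, interactome.adj, max_inter)
    nodes, _ = _largest_component(edges)
    if seeds_only:
        nodes = nodes & present
    if not nodes:
        return 0.0
    return float(np.mean([len(interactome.adj[v]) for v in nodes]))


def empirical_null(
    N: int,
    interactome: Interactome,
    config: NetworkScanConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null sample of the connectivity statistic: random N-gene sets put
    through the same subnetwork construction.  Draws yielding an empty
    subnetwork score 0 (the least connected possible outcome)."""
    config = config or NetworkScanConfig()
    nodes = interactome.nodes
    if N > len(nodes):
        raise ValueError("N exceeds the interactome node count")
    if rng is None:
        rng = rng_for(config.seed, "network-null", N)
    nodes_arr = np.asarray(nodes)
    out = np.empty(config.n_null_samples)
    for i in range(config.n_null_samples):
        draw = nodes_arr[rng.choice(len(nodes_arr), size=N, replace=False)]
        out[i] = _statistic(
            set(draw),
            interactome,
            config.max_intermediates_per_link,
            config.seeds_only_connectivity,
        )
    return out


def scan(
    ranked_genes, interactome: Interactome, config: NetworkScanConfig | None = None
) -> NetworkResult:
    """Incremental significance scan over the ranked gene list.

    For N = n_start .. n_max the top-N genes (of those present in the
    interactome) are connected, the average connectivity computed, and
    the add-one empirical p-value

        p = (1 + #{null >= observed}) / (1 + n_null_samples)

    evaluated against a freshly drawn null for that N.  The scan stops at
    the first significant N; otherwise it returns the best (lowest-p) N
    flagged not significant.
    """
    config = config or NetworkScanConfig()
    ranked_genes = list(ranked_genes)
    in_graph = [g for g in ranked_genes if g in interactome.adj]
    dropped = len(ranked_genes) - len(in_graph)
    if dropped:
        logger.info("scan: %d ranked gene(s) not in the interactome", dropped)
    if len(in_graph) < config.n_start:
        raise ValueError(
            f"only {len(in_graph)} ranked genes map into the interactome; "
            f"n_start={config.n_start}"
        )

    trace: list[tuple[int, float, float]] = []
    best: tuple[float, int, float, np.ndarray] | None = None
    stopped: tuple[float, int, float, np.ndarray] | None = None
    n_max = min(config.n_max, len(in_graph))
    for N in range(config.n_start, n_max + 1):
        seed_set = set(in_graph[:N])
        observed = _statistic(
            seed_set,
            interactome,
            config.max_intermediates_per_link,
            config.seeds_only_connectivity,
        )
        null = empirical_null(N, interactome, config)
        p = (1.0 + int((null >= observed).sum())) / (1.0 + config.n_null_samples)
        trace.append((N, observed, p))
        if best is None or p < best[0]:
            best = (p, N, observed, null)
        if p <= config.alpha:
            stopped = (p, N, observed, null)  # first significant N
            break

    p, N, observed, null = stopped if stopped is not None else best
    sub = minimal_connected_network(
        in_graph[:N], interactome, config.max_intermediates_per_link
    )
    return NetworkResult(
        n_final=N,
        significant=bool(p <= config.alpha),
        observed_avg_connectivity=observed,
        empirical_p=float(p),
        subnetwork=sub,
        null_mean=float(null.mean()),
        null_q95=float(np.quantile(null, 0.95)),
        trace=trace,
    )
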