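"""Projection of SNP-level TDT p-values onto genes.

A SNP belongs to a gene when it falls inside the gene limits extended by
a flank (500 bp by default) on both sides, boundary inclusive; a SNP
inside several overlapping gene windows counts for each of them.  The
gene score is the best (smallest) p-value over its mapped SNPs, so a
gene's evidence is carried by its single most associated marker.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("triopba")

GENE_SCORE_COLUMNS = ["gene_id", "best_p", "best_snp_id", "n_snps_mapped", "gene_length"]


def map_snps_to_genes(
    snps, genes: pd.DataFrame, flank_bp: int = 500
) -> tuple[dict[str, set[str]], list[str]]:
    """Assign SNPs to genes by position.

    ``snps`` is a sequence of records with ``snp_id``, ``chrom`` and
    1-based ``position``; ``genes`` a BED-convention frame (0-based
    half-open).  A SNP maps to every gene whose closed 1-based interval
    ``[start + 1 - flank, end + flank]`` contains it.  Returns the
    snp -> gene-set map plus the list of extra-genic SNP ids.
    """
    snp_chroms = {s.chrom for s in snps}
    gene_chroms = set(genes["chrom"])
    if snp_chroms.isdisjoint(gene_chroms):
        raise ValueError("no chromosome shared between SNP map and gene intervals")
    only_snp = snp_chroms - gene_chroms
    if only_snp:
        logger.warning(
            "%d chromosome(s) present in the SNP map but absent from the gene "
            "intervals: %s",
            len(only_snp),
            ", ".join(sorted(only_snp)[:5]),
        )

    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, gid in genes[["chrom", "start", "end", "gene_id"]].itertuples(
        index=False
    ):
        # BED 0-based half-open -> 1-based closed, then widen by the flank
        by_chrom.setdefault(chrom, []).append(
            (int(start) + 1 - flank_bp, int(end) + flank_bp, gid)
        )
    for windows in by_chrom.values():
        windows.sort()

    mapping: dict[str, set[str]] = {}
    extra_genic: list[str] = []
    for s in snps:
        windows = by_chrom.get(s.chrom, ())
        hits = {gid for lo, hi, gid in windows if lo <= s.position <= hi}
        if hits:
            mapping[s.snp_id] = hits
        else:
            extra_genic.append(s.snp_id)
    if not mapping:
        raise ValueError("no SNP maps to any gene: check coordinates and flank")
    return mapping, extra_genic


def best_p_per_gene(
    tdt_results: pd.DataFrame,
    snp_to_genes: dict[str, set[str]],
    gene_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-gene minimum SNP p-value (ties: lowest p, then snp_id).

    Genes with no mapped, tested SNP are absent from the table.  The
    result is sorted ascending by ``best_p`` (ties by gene_id) with
    columns gene_id, best_p, best_snp_id, n_snps_mapped, gene_length.
    """
    rows = []
    for snp_id, p in zip(tdt_results["snp_id"], tdt_results["p"]):
        if not np.isfinite(p):
            continue
        for gid in snp_to_genes.get(snp_id, ()):
            rows.append((gid, float(p), snp_id))
    if not rows:
        raise ValueError("no mapped SNP carries a TDT result")
    long = pd.DataFrame(rows, columns=["gene_id", "p", "snp_id"])
    long = long.sort_values(["gene_id", "p", "snp_id"], kind="mergesort")
    best = long.groupby("gene_id", sort=True).first().reset_index()
    counts = long.groupby("gene_id", sort=True).size().rename("n_snps_mapped")
    table = best.merge(counts, on="gene_id")
    table = table.rename(columns={"p": "best_p", "snp_id": "best_snp_id"})
    lengths = gene_lengths or {}
    table["gene_length"] = [int(lengths.get(g, -1)) for g in table["gene_id"]]
    table = table.sort_values(["best_p", "gene_id"], kind="mergesort").reset_index(drop=True)
    return table[GENE_SCORE_COLUMNS]


def write_gene_scores(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
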