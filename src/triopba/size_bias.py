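"""Gene-length bias diagnostics for significant terms.

Best-SNP gene p-values are biased toward long genes: a longer gene hosts
more markers and so more chances for a small p-value by luck alone.  The
diagnostic flags each significant term whose median member-gene length
exceeds the third quartile of the per-term median lengths over all
tested terms — terms that could owe their signal to gene size rather
than biology.  The report inspects; it does not correct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneSetCollection

logger = logging.getLogger("triopba")


@dataclass
class BiasReport:
    per_term: pd.DataFrame  # term_id, q_fdr, n_with_length, median_length, flag_biased
    q3_of_term_medians: float
    background: dict[str, float]  # summary of the scored-gene length distribution

    def flagged(self) -> list[str]:
        return self.per_term.loc[self.per_term["flag_biased"], "term_id"].tolist()

    def write_tsv(self, path) -> None:
        self.per_term.to_csv(path, sep="\t", index=False, float_format="%.6g")


def bias_report(
    enrichment: pd.DataFrame,
    collection: GeneSetCollection,
    gene_lengths: dict[str, int],
    scored_genes=None,
    alpha: float = 0.05,
) -> BiasReport:
    """Flag significant terms with unusually long member genes.

    Per-term medians are taken over scored member genes with known
    length ("gene size" = genomic span); the reference third quartile is
    computed over the medians of ALL tested terms (linear-interpolation
    quantile), and a term is flagged iff its median strictly exceeds it.
    Requires lengths for at least 95% of scored genes.
    """
    if scored_genes is None:
        scored = set(gene_lengths)
    else:
        scored = set(scored_genes)
        with_len = sum(1 for g in scored if g in gene_lengths)
        if scored and with_len / len(scored) < 0.95:
            raise ValueError(
                f"gene lengths available for only {with_len}/{len(scored)} scored genes"
            )

    def term_median(term_id: str) -> tuple[int, float]:
        members = collection.members(term_id) & scored
        lengths = [gene_lengths[g] for g in members if g in gene_lengths]
        return len(lengths), (float(np.median(lengths)) if lengths else np.nan)

    medians = {}
    for term_id in enrichment["term_id"]:
        n, med = term_median(term_id)
        if n == 0:
            logger.warning("size_bias: term %s has no length data; excluded", term_id)
            continue
        medians[term_id] = (n, med)
    if not medians:
        raise ValueError("no tested term has gene-length data")

    q3 = float(np.quantile([m for _n, m in medians.values()], 0.75))

    sig = enrichment[enrichment["q_fdr"] < alpha]
    rows = []
    for term_id, q in zip(sig["term_id"], sig["q_fdr"]):
        if term_id not in medians:
            continue
        n, med = medians[term_id]
        rows.append((term_id, float(q), n, med, bool(med > q3)))
    per_term = pd.DataFrame(
        rows, columns=["term_id", "q_fdr", "n_with_length", "median_length", "flag_biased"]
    )

    bg = np.asarray([gene_lengths[g] for g in scored if g in gene_lengths], dtype=float)
    background = {
        "n": float(bg.size),
        "min": float(bg.min()),
        "q1": float(np.quantile(bg, 0.25)),
        "median": float(np.median(bg)),
        "q3": float(np.quantile(bg, 0.75)),
        "max": float(bg.max()),
    }
    return BiasReport(per_term=per_term, q3_of_term_medians=q3, background=background)
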