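"""Ranked-list gene-set association by logistic regression.

A term (gene set) is associated when more of its member genes than
expected by chance sit near the top of the gene list ranked by best SNP
p-value — the members need not be individually significant.  The test
regresses binary term membership, over all scored genes, on a transform
of the gene score:

    logit P(gene in term) = beta0 + beta1 * x(gene)

with ``x`` the percentile rank of -log10(best_p) by default (1 = most
associated; mid-ranks for ties), and reports the one-sided p-value for
``beta1 > 0``.  Terms are pre-filtered by hierarchy level and by the
number of member genes actually scored, so terms too unspecific or too
specific to be informative never enter the multiple-testing burden.
False discoveries are controlled by Benjamini-Hochberg; when a study
spans several populations or chips the adjustment pools every test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.stats import chi2 as chi2_dist
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError

from .io import GeneSetCollection

logger = logging.getLogger("triopba")

ENRICHMENT_COLUMNS = [
    "term_id",
    "name",
    "level",
    "size_tested",
    "coefficient",
    "p_raw",
    "q_fdr",
    "separated",
    "top_decile_members",
]


@dataclass
class PbaConfig:
    """Term filters and test options.

    Level bounds refer to the shortest-path depth from the hierarchy root
    (root = 1); size bounds count member genes present in the gene score
    table, not the full annotation.
    """

    level_min: int = 3
    level_max: int = 13
    size_min: int = 5
    size_max: int = 600
    alpha_fdr: float = 0.05
    score_transform: str = "rank_percentile"  # or "neg_log10_p"

    def __post_init__(self) -> None:
        if self.level_min > self.level_max:
            raise ValueError("level_min must be <= level_max")
        if self.size_min > self.size_max:
            raise ValueError("size_min must be <= size_max")
        if self.score_transform not in ("rank_percentile", "neg_log10_p"):
            raise ValueError(f"unknown score_transform {self.score_transform!r}")


class TermAssociation(NamedTuple):
    coefficient: float
    p_raw: float
    separated: bool


def transform_scores(best_p: np.ndarray, transform: str) -> np.ndarray:
    """Gene-score predictor: higher = more associated."""
    p = np.clip(np.asarray(best_p, dtype=float), 1e-300, 1.0)
    if transform == "rank_percentile":
        # mid-rank percentile of -log10(p) in (0, 1]
        return rankdata(-np.log10(p), method="average") / len(p)
    if transform == "neg_log10_p":
        return -np.log10(p)
    raise ValueError(f"unknown score_transform {transform!r}")


def filter_terms(
    collection: GeneSetCollection, scored_genes, config: PbaConfig
) -> list[tuple[str, int, int]]:
    """Terms to test: level within bounds AND scored-member count within
    bounds.  Returns (term_id, level, size_tested) triples."""
    if not collection.levels:
        raise ValueError("hierarchy levels not computed; read a hierarchy first")
    scored = set(scored_genes)
    kept = []
    n_level, n_size = 0, 0
    for term_id in collection.term_ids():
        level = collection.levels[term_id]
        if not (config.level_min <= level <= config.level_max):
            n_level += 1
            continue
        size = len(collection.members(term_id) & scored)
        if not (config.size_min <= size <= config.size_max):
            n_size += 1
            continue
        kept.append((term_id, level, size))
    if not kept:
        raise ValueError(
            f"no term passes the filters (level bounds removed {n_level}, "
            f"size bounds removed {n_size})"
        )
    return kept


def term_association(
    gene_scores: pd.DataFrame, members, transform: str = "rank_percentile"
) -> TermAssociation:
    """One term's logistic-regression association.

    ``gene_scores`` is the per-gene score table (needs gene_id, best_p);
    ``members`` the term's gene set.  Returns the membership coefficient
    and the one-sided p-value for enrichment toward low p-values; under
    complete separation the p-value falls back to a ridge-penalised
    likelihood-ratio test and is flagged.
    """
    x = transform_scores(gene_scores["best_p"].to_numpy(), transform)
    y = np.isin(gene_scores["gene_id"].to_numpy(), list(members)).astype(float)
    if x.std() == 0:
        raise ValueError("zero variance in the transformed gene score")
    if y.min() == y.max():
        raise ValueError("term membership must vary across scored genes")

    design = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        coef = float(fit.params[1])
        se = float(fit.bse[1])
        if not (np.isfinite(coef) and np.isfinite(se)) or abs(coef) > 30 or se > 1e3:
            raise _Separation()
        if not fit.mle_retvals.get("converged", True):
            raise _Separation()
        # signed likelihood-ratio test: one-sided for enrichment toward low
        # p-values.  (The Wald statistic deflates under strong enrichment —
        # the Hauck-Donner effect — so the LR form is used throughout.)
        ybar = y.mean()
        ll_null = len(y) * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))
        lr = max(0.0, 2.0 * (float(fit.llf) - ll_null))
        p_two = float(chi2_dist.sf(lr, 1))
        p_one = p_two / 2.0 if coef > 0 else 1.0 - p_two / 2.0
        return TermAssociation(coef, p_one, False)
    except (_Separation, PerfectSeparationError, np.linalg.LinAlgError, ConvergenceWarning):
        coef, p = _ridge_lr_fallback(x, y)
        return TermAssociation(coef, p, True)


class _Separation(Exception):
    pass


def _ridge_lr_fallback(x: np.ndarray, y: np.ndarray, lam: float = 1e-3):
    """One-sided likelihood-ratio p-value from a weakly ridge-penalised
    logistic fit; used when the unpenalised MLE does not exist."""

    def nll(beta):
        eta = beta[0] + beta[1] * x
        # -log L = sum log(1 + exp(eta)) - y * eta, computed stably
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta) + lam * beta[1] ** 2)

    res = minimize(nll, x0=np.zeros(2), method="BFGS")
    beta = res.x
    ll_alt = -(nll(beta) - lam * beta[1] ** 2)
    ybar = y.mean()
    ll_null = len(y) * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))
    lr = max(0.0, 2.0 * (ll_alt - ll_null))
    p_two = float(chi2_dist.sf(lr, 1))
    p_one = p_two / 2.0 if beta[1] > 0 else 1.0 - p_two / 2.0
    return float(beta[1]), p_one


def adjust_fdr(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, >= p elementwise)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_pba(
    gene_scores: pd.DataFrame,
    collection: GeneSetCollection,
    config: PbaConfig | None = None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Full term association over the filtered collection.

    Set ``adjust=False`` when q-values will be computed jointly across
    several runs with :func:`pool_fdr` (the default for multi-population
    studies, where every individual test enters one adjustment).
    """
    config = config or PbaConfig()
    tested = filter_terms(collection, gene_scores["gene_id"], config)
    x = transform_scores(gene_scores["best_p"].to_numpy(), config.score_transform)
    top_decile = set(gene_scores["gene_id"].to_numpy()[x >= 0.9])

    rows = []
    for term_id, level, size in tested:
        members = collection.members(term_id)
        assoc = term_association(gene_scores, members, config.score_transform)
        rows.append(
            {
                "term_id": term_id,
                "name": collection.name(term_id),
                "level": level,
                "size_tested": size,
                "coefficient": assoc.coefficient,
                "p_raw": assoc.p_raw,
                "q_fdr": np.nan,
                "separated": assoc.separated,
                "top_decile_members": ",".join(sorted(members & top_decile)),
            }
        )
    table = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    if adjust:
        table["q_fdr"] = adjust_fdr(table["p_raw"].to_numpy())
        table = sort_enrichment(table)
    return table


def sort_enrichment(table: pd.DataFrame) -> pd.DataFrame:
    return table.sort_values(
        ["q_fdr", "p_raw", "term_id"], kind="mergesort"
    ).reset_index(drop=True)


def pool_fdr(tables: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Joint BH adjustment over the pooled tests of several runs
    (populations/chips); every individual test is considered."""
    labels, sizes, pooled = [], [], []
    for label, t in tables.items():
        labels.append(label)
        sizes.append(len(t))
        pooled.append(t["p_raw"].to_numpy())
    q = adjust_fdr(np.concatenate(pooled)) if pooled else np.array([])
    out = {}
    offset = 0
    for label, size in zip(labels, sizes):
        t = tables[label].copy()
        t["q_fdr"] = q[offset : offset + size]
        out[label] = sort_enrichment(t)
        offset += size
    return out


def write_enrichment(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
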