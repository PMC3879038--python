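import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

import triopba as tp
from triopba.io import GeneSetCollection
from triopba.pba import (
    PbaConfig,
    adjust_fdr,
    filter_terms,
    run_pba,
    term_association,
    transform_scores,
)

from conftest import bh_stepup_oracle


def scores_frame(n=400, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {"gene_id": [f"G{i:04d}" for i in range(n)], "best_p": np.sort(rng.random(n))}
    )


def toy_collection(levels_and_sizes, genes):
    """Chain hierarchy root -> T1 -> T2 ... with prescribed member sets."""
    terms = {"root": ("root", set())}
    dag = []
    prev = "root"
    for i, members in enumerate(levels_and_sizes, start=1):
        tid = f"T{i}"
        terms[tid] = (tid, set(members))
        dag.append((prev, tid))
        prev = tid
    coll = GeneSetCollection(terms=terms, dag=dag)
    coll.compute_levels()
    return coll


class TestFilterTerms:
    def test_level_and_size_bounds(self):
        genes = [f"G{i:04d}" for i in range(100)]
        coll = toy_collection(
            [genes[:50], genes[:10], genes[:4], genes[:60]], genes
        )  # T1 level 2, T2 level 3, T3 level 4 (4 scored), T4 level 5
        kept = filter_terms(coll, genes, PbaConfig(size_min=5, size_max=55))
        ids = [t for t, _l, _s in kept]
        assert "T1" not in ids  # level 2 excluded
        assert "T2" in ids
        assert "T3" not in ids  # only 4 scored members
        assert "T4" not in ids  # 60 > 55
    def test_size_counts_scored_genes_only(self):
        genes = [f"G{i:04d}" for i in range(700)]
        coll = toy_collection([genes[:10], genes], genes)  # T2 level 3: all 700
        kept = filter_terms(coll, genes[:580], PbaConfig())
        sizes = {t: s for t, _l, s in kept}
        assert sizes["T2"] == 580  # 700 annotated, 580 scored -> included

    def test_empty_result_is_an_error(self):
        genes = [f"G{i}" for i in range(20)]
        coll = toy_collection([genes[:10]], genes)
        with pytest.raises(ValueError, match="level bounds"):
            filter_terms(coll, genes, PbaConfig(level_min=5))


class TestTermAssociation:
    def test_extreme_enrichment_is_overwhelming(self):
        scores = scores_frame(1000)
        members = set(scores["gene_id"].head(20))  # the 20 lowest p-values
        assoc = term_association(scores, members)
        assert assoc.coefficient > 0
        assert assoc.p_raw < 1e-6

    def test_anti_enrichment_one_sided_p_near_one(self):
        scores = scores_frame(1000)
        members = set(scores["gene_id"].tail(20))
        assoc = term_association(scores, members)
        assert assoc.p_raw > 0.9

    def test_null_p_values_uniform(self):
        """Random memberships give uniform one-sided p-values."""
        scores = scores_frame(400, seed=5)
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(400):
            members = set(rng.choice(scores["gene_id"], size=25, replace=False))
            ps.append(term_association(scores, members).p_raw)
        assert kstest(ps, "uniform").pvalue > 0.001

    def test_zero_variance_score_is_an_error(self):
        scores = pd.DataFrame({"gene_id": ["a", "b", "c"], "best_p": [0.5] * 3})
        scores = pd.concat([scores] * 4, ignore_index=True)
        scores["gene_id"] = [f"g{i}" for i in range(12)]
        with pytest.raises(ValueError, match="variance|membership"):
            term_association(scores, {"g0", "g1"}, transform="neg_log10_p")

    def test_rank_transform_invariant_to_monotone_p_transform(self):
        scores = scores_frame(300, seed=9)
        rng = np.random.default_rng(10)
        members = set(rng.choice(scores["gene_id"], size=20, replace=False))
        a = term_association(scores, members, "rank_percentile")
        warped = scores.copy()
        warped["best_p"] = scores["best_p"] ** 3  # strictly monotone
        b = term_association(warped, members, "rank_percentile")
        assert a.p_raw == pytest.approx(b.p_raw, rel=1e-9)


class TestAdjustFdr:
    def test_hand_computed_example(self):
        q = adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.3])[0] == pytest.approx(0.3)

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=10)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_stepup_oracle_and_bh_properties(self, pvals):
        q = adjust_fdr(pvals)
        oracle = bh_stepup_oracle(pvals)
        assert np.allclose(q, oracle, atol=1e-12)
        assert (q >= np.asarray(pvals) - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])


class TestRunPba:
    def test_relabeling_invariance(self, small_study):
        _cfg, ann, cohorts, _inter = small_study
        cohort, _ = cohorts["pop1"]
        clean, _ = tp.run_qc(cohort)
        res = tp.run_tdt(clean)
        mapping, _ = tp.map_snps_to_genes(clean.snps, ann.genes)
        scores = tp.best_p_per_gene(res, mapping, ann.gene_lengths())
        cfg = PbaConfig(size_min=3)
        base = run_pba(scores, ann.collection, cfg)

        # consistent relabeling of every gene id
        relabel = {g: f"X{g}" for g in ann.collection.all_genes() | set(scores.gene_id)}
        scores2 = scores.copy()
        scores2["gene_id"] = [relabel[g] for g in scores2["gene_id"]]
        coll2 = GeneSetCollection(
            terms={
                t: (n, {relabel.get(g, g) for g in m})
                for t, (n, m) in ann.collection.terms.items()
            },
            dag=list(ann.collection.dag),
        )
        coll2.compute_levels()
        other = run_pba(scores2, coll2, cfg)
        assert np.allclose(base["p_raw"], other["p_raw"])
        assert np.allclose(base["q_fdr"], other["q_fdr"])

    def test_determinism(self, small_study):
        _cfg, ann, cohorts, _inter = small_study
        cohort, _ = cohorts["pop2"]
        clean, _ = tp.run_qc(cohort)
        res = tp.run_tdt(clean)
        mapping, _ = tp.map_snps_to_genes(clean.snps, ann.genes)
        scores = tp.best_p_per_gene(res, mapping, ann.gene_lengths())
        a = run_pba(scores, ann.collection, PbaConfig(size_min=3))
        b = run_pba(scores, ann.collection, PbaConfig(size_min=3))
        pd.testing.assert_frame_equal(a, b)

    def test_pooled_fdr_spans_populations(self):
        t1 = pd.DataFrame({"term_id": ["a", "b"], "p_raw": [0.01, 0.5],
                           "q_fdr": np.nan})
        t2 = pd.DataFrame({"term_id": ["a", "b"], "p_raw": [0.02, 0.9],
                           "q_fdr": np.nan})
        pooled = tp.pool_fdr({"x": t1, "y": t2})
        all_q = np.sort(
            np.concatenate([pooled["x"]["q_fdr"], pooled["y"]["q_fdr"]])
        )
        expected = np.sort(adjust_fdr([0.01, 0.5, 0.02, 0.9]))
        assert np.allclose(all_q, expected)
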