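import itertools
from math import comb

import numpy as np
import pytest

import triopba as tp
from triopba.qc import QcThresholds, hwe_chi2_test, hwe_exact_test, mendelian_consistent, run_qc
from triopba.sim import SimConfig, generate_cohort

from conftest import BIALLELIC_GENOTYPES, gamete_consistent


class TestMendelianConsistency:
    @pytest.mark.parametrize(
        "f,m,c,expected",
        [
            (("A", "A"), ("A", "A"), ("A", "G"), False),
            (("A", "G"), ("A", "G"), ("G", "G"), True),
            (("A", "A"), ("G", "G"), ("A", "A"), False),
            (("A", "A"), ("G", "G"), ("A", "G"), True),
        ],
    )
    def test_examples(self, f, m, c, expected):
        assert mendelian_consistent(f, m, c) is expected

    def test_missing_members_non_assessable(self):
        assert mendelian_consistent(None, ("A", "A"), ("A", "G"))
        assert mendelian_consistent(("0", "0"), ("A", "A"), ("G", "G"))

    def test_exhaustive_against_gamete_enumeration(self):
        """All 27 biallelic trio genotype combinations match the
        brute-force gamete oracle."""
        for f, m, c in itertools.product(BIALLELIC_GENOTYPES, repeat=3):
            assert mendelian_consistent(f, m, c) == gamete_consistent(f, m, c)


def hwe_exact_oracle(n_aa, n_ab, n_bb):
    """Exact HWE p by integer-arithmetic enumeration of heterozygote
    counts conditional on allele totals (independent of the gammaln
    implementation)."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    denom = comb(2 * n, na)

    def prob(h):
        if (na - h) % 2 or h > min(na, nb):
            return 0.0
        return comb(n, (na - h) // 2) * comb(n - (na - h) // 2, h) * 2**h / denom

    probs = {h: prob(h) for h in range(min(na, nb) + 1)}
    p_obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestHweExact:
    def test_extreme_heterozygote_excess(self):
        assert hwe_exact_test(0, 100, 0) < 1e-5

    def test_modal_configuration_near_one(self):
        assert hwe_exact_test(25, 50, 25) > 0.5

    def test_all_zero_counts_defined_as_one(self):
        assert hwe_exact_test(0, 0, 0) == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            counts = rng.integers(0, 18, size=3)
            if counts.sum() == 0 or counts.sum() > 50:
                continue
            got = hwe_exact_test(*map(int, counts))
            want = hwe_exact_oracle(*map(int, counts))
            assert got == pytest.approx(want, rel=1e-9)

    def test_chi2_variant_agrees_roughly_at_large_counts(self):
        exact = hwe_exact_test(100, 180, 120)
        chi2 = hwe_chi2_test(100, 180, 120)
        assert abs(np.log10(exact + 1e-12) - np.log10(chi2 + 1e-12)) < 1.0


def clean_cohort(n_trios=100, n_snps=400, seed=5):
    cfg = SimConfig(
        n_trios=n_trios, n_snps=n_snps, n_genes=100, n_terms=10,
        term_size_range=(5, 20), maf_range=(0.2, 0.4), tau=0.5,
        missing_rate=0.0, mendel_error_rate=0.0, seed=seed,
    )
    cohort, _ = generate_cohort(cfg, "pop1")
    return cohort


def plant_violations(cohort):
    """Corrupt a clean cohort with exactly countable QC violations:
    10 high-missing SNPs, 5 low-MAF SNPs, 3 Mendelian-error SNPs,
    2 HWE-violating SNPs, and 1 broken trio."""
    g = cohort.genotypes
    rng = np.random.default_rng(99)
    n_samples = cohort.n_samples

    # SNPs 0-9: missing in 25% of samples (> 20% threshold)
    for j in range(10):
        rows = rng.choice(n_samples, size=int(0.25 * n_samples) + 1, replace=False)
        g[rows, j, :] = 0

    def observed_pair(j):
        codes = np.unique(g[:, j, :])
        codes = [int(c) for c in codes if c > 0]
        assert len(codes) == 2
        return codes

    # SNPs 10-14: founder MAF below 0.5% (single minor-allele copy)
    for j in range(10, 15):
        a, b = observed_pair(j)
        g[:, j, :] = a  # monomorphic in the first allele
        g[0, j, 0] = b  # father of trio 0 carries 1 copy of the other

    # SNPs 15-17: one Mendelian-impossible trio (aa x aa -> ab)
    for j in range(15, 18):
        a, b = observed_pair(j)
        f, m, c = cohort.trio_index[1]
        g[f, j, :] = a
        g[m, j, :] = a
        g[c, j, 0] = b
        g[c, j, 1] = a

    # SNPs 18-19: all founders heterozygous (gross HWE violation)
    for j in (18, 19):
        a, b = observed_pair(j)
        g[:, j, 0] = a
        g[:, j, 1] = b

    # break the last trio: drop the father's row entirely
    f, _m, _c = cohort.trio_index[-1]
    keep = np.ones(n_samples, dtype=bool)
    keep[f] = False
    return cohort.subset_samples(keep)


class TestRunQc:
    def test_planted_violations_removed_at_the_right_steps(self):
        cohort = plant_violations(clean_cohort())
        clean, report = run_qc(cohort)
        assert report.removed("snp_call_rate") == 10
        assert report.removed("sample_missingness") == 0
        assert report.removed("incomplete_trios") == 1
        assert report.removed("founder_maf") == 5
        assert report.removed("mendelian_errors") == 3
        assert report.removed("founder_hwe") == 2
        assert clean.n_snps == 400 - 20
        assert clean.n_trios == 99

    def test_counts_balance_at_every_step(self):
        cohort = plant_violations(clean_cohort(seed=6))
        _clean, report = run_qc(cohort)
        frame = report.to_frame()
        totals = {"SNPs": cohort.n_snps, "trios": cohort.n_trios + 1, "samples": None}
        prev = {}
        for _, row in frame.iterrows():
            if row["unit"] in prev:
                assert row["removed"] + row["retained"] <= prev[row["unit"]]
            prev[row["unit"]] = row["retained"]

    def test_clean_cohort_loses_nothing_at_corruption_steps(self):
        _clean, report = run_qc(clean_cohort(seed=8))
        for step in ("snp_call_rate", "sample_missingness", "incomplete_trios",
                     "mendelian_errors", "founder_maf"):
            assert report.removed(step) == 0

    def test_qc_is_idempotent(self):
        cohort = plant_violations(clean_cohort(seed=9))
        clean1, _ = run_qc(cohort)
        clean2, report2 = run_qc(clean1)
        assert clean2.n_snps == clean1.n_snps
        assert clean2.n_trios == clean1.n_trios
        assert all(removed == 0 for _s, _u, removed, _r in report2.steps)

    def test_empty_cohort_after_qc_is_an_error(self):
        cohort = clean_cohort(n_trios=10, n_snps=120)
        cohort.genotypes[:, :, :] = 0  # everything missing
        with pytest.raises(ValueError):
            run_qc(cohort)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            QcThresholds(maf_min=0.0)
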