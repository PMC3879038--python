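"""Trio-cohort quality control.

Filters are applied in a fixed, logged order — (1) SNP call rate,
(2) sample missingness, (3) incomplete-trio removal, (4) founder MAF,
(5) Mendelian-error SNPs, (6) founder Hardy-Weinberg — and each step's
attrition is recorded so the report reads like a per-step QC table.
MAF and HWE are computed on founders (parents) only: children are
excluded because transmission distortion at a true risk locus would
masquerade as a frequency or equilibrium violation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

from .genotypes import (
    MENDEL_OK,
    allele_counts,
    dosage_matrix,
    minor_major_codes,
    missing_mask,
    trio_dosages,
)
from .io import TrioCohort

logger = logging.getLogger("triopba")


@dataclass
class QcThresholds:
    """QC cutoffs; defaults follow standard practice for trio GWAS panels
    (20% SNP missingness, 0.5% MAF, HWE p < 1e-5 in founders, 5% sample
    missingness)."""

    snp_missing_max: float = 0.20
    maf_min: float = 0.005
    hwe_alpha: float = 1e-5
    sample_missing_max: float = 0.05
    drop_mendel_snps: bool = True
    hwe_chi2: bool = False  # use the chi-square approximation instead of exact

    def __post_init__(self) -> None:
        for name in ("snp_missing_max", "maf_min", "hwe_alpha", "sample_missing_max"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class QcReport:
    """Per-step attrition: (step, unit, removed, retained)."""

    steps: list[tuple[str, str, int, int]] = field(default_factory=list)

    def add(self, step: str, unit: str, removed: int, retained: int) -> None:
        self.steps.append((step, unit, removed, retained))
        logger.info("QC %-28s removed %6d %-7s retained %6d", step, removed, unit, retained)

    def removed(self, step: str) -> int:
        for s, _u, rem, _ret in self.steps:
            if s == step:
                return rem
        raise KeyError(step)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "unit", "removed", "retained"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def mendelian_consistent(father_gt, mother_gt, child_gt) -> bool:
    """Can the child's alleles be split into one from each parent?

    Genotypes are allele pairs (e.g. ``("A", "G")``); ``None`` or any
    missing allele ("0") makes the trio non-assessable and returns True.
    """
    gts = [father_gt, mother_gt, child_gt]
    if any(g is None or "0" in g for g in gts):
        return True
    (c1, c2) = child_gt
    f, m = set(father_gt), set(mother_gt)
    return (c1 in f and c2 in m) or (c2 in f and c1 in m)


def hwe_exact_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Two-sided exact Hardy-Weinberg test (conditional on allele counts).

    Sums the probabilities of all heterozygote counts no more likely than
    the observed one, conditioning on the observed allele totals.  An
    all-zero table is defined to have p = 1.
    """
    if min(n_hom_minor, n_het, n_hom_major) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom_minor + n_het + n_hom_major
    if n == 0:
        return 1.0
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    rare, common = min(n_minor, n_major), max(n_minor, n_major)
    # possible het counts share the parity of the rare-allele total
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = h | allele counts), up to the common normalising constant
    logp = (
        h_log_fact(n)
        - h_log_fact((rare - hets) // 2)
        - h_log_fact((common - hets) // 2)
        - h_log_fact(hets)
        + hets * np.log(2.0)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.nonzero(hets == n_het)[0][0]]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def h_log_fact(x):
    return gammaln(np.asarray(x, dtype=float) + 1.0)


def hwe_chi2_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """One-df chi-square HWE test (no continuity correction)."""
    n = n_hom_minor + n_het + n_hom_major
    if n == 0:
        return 1.0
    p = (2 * n_hom_minor + n_het) / (2 * n)
    q = 1.0 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_hom_minor, n_het, n_hom_major], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0))
    return float(chi2_dist.sf(stat, 1))


def run_qc(cohort: TrioCohort, thresholds: QcThresholds | None = None):
    """Apply all QC filters in order; returns (clean cohort, report)."""
    th = thresholds or QcThresholds()
    report = QcReport()

    # (1) SNP call rate
    miss = missing_mask(cohort)
    snp_miss_rate = miss.mean(axis=0) if cohort.n_samples else np.zeros(cohort.n_snps)
    keep = snp_miss_rate <= th.snp_missing_max
    report.add("snp_call_rate", "SNPs", int((~keep).sum()), int(keep.sum()))
    cohort = cohort.subset_snps(keep)

    # (2) sample missingness
    miss = missing_mask(cohort)
    sample_miss = miss.mean(axis=1) if cohort.n_snps else np.zeros(cohort.n_samples)
    keep_s = sample_miss <= th.sample_missing_max
    report.add("sample_missingness", "samples", int((~keep_s).sum()), int(keep_s.sum()))
    cohort = cohort.subset_samples(keep_s)

    # (3) incomplete families: drop samples outside complete trios and
    # count the families discarded with them
    in_trio = np.zeros(len(cohort.samples), dtype=bool)
    for f, m, c in cohort.trio_index:
        in_trio[[f, m, c]] = True
    n_families_removed = cohort.samples.loc[~in_trio, "family_id"].nunique()
    n_trios_before = cohort.n_trios
    cohort = cohort.subset_samples(in_trio)
    report.add("incomplete_trios", "trios", int(n_families_removed), cohort.n_trios)
    if cohort.n_trios == 0:
        raise ValueError("no complete trios remain after QC")
    if cohort.n_trios != n_trios_before:
        raise AssertionError("complete trios must survive the incomplete-family step")

    founders = cohort.founder_rows()

    # (4) founder MAF
    counts = allele_counts(cohort, founders)
    totals = counts.sum(axis=0)
    top = np.sort(counts, axis=0)[-2:]  # second-most and most frequent
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(totals > 0, top[0] / np.maximum(totals, 1), 0.0)
    keep = maf >= th.maf_min
    report.add("founder_maf", "SNPs", int((~keep).sum()), int(keep.sum()))
    cohort = cohort.subset_snps(keep)

    # (5) SNPs with any Mendelian-inconsistent trio
    if th.drop_mendel_snps:
        counts = allele_counts(cohort, cohort.founder_rows())
        minor, major = minor_major_codes(counts)
        tested = np.where(minor > 0, minor, major)  # any observed allele works
        dosage = dosage_matrix(cohort, tested)
        df, dm, dc = trio_dosages(cohort, dosage)
        complete = (df >= 0) & (dm >= 0) & (dc >= 0)
        ok = np.ones_like(complete)
        ok[complete] = MENDEL_OK[df[complete], dm[complete], dc[complete]]
        keep = ok.all(axis=0)
        report.add("mendelian_errors", "SNPs", int((~keep).sum()), int(keep.sum()))
        cohort = cohort.subset_snps(keep)

    # (6) founder HWE
    founders = cohort.founder_rows()
    counts = allele_counts(cohort, founders)
    minor, major = minor_major_codes(counts)
    dosage = dosage_matrix(cohort, np.where(minor > 0, minor, major))[founders]
    test = hwe_chi2_test if th.hwe_chi2 else hwe_exact_test
    pvals = np.ones(cohort.n_snps)
    for j in range(cohort.n_snps):
        if minor[j] == 0:
            continue  # monomorphic in founders: HWE trivially holds
        d = dosage[:, j]
        pvals[j] = test(int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum()))
    keep = pvals >= th.hwe_alpha
    report.add("founder_hwe", "SNPs", int((~keep).sum()), int(keep.sum()))
    cohort = cohort.subset_snps(keep)

    if cohort.n_snps == 0:
        raise ValueError("no SNPs remain after QC")
    return cohort, report
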