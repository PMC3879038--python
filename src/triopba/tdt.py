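"""Allele-based Transmission Disequilibrium Test.

For each SNP, every heterozygous parent of an affected child is an
informative transmission: it passes the tested allele (count ``b``) or
the other allele (count ``c``).  Under the null of no linkage/association
transmissions are symmetric and

    chi2 = (b - c)^2 / (b + c)

is asymptotically chi-square with 1 df (McNemar form, no continuity
correction).  The tested allele is the minor allele among founders, and
results are allele-labelled so the choice is auditable.  Trios with a
Mendelian inconsistency or a missing genotype at a SNP are skipped for
that SNP only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .genotypes import (
    MENDEL_OK,
    allele_counts,
    dosage_matrix,
    minor_major_codes,
    trio_dosages,
)
from .io import CODE_TO_ALLELE, TrioCohort
from .qc import mendelian_consistent

logger = logging.getLogger("triopba")

RESULT_COLUMNS = [
    "snp_id",
    "chrom",
    "position",
    "tested_allele",
    "b",
    "c",
    "n_informative",
    "chi2",
    "p",
]


@dataclass(frozen=True)
class TdtResult:
    snp_id: str
    tested_allele: str
    b: int
    c: int
    chi2: float
    p: float

    @property
    def n_informative(self) -> int:
        return self.b + self.c


def count_transmissions(father_gt, mother_gt, child_gt, tested_allele: str):
    """(b, c) transmission counts of ``tested_allele`` for one trio.

    Each heterozygous parent contributes exactly one count; homozygous
    parents contribute nothing.  When both parents are heterozygous and
    the child is heterozygous, one transmission of each allele occurred,
    so one count goes to each of b and c.  Incomplete or Mendelian-
    inconsistent trios contribute (0, 0).
    """
    gts = (father_gt, mother_gt, child_gt)
    if any(g is None or "0" in g for g in gts):
        return 0, 0
    if not mendelian_consistent(father_gt, mother_gt, child_gt):
        return 0, 0
    dose = lambda gt: sum(a == tested_allele for a in gt)
    df, dm, dc = (dose(g) for g in gts)
    het = (df == 1) + (dm == 1)
    hom_tested = (df == 2) + (dm == 2)
    b = dc - hom_tested  # tested-allele copies that came from het parents
    c = het - b
    return int(b), int(c)


def tdt_test(b: int, c: int) -> tuple[float, float]:
    """Classical TDT statistic and its chi-square(1) upper-tail p-value."""
    n = b + c
    if n < 1:
        raise ValueError("tdt_test needs at least one informative transmission")
    chi2 = (b - c) ** 2 / n
    return float(chi2), float(chi2_dist.sf(chi2, 1))


def run_tdt(cohort: TrioCohort, keep_noninformative: bool = False) -> pd.DataFrame:
    """TDT over all SNPs of a QC'd cohort, ranked by ascending p-value.

    Returns a frame with one row per polymorphic, informative SNP, sorted
    by (p, snp_id).  Non-informative SNPs (no heterozygous parent in any
    complete, consistent trio) are excluded from the ranking unless
    ``keep_noninformative`` is set, in which case they appear at the end
    with NaN statistics.
    """
    if not cohort.trio_index:
        raise ValueError("cohort has no complete trios")

    counts = allele_counts(cohort, cohort.founder_rows())
    minor, major = minor_major_codes(counts)
    tested = np.where(minor > 0, minor, 0)  # monomorphic SNPs drop out
    dosage = dosage_matrix(cohort, tested.astype(np.int8))
    df, dm, dc = trio_dosages(cohort, dosage)

    usable = (df >= 0) & (dm >= 0) & (dc >= 0)
    ok = np.zeros_like(usable)
    ok[usable] = MENDEL_OK[df[usable], dm[usable], dc[usable]]

    het = ((df == 1).astype(np.int64) + (dm == 1)) * ok
    hom_tested = ((df == 2).astype(np.int64) + (dm == 2)) * ok
    b_trio = (np.where(ok, dc, 0) - hom_tested) * ok
    b = b_trio.sum(axis=0)
    n_inf = het.sum(axis=0)
    c = n_inf - b

    polymorphic = minor > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(n_inf > 0, (b - c) ** 2 / np.maximum(n_inf, 1), np.nan)
    p = np.where(n_inf > 0, chi2_dist.sf(np.nan_to_num(chi2), 1), np.nan)

    frame = pd.DataFrame(
        {
            "snp_id": cohort.snp_ids(),
            "chrom": [s.chrom for s in cohort.snps],
            "position": [s.position for s in cohort.snps],
            "tested_allele": [CODE_TO_ALLELE[t] for t in tested],
            "b": b,
            "c": c,
            "n_informative": n_inf,
            "chi2": chi2,
            "p": p,
        }
    )
    frame = frame[polymorphic]
    n_noninf = int((frame["n_informative"] == 0).sum())
    if n_noninf:
        logger.info("run_tdt: %d non-informative SNP(s) excluded from ranking", n_noninf)
    if not keep_noninformative:
        frame = frame[frame["n_informative"] > 0]
    frame = frame.sort_values(
        ["p", "snp_id"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    return frame


def write_tdt(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
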