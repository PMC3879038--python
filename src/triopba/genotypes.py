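"""Internal genotype encodings shared by the QC and TDT stages.

A cohort's genotypes are allele-code pairs; for the statistics we reduce
each genotype to the dosage of one tested allele (0, 1, 2; -1 missing)
and work with vectorised dosage matrices.
"""

from __future__ import annotations

import numpy as np

from .io import TrioCohort

#: MENDEL_OK[df, dm, dc] — is child dosage dc possible given parent dosages?
MENDEL_OK = np.zeros((3, 3, 3), dtype=bool)
_TRANSMIT = {0: {0}, 1: {0, 1}, 2: {1}}
for _df in range(3):
    for _dm in range(3):
        for _a in _TRANSMIT[_df]:
            for _b in _TRANSMIT[_dm]:
                MENDEL_OK[_df, _dm, _a + _b] = True


def missing_mask(cohort: TrioCohort) -> np.ndarray:
    """(n_samples, n_snps) boolean: genotype has any missing allele."""
    return (cohort.genotypes == 0).any(axis=2)


def allele_counts(cohort: TrioCohort, rows: np.ndarray) -> np.ndarray:
    """(4, n_snps) counts of allele codes 1..4 over the given sample rows."""
    g = cohort.genotypes[rows]  # (R, S, 2)
    out = np.empty((4, cohort.n_snps), dtype=np.int64)
    for code in range(1, 5):
        out[code - 1] = (g == code).sum(axis=(0, 2))
    return out


def minor_major_codes(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Minor and major allele codes per SNP from a (4, n_snps) count table.

    The minor allele is the less frequent of the two observed alleles;
    ties break toward the smaller allele code.  Monomorphic SNPs get the
    single observed allele as major and code 0 as minor.
    """
    n_snps = counts.shape[1]
    minor = np.zeros(n_snps, dtype=np.int8)
    major = np.zeros(n_snps, dtype=np.int8)
    order = np.argsort(counts, axis=0, kind="stable")  # ascending counts, stable
    for j in range(n_snps):
        observed = [c for c in range(4) if counts[c, j] > 0]
        if not observed:
            continue
        if len(observed) == 1:
            major[j] = observed[0] + 1
            continue
        # two (or more) alleles: top two by count; stable sort keeps the
        # smaller code first among ties, so taking from the end is
        # deterministic
        top = order[-1, j]
        second = order[-2, j]
        major[j] = top + 1
        minor[j] = second + 1
    return minor, major


def dosage_matrix(cohort: TrioCohort, tested_codes: np.ndarray) -> np.ndarray:
    """(n_samples, n_snps) dosage of the tested allele; -1 where missing
    or where the SNP has no tested allele (monomorphic)."""
    g = cohort.genotypes
    d = (g == tested_codes[None, :, None]).sum(axis=2).astype(np.int8)
    d[missing_mask(cohort)] = -1
    d[:, tested_codes == 0] = -1
    return d


def trio_dosages(cohort: TrioCohort, dosage: np.ndarray):
    """Split a dosage matrix into father/mother/child stacks, one row per
    trio."""
    idx = np.asarray(cohort.trio_index, dtype=int)
    return dosage[idx[:, 0]], dosage[idx[:, 1]], dosage[idx[:, 2]]
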