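"""Per-SNP genotype quality control: call rate, MAF, and exact HWE test.

The three screening filters keep a SNP when, on the analysis subjects,

* call rate >= ``min_call_rate``  (default 0.95),
* minor allele frequency >= ``min_maf``  (default 0.10),
* Hardy-Weinberg exact P >= ``min_hwe_p``  (default 1e-4).

All three comparisons are inclusive.  The HWE test is the exact conditional
test: given the observed allele counts, the heterozygote count has a fixed
parity, and the P value sums the probabilities of all heterozygote counts
whose conditional probability does not exceed that of the observed count.
It is computed with exact integer weights, so results carry no rounding
beyond the final division; a 1-df chi-square variant is available for
comparison with older pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypePanel

QC_REPORT_COLUMNS = ("snp_id", "chrom", "pos", "call_rate",
                     "n0", "n1", "n2", "maf", "hwe_p", "passed")


@dataclass(frozen=True)
class QCThresholds:
    """Inclusive lower bounds for the three per-SNP filters."""

    min_call_rate: float = 0.95
    min_maf: float = 0.10
    min_hwe_p: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "min_hwe_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def call_rate(calls_for_snp) -> float:
    """Fraction of non-missing calls at one SNP."""
    calls = np.asarray(calls_for_snp)
    if calls.size == 0:
        raise ValueError("call_rate of an empty call vector is undefined")
    return float(np.mean(calls != MISSING))


def genotype_counts(calls_for_snp) -> tuple:
    """Non-missing genotype counts (n0, n1, n2) at one SNP."""
    calls = np.asarray(calls_for_snp)
    return tuple(int(np.sum(calls == g)) for g in (0, 1, 2))


def compute_maf(counts) -> tuple:
    """Minor allele frequency from genotype counts.

    Returns ``(maf, minor_is_coded_allele)`` where the flag is True iff the
    coded (code-2) allele is the rarer one (frequency <= 0.5).
    """
    n0, n1, n2 = counts
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("MAF undefined for an all-missing SNP")
    f = (n1 + 2 * n2) / (2 * n)
    return min(f, 1.0 - f), f <= 0.5


def hwe_exact_p(n0: int, n1: int, n2: int) -> float:
    """Exact conditional Hardy-Weinberg test P value.

    Conditional on the observed allele counts, the probability of ``h``
    heterozygotes is proportional to ``2**h * n! / (n_rr! h! n_cc!)`` with
    ``n_rr = (r - h) / 2`` rare homozygotes.  Sums all configurations no more
    probable than the observed one, using exact integers throughout.
    """
    if min(n0, n1, n2) < 0:
        raise ValueError("negative genotype count")
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("HWE test undefined for an all-missing SNP")
    r = min(n1 + 2 * n2, n1 + 2 * n0)  # rare-allele count, r <= n
    weights = {}
    for h in range(r % 2, r + 1, 2):
        n_rare_hom = (r - h) // 2
        weights[h] = comb(n, n_rare_hom) * comb(n - n_rare_hom, h) * (1 << h)
    w_obs = weights[n1]
    total = sum(weights.values())
    return sum(w for w in weights.values() if w <= w_obs) / total


def hwe_chisq_p(n0: int, n1: int, n2: int) -> float:
    """1-df goodness-of-fit chi-square HWE test (no continuity correction)."""
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("HWE test undefined for an all-missing SNP")
    q = (n1 + 2 * n2) / (2 * n)
    expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2]) * n
    if np.any(expected == 0):  # monomorphic: observed matches expectation exactly
        return 1.0
    chi2 = float(np.sum((np.array([n0, n1, n2]) - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def apply_qc(panel: GenotypePanel, thresholds: QCThresholds = QCThresholds(),
             hwe_test: str = "exact"):
    """Screen every SNP; return the report and the panel of passing SNPs.

    A SNP with zero non-missing calls fails (call rate 0) and is reported
    with undefined MAF and HWE P.
    """
    if hwe_test not in ("exact", "chisq"):
        raise ValueError("hwe_test must be 'exact' or 'chisq'")
    hwe = hwe_exact_p if hwe_test == "exact" else hwe_chisq_p
    records = []
    for j, snp_id in enumerate(panel.snp_ids):
        calls = panel.calls[:, j]
        rate = call_rate(calls)
        n0, n1, n2 = genotype_counts(calls)
        if n0 + n1 + n2 == 0:
            maf, hwe_p, passed = np.nan, np.nan, False
        else:
            maf, _ = compute_maf((n0, n1, n2))
            hwe_p = hwe(n0, n1, n2)
            passed = (rate >= thresholds.min_call_rate
                      and maf >= thresholds.min_maf
                      and hwe_p >= thresholds.min_hwe_p)
        meta = panel.snp_meta.loc[snp_id]
        records.append((snp_id, meta["chrom"], int(meta["pos"]), rate,
                        n0, n1, n2, maf, hwe_p, passed))
    report = pd.DataFrame.from_records(records, columns=QC_REPORT_COLUMNS)
    filtered = panel.select_snps(report["passed"].to_numpy(dtype=bool))
    return report, filtered


def write_qc_report_tsv(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False, na_rep="NA")
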