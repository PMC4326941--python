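"""Maximally selected phenotype-threshold scan scored by Fisher's exact test.

For each SNP the quantitative trait (percent lean body mass, residualized on
age) is dichotomized at every candidate threshold — the midpoints between
consecutive distinct trait values — and each resulting 2x2 genotype-group x
phenotype-category table is scored with the two-sided Fisher exact test.
The scan reports the threshold attaining the minimum P, together with the
relative risk of the "low" phenotype category in the carrier group and its
95% confidence interval.

Conventions, used everywhere in the package:

* genotype groups: ``dominant_minor`` puts carriers of >= 1 minor allele
  (codes 1, 2) in the carrier group; ``recessive_minor`` puts minor-allele
  homozygotes (code 2) there.  The remainder is the reference group.
* "low" phenotype category = trait strictly below the threshold; at-or-above
  is "high".
* 2x2 table orientation: rows (carrier, reference), columns (low, high), so
  ``a`` = carriers below threshold, ``d`` = reference subjects at-or-above.
* two-sided Fisher P = sum of hypergeometric probabilities of all tables
  with the observed margins whose probability is <= that of the observed
  table, the comparison carrying a 1e-7 relative tolerance (the convention
  of R's fisher.test).

The minimum over thresholds is an anticonservative statistic when compared
against nominal critical values; the calibration tests quantify this, and
screening thresholds must be interpreted accordingly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .io import MISSING, GenotypePanel, PhenotypeTable

_FISHER_REL_TOL = 1e-7
_TIE_REL_TOL = 1e-12
_Z_95 = 1.96

SCAN_RESULT_COLUMNS = ("snp_id", "chrom", "pos", "model", "n_used",
                       "best_threshold", "a", "b", "c", "d", "min_p",
                       "rr", "rr_ci_low", "rr_ci_high", "degenerate",
                       "n_thresholds_tested")


class GeneticModel(enum.Enum):
    """Genotype-collapsing rule for the minor allele."""

    DOMINANT_MINOR = "dominant_minor"
    RECESSIVE_MINOR = "recessive_minor"

    def carrier_codes(self) -> tuple:
        return (1, 2) if self is GeneticModel.DOMINANT_MINOR else (2,)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows (carrier, reference) and columns (low, high)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RelativeRisk:
    rr: float
    ci_low: float
    ci_high: float
    corrected: bool  # Haldane-Anscombe 0.5 applied to every cell


@dataclass
class ScanResult:
    """Outcome of the threshold scan for one (SNP, model) pair."""

    snp_id: Optional[str]
    model: Optional[GeneticModel]
    best_threshold: float
    min_p: float
    table: Optional[ContingencyTable2x2]
    rr: Optional[RelativeRisk]
    n_thresholds_tested: int
    degenerate: bool
    n_used: int


# ---------------------------------------------------------------------------
# age adjustment


def adjust_for_age(pheno: PhenotypeTable, mode: str = "linear") -> pd.Series:
    """Residualize lean mass on age; keep values on the percent scale.

    Ordinary least squares of lean mass on (intercept, age), residuals plus
    the sample mean.  ``mode='none'`` returns the raw trait.  An age with no
    variance contributes a zero slope, so the trait passes through unchanged.
    Only usable subjects (both trait and age present) appear in the output.
    """
    if mode not in ("linear", "none"):
        raise ValueError("mode must be 'linear' or 'none'")
    usable = pheno.usable
    y = pheno.data.loc[usable, "lean_mass_pct"].astype(float)
    if mode == "none":
        return y.copy()
    if usable.sum() < 3:
        raise ValueError("age adjustment requires at least 3 usable subjects")
    age = pheno.data.loc[usable, "age_years"].astype(float)
    x = age - age.mean()
    sxx = float((x ** 2).sum())
    slope = float((x * (y - y.mean())).sum()) / sxx if sxx > 0 else 0.0
    return y - slope * x


# ---------------------------------------------------------------------------
# genotype collapsing


def collapse_genotypes(calls_for_snp, model: GeneticModel) -> np.ndarray:
    """Label each subject 1 (carrier group), 0 (reference), -1 (missing)."""
    calls = np.asarray(calls_for_snp)
    labels = np.where(np.isin(calls, model.carrier_codes()), 1, 0).astype(np.int8)
    labels[calls == MISSING] = -1
    return labels


# ---------------------------------------------------------------------------
# Fisher's exact test


_LOG_FISHER_TOL = float(np.log1p(_FISHER_REL_TOL))
_gammaln_table = np.array([])


def _lgamma_ints(n: int) -> np.ndarray:
    """Cached ln Gamma over the integers 0..n+1 (index i holds ln((i-1)!))."""
    global _gammaln_table
    if _gammaln_table.size < n + 2:
        _gammaln_table = gammaln(np.arange(max(n + 2, 1024), dtype=float))
    return _gammaln_table


def _log_pmf_matrix(n: int, m: int, k_arr: np.ndarray) -> np.ndarray:
    """Hypergeometric log-pmf, rows x = 0..min(m, max k), columns the k values.

    Entry (x, j) is ln P[carrier-low cell = x] for the table with row
    margins (m, n-m) and column margins (k_j, n-k_j); -inf off support.
    """
    gl = _lgamma_ints(n)
    x = np.arange(min(m, int(k_arr.max())) + 1)
    X = x[:, None]
    K = np.asarray(k_arr, dtype=np.intp)[None, :]
    valid = (X <= K) & (K - X <= n - m)
    KX = np.clip(K - X, 0, n - m)
    lnp = ((gl[m + 1] - gl[X + 1] - gl[m - X + 1])
           + (gl[n - m + 1] - gl[KX + 1] - gl[n - m - KX + 1])
           - (gl[n + 1] - gl[K + 1] - gl[n - K + 1]))
    return np.where(valid, lnp, -np.inf)


def _fisher_scan(a_arr: np.ndarray, k_arr: np.ndarray, m: int, n: int) -> np.ndarray:
    """Two-sided Fisher P for tables sharing row margins (m, n-m).

    ``k_arr`` are the "low" column totals at each threshold and ``a_arr``
    the carrier-low counts.  Comparisons and summation run in log space, so
    P values remain defined for extreme tables at large n.
    """
    lnpmf = _log_pmf_matrix(n, m, np.asarray(k_arr))
    lnp_obs = lnpmf[np.asarray(a_arr, dtype=np.intp), np.arange(len(k_arr))]
    include = lnpmf <= lnp_obs[None, :] + _LOG_FISHER_TOL
    p = np.exp(logsumexp(lnpmf, axis=0, b=include))
    return np.clip(np.atleast_1d(p), np.finfo(float).tiny, 1.0)


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact test P value; returns 1.0 for a zero margin."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    m, k = a + b, a + c
    if m == 0 or k == 0 or m == n or k == n:
        return 1.0
    return float(_fisher_scan(np.array([a]), np.array([k]), m, n)[0])


# ---------------------------------------------------------------------------
# relative risk


def relative_risk(table: ContingencyTable2x2) -> RelativeRisk:
    """Risk of the low-trait category in carriers relative to the reference.

    rr = [a/(a+b)] / [c/(c+d)]; 95% CI = rr * exp(+-1.96 * SE) with
    SE = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)).  If a or c is zero the
    Haldane-Anscombe correction (0.5 added to every cell) is applied and
    flagged.  Either direction can be read off by inverting rr.
    """
    a, b, c, d = (float(v) for v in (table.a, table.b, table.c, table.d))
    if a + b == 0 or c + d == 0:
        raise ValueError("relative risk undefined: empty genotype group")
    corrected = table.a == 0 or table.c == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    rr = (a / (a + b)) / (c / (c + d))
    se = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return RelativeRisk(rr=float(rr),
                        ci_low=float(rr * np.exp(-_Z_95 * se)),
                        ci_high=float(rr * np.exp(_Z_95 * se)),
                        corrected=corrected)


# ---------------------------------------------------------------------------
# the scan


def _degenerate_result(snp_id, model, n_used) -> ScanResult:
    return ScanResult(snp_id=snp_id, model=model, best_threshold=np.nan,
                      min_p=1.0, table=None, rr=None, n_thresholds_tested=0,
                      degenerate=True, n_used=n_used)


def scan_thresholds(trait, groups, min_group_cells: int = 5,
                    snp_id: Optional[str] = None,
                    model: Optional[GeneticModel] = None) -> ScanResult:
    """Scan all candidate trait thresholds for one SNP's genotype grouping.

    ``trait`` and ``groups`` are aligned vectors; subjects with group label
    -1 are excluded pairwise.  Candidate thresholds are the midpoints
    between consecutive distinct sorted trait values; thresholds leaving
    fewer than ``min_group_cells`` subjects in either phenotype category
    are skipped.  Ties in the minimum P are broken toward the threshold
    nearest the trait median, then the smaller threshold.

    When no candidate survives, or either genotype group has fewer than two
    subjects, the result is flagged degenerate with ``min_p = 1``.
    """
    trait = np.asarray(trait, dtype=float)
    groups = np.asarray(groups)
    if trait.shape != groups.shape:
        raise ValueError("trait and group vectors differ in length")
    keep = (groups >= 0) & ~np.isnan(trait)
    trait, groups = trait[keep], groups[keep]
    n = trait.size
    m = int((groups == 1).sum())
    if m < 2 or n - m < 2:
        return _degenerate_result(snp_id, model, n)

    order = np.argsort(trait, kind="stable")
    sv = trait[order]
    carrier_sorted = (groups[order] == 1)
    boundaries = np.flatnonzero(np.diff(sv) > 0)  # threshold between i and i+1
    if boundaries.size == 0:  # constant trait
        return _degenerate_result(snp_id, model, n)
    k_arr = boundaries + 1                        # subjects strictly below
    thresholds = (sv[boundaries] + sv[boundaries + 1]) / 2.0
    ok = (k_arr >= min_group_cells) & (n - k_arr >= min_group_cells)
    if not ok.any():
        return _degenerate_result(snp_id, model, n)
    k_arr, thresholds = k_arr[ok], thresholds[ok]
    a_arr = np.cumsum(carrier_sorted)[k_arr - 1]  # carriers strictly below

    pvals = _fisher_scan(a_arr.astype(np.intp), k_arr.astype(np.intp), m, n)
    min_p = float(pvals.min())
    tied_idx = np.flatnonzero(pvals <= min_p * (1.0 + _TIE_REL_TOL))
    cand = thresholds[tied_idx]
    dist = np.abs(cand - np.median(trait))
    pick = int(tied_idx[np.lexsort((cand, dist))[0]])
    best_t = float(thresholds[pick])

    a, k = int(a_arr[pick]), int(k_arr[pick])
    table = ContingencyTable2x2(a=a, b=m - a, c=k - a, d=(n - m) - (k - a))
    return ScanResult(snp_id=snp_id, model=model, best_threshold=best_t,
                      min_p=float(pvals[pick]), table=table,
                      rr=relative_risk(table),
                      n_thresholds_tested=int(len(k_arr)),
                      degenerate=False, n_used=n)


def scan_panel(panel: GenotypePanel, trait, models=None,
               min_group_cells: int = 5) -> list:
    """Run the threshold scan for every (SNP, model) pair in the panel.

    ``trait`` is aligned with ``panel.subject_ids`` (NaN allowed; such
    subjects are dropped pairwise together with missing genotype calls).
    """
    if models is None:
        models = (GeneticModel.DOMINANT_MINOR, GeneticModel.RECESSIVE_MINOR)
    trait = np.asarray(trait, dtype=float)
    if trait.size != panel.n_subjects:
        raise ValueError("trait vector does not match panel subjects")
    results = []
    for j, snp_id in enumerate(panel.snp_ids):
        calls = panel.calls[:, j]
        for model in models:
            groups = collapse_genotypes(calls, model)
            results.append(scan_thresholds(trait, groups,
                                           min_group_cells=min_group_cells,
                                           snp_id=snp_id, model=model))
    return results


def results_to_frame(results, panel: Optional[GenotypePanel] = None) -> pd.DataFrame:
    """Tabulate scan results in the documented TSV column order."""
    meta = panel.snp_meta if panel is not None else None
    rows = []
    for r in results:
        chrom, pos = ("un", 0) if meta is None or r.snp_id not in meta.index \
            else (meta.loc[r.snp_id, "chrom"], int(meta.loc[r.snp_id, "pos"]))
        t = r.table
        rr = r.rr
        rows.append((r.snp_id, chrom, pos,
                     r.model.value if r.model else "NA", r.n_used,
                     r.best_threshold,
                     *( (t.a, t.b, t.c, t.d) if t else (0, 0, 0, 0) ),
                     r.min_p,
                     rr.rr if rr else np.nan,
                     rr.ci_low if rr else np.nan,
                     rr.ci_high if rr else np.nan,
                     r.degenerate, r.n_thresholds_tested))
    return pd.DataFrame.from_records(rows, columns=SCAN_RESULT_COLUMNS)


def write_scan_results_tsv(results, path, panel=None) -> None:
    results_to_frame(results, panel).to_csv(path, sep="\t", index=False,
                                            na_rep="NA")
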