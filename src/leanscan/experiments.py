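"""Self-contained simulation studies of the scan's operating characteristics.

Two reusable study procedures:

* :func:`null_calibration` — size of the threshold-scan statistic versus a
  fixed median-split Fisher test on null SNPs (trait independent of
  genotype).  The median split inherits Fisher conservatism
  (P(p <= alpha) <= alpha); the minimum over all thresholds is markedly
  anticonservative, which is why genome-screen hits need replication.
* :func:`recovery_study` — how often a single causal SNP attains the
  panel-wide minimum scan P among many null SNPs, across seeded replicates.

Problem sizes default to the screening-stage design: 269 subjects, MAF in
[0.10, 0.50].
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .scan import (
    ContingencyTable2x2,
    GeneticModel,
    adjust_for_age,
    collapse_genotypes,
    fisher_exact_2x2,
    scan_thresholds,
)
from .simulate import SimConfig, null_panel_for_calibration, simulate_cohort

_SEED_MOD = 2 ** 31 - 1


class CalibrationResult(NamedTuple):
    scan_rate: float          # P(min_p <= alpha) across null SNPs
    median_split_rate: float  # P(p <= alpha) for the fixed median split
    n_snps: int
    alpha: float


def median_split_fisher_p(trait, groups) -> float:
    """Fisher P for the single dichotomization at the trait median."""
    trait = np.asarray(trait, dtype=float)
    groups = np.asarray(groups)
    keep = (groups >= 0) & ~np.isnan(trait)
    trait, groups = trait[keep], groups[keep]
    low = trait < np.median(trait)
    m = int((groups == 1).sum())
    a = int((low & (groups == 1)).sum())
    k = int(low.sum())
    n = trait.size
    table = ContingencyTable2x2(a, m - a, k - a, (n - m) - (k - a))
    return fisher_exact_2x2(table)


def null_calibration(n_snps: int = 2000, n_subjects: int = 269,
                     alpha: float = 0.05, min_group_cells: int = 5,
                     seed: int = 0) -> CalibrationResult:
    """Empirical size of scan and median-split tests on null SNPs.

    One null cohort of ``n_snps`` independent SNPs; each SNP is collapsed
    under the minor-allele-dominant model and scanned over all thresholds
    of the age-adjusted trait.
    """
    cfg = SimConfig(n_subjects=n_subjects, n_snps=n_snps,
                    seed=seed % _SEED_MOD)
    panel, pheno = null_panel_for_calibration(cfg)
    trait = adjust_for_age(pheno).reindex(panel.subject_ids).to_numpy()
    scan_hits = median_hits = 0
    for j in range(panel.n_snps):
        groups = collapse_genotypes(panel.calls[:, j],
                                    GeneticModel.DOMINANT_MINOR)
        result = scan_thresholds(trait, groups,
                                 min_group_cells=min_group_cells)
        scan_hits += (not result.degenerate) and result.min_p <= alpha
        median_hits += median_split_fisher_p(trait, groups) <= alpha
    return CalibrationResult(scan_rate=scan_hits / n_snps,
                             median_split_rate=median_hits / n_snps,
                             n_snps=n_snps, alpha=alpha)


def recovery_study(n_replicates: int = 50, n_null_snps: int = 1000,
                   n_subjects: int = 269, effect_sd_units: float = 0.5,
                   causal_maf: float = 0.35, seed: int = 0) -> float:
    """Fraction of replicates where the causal SNP tops the panel ranking.

    Each replicate simulates ``n_null_snps`` null SNPs plus one causal SNP
    (trait shift ``effect_sd_units * trait_sd`` for minor-allele-dominant
    carriers at ``causal_maf``), scans every SNP under the matching model
    on the age-adjusted trait, and records whether the causal SNP attains
    the panel-wide minimum P.
    """
    wins = 0
    for rep in range(n_replicates):
        cfg = SimConfig(n_subjects=n_subjects, n_snps=n_null_snps + 1,
                        causal_snp_index=0, causal_maf=causal_maf,
                        causal_model=GeneticModel.DOMINANT_MINOR,
                        effect_beta=effect_sd_units * 3.5,
                        seed=(seed + 7919 * rep) % _SEED_MOD)
        panel, pheno = simulate_cohort(cfg)
        trait = adjust_for_age(pheno).reindex(panel.subject_ids).to_numpy()
        best_p, best_j = np.inf, -1
        for j in range(panel.n_snps):
            groups = collapse_genotypes(panel.calls[:, j],
                                        GeneticModel.DOMINANT_MINOR)
            p = scan_thresholds(trait, groups).min_p
            if p < best_p:
                best_p, best_j = p, j
        wins += best_j == 0
    return wins / n_replicates
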