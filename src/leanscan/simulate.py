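"""Synthetic cohorts with the statistical structure the scan assumes.

The generator emulates a cohort of postmenopausal women characterized by
percent lean body mass (marginal mean 34.2, SD 3.5), age (65.1 +- 9.4 y),
and a panel of independent biallelic SNPs in Hardy-Weinberg equilibrium at
configurable minor allele frequencies.  An optional causal SNP adds a fixed
trait shift to its carrier group under a chosen genetic model; secondary
traits (fat mass, bone mineral density) are generated independent of
genotype so that replication-stage comparisons have a known null ground
truth.  Linkage disequilibrium, population structure, and genotyping error
are deliberately not modelled: the scan treats SNPs marginally.

The marginal trait SD is held at ``trait_sd`` by shrinking the residual
noise as the age and genetic components grow, so cohorts stay comparable
across configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .io import MISSING, GenotypePanel, PhenotypeTable
from .scan import GeneticModel, collapse_genotypes

_N_AUTOSOMES = 22


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of a synthetic cohort.

    Defaults reproduce the replication-cohort template: 1081 subjects,
    lean mass 34.2 +- 3.5 %, age 65.1 +- 9.4 years, no genetic or age
    effect, no missing calls.
    """

    n_subjects: int = 1081
    n_snps: int = 1000
    maf_range: tuple = (0.10, 0.50)
    causal_snp_index: Optional[int] = None
    causal_model: GeneticModel = GeneticModel.DOMINANT_MINOR
    causal_maf: Optional[float] = None
    effect_beta: float = 0.0       # trait units added to the carrier group
    trait_mean: float = 34.2       # percent lean body mass
    trait_sd: float = 3.5
    age_mean: float = 65.1         # years
    age_sd: float = 9.4
    age_slope: float = 0.0         # percent lean mass per year
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.trait_sd <= 0 or self.age_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.causal_maf is not None and not 0.0 < self.causal_maf <= 0.5:
            raise ValueError("causal_maf must lie in (0, 0.5]")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent streams for genotypes (0) and phenotypes (1)
    return np.random.default_rng([config.seed, stream])


def simulate_genotypes(config: SimConfig) -> GenotypePanel:
    """HWE genotypes: per-SNP allele frequency uniform in ``maf_range``.

    Genotypes are i.i.d. Binomial(2, q) across subjects — the HWE
    proportions ((1-q)^2, 2q(1-q), q^2) — with missingness applied i.i.d.
    at ``missing_rate``.  The causal SNP's frequency is fixed at
    ``causal_maf`` when given.
    """
    rng = _rng(config, 0)
    n, p = config.n_subjects, config.n_snps
    q = rng.uniform(config.maf_range[0], config.maf_range[1], size=p)
    if config.causal_snp_index is not None:
        if not 0 <= config.causal_snp_index < p:
            raise ValueError("causal_snp_index out of range")
        if config.causal_maf is not None:
            q[config.causal_snp_index] = config.causal_maf
    calls = rng.binomial(2, q, size=(n, p)).astype(np.int8)
    if config.missing_rate > 0:
        calls[rng.random(size=(n, p)) < config.missing_rate] = MISSING

    width = max(4, len(str(n)))
    subject_ids = np.array([f"S{i:0{width}d}" for i in range(1, n + 1)],
                           dtype=object)
    snp_ids = np.array([f"snp{j:06d}" for j in range(1, p + 1)], dtype=object)
    chroms = [str(j % _N_AUTOSOMES + 1) for j in range(p)]
    meta = pd.DataFrame(
        {"chrom": chroms,
         "pos": np.arange(1, p + 1, dtype=np.int64) * 1000,
         "major": "T", "minor": "C"},
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypePanel(subject_ids, snp_ids, calls, meta)


def simulate_phenotype(panel: GenotypePanel, config: SimConfig) -> PhenotypeTable:
    """Trait with age structure, optional genetic effect, normal noise.

    lean = trait_mean + age_slope * (age - age_mean)
         + effect_beta * carrier_indicator + residual,
    with the residual SD chosen so the marginal trait SD equals
    ``trait_sd``.  Fat mass and bone mineral density are simulated null
    (independent of genotype).
    """
    rng = _rng(config, 1)
    n = panel.n_subjects
    age = rng.normal(config.age_mean, config.age_sd, size=n)

    genetic = np.zeros(n)
    effect_var = 0.0
    if config.causal_snp_index is not None and config.effect_beta != 0.0:
        if not 0 <= config.causal_snp_index < panel.n_snps:
            raise ValueError("causal_snp_index out of range")
        calls = panel.calls[:, config.causal_snp_index]
        labels = collapse_genotypes(calls, config.causal_model)
        carrier = (labels == 1).astype(float)
        carrier[labels == -1] = carrier[labels == 1].mean() if (labels == 1).any() else 0.0
        genetic = config.effect_beta * carrier
        effect_var = float(np.var(genetic))
    age_var = (config.age_slope * config.age_sd) ** 2
    resid_var = config.trait_sd ** 2 - age_var - effect_var
    if resid_var <= 0:
        raise ValueError(
            "age and genetic components exceed the marginal trait variance; "
            "increase trait_sd or reduce age_slope/effect_beta"
        )
    lean = (config.trait_mean
            + config.age_slope * (age - config.age_mean)
            + genetic
            + rng.normal(0.0, np.sqrt(resid_var), size=n))
    lean = np.clip(lean, 1e-6, 100 - 1e-6)  # trait is a percentage

    # null secondary traits, template values from the replication cohort
    fat = np.clip(rng.normal(31.9, 7.7, size=n), 1e-6, 100 - 1e-6)
    bmd = np.clip(rng.normal(0.98, 0.15, size=n), 1e-6, None)
    data = pd.DataFrame(
        {"lean_mass_pct": lean, "age_years": np.clip(age, 1e-6, None),
         "fat_mass_pct": fat, "bmd": bmd},
        index=pd.Index(panel.subject_ids, name="subject_id"),
    )
    return PhenotypeTable(data)


def simulate_cohort(config: SimConfig):
    """Genotype panel plus matching phenotype table from one config."""
    panel = simulate_genotypes(config)
    return panel, simulate_phenotype(panel, config)


def null_panel_for_calibration(config: SimConfig):
    """Cohort with the genetic effect forced to zero (trait independent of genotype)."""
    return simulate_cohort(replace(config, effect_beta=0.0))


def replication_preset(seed: int, n_subjects: int = 1081) -> SimConfig:
    """Single-SNP cohort shaped like the published replication stage.

    Carrier fraction 624/1081 under the minor-allele-dominant grouping
    implies an allele frequency q with (1-q)^2 = 457/1081, i.e. q ~= 0.35;
    the carrier-group trait shift of 0.7 % echoes the published group means
    (34.5 vs 33.8).
    """
    q = 1.0 - np.sqrt(457.0 / 1081.0)
    return SimConfig(n_subjects=n_subjects, n_snps=1,
                     causal_snp_index=0, causal_maf=float(q),
                     causal_model=GeneticModel.DOMINANT_MINOR,
                     effect_beta=0.7, seed=seed)
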