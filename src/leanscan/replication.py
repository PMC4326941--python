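"""Replication-stage statistics: unpaired t-tests between genotype groups.

The second stage of the screen compares the raw trait between minor-allele
carriers and non-carriers with an unpaired t-test — classical equal-variance
("Student's") by default, Welch as an option.  Tests can be run from raw
per-subject values or reconstructed from published group summaries
(n, mean, SE), and a convenience routine sweeps the secondary traits
(fat mass, bone density, anthropometrics) that are expected to show no
genotype association.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .io import PhenotypeTable

REPLICATION_COLUMNS = ("trait", "group1_n", "group1_mean", "group1_se",
                       "group2_n", "group2_mean", "group2_se",
                       "t", "df", "p", "variant")


class GroupSummary(NamedTuple):
    """Published summary of one genotype group: size, mean, SE of the mean."""

    n: int
    mean: float
    se: float


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float


def _validate_summary(g: GroupSummary) -> None:
    if g.n < 2:
        raise ValueError("group summary requires n >= 2")
    if g.se <= 0:
        raise ValueError("group summary requires se > 0")


def ttest_raw(group1, group2, variant: str = "pooled") -> TTestResult:
    """Unpaired two-sided t-test on raw values.

    ``variant='pooled'`` is the classical equal-variance test; ``'welch'``
    uses the Welch-Satterthwaite degrees of freedom.  Zero variance in both
    groups yields p = 1 for equal means and the p -> 0 limit otherwise.

    Sign convention: t > 0 when group1's mean exceeds group2's (the usual
    raw-data orientation); note :func:`ttest_from_summaries` reports the
    opposite orientation, matching how published group tables are read.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 values")
    if g1.var(ddof=1) == 0.0 and g2.var(ddof=1) == 0.0:
        df = (g1.size + g2.size - 2) if variant == "pooled" else float("nan")
        if g1.mean() == g2.mean():
            return TTestResult(0.0, float(df), 1.0)
        sign = np.sign(g1.mean() - g2.mean())
        return TTestResult(float(sign * np.inf), float(df), 0.0)
    res = stats.ttest_ind(g1, g2, equal_var=(variant == "pooled"))
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def ttest_from_summaries(g1: GroupSummary, g2: GroupSummary,
                         variant: str = "welch") -> TTestResult:
    """Reconstruct the unpaired t-test from (n, mean, SE) group summaries.

    Welch: t = (mean2 - mean1) / sqrt(se1^2 + se2^2) with Welch-Satterthwaite
    degrees of freedom.  Pooled: group SDs are recovered as se * sqrt(n),
    pooled classically, df = n1 + n2 - 2.  Printed summaries are usually
    rounded, so P values derived this way are approximate bounds.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    _validate_summary(g1)
    _validate_summary(g2)
    if variant == "welch":
        v1, v2 = g1.se ** 2, g2.se ** 2
        t = (g2.mean - g1.mean) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 ** 2 / (g1.n - 1) + v2 ** 2 / (g2.n - 1))
    else:
        s1sq = g1.se ** 2 * g1.n
        s2sq = g2.se ** 2 * g2.n
        df = g1.n + g2.n - 2
        sp_sq = ((g1.n - 1) * s1sq + (g2.n - 1) * s2sq) / df
        t = (g2.mean - g1.mean) / np.sqrt(sp_sq * (1 / g1.n + 1 / g2.n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(float(t), float(df), min(p, 1.0))


def group_summary(values) -> GroupSummary:
    """(n, mean, SE) of one group of raw values."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("group summary requires n >= 2 non-missing values")
    return GroupSummary(n=int(v.size), mean=float(v.mean()),
                        se=float(v.std(ddof=1) / np.sqrt(v.size)))


def compare_traits(pheno: PhenotypeTable, groups, traits=None,
                   variant: str = "pooled") -> pd.DataFrame:
    """Per-trait genotype-group comparison in the replication report layout.

    ``groups`` is aligned with ``pheno.subject_ids``: 1 = carrier group,
    0 = reference, -1 = excluded.  Group 1 of the report is the reference
    group (non-carriers), group 2 the carriers, matching the published
    TT vs CC+CT ordering.  Traits absent from the table are skipped;
    requesting only absent traits raises.
    """
    groups = np.asarray(groups)
    if groups.size != len(pheno.subject_ids):
        raise ValueError("group labels do not match phenotype subjects")
    if traits is None:
        traits = ["lean_mass_pct", *pheno.optional_traits(), "age_years"]
    available = [t for t in traits if t in pheno.data.columns]
    if not available:
        raise ValueError("none of the requested traits are present")
    rows = []
    for trait in available:
        vals = pheno.data[trait].to_numpy(dtype=float)
        ref = vals[(groups == 0) & ~np.isnan(vals)]
        car = vals[(groups == 1) & ~np.isnan(vals)]
        s_ref, s_car = group_summary(ref), group_summary(car)
        t, df, p = ttest_raw(ref, car, variant=variant)
        rows.append((trait, s_ref.n, s_ref.mean, s_ref.se,
                     s_car.n, s_car.mean, s_car.se, t, df, p, variant))
    return pd.DataFrame.from_records(rows, columns=REPLICATION_COLUMNS)


def compare_secondary_traits(pheno: PhenotypeTable, groups,
                             variant: str = "pooled") -> pd.DataFrame:
    """Genotype-group t-tests for the secondary traits only (fat, BMD, ...)."""
    traits = [*pheno.optional_traits(), "age_years"]
    if not pheno.optional_traits():
        raise ValueError("phenotype table has no optional traits to compare")
    return compare_traits(pheno, groups, traits=traits, variant=variant)
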