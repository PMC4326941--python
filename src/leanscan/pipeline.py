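"""End-to-end orchestration of the two-stage association screen.

Stage 1 (``run_screen``): subject alignment, per-SNP QC, age
residualization of the trait, dual-model threshold scan, and hit selection
at a stringent P cutoff (strict ``<``, default 1e-6).  Stage 2
(``run_replication``): group summaries and unpaired t-tests for a single
candidate SNP in an independent cohort, on the raw (unadjusted) traits.

No multiplicity correction is applied beyond the fixed screening cutoff;
because the scanned statistic is a minimum over thresholds, its null
distribution is anticonservative relative to nominal Fisher P values (see
the calibration tests), so stage-1 hits are candidates, not confirmed
associations — hence the replication stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from . import __version__
from . import io as lio
from . import qc as lqc
from . import replication as lrep
from . import scan as lscan

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Stage-1 configuration."""

    qc: lqc.QCThresholds = field(default_factory=lqc.QCThresholds)
    models: tuple = (lscan.GeneticModel.DOMINANT_MINOR,
                     lscan.GeneticModel.RECESSIVE_MINOR)
    screen_alpha: float = 1e-6
    min_group_cells: int = 5
    age_adjust: bool = True
    output_dir: Optional[Path] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.screen_alpha <= 1.0:
            raise ValueError("screen_alpha must lie in (0, 1]")


class ScreenOutput(NamedTuple):
    qc_report: pd.DataFrame
    results: list
    hits: list


def run_screen(panel: lio.GenotypePanel, pheno: lio.PhenotypeTable,
               config: ScreenConfig = ScreenConfig()) -> ScreenOutput:
    """QC -> age adjustment -> dual-model threshold scan -> hit selection.

    Hits are non-degenerate scan results with ``min_p < screen_alpha``
    (strict), sorted by ascending P.  When ``output_dir`` is set, the QC
    report, full scan table, hit table, and a run manifest are written
    there; inputs are never mutated.
    """
    panel, pheno = lio.align_subjects(panel, pheno)
    qc_report, filtered = lqc.apply_qc(panel, config.qc)
    logger.info("QC: %d of %d SNPs pass on %d subjects",
                filtered.n_snps, panel.n_snps, panel.n_subjects)
    if filtered.n_snps == 0:
        raise ValueError(
            f"no SNPs pass QC ({panel.n_snps} screened, "
            f"{int((qc_report['call_rate'] < config.qc.min_call_rate).sum())} "
            f"below call rate, "
            f"{int((qc_report['maf'] < config.qc.min_maf).sum())} below MAF, "
            f"{int((qc_report['hwe_p'] < config.qc.min_hwe_p).sum())} "
            f"below HWE)"
        )

    adjusted = lscan.adjust_for_age(
        pheno, mode="linear" if config.age_adjust else "none")
    trait = adjusted.reindex(pd.Index(panel.subject_ids)).to_numpy(dtype=float)

    results = lscan.scan_panel(filtered, trait, models=config.models,
                               min_group_cells=config.min_group_cells)
    hits = sorted((r for r in results
                   if not r.degenerate and r.min_p < config.screen_alpha),
                  key=lambda r: (r.min_p, r.snp_id, r.model.value))
    logger.info("screen: %d hits at P < %g among %d (SNP, model) results",
                len(hits), config.screen_alpha, len(results))

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        lqc.write_qc_report_tsv(qc_report, out / "qc_report.tsv")
        lscan.write_scan_results_tsv(results, out / "scan_results.tsv",
                                     panel=filtered)
        lscan.write_scan_results_tsv(hits, out / "hits.tsv", panel=filtered)
        _write_manifest(out / "run_manifest.json", config, panel, filtered,
                        len(hits))
    return ScreenOutput(qc_report, results, hits)


def _write_manifest(path: Path, config: ScreenConfig, panel, filtered,
                    n_hits: int) -> None:
    manifest = {
        "version": __version__,
        "n_subjects": int(panel.n_subjects),
        "n_snps_input": int(panel.n_snps),
        "n_snps_post_qc": int(filtered.n_snps),
        "n_hits": n_hits,
        "qc": {"min_call_rate": config.qc.min_call_rate,
               "min_maf": config.qc.min_maf,
               "min_hwe_p": config.qc.min_hwe_p},
        "screen_alpha": config.screen_alpha,
        "min_group_cells": config.min_group_cells,
        "age_adjust": config.age_adjust,
        "models": [m.value for m in config.models],
        "seed": config.seed,
        "input_checksum": hashlib.sha256(panel.calls.tobytes()).hexdigest(),
    }
    path.write_text(json.dumps(manifest, indent=2) + "\n")


def manhattan_data(results, panel: Optional[lio.GenotypePanel] = None):
    """-log10(P) table for Manhattan plotting, ordered by (chrom, pos).

    Degenerate results are emitted with ``neg_log10_p = 0``.  The returned
    frame carries ``attrs['reference_lines'] = [5.0, 6.0]`` — the customary
    suggestive (1e-5) and screening (1e-6) guide lines.
    """
    frame = lscan.results_to_frame(results, panel)
    neg = np.where(frame["degenerate"], 0.0, -np.log10(frame["min_p"]))
    out = pd.DataFrame({"chrom": frame["chrom"], "pos": frame["pos"],
                        "snp_id": frame["snp_id"], "model": frame["model"],
                        "neg_log10_p": neg})
    out = out.sort_values(["chrom", "pos", "model"],
                          kind="stable").reset_index(drop=True)
    out.attrs["reference_lines"] = [5.0, 6.0]
    return out


def run_replication(panel: lio.GenotypePanel, pheno: lio.PhenotypeTable,
                    snp_id: str,
                    grouping: lscan.GeneticModel = lscan.GeneticModel.DOMINANT_MINOR,
                    variant: str = "pooled",
                    age_adjust: bool = False) -> pd.DataFrame:
    """Stage-2 report: per-trait group summaries and unpaired t-tests.

    Produces one row per trait (lean mass first, then the available
    secondary traits and age) with (n, mean, SE) for the reference and
    carrier groups.  Raw traits by default; ``age_adjust=True``
    residualizes lean mass on age first.
    """
    panel, pheno = lio.align_subjects(panel, pheno)
    labels = lscan.collapse_genotypes(panel.snp_calls(snp_id), grouping)
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValueError(
            f"replication grouping leaves a genotype group with < 2 subjects "
            f"for {snp_id} under {grouping.value}"
        )
    pheno_used = pheno
    if age_adjust:
        adjusted = lscan.adjust_for_age(pheno)
        data = pheno.data.copy()
        data.loc[adjusted.index, "lean_mass_pct"] = adjusted
        pheno_used = lio.PhenotypeTable(data)
    return lrep.compare_traits(pheno_used, labels, variant=variant)
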