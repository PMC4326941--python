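"""Input/output for genotype panels and phenotype tables.

Genotype calls are coded as counts of the *coded* allele per subject:
0 (homozygous major), 1 (heterozygous), 2 (homozygous minor), with
:data:`MISSING` (= -1) for a failed call.  Whether the coded allele really
is the minor allele in-sample is established downstream by
:func:`leanscan.qc.compute_maf`; the VCF importer flips codes on import so
that code 2 always counts the in-sample minor allele.

On-disk dialects (all tab-separated, plain text):

* genotype TSV — header ``subject_id`` followed by one column per SNP id;
  body cells in ``{0, 1, 2, NA}``.
* SNP map TSV — columns ``snp_id, chrom, pos, major, minor`` (pos 1-based).
* phenotype TSV — columns ``subject_id, lean_mass_pct, age_years`` plus any
  of the optional trait columns; ``NA`` marks a missing value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call in the in-memory matrix.
MISSING: int = -1

_CODE_FROM_TEXT = {"0": 0, "1": 1, "2": 2, "NA": MISSING}
_TEXT_FROM_CODE = {0: "0", 1: "1", 2: "2", MISSING: "NA"}

MAP_COLUMNS = ("chrom", "pos", "major", "minor")

#: Required phenotype columns (besides the subject id).
PHENO_REQUIRED = ("lean_mass_pct", "age_years")
#: Recognised optional trait columns, in canonical output order.
PHENO_OPTIONAL = ("fat_mass_pct", "bmd", "body_weight_kg", "body_height_cm", "bmi")


class FormatError(ValueError):
    """A file does not follow the documented dialect."""


@dataclass
class GenotypePanel:
    """Subjects x SNPs matrix of coded-allele counts plus per-SNP metadata.

    Attributes
    ----------
    subject_ids : ndarray of str, shape (n_subjects,)
    snp_ids : ndarray of str, shape (n_snps,)
    calls : ndarray of int8, shape (n_subjects, n_snps)
        Values in {0, 1, 2, MISSING}.
    snp_meta : DataFrame indexed by snp_id
        Columns ``chrom`` (str), ``pos`` (1-based int), ``major``, ``minor``.
    """

    subject_ids: np.ndarray
    snp_ids: np.ndarray
    calls: np.ndarray
    snp_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise FormatError("duplicate subject ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise FormatError("duplicate SNP ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid genotype codes: {np.unique(self.calls[bad])}")
        if list(self.snp_meta.index) != list(self.snp_ids):
            raise ValueError("snp_meta index does not match snp_ids")
        missing_cols = set(MAP_COLUMNS) - set(self.snp_meta.columns)
        if missing_cols:
            raise ValueError(f"snp_meta lacks columns {sorted(missing_cols)}")
        pos = self.snp_meta["pos"]
        if not ((pos == pos.astype(int)) & (pos > 0)).all():
            raise ValueError("positions must be positive integers")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def select_subjects(self, subject_ids) -> "GenotypePanel":
        """Restrict to the given subjects, in the given order."""
        index = pd.Index(self.subject_ids)
        pos = index.get_indexer(list(subject_ids))
        if (pos < 0).any():
            raise KeyError("unknown subject id(s) requested")
        return GenotypePanel(
            np.asarray(list(subject_ids), dtype=object),
            self.snp_ids.copy(),
            self.calls[pos, :],
            self.snp_meta.copy(),
        )

    def select_snps(self, mask_or_ids) -> "GenotypePanel":
        """Restrict to SNPs given as a boolean mask or an id sequence."""
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            index = pd.Index(self.snp_ids)
            idx = index.get_indexer(list(mask_or_ids))
            if (idx < 0).any():
                raise KeyError("unknown SNP id(s) requested")
        return GenotypePanel(
            self.subject_ids.copy(),
            self.snp_ids[idx],
            self.calls[:, idx],
            self.snp_meta.iloc[idx].copy(),
        )

    def snp_calls(self, snp_id: str) -> np.ndarray:
        """Genotype code vector for one SNP, aligned with ``subject_ids``."""
        j = int(np.flatnonzero(self.snp_ids == snp_id)[0]) if snp_id in self.snp_ids else None
        if j is None:
            raise KeyError(f"SNP {snp_id!r} not in panel")
        return self.calls[:, j]


def default_snp_meta(snp_ids, chrom: str = "un") -> pd.DataFrame:
    """Placeholder metadata for panels whose map is unknown (tests, ad hoc use)."""
    ids = list(snp_ids)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, len(ids) + 1, dtype=np.int64),
            "major": "A",
            "minor": "B",
        },
        index=pd.Index(ids, name="snp_id"),
    )


@dataclass
class PhenotypeTable:
    """Per-subject quantitative traits, indexed by subject id.

    ``data`` holds ``lean_mass_pct`` and ``age_years`` plus any of the
    optional trait columns.  Rows with a missing lean mass or age are kept
    but excluded from the ``usable`` mask.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise FormatError("duplicate subject ids in phenotype table")
        for col in PHENO_REQUIRED:
            if col not in df.columns:
                raise FormatError(f"phenotype table lacks required column {col!r}")
        df.index.name = "subject_id"
        for col in ("lean_mass_pct", "fat_mass_pct"):
            if col in df.columns:
                vals = df[col].dropna()
                if ((vals <= 0) | (vals >= 100)).any():
                    raise ValueError(f"{col} values must lie strictly in (0, 100)")
        ages = df["age_years"].dropna()
        if (ages <= 0).any():
            raise ValueError("ages must be positive")

    @property
    def subject_ids(self) -> np.ndarray:
        return np.asarray(self.data.index, dtype=object)

    @property
    def usable(self) -> pd.Series:
        """True where both lean mass and age are present."""
        return self.data["lean_mass_pct"].notna() & self.data["age_years"].notna()

    def optional_traits(self) -> list:
        return [c for c in PHENO_OPTIONAL if c in self.data.columns]

    def select_subjects(self, subject_ids) -> "PhenotypeTable":
        return PhenotypeTable(self.data.loc[list(subject_ids)].copy())


# ---------------------------------------------------------------------------
# genotype TSV


def read_genotype_tsv(path, map_path=None) -> GenotypePanel:
    """Read the genotype TSV dialect (plus optional companion map TSV).

    Unparseable cells raise :class:`FormatError`; nothing is coerced.
    """
    with open(path) as fh:  # pandas mangles duplicate headers, so check raw
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "subject_id":
        raise FormatError("first header cell must be 'subject_id'")
    if len(set(header[1:])) != len(header[1:]):
        raise FormatError("duplicate SNP column ids")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    snp_ids = list(df.columns[1:])
    subject_ids = df["subject_id"].tolist()
    if len(set(subject_ids)) != len(subject_ids):
        raise FormatError("duplicate subject ids")
    body = df.iloc[:, 1:].to_numpy(dtype=object)
    calls = np.empty(body.shape, dtype=np.int8)
    for text, code in _CODE_FROM_TEXT.items():
        calls[body == text] = code
    known = np.isin(body, list(_CODE_FROM_TEXT))
    if not known.all():
        i, j = np.argwhere(~known)[0]
        raise FormatError(
            f"invalid genotype cell {body[i, j]!r} for subject {subject_ids[i]!r}, "
            f"SNP {snp_ids[j]!r}"
        )
    if map_path is not None:
        meta = read_snp_map_tsv(map_path)
        missing = set(snp_ids) - set(meta.index)
        if missing:
            raise FormatError(f"map file lacks SNPs: {sorted(missing)[:5]} ...")
        meta = meta.loc[snp_ids]
    else:
        meta = default_snp_meta(snp_ids)
    return GenotypePanel(np.array(subject_ids, dtype=object),
                         np.array(snp_ids, dtype=object), calls, meta)


def read_snp_map_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str,
                                              "major": str, "minor": str})
    missing = {"snp_id", *MAP_COLUMNS} - set(meta.columns)
    if missing:
        raise FormatError(f"map file lacks columns {sorted(missing)}")
    if meta["snp_id"].duplicated().any():
        raise FormatError("duplicate SNP ids in map file")
    meta = meta.set_index("snp_id")
    meta["pos"] = meta["pos"].astype(np.int64)
    if (meta["pos"] <= 0).any():
        raise FormatError("positions must be positive integers")
    return meta[list(MAP_COLUMNS)]


def write_genotype_tsv(panel: GenotypePanel, path, map_path=None) -> None:
    body = np.empty(panel.calls.shape, dtype=object)
    for code, text in _TEXT_FROM_CODE.items():
        body[panel.calls == code] = text
    df = pd.DataFrame(body, columns=panel.snp_ids)
    df.insert(0, "subject_id", panel.subject_ids)
    df.to_csv(path, sep="\t", index=False)
    if map_path is not None:
        panel.snp_meta.reset_index().rename(columns={"index": "snp_id"}).to_csv(
            map_path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# phenotype TSV


def read_phenotype_tsv(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str},
                     na_values=["NA"], keep_default_na=False)
    if "subject_id" not in df.columns:
        raise FormatError("phenotype file lacks 'subject_id' column")
    for col in PHENO_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"phenotype file lacks required column {col!r}")
    if df["subject_id"].duplicated().any():
        raise FormatError("duplicate subject ids in phenotype file")
    df = df.set_index("subject_id")
    keep = [c for c in (*PHENO_REQUIRED, *PHENO_OPTIONAL) if c in df.columns]
    return PhenotypeTable(df[keep].astype(float))


def write_phenotype_tsv(pheno: PhenotypeTable, path) -> None:
    pheno.data.reset_index().to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# VCF import


def import_vcf(path) -> GenotypePanel:
    """Import biallelic SNPs from a VCF, coding genotypes as minor-allele counts.

    ALT-allele counts are flipped (2 - code) wherever the ALT allele turns
    out to be the in-sample *major* allele, so that code 2 always counts the
    minor allele; flips are logged.  Multiallelic records are skipped with a
    warning.  Phased separators are accepted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = list(vcf.samples)
    columns, ids, chroms, poss, refs, alts = [], [], [], [], [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            logger.warning("skipping multiallelic record at %s:%d",
                           variant.CHROM, variant.POS)
            continue
        codes = np.empty(len(subject_ids), dtype=np.int8)
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]  # trailing element is the phased flag
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                codes[i] = MISSING
            else:
                codes[i] = sum(1 for a in alleles if a == 1)
        columns.append(codes)
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chroms.append(variant.CHROM)
        poss.append(variant.POS)
        refs.append(variant.REF)
        alts.append(variant.ALT[0])
    vcf.close()
    calls = (np.column_stack(columns) if columns
             else np.empty((len(subject_ids), 0), dtype=np.int8))
    major, minor = list(refs), list(alts)
    for j in range(calls.shape[1]):
        col = calls[:, j]
        obs = col[col != MISSING]
        if obs.size and obs.sum() > obs.size:  # ALT frequency > 0.5: ALT is major
            obs_idx = col != MISSING
            calls[obs_idx, j] = 2 - col[obs_idx]
            major[j], minor[j] = minor[j], major[j]
            logger.info("flipped allele coding for %s (ALT is the major allele)",
                        ids[j])
    meta = pd.DataFrame(
        {"chrom": chroms, "pos": np.asarray(poss, dtype=np.int64),
         "major": major, "minor": minor},
        index=pd.Index(ids, name="snp_id"),
    )
    return GenotypePanel(np.array(subject_ids, dtype=object),
                         np.array(ids, dtype=object), calls, meta)


# ---------------------------------------------------------------------------


def align_subjects(panel: GenotypePanel, pheno: PhenotypeTable):
    """Restrict both inputs to their common subjects, in sorted order."""
    common = sorted(set(panel.subject_ids) & set(pheno.subject_ids))
    if not common:
        raise ValueError("no subjects shared between genotype panel and phenotypes")
    dropped_panel = panel.n_subjects - len(common)
    dropped_pheno = len(pheno.subject_ids) - len(common)
    if dropped_panel or dropped_pheno:
        logger.info("align_subjects: dropped %d panel / %d phenotype subjects",
                    dropped_panel, dropped_pheno)
    return panel.select_subjects(common), pheno.select_subjects(common)
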