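"""Readers and writers for the genotype/phenotype formats used by the tests.

Genotypes come from biallelic VCF (GT parsed to dosage 0/1/2, carriage =
dosage >= 1); phenotypes and covariates from a tab-separated table with a
``sample_id`` and binary ``status`` column, any further numeric columns
being covariates.  Readers are order-normalizing: outputs depend on record
content keyed by id, never on file order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = ["GenotypeDataset", "read_vcf", "read_pheno", "write_results"]


@dataclass
class GenotypeDataset:
    """A subjects x variants dosage matrix with ids and per-variant sample MAF."""

    sample_ids: list[str]
    variant_ids: list[str]
    matrix: np.ndarray  # dosage 0/1/2
    mafs: np.ndarray

    @property
    def carriage_matrix(self) -> np.ndarray:
        return (self.matrix >= 1).astype(np.int8)

    @property
    def carriage(self) -> np.ndarray:
        return self.carriage_matrix.any(axis=1).astype(np.int64)


# cyvcf2 gt_types codes
_HOM_REF, _HET, _UNKNOWN, _HOM_ALT = 0, 1, 2, 3


def read_vcf(path: str, missing_drop: bool = False) -> GenotypeDataset:
    """Read a biallelic VCF into a dosage matrix.

    Missing genotypes are imputed as homozygous reference (non-carrier) with
    a logged count, unless ``missing_drop`` is set, in which case samples
    with any missing call are excluded.  Multi-allelic records are rejected.
    """
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variant_ids: list[str] = []
    rows: list[np.ndarray] = []
    missing_mask = np.zeros(len(sample_ids), dtype=bool)
    n_missing = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record not supported: {rec.CHROM}:{rec.POS} "
                f"ALT={rec.ALT}"
            )
        gt = np.asarray(rec.gt_types)
        dosage = np.zeros(gt.shape[0], dtype=np.int8)
        dosage[gt == _HET] = 1
        dosage[gt == _HOM_ALT] = 2
        miss = gt == _UNKNOWN
        if miss.any():
            n_missing += int(miss.sum())
            missing_mask |= miss
            if miss.all():
                logger.warning(
                    "all genotypes missing at %s:%s; site treated as monomorphic",
                    rec.CHROM, rec.POS,
                )
        rows.append(dosage)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variant_ids.append(vid)
    vcf.close()
    if not rows:
        raise ValueError(f"no variant records in {path}")
    matrix = np.stack(rows, axis=1)
    if n_missing:
        logger.info("%d missing genotype calls imputed as non-carrier", n_missing)
    if missing_drop and missing_mask.any():
        keep = ~missing_mask
        matrix = matrix[keep]
        sample_ids = [s for s, k in zip(sample_ids, keep) if k]

    n = matrix.shape[0]
    mafs = matrix.sum(axis=0) / (2.0 * n) if n else np.zeros(matrix.shape[1])
    mafs = np.minimum(mafs, 1.0 - mafs)
    order = np.argsort(variant_ids, kind="stable")
    return GenotypeDataset(
        sample_ids=sample_ids,
        variant_ids=[variant_ids[i] for i in order],
        matrix=matrix[:, order],
        mafs=mafs[order],
    )


def read_pheno(
    path: str, align_to: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray | None, list[str]]:
    """Read the phenotype/covariate TSV; returns (y, covariates, sample_ids).

    ``status`` must be binary 0/1; any additional numeric columns become the
    covariate matrix (in column order).  With ``align_to``, rows are
    reordered to that sample order and unmatched ids raise.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "status"):
        if col not in df.columns:
            raise ValueError(f"phenotype table must have a '{col}' column")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicated sample ids: {sorted(set(dup))[:5]}")
    if not set(pd.unique(df["status"])) <= {0, 1}:
        raise ValueError("status must be binary 0/1")
    df = df.set_index("sample_id")
    if align_to is not None:
        missing = [s for s in align_to if s not in df.index]
        if missing:
            raise ValueError(f"samples absent from phenotype table: {missing[:10]}")
        df = df.loc[align_to]
    else:
        df = df.sort_index()
    cov_cols = [c for c in df.columns if c != "status"]
    cov = None
    if cov_cols:
        cov = df[cov_cols].to_numpy(dtype=float)
        if np.isnan(cov).any():
            raise ValueError("covariate columns contain missing/non-numeric values")
    return df["status"].to_numpy(dtype=np.int64), cov, list(df.index)


def write_results(results, path: str) -> pd.DataFrame:
    """Serialize a list of TestResult to CSV (method, statistic, p_value, ...)."""
    df = pd.DataFrame(
        [
            {
                "method": r.method,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "mode": r.mode,
                "n_resamples": r.n_resamples,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    )
    df.to_csv(path, index=False)
    return df
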