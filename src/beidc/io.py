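"""Reading and writing genotype/phenotype tables.

Two on-disk formats are supported: a plain TSV dialect (header row of
feature identifiers, one row per sample, first column the sample ID) and
VCF, where biallelic sites are converted to alternate-allele dosages 0/1/2
from the GT field.  Missing genotypes are mean-imputed per feature (the
count is logged); features missing everywhere are dropped with a warning.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix

logger = logging.getLogger("beidc")

__all__ = ["read_genotypes", "write_genotypes", "read_phenotype", "write_phenotype"]

MISSING_SENTINELS = {"", "NA", "NaN", "nan", ".", "na"}


def _impute(values: np.ndarray, ids: List[str], coords) -> FeatureMatrix:
    keep = ~np.all(np.isnan(values), axis=0)
    if not keep.all():
        dropped = [i for i, k in zip(ids, keep) if not k]
        logger.warning("dropping %d all-missing feature(s): %s", len(dropped), dropped[:5])
        values = values[:, keep]
        ids = [i for i, k in zip(ids, keep) if k]
        if coords is not None:
            coords = [c for c, k in zip(coords, keep) if k]
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        col_means = np.nanmean(values, axis=0)
        idx = np.where(np.isnan(values))
        values[idx] = col_means[idx[1]]
        logger.info("mean-imputed %d missing genotype value(s)", n_missing)
    return FeatureMatrix(values=values, feature_ids=ids, coords=coords)


def _read_tsv(path: str) -> Tuple[FeatureMatrix, List[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    sample_ids = [str(s) for s in df.index]
    ids = [str(c) for c in df.columns]
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col].astype(str).str.strip()
        cell = raw.where(~raw.isin(MISSING_SENTINELS), "nan").to_numpy()
        try:
            # numpy's parser round-trips %.17g exactly (pandas' fast path does not)
            values[:, j] = cell.astype(float)
        except ValueError:
            for row, v in zip(df.index, cell):
                try:
                    float(v)
                except ValueError:
                    raise ValueError(
                        f"non-numeric value {v!r} at row {row!r}, column {col!r}"
                    ) from None
            raise
    return _impute(values, ids, None), sample_ids


def _read_vcf(path: str) -> Tuple[FeatureMatrix, List[str]]:
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    cols, ids, coords = [], [], []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(variant.gt_types, dtype=float)
        dosage = np.where(gt == 3, 2.0, gt)
        dosage[gt == 2] = np.nan
        cols.append(dosage)
        vid = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        ids.append(vid)
        coords.append((variant.CHROM, int(variant.POS)))
    vcf.close()
    if n_multi:
        logger.info("skipped %d multi-allelic site(s)", n_multi)
    if not cols:
        raise ValueError(f"no usable biallelic sites in {path}")
    return _impute(np.column_stack(cols), ids, coords), sample_ids


def read_genotypes(path: str, fmt: str = "tsv") -> Tuple[FeatureMatrix, List[str]]:
    """Load a genotype table; returns (FeatureMatrix, sample_ids)."""
    if fmt == "tsv":
        return _read_tsv(path)
    if fmt == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {fmt!r} (expected 'tsv' or 'vcf')")


def write_genotypes(path: str, X: FeatureMatrix, sample_ids: Optional[List[str]] = None) -> None:
    """Write a FeatureMatrix to the TSV dialect (exact round trip)."""
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(X.n)]
    df = pd.DataFrame(X.values, index=pd.Index(sample_ids, name="sample_id"),
                      columns=list(X.feature_ids))
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_phenotype(path: str) -> Tuple[np.ndarray, Optional[List[str]]]:
    """Read a phenotype file: TSV with (sample_id, value) or a single value column."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] == 1:
        return df.iloc[:, 0].to_numpy().astype(float), None
    return df.iloc[:, 1].to_numpy().astype(float), [str(s) for s in df.iloc[:, 0]]


def write_phenotype(path: str, y: np.ndarray, sample_ids: Optional[List[str]] = None) -> None:
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(len(y))]
    pd.DataFrame({"sample_id": sample_ids, "phenotype": np.asarray(y, dtype=float)}).to_csv(
        path, sep="\t", index=False, float_format="%.17g")
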