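"""Readers, writers and deterministic SNP subsetting.

Delimited matrices are plain TSV/CSV: one header row of feature ids, first
column of sample ids. Genotype layers are additionally accepted as PLINK
``.raw`` dosage exports (header ``FID IID PAT MAT SEX PHENOTYPE`` followed
by one column per SNP, values 0/1/2; the sample id is the IID). Missing
entries are an input error at this layer and are reported with their
(sample, SNP) coordinates rather than imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import FeatureMatrix, GenotypeMatrix, subset_columns
from .exceptions import (
    DuplicateIds,
    InvalidCount,
    MissingValues,
    ParseError,
)

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_matrix(path, format: str = "tsv"):
    """Read a layer from disk.

    format
        ``tsv``/``csv`` — delimited numeric matrix, returns FeatureMatrix;
        ``plink_raw`` — PLINK .raw dosage export, returns GenotypeMatrix.
    """
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(set(header)) != len(header):
            raise DuplicateIds(f"{path}: duplicate feature ids in header")
        try:
            df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        except (pd.errors.ParserError, ValueError) as err:
            raise ParseError(f"{path}: {err}") from err
        if df.index.has_duplicates:
            raise DuplicateIds(f"{path}: duplicate sample ids")
        vals = df.to_numpy(dtype=float)
        bad = np.argwhere(~np.isfinite(vals))
        if bad.size:
            raise MissingValues(
                [(str(df.index[i]), str(df.columns[j])) for i, j in bad]
            )
        return FeatureMatrix(
            vals, [str(s) for s in df.index], [str(c) for c in df.columns]
        )
    if format == "plink_raw":
        try:
            df = pd.read_csv(path, sep=r"\s+")
        except (pd.errors.ParserError, ValueError) as err:
            raise ParseError(f"{path}: {err}") from err
        missing_meta = [c for c in _PLINK_META if c not in df.columns]
        if missing_meta:
            raise ParseError(f"{path}: missing PLINK columns {missing_meta}")
        samples = [str(s) for s in df["IID"]]
        if len(set(samples)) != len(samples):
            raise DuplicateIds(f"{path}: duplicate IID values")
        snps = [c for c in df.columns if c not in _PLINK_META]
        vals = df[snps].to_numpy(dtype=float)
        bad = np.argwhere(~np.isfinite(vals))
        if bad.size:
            raise MissingValues([(samples[i], snps[j]) for i, j in bad])
        if not np.isin(vals, [0.0, 1.0, 2.0]).all():
            i, j = np.argwhere(~np.isin(vals, [0.0, 1.0, 2.0]))[0]
            raise ParseError(
                f"{path}: non-dosage value {vals[i, j]!r} at ({samples[i]}, {snps[j]})"
            )
        return GenotypeMatrix(vals, samples, snps, ploidy=2)
    raise ValueError(f"unknown format {format!r}")


def write_matrix(M: FeatureMatrix, path, format: str = "tsv") -> None:
    """Write a layer as delimited text; round-trips bit-exactly with
    :func:`read_matrix` (numeric output at 17 significant digits)."""
    sep = "\t" if format == "tsv" else ","
    df = pd.DataFrame(M.values, index=M.sample_ids, columns=M.feature_ids)
    df.to_csv(path, sep=sep, float_format="%.17g")


def evenly_spaced_subset(G, k: int):
    """Keep k evenly spaced (in variant counts) columns, endpoints included.

    Retains 1-based indices round(1 + (j - 1)(p - 1)/(k - 1)) for
    j = 1..k under round-half-up; deterministic.
    """
    p = G.n_features
    if not 2 <= k <= p:
        raise InvalidCount(f"k must be in [2, {p}], got {k}")
    j = np.arange(1, k + 1, dtype=float)
    idx = np.floor(1.0 + (j - 1.0) * (p - 1.0) / (k - 1.0) + 0.5).astype(int) - 1
    return subset_columns(G, idx)
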