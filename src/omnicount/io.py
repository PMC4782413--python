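"""Delimited-text I/O: count matrices, covariate matrices, BED positions, strata.

Conventions: matrices are TSV with a header row of sample ids and a first
column of feature (gene/covariate) ids; positions are BED (chrom, start,
end, name) with 0-based half-open coordinates; strata are a two-column TSV
(sample id, stratum label) without a header.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError


def read_count_matrix(path) -> pd.DataFrame:
    """Read a genes x samples count matrix; cells must be non-negative integers."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise InvalidInputError(f"duplicate gene ids in {path}")
    if df.columns.has_duplicates:
        raise InvalidInputError(f"duplicate sample ids in {path}")
    values = df.to_numpy()
    if values.size == 0:
        raise InvalidInputError(f"empty count matrix in {path}")
    if not np.issubdtype(values.dtype, np.number):
        raise InvalidInputError(f"non-numeric cells in {path}")
    if np.any(~np.isfinite(values.astype(float))):
        raise InvalidInputError(f"missing or non-finite counts in {path}")
    if np.any(values < 0) or not np.allclose(values, np.round(values)):
        raise InvalidInputError(f"counts must be non-negative integers in {path}")
    return df.astype(np.int64)


def read_covariate_matrix(path) -> pd.DataFrame:
    """Read a covariates x samples matrix of quantitative or dosage values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise InvalidInputError(f"duplicate covariate ids in {path}")
    if df.columns.has_duplicates:
        raise InvalidInputError(f"duplicate sample ids in {path}")
    values = df.to_numpy()
    if values.size == 0 or not np.issubdtype(values.dtype, np.number):
        raise InvalidInputError(f"covariate matrix in {path} must be numeric and non-empty")
    return df.astype(float)


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (chrom, start, end, name); coordinates 0-based half-open."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"],
        dtype={"chrom": str, "name": str},
    )
    if df.empty:
        raise InvalidInputError(f"no intervals in {path}")
    if (df["start"] > df["end"]).any():
        raise InvalidInputError(f"interval with start > end in {path}")
    if df["name"].duplicated().any():
        raise InvalidInputError(f"duplicate interval names in {path}")
    return df


def read_strata(path) -> pd.Series:
    """Read sample->stratum labels from a two-column TSV without header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "stratum"], dtype=str)
    if df["sample"].duplicated().any():
        raise InvalidInputError(f"duplicate sample ids in {path}")
    return df.set_index("sample")["stratum"]


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
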