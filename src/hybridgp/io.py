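"""Delimited-text readers and writers for markers, pedigrees, kernels,
phenotypes and environment covariance matrices.

Comma is the default delimiter and tab is auto-detected; ids are opaque
strings (never coerced to numbers).  Kernel round-trips are bit-stable:
matrices are written with 17 significant digits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from hybridgp.phenotypes import PhenotypeTable
from hybridgp.relation_kernels import MarkerMatrix, PedigreeTable, RelationshipKernel

__all__ = [
    "read_markers",
    "write_markers",
    "read_pedigree",
    "write_pedigree",
    "read_kernel",
    "write_kernel",
    "read_phenotypes",
    "write_phenotypes",
    "read_env_cov",
    "write_env_cov",
]

FLOAT_FMT = "%.17g"


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") > first.count(",") else ","


def read_markers(path, transpose: bool = False) -> MarkerMatrix:
    """Read a genotype x marker dosage table.

    First column holds genotype ids, header row holds marker ids.  With
    ``transpose=True`` the file is marker x genotype (numeric-HapMap
    style matrix) and is transposed after reading.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, dtype={0: str},
                     float_precision="round_trip")
    if transpose:
        df = df.T
    values = df.to_numpy(dtype=float)
    return MarkerMatrix(
        ids=[str(i) for i in df.index],
        values=values,
        marker_ids=[str(c) for c in df.columns],
    )


def write_markers(markers: MarkerMatrix, path, sep: str = ",") -> None:
    df = pd.DataFrame(markers.values, index=markers.ids, columns=markers.marker_ids)
    df.to_csv(path, sep=sep, float_format=FLOAT_FMT, index_label="id")


def read_pedigree(path) -> PedigreeTable:
    """Read 3-column pedigree (id, parent1, parent2; empty/NA = unknown)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ValueError("pedigree file needs 3 columns: id, parent1, parent2")
    records = [
        (row.iloc[0], row.iloc[1] or None, row.iloc[2] or None)
        for _, row in df.iterrows()
    ]
    return PedigreeTable(records)


def write_pedigree(pedigree: PedigreeTable, path, sep: str = ",") -> None:
    df = pd.DataFrame(pedigree.records, columns=["id", "parent1", "parent2"])
    df.to_csv(path, sep=sep, index=False)


def read_kernel(path, kind: str = "custom") -> RelationshipKernel:
    """Read a square kernel matrix with id header row and id first column."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, float_precision="round_trip")
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValueError("kernel row and column ids differ")
    return RelationshipKernel(ids=ids, matrix=df.to_numpy(dtype=float), kind=kind)


def write_kernel(kernel: RelationshipKernel, path, sep: str = ",") -> None:
    df = pd.DataFrame(kernel.matrix, index=kernel.ids, columns=kernel.ids)
    df.to_csv(path, sep=sep, float_format=FLOAT_FMT, index_label="id")


def read_phenotypes(path) -> PhenotypeTable:
    """Read long-format phenotypes with columns genotype, environment, value."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype={"genotype": str, "environment": str},
                     float_precision="round_trip")
    return PhenotypeTable(df)


def write_phenotypes(phenotypes: PhenotypeTable, path, sep: str = ",") -> None:
    phenotypes.df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)


def read_env_cov(path) -> pd.DataFrame:
    """Read a square environment covariance with environment-id headers."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, float_precision="round_trip")
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    df.index.name = None
    df.columns.name = None
    if list(df.index) != list(df.columns):
        raise ValueError("environment covariance row/column ids differ")
    return df.astype(float)


def write_env_cov(E: pd.DataFrame, path, sep: str = ",") -> None:
    E.to_csv(path, sep=sep, float_format=FLOAT_FMT, index_label="env")
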