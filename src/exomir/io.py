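"""Readers and writers for the pipeline's tab-separated formats, plus packaged
fixtures transcribing the source study's printed result tables.

Matrix format: first column is the feature/assay id, header row carries sample
ids, tab-delimited, decimal point ``.``.  Missing Ct values are written as
empty fields.  Sample metadata is a two-column TSV ``sample<TAB>group`` with
group in ``{case, control}``.

Fixtures (``load_fixture``) ship inside the package as plain TSV and transcribe
the printed tables verbatim — including P values printed as ``0.000`` or
``0.050`` — so that acceptance checks count printed rows rather than re-derived
significance.
"""

from __future__ import annotations

import sys
from importlib import resources
from pathlib import Path
from typing import IO, Union

import numpy as np
import pandas as pd

from .containers import CtMatrix, ExpressionMatrix, ValidationError

PathLike = Union[str, Path, IO[str]]

FIXTURES = ("table2", "table3", "table4", "table6")


def _read_table(path: PathLike) -> pd.DataFrame:
    if path == "-":
        path = sys.stdin
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_metadata(path: PathLike) -> pd.Series:
    """Read the two-column sample metadata TSV into a sample -> group Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("metadata must have columns: sample, group")
    df = df.iloc[:, :2]
    df.columns = ["sample", "group"]
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValidationError(f"duplicated sample ids in metadata: {dups}")
    return df.set_index("sample")["group"]


def write_metadata(groups: pd.Series, path: PathLike) -> None:
    df = pd.DataFrame({"sample": groups.index, "group": groups.values})
    df.to_csv(path, sep="\t", index=False)


def read_expression(path: PathLike, metadata: PathLike, unit: str = "count") -> ExpressionMatrix:
    """Load an expression matrix TSV plus its sample metadata.

    Raises a labelled error naming the offending sample/feature on duplicate
    ids, missing metadata rows, or negative values (via container validation).
    """
    values = _read_table(path)
    groups = read_metadata(metadata)
    return ExpressionMatrix(values, groups, unit=unit)


def write_expression(m: ExpressionMatrix, path: PathLike, metadata: PathLike | None = None) -> None:
    """Write matrix (and optionally metadata) as TSV; integer counts bit-exact."""
    values = m.values
    if m.unit == "count" and np.allclose(values.to_numpy() % 1, 0):
        values = values.astype(np.int64)
    values.to_csv(path, sep="\t", index_label="feature")
    if metadata is not None:
        write_metadata(m.groups, metadata)


def read_ct(path: PathLike, metadata: PathLike) -> CtMatrix:
    """Load a Ct table TSV; empty fields become missing (NaN)."""
    values = _read_table(path).astype(float)
    groups = read_metadata(metadata)
    return CtMatrix(values, groups)


def write_ct(ct: CtMatrix, path: PathLike, metadata: PathLike | None = None) -> None:
    ct.values.to_csv(path, sep="\t", index_label="assay", na_rep="")
    if metadata is not None:
        write_metadata(ct.groups, metadata)


def _fixture_path(name: str):
    return resources.files("exomir.data").joinpath(f"{name}.tsv")


def fixture_text(name: str) -> str:
    """Raw fixture file content (used to pin transcription checksums)."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {list(FIXTURES)}")
    return _fixture_path(name).read_text()


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged result-table transcriptions.

    ================  =====================================================
    name              contents
    ================  =====================================================
    ``table2``        75 differential serum-exosomal miRNAs from the 6+6
                      discovery set: read counts, log2FC, P, direction
    ``table3``        tidy long table of the five stability analyses over
                      nine candidate references: method, printed rank, gene,
                      statistic (BestKeeper rows carry CV[%CP] in ``extra``)
    ``table4``        ROC summaries for the two validated markers
    ``table6``        tissue-cohort read counts and log2FC for miR-941
    ================  =====================================================

    P values are returned both as printed strings (``pvalue``) and parsed
    floats (``pvalue_float``; ``<0.001`` parses to 0.001 as an upper bound).
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {list(FIXTURES)}")
    with resources.as_file(_fixture_path(name)) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    if name == "table2":
        for col in ("case_readcount", "control_readcount", "log2FoldChange"):
            df[col] = df[col].astype(float)
        df["pvalue_float"] = df["pvalue"].astype(float)
    elif name == "table3":
        df["printed_rank"] = df["printed_rank"].astype(int)
        df["statistic"] = df["statistic"].astype(float)
        df["extra"] = df["extra"].astype(float)
    elif name == "table4":
        for col in ("auc", "se", "ci_low", "ci_high"):
            df[col] = df[col].astype(float)
        df["pvalue_float"] = df["pvalue"].str.lstrip("<").astype(float)
    elif name == "table6":
        for col in ("tumor_readcount", "normal_readcount", "log2FoldChange"):
            df[col] = df[col].astype(float)
        df["pvalue_float"] = df["pvalue"].astype(float)
    return df


def table3_statistics(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pivot the table3 fixture to a gene x method matrix of printed statistics.

    Columns are the four input stability methods (smaller = more stable);
    the consensus aggregator column is excluded.
    """
    if df is None:
        df = load_fixture("table3")
    methods = ["bestkeeper", "normfinder", "genorm", "delta_ct"]
    wide = (
        df[df["method"].isin(methods)]
        .pivot(index="gene", columns="method", values="statistic")
        .loc[:, methods]
    )
    wide.columns.name = None
    return wide
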