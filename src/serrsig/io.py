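"""Readers and writers for the plain-text formats the pipeline exchanges.

All tables are tab-separated. Expression matrices carry a ``gene_id`` first
column and one column per sample; sample annotations are two-column
``sample_id<TAB>group``; homolog maps follow the headerless Homologene dialect
``group_id<TAB>taxon_id<TAB>gene_id<TAB>gene_symbol``; survival records are
``sample_id<TAB>time_days<TAB>event<TAB>group``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from serrsig.matrix import ExpressionMatrix, SerrsigError

FLOAT_FMT = "%.6g"  # fixed formatting so identical seeds give identical files


def read_expression(expr_path, groups_path) -> ExpressionMatrix:
    """Read an expression TSV plus its sample->group annotation TSV."""
    df = pd.read_csv(expr_path, sep="\t", index_col="gene_id")
    groups = read_sample_groups(groups_path)
    if df.isna().any().any():
        n_bad = int(df.isna().any(axis=1).sum())
        df = df.dropna(axis=0)
        if df.empty:
            raise SerrsigError(f"all rows of {expr_path} had missing values")
        import warnings

        warnings.warn(f"dropped {n_bad} rows with missing values from {expr_path}")
    return ExpressionMatrix(df, groups)


def write_expression(X: ExpressionMatrix, expr_path, groups_path=None) -> None:
    X.values.to_csv(expr_path, sep="\t", index_label="gene_id", float_format=FLOAT_FMT)
    if groups_path is not None:
        write_sample_groups(X.sample_groups, groups_path)


def read_sample_groups(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise SerrsigError(f"{path}: expected columns sample_id and group")
    return df.set_index("sample_id")["group"]


def write_sample_groups(groups: pd.Series, path) -> None:
    groups.rename("group").rename_axis("sample_id").to_frame().to_csv(path, sep="\t")


def read_homolog_map(path) -> pd.DataFrame:
    """Read a headerless Homologene-dialect TSV into a tidy record table."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["group_id", "taxon_id", "gene_id", "gene_symbol"],
        dtype={"group_id": str, "taxon_id": str, "gene_id": str, "gene_symbol": str},
    )
    if df["group_id"].isna().any() or df["gene_id"].isna().any():
        raise SerrsigError(f"{path}: malformed homolog record")
    return df


def write_homolog_map(records: pd.DataFrame, path) -> None:
    records[["group_id", "taxon_id", "gene_id", "gene_symbol"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"sample_id", "time_days", "event", "group"}
    if not need <= set(df.columns):
        raise SerrsigError(f"{path}: expected columns {sorted(need)}")
    if (df["time_days"] <= 0).any():
        raise SerrsigError(f"{path}: nonpositive survival time")
    return df


def write_survival(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_marker_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="case_id")


def write_marker_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="case_id")


def read_gene_list(path) -> list[str]:
    """One gene identifier per line; blank lines ignored."""
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))
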