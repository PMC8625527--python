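"""TSV dialects for the pipeline's inputs and outputs.

All tables are tab-separated with a header row.

* beta matrix — first column ``probe_id``, one column per sample;
  decimal values in [0, 1], empty cell = missing.
* probe annotation — ``probe_id``, ``gene``, ``region``.
* groups — ``sample_id``, ``group`` (``control`` / ``treated``).
* GWAS summary — ``snp``, ``effect_allele``, ``other_allele``,
  ``beta``, ``se``, ``pval`` and optionally ``eaf``, ``trait``.

Readers validate schema and raise ``ValueError`` naming the offending
column or key; writers print floats at full round-trip precision.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .harmonize import GWAS_COLUMNS

__all__ = [
    "read_beta_matrix",
    "read_probe_annotation",
    "read_groups",
    "read_gwas",
    "write_table",
]


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_beta_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name is None or df.shape[1] == 0:
        raise ValueError(f"{path}: expected probe_id column plus sample columns")
    df.index.name = "probe_id"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate probe_id {dup!r}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric beta value ({exc})") from exc
    vals = df.stack(future_stack=True).dropna()
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError(f"{path}: beta values outside [0, 1]")
    return df


def read_probe_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, ["probe_id", "gene", "region"], path)
    return df


def read_groups(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, ["sample_id", "group"], path)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    return df.set_index("sample_id")["group"]


def read_gwas(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, GWAS_COLUMNS, path)
    if df["snp"].duplicated().any():
        dups = sorted(df.loc[df["snp"].duplicated(), "snp"].unique())
        raise ValueError(f"{path}: duplicate rsIDs {dups[:5]}")
    for col in ("beta", "se", "pval"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: column {col!r} is not numeric")
    return df


def write_table(table: pd.DataFrame, path, index: bool = False) -> None:
    """Write a TSV with floats at full round-trip precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=index, float_format="%.17g")
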