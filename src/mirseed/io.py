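"""Shared file I/O: the TSV matrix dialect, GMT gene sets, plate tables, reports.

Canonical matrix dialect: tab-separated, features as rows, first column
``feature_id``, header row of sample ids, missing entries written as ``NA``.
CSV is accepted on read (sniffed by extension).  All writers round-trip
bit-identically through the matching reader.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import CtMatrix, GeneSetCollection

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_ct_tsv",
    "write_ct_tsv",
    "read_meta_tsv",
    "write_meta_tsv",
    "read_gmt",
    "write_gmt",
    "read_de_tsv",
    "write_de_tsv",
    "read_disease_fc_tsv",
]

_NA = "NA"


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"empty or missing matrix file: {path}")
    df = pd.read_csv(path, sep=_sep(path), na_values=[_NA], keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: matrix needs a feature_id column plus >=1 sample")
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dup = df.loc[df[id_col].duplicated(), id_col].iloc[0]
        line = int(df.index[df[id_col] == dup][1]) + 2
        raise ValueError(f"{path}:{line}: duplicate feature id {dup!r}")
    return df.set_index(id_col).astype(float).rename_axis("feature_id")


def write_matrix_tsv(values: pd.DataFrame, path) -> None:
    values.rename_axis("feature_id").to_csv(path, sep="\t", na_rep=_NA)


def read_meta_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep=_sep(path), na_values=[_NA], keep_default_na=False)
    id_col = meta.columns[0]
    if meta[id_col].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in metadata")
    return meta.set_index(id_col).rename_axis("sample_id")


def write_meta_tsv(meta: pd.DataFrame, path) -> None:
    meta.rename_axis("sample_id").to_csv(path, sep="\t", na_rep=_NA)


def read_ct_tsv(matrix_path, meta_path) -> CtMatrix:
    values = read_matrix_tsv(matrix_path)
    meta = read_meta_tsv(meta_path)
    try:
        meta = meta.loc[values.columns].rename_axis("sample_id")
    except KeyError as exc:
        raise ValueError(f"metadata does not cover all samples in {matrix_path}") from exc
    return CtMatrix(values, meta)


def write_ct_tsv(m: CtMatrix, matrix_path, meta_path) -> None:
    write_matrix_tsv(m.values, matrix_path)
    write_meta_tsv(m.sample_meta, meta_path)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name <tab> description <tab> members...).

    The universe is the union of all members; a description field of the form
    ``provenance=<tag>`` sets the set's provenance.
    """
    sets: dict[str, set] = {}
    provenance: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, members")
            name, desc, members = parts[0], parts[1], [g for g in parts[2:] if g]
            if not members:
                raise ValueError(f"{path}:{lineno}: empty gene set {name!r}")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(members)
            if desc.startswith("provenance="):
                provenance[name] = desc.split("=", 1)[1]
    universe = set().union(*sets.values())
    return GeneSetCollection(universe, sets, provenance)


def write_gmt(dbs: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in dbs.sets.items():
            desc = f"provenance={dbs.provenance[name]}" if name in dbs.provenance else "na"
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_de_tsv(path) -> pd.DataFrame:
    """Read a DE table; accepts this package's dialect and DESeq2-style exports.

    Recognized gene columns: ``feature_id`` / ``gene`` / unnamed first column;
    fold-change columns: ``log2fc`` / ``log2FoldChange`` / ``fc_linear`` /
    ``effect``; adjusted p: ``p_adj`` / ``padj``.
    """
    df = pd.read_csv(path, sep=_sep(path), na_values=[_NA], keep_default_na=False)
    rename = {"log2FoldChange": "log2fc", "padj": "p_adj", "gene": "feature_id", "pvalue": "p_raw"}
    df = df.rename(columns=rename)
    if "feature_id" not in df:
        df = df.rename(columns={df.columns[0]: "feature_id"})
    if "p_adj" not in df:
        raise ValueError(f"{path}: DE table lacks an adjusted-p column (p_adj/padj)")
    if not any(c in df for c in ("log2fc", "fc_linear", "effect")):
        raise ValueError(f"{path}: DE table lacks a fold-change column")
    return df


def write_de_tsv(de: pd.DataFrame, path) -> None:
    lead = [c for c in ("feature_id", "effect", "fc_linear", "t", "df", "p_raw", "p_adj", "direction") if c in de]
    rest = [c for c in de.columns if c not in lead]
    de[lead + rest].to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_disease_fc_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path))
    needed = {"gene", "study", "fc_signed"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: disease FC table needs columns {sorted(needed)}")
    if df["fc_signed"].abs().lt(1).any():
        raise ValueError(f"{path}: signed FC convention violated (|FC| must be >= 1)")
    return df
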