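"""Typed table input/output.

All tables are TSV (UTF-8, dot decimal), samples in rows, with the metadata
columns ``sample_id, treatment, time_h, bio_rep, tech_rep`` first and feature
columns after.  VOC tables carry a sidecar annotation file
(``compound_id, chemical_class``).  Trees are standard newick with branch
lengths.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from skbio import TreeNode

from .config import META_COLS, QPI_TARGETS
from .volatilome import VOCTable

__all__ = [
    "read_table",
    "write_table",
    "read_qpcr_table",
    "read_voc_table",
    "write_voc_table",
    "read_tree",
]


def _check_schema(df: pd.DataFrame, path: Path, feature_kind: str) -> None:
    for col in META_COLS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicated sample ids: {sorted(set(dup))}")
    features = [c for c in df.columns if c not in META_COLS]
    for col in features:
        if df[col].dtype == object:
            sample = df[col].astype(str)
            if sample.str.contains(",").any():
                raise ValueError(
                    f"{path}: column {col!r} contains comma decimals; "
                    "re-export the file with dot-decimal (C locale) formatting"
                )
            raise ValueError(f"{path}: non-numeric values in {feature_kind} column {col!r}")


def read_table(path: str | Path, feature_kind: str = "feature") -> pd.DataFrame:
    """Read a samples-by-features TSV with leading metadata columns."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _check_schema(df, path, feature_kind)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    meta = [c for c in META_COLS if c in df.columns]
    rest = [c for c in df.columns if c not in meta]
    df[meta + rest].to_csv(path, sep="\t", index=False)
    return path


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR quantification table; the five index targets are mandatory."""
    df = read_table(path, feature_kind="qPCR target")
    missing = set(QPI_TARGETS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing qPCR target columns: {sorted(missing)}")
    return df


def read_voc_table(path: str | Path, classes_path: str | Path) -> VOCTable:
    """Read a VOC table plus its compound-annotation sidecar."""
    df = read_table(path, feature_kind="compound")
    ann = pd.read_csv(classes_path, sep="\t")
    for col in ("compound_id", "chemical_class"):
        if col not in ann.columns:
            raise ValueError(f"{classes_path}: missing required column {col!r}")
    classes = dict(zip(ann["compound_id"], ann["chemical_class"]))
    return VOCTable(data=df, classes=classes, provenance="raw")


def write_voc_table(table: VOCTable, path: str | Path, classes_path: str | Path) -> None:
    write_table(table.data, path)
    ann = pd.DataFrame(
        {"compound_id": table.compounds,
         "chemical_class": [table.classes[c] for c in table.compounds]}
    )
    ann.to_csv(classes_path, sep="\t", index=False)


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted newick tree; every branch must carry a length."""
    tree = TreeNode.read(str(path))
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(
                f"{path}: branch without a length (node {node.name!r}); "
                "UniFrac requires branch lengths on every edge"
            )
    return tree
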