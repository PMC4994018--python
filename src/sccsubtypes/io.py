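"""Readers and writers for the delimited-text formats used throughout.

Expression matrices and drug panels are TSV with features (or compounds) as
rows, a header row of sample ids and the feature id in the first column.
Cluster assignments are two-column TSV (sample, cluster).  Gene sets use GMT
(set name TAB description TAB gene ids).  TFBS annotations are two-column
TSV (mir_id, tf_id).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature-by-sample TSV matrix and validate its invariants."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    validate_matrix(df)
    return df


def validate_matrix(df: pd.DataFrame) -> None:
    if df.index.has_duplicates:
        raise ValueError("duplicate feature ids")
    if df.columns.has_duplicates:
        raise ValueError("duplicate sample ids")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("matrix must be numeric")
    if not np.isfinite(values).all():
        raise ValueError("matrix contains NaN or Inf")


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label=df.index.name or "feature",
              float_format="%.6g")


def read_labels(path: str | Path) -> pd.Series:
    """Two-column TSV (sample, cluster) -> sample-indexed int Series."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    s = pd.Series(df.iloc[:, 1].astype(int).to_numpy(),
                  index=df.iloc[:, 0], name="cluster")
    if s.index.has_duplicates:
        raise ValueError("duplicate sample ids in labels")
    return s


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("cluster").to_frame().to_csv(path, sep="\t",
                                               index_label="sample")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT reader: set name, description, then gene ids, tab-separated."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, genes = parts[0], [g for g in parts[2:] if g]
        if name in sets:
            raise ValueError(f"duplicate set name {name!r}")
        if not genes:
            raise ValueError(f"empty gene set {name!r}")
        sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for name, genes in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_tfbs(path: str | Path) -> dict[str, set[str]]:
    """TFBS TSV (mir_id, tf_id per line) -> miR -> set of TFs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("TFBS annotation needs mir_id and tf_id columns")
    out: dict[str, set[str]] = {}
    for mir, tf in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(mir, set()).add(tf)
    return out


def read_gene_list(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
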