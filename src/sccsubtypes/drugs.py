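"""Compound sensitivity scoring over clustered cell-line panels.

The score for compound c in cluster g is

    score(c, g) = mean(-log10 GI50 over cluster-g lines)
                - mean(-log10 GI50 over the whole panel)

computed over non-missing entries (pairwise deletion).  Positive scores mean
the cluster is more sensitive than the panel as a whole, negative more
resistant.  With complete data the cluster-size-weighted scores of a compound
sum to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SensitivityScoreTable", "sensitivity_score", "rank_compounds_per_cluster"]


@dataclass
class SensitivityScoreTable:
    score: pd.DataFrame    # compounds x clusters; NaN = undefined
    n_cells: pd.DataFrame  # non-missing count per (compound, cluster)


def sensitivity_score(D: pd.DataFrame, labels: pd.Series,
                      min_cells: int = 2) -> SensitivityScoreTable:
    """Cluster-mean minus panel-mean -log GI50 per compound.

    Entries backed by fewer than ``min_cells`` non-missing measurements are
    reported as NaN (undefined), never silently zero.
    """
    unlabeled = [c for c in D.columns if c not in labels.index]
    if unlabeled:
        raise ValueError(f"unlabeled cell line(s): {unlabeled[:5]}")
    if D.isna().all(axis=1).any():
        bad = D.index[D.isna().all(axis=1)].tolist()
        raise ValueError(f"compound(s) with no measurements: {bad[:5]}")
    lab = labels.reindex(D.columns)
    clusters = sorted(int(c) for c in lab.unique())
    panel_mean = D.mean(axis=1, skipna=True)
    score, n_cells = {}, {}
    for g in clusters:
        sub = D.loc[:, (lab == g).to_numpy()]
        n = sub.notna().sum(axis=1)
        s = sub.mean(axis=1, skipna=True) - panel_mean
        s[n < min_cells] = np.nan
        score[g], n_cells[g] = s, n
    return SensitivityScoreTable(score=pd.DataFrame(score),
                                 n_cells=pd.DataFrame(n_cells))


def rank_compounds_per_cluster(S: SensitivityScoreTable,
                               top_m: int | None = None) -> pd.DataFrame:
    """Per-cluster compound ranking by descending score.

    Undefined (NaN) entries are excluded; ties break lexicographically by
    compound id.  Returns a long table (cluster, rank, compound, score).
    """
    if S.score.notna().to_numpy().sum() == 0:
        raise ValueError("no defined scores to rank")
    rows = []
    for g in S.score.columns:
        col = S.score[g].dropna()
        col = col.iloc[np.lexsort((col.index.to_numpy(), -col.to_numpy()))]
        if top_m is not None:
            col = col.iloc[:top_m]
        rows += [(int(g), r + 1, cmpd, float(v))
                 for r, (cmpd, v) in enumerate(col.items())]
    return pd.DataFrame(rows, columns=["cluster", "rank", "compound", "score"])
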