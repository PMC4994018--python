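"""Project a second cohort onto discovered subtypes via signature genes.

Mirrors the study design where subtypes found in a large tumor cohort are
carried over to a small cell-line panel: the new cohort is restricted to the
metagene signature genes, z-scored per gene within the cohort (to absorb
platform offsets between, e.g., arrays and RNA-seq), hierarchically clustered
with correlation distance and average linkage, cut into k groups, and each
group is mapped to the reference metagene whose signature centroid it
correlates with best, greedily and injectively.  A nearest-centroid assigner
provides an independent cross-check of the hierarchical route.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

__all__ = [
    "ProjectionResult",
    "compute_reference_centroids",
    "project_by_hierarchical_clustering",
    "nearest_centroid_assign",
]


@dataclass
class ProjectionResult:
    assignment: pd.Series            # new-cohort sample -> reference metagene
    mapping: dict[int, int]          # tree group -> reference metagene
    centroid_correlations: pd.DataFrame  # groups x metagenes


def _zscore_rows(X: pd.DataFrame) -> pd.DataFrame:
    mu = X.mean(axis=1)
    sd = X.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant gene(s) before z-scoring")
        X, mu, sd = X.loc[keep], mu[keep], sd[keep]
    return X.sub(mu, axis=0).div(sd, axis=0)


def _restrict_to_signature(X: pd.DataFrame, signature_genes: list[str]) -> pd.DataFrame:
    present = [g for g in signature_genes if g in X.index]
    missing = len(signature_genes) - len(present)
    if missing:
        warnings.warn(f"{missing} signature gene(s) absent from the new cohort; dropped")
    if len(present) < 2:
        raise ValueError("fewer than 2 shared signature genes")
    return X.loc[present]


def compute_reference_centroids(X_ref: pd.DataFrame, labels: pd.Series,
                                signature: pd.DataFrame) -> pd.DataFrame:
    """Per-metagene mean z-scored profile of the reference cohort over
    signature genes.  ``signature`` is the feature table from
    :func:`sccsubtypes.nmf.extract_metagene_features`; metagene columns are
    keyed by its 1-based indices."""
    genes = signature["feature_id"].tolist()
    Xs = _zscore_rows(_restrict_to_signature(X_ref, genes))
    cents = {}
    for mg in sorted(signature["metagene"].unique()):
        samples = [s for s in labels[labels == mg].index if s in Xs.columns]
        if not samples:
            raise ValueError(f"metagene {mg} has no reference samples")
        cents[int(mg)] = Xs[samples].mean(axis=1)
    return pd.DataFrame(cents)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        raise ValueError("undefined correlation: constant vector")
    return float(np.corrcoef(a, b)[0, 1])


def _greedy_injective_map(corr: pd.DataFrame) -> dict[int, int]:
    """Map each row (group) to a distinct column (metagene), taking the
    globally best remaining correlation each time."""
    corr = corr.copy()
    mapping: dict[int, int] = {}
    while not corr.empty and corr.shape[1] > 0:
        idx = np.unravel_index(np.nanargmax(corr.to_numpy()), corr.shape)
        g, m = corr.index[idx[0]], corr.columns[idx[1]]
        mapping[int(g)] = int(m)
        corr = corr.drop(index=g, columns=m)
    return mapping


def project_by_hierarchical_clustering(
    X_new: pd.DataFrame, signature: pd.DataFrame,
    reference_centroids: pd.DataFrame, k: int,
) -> ProjectionResult:
    """Hierarchical assignment of a new cohort to reference metagenes.

    Groups may be as small as a single sample; no minimum size is enforced
    (a 15/7/2 split across 24 lines is a legitimate outcome).
    """
    if X_new.shape[1] < k:
        raise ValueError(f"need at least k={k} samples, got {X_new.shape[1]}")
    genes = signature["feature_id"].tolist()
    Xs = _zscore_rows(_restrict_to_signature(X_new, genes))
    V = Xs.to_numpy()
    R = np.corrcoef(V.T)
    D = np.clip(1.0 - R, 0.0, None)
    np.fill_diagonal(D, 0.0)
    Z = average(squareform(D, checks=False))
    groups = fcluster(Z, t=k, criterion="maxclust")

    shared = [g for g in reference_centroids.index if g in Xs.index]
    if len(shared) < 2:
        raise ValueError("fewer than 2 genes shared with reference centroids")
    corr = {}
    for g in np.unique(groups):
        gc = Xs.loc[shared].to_numpy()[:, groups == g].mean(axis=1)
        corr[int(g)] = {
            int(m): _corr(gc, reference_centroids.loc[shared, m].to_numpy())
            for m in reference_centroids.columns
        }
    corr_df = pd.DataFrame(corr).T.sort_index()
    mapping = _greedy_injective_map(corr_df)
    assignment = pd.Series([mapping[int(g)] for g in groups],
                           index=X_new.columns, name="cluster")
    return ProjectionResult(assignment=assignment, mapping=mapping,
                            centroid_correlations=corr_df)


def nearest_centroid_assign(X_new: pd.DataFrame, signature: pd.DataFrame,
                            reference_centroids: pd.DataFrame) -> pd.Series:
    """Per-sample assignment to the best-correlated metagene centroid over
    shared signature genes; ties to the smallest metagene index.

    Works on raw per-sample profiles: Pearson correlation is invariant to
    each sample's own offset and scale, so no per-gene z-scoring is applied
    (unlike the hierarchical route, whose across-sample distances need it).
    """
    genes = signature["feature_id"].tolist()
    Xs = _restrict_to_signature(X_new, genes)
    shared = [g for g in reference_centroids.index if g in Xs.index]
    if len(shared) < 2:
        raise ValueError("fewer than 2 genes shared with reference centroids")
    cents = reference_centroids.loc[shared]
    cols = sorted(int(m) for m in cents.columns)
    out = {}
    for s in Xs.columns:
        v = Xs.loc[shared, s].to_numpy()
        cors = [_corr(v, cents[m].to_numpy()) for m in cols]
        out[s] = cols[int(np.argmax(cors))]
    return pd.Series(out, name="cluster")
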