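"""Per-feature one-way ANOVA across clusters, BH-FDR, cluster-vs-rest fold
changes and cross-cohort signature intersection.

The same fixed-effects ANOVA applies unchanged to log2 expression matrices
(mRNA or miRNA) and to methylation beta-value matrices.  Fold changes are
ratios of geometric means: 2 raised to the difference between the cluster's
mean log2 level and the mean over all other samples, so FC > 1 reads
"up in this cluster".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "anova_per_feature",
    "bh_fdr",
    "cluster_vs_rest_fold_change",
    "diff_expr_table",
    "cross_cohort_signature",
]


def _check_groups(labels: pd.Series) -> list[int]:
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 clusters")
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"cluster(s) with < 2 samples: {small.index.tolist()}")
    return sorted(int(c) for c in counts.index)


def anova_per_feature(X: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Vectorized one-way fixed-effects ANOVA per feature.

    F = [SSB/(g-1)] / [SSW/(n-g)] with p from the upper F tail.  Degenerate
    rows follow the conventions: SSW = 0 with SSB > 0 gives F = inf, p = 0;
    SSB = 0 gives F = 0, p = 1 (a constant feature is not an error).
    """
    labels = labels.reindex(X.columns)
    if labels.isna().any():
        raise ValueError("every sample must be labeled")
    clusters = _check_groups(labels)
    V = X.to_numpy(dtype=float)
    n = V.shape[1]
    g = len(clusters)
    grand = V.mean(axis=1)
    ssb = np.zeros(V.shape[0])
    ssw = np.zeros(V.shape[0])
    lab = labels.to_numpy()
    for c in clusters:
        sub = V[:, lab == c]
        m = sub.mean(axis=1)
        ssb += sub.shape[1] * (m - grand) ** 2
        ssw += ((sub - m[:, None]) ** 2).sum(axis=1)
    scale = np.maximum((V ** 2).mean(axis=1), 1.0)
    tol = 1e-12 * scale
    F = np.full(V.shape[0], np.nan)
    p = np.full(V.shape[0], np.nan)
    zero_b = ssb <= tol
    zero_w = ssw <= tol
    ok = ~zero_b & ~zero_w
    F[ok] = (ssb[ok] / (g - 1)) / (ssw[ok] / (n - g))
    p[ok] = stats.f.sf(F[ok], g - 1, n - g)
    F[zero_b] = 0.0
    p[zero_b] = 1.0
    sing = ~zero_b & zero_w
    F[sing] = np.inf
    p[sing] = 0.0
    return pd.DataFrame({"F": F, "p": p}, index=X.index)


def bh_fdr(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def cluster_vs_rest_fold_change(X: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Linear-scale fold change of each cluster versus all other samples."""
    labels = labels.reindex(X.columns)
    if labels.isna().any():
        raise ValueError("every sample must be labeled")
    clusters = sorted(int(c) for c in labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters (empty rest-group otherwise)")
    V = X.to_numpy(dtype=float)
    lab = labels.to_numpy()
    out = {}
    for c in clusters:
        inside = V[:, lab == c].mean(axis=1)
        outside = V[:, lab != c].mean(axis=1)
        out[f"FC_{c}"] = 2.0 ** (inside - outside)
    return pd.DataFrame(out, index=X.index)


def diff_expr_table(X: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """ANOVA + BH-FDR + per-cluster fold changes in one table."""
    res = anova_per_feature(X, labels)
    res["q"] = bh_fdr(res["p"])
    fc = cluster_vs_rest_fold_change(X, labels)
    return pd.concat([res, fc], axis=1)


def cross_cohort_signature(resA: pd.DataFrame, resB: pd.DataFrame,
                           alpha: float = 0.05,
                           aliases: dict[str, str] | None = None) -> pd.DataFrame:
    """Features significant (p < alpha) in both cohorts, with per-cluster
    direction concordance.

    ``aliases`` maps cohort-specific feature ids onto a shared namespace
    (e.g. two genomic loci of one mature miR); when several rows collapse
    onto one id the row with the smallest p represents it.  Output carries
    both cohorts' p and FC columns plus, per cluster, a direction field:
    'up' (FC > 1 in both), 'down' (FC < 1 in both) or 'discordant'.
    """
    def _collapse(res: pd.DataFrame) -> pd.DataFrame:
        res = res.copy()
        ids = res.index.to_series().map(lambda i: (aliases or {}).get(i, i))
        res.index = pd.Index(ids, name="feature")
        return res.sort_values("p", kind="mergesort").groupby(level=0).first()

    A, B = _collapse(resA), _collapse(resB)
    shared = A.index.intersection(B.index)
    if shared.empty:
        raise ValueError("cohorts share no feature ids")
    sig = shared[(A.loc[shared, "p"] < alpha) & (B.loc[shared, "p"] < alpha)]
    fc_cols = [c for c in A.columns if c.startswith("FC_") and c in B.columns]
    out = pd.DataFrame(index=sig)
    out["p_a"] = A.loc[sig, "p"]
    out["p_b"] = B.loc[sig, "p"]
    for c in fc_cols:
        fa, fb = A.loc[sig, c], B.loc[sig, c]
        out[f"{c}_a"], out[f"{c}_b"] = fa, fb
        direction = np.where((fa > 1) & (fb > 1), "up",
                             np.where((fa < 1) & (fb < 1), "down", "discordant"))
        out[f"direction_{c.removeprefix('FC_')}"] = direction
    return out.sort_index()
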