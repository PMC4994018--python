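"""Regulatory inference: TF master lists, cross-cohort TF candidates, and
inverse-correlation microRNA target screening.

Reproduces the Venn-style logic that nominated a single transcription factor
per subtype: the "master list" is the union of TFs predicted to bind the
promoters of differentially expressed miRs; a TF is called upregulated in a
cluster only if its mean is higher and a two-sided Welch t-test rejects at
alpha versus every other cluster separately; candidates are the intersection
of the master list with the upregulated sets of two independent cohorts.
Candidate targets of a miR are screened by simple OLS of each gene on the miR
(inverse regulation = negative slope) and filtered by cluster-vs-rest fold
change direction in both cohorts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compile_master_list",
    "upregulated_tfs",
    "passing_tfs",
    "intersect_tf_candidates",
    "inverse_correlation_screen",
    "filter_candidate_targets",
]

logger = logging.getLogger(__name__)


def compile_master_list(annotation: dict[str, set[str]],
                        diff_mirs: list[str]) -> set[str]:
    """Union of TFs annotated to the promoters of the given miRs.

    miRs absent from the annotation are skipped with a logged warning; if
    every miR is unannotated the list is undefined and an error is raised.
    """
    if not diff_mirs:
        raise ValueError("diff_mirs must be nonempty")
    missing = [m for m in diff_mirs if m not in annotation]
    if missing:
        logger.warning("%d miR(s) missing from the TFBS annotation: %s",
                       len(missing), missing[:5])
    if len(missing) == len(diff_mirs):
        raise ValueError("no provided miR is present in the annotation")
    out: set[str] = set()
    for m in diff_mirs:
        out |= set(annotation.get(m, ()))
    return out


def upregulated_tfs(X: pd.DataFrame, labels: pd.Series, cluster_k: int,
                    tf_ids: list[str], alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Welch tests of each TF in ``cluster_k`` vs every other cluster.

    Returns a long table (tf, other_cluster, mean_diff, t, p, passes); a TF
    is upregulated iff it passes against every other cluster.  Use
    :func:`passing_tfs` for the final set.  Missing TF ids are reported and
    skipped.
    """
    labels = labels.reindex(X.columns)
    if labels.isna().any():
        raise ValueError("every sample must be labeled")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("every cluster needs >= 2 samples")
    clusters = sorted(int(c) for c in counts.index)
    if cluster_k not in clusters:
        raise ValueError(f"cluster {cluster_k} not present in labels")
    present = [t for t in tf_ids if t in X.index]
    missing = sorted(set(tf_ids) - set(present))
    if missing:
        logger.warning("%d TF id(s) not in the expression matrix: %s",
                       len(missing), missing[:5])
    lab = labels.to_numpy()
    rows = []
    for tf in present:
        x = X.loc[tf].to_numpy(dtype=float)
        a = x[lab == cluster_k]
        for other in clusters:
            if other == cluster_k:
                continue
            b = x[lab == other]
            t, p = stats.ttest_ind(a, b, equal_var=False)
            diff = float(a.mean() - b.mean())
            rows.append((tf, other, diff, float(t), float(p),
                         bool(diff > 0 and p < alpha)))
    return pd.DataFrame(rows, columns=["tf", "other_cluster", "mean_diff",
                                       "t", "p", "passes"])


def passing_tfs(pairwise: pd.DataFrame) -> set[str]:
    """TFs that pass against every other cluster."""
    if pairwise.empty:
        return set()
    ok = pairwise.groupby("tf")["passes"].all()
    return set(ok.index[ok])


def intersect_tf_candidates(master: set[str], upA: set[str],
                            upB: set[str]) -> list[str]:
    """Master list intersected with both cohorts' upregulated TFs, sorted."""
    return sorted(set(master) & set(upA) & set(upB))


def inverse_correlation_screen(mir_vector: pd.Series, X: pd.DataFrame,
                               gene_ids: list[str] | None = None) -> pd.DataFrame:
    """OLS of each candidate gene (response) on the miR (predictor).

    Reports slope, intercept, R^2, the two-sided t-test p for the slope and
    an ``inverse`` flag (slope < 0).  Genes are ranked by p among
    negative-slope genes first, then non-negative slopes by p.  Constant gene
    vectors get R^2 = 0, p = 1.
    """
    x = mir_vector.to_numpy(dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 samples")
    if np.ptp(x) == 0:
        raise ValueError("constant miR vector")
    genes = list(X.index) if gene_ids is None else \
        [g for g in gene_ids if g in X.index]
    missing = [] if gene_ids is None else sorted(set(gene_ids) - set(genes))
    if missing:
        logger.warning("%d candidate gene(s) not in the matrix: %s",
                       len(missing), missing[:5])
    Y = X.loc[genes, mir_vector.index].to_numpy(dtype=float)
    xc = x - x.mean()
    sxx = float((xc ** 2).sum())
    yc = Y - Y.mean(axis=1, keepdims=True)
    sxy = yc @ xc
    syy = (yc ** 2).sum(axis=1)
    slope = sxy / sxx
    intercept = Y.mean(axis=1) - slope * x.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(syy > 0, (sxy ** 2) / (sxx * syy), 0.0)
        resid = np.maximum(syy - slope * sxy, 0.0)
        se = np.sqrt(resid / (n - 2) / sxx)
        t = np.where(se > 0, slope / se, np.inf * np.sign(slope))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(syy > 0, p, 1.0)
    r2 = np.clip(r2, 0.0, 1.0)
    df = pd.DataFrame({"slope": slope, "intercept": intercept, "r2": r2,
                       "p": p, "inverse": slope < 0},
                      index=pd.Index(genes, name="gene"))
    order = np.lexsort((df.index.to_numpy(), df["p"].to_numpy(),
                        (~df["inverse"]).to_numpy()))
    df = df.iloc[order]
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def filter_candidate_targets(predicted_targets: list[str],
                             diffA: pd.DataFrame, diffB: pd.DataFrame,
                             mir_high_cluster: int,
                             mir_low_cluster: int) -> list[str]:
    """Keep genes repressed where the miR is high and elevated where it is low.

    A gene passes iff FC < 1 in the miR-high cluster and FC > 1 in the
    miR-low cluster, in both cohorts' differential tables.  Genes missing
    from either table are reported and skipped.
    """
    hi, lo = f"FC_{mir_high_cluster}", f"FC_{mir_low_cluster}"
    for name, df in (("A", diffA), ("B", diffB)):
        for col in (hi, lo):
            if col not in df.columns:
                raise KeyError(f"cohort {name} table lacks column {col}")
    kept = []
    missing = []
    for g in predicted_targets:
        if g not in diffA.index or g not in diffB.index:
            missing.append(g)
            continue
        if (diffA.loc[g, hi] < 1 and diffA.loc[g, lo] > 1
                and diffB.loc[g, hi] < 1 and diffB.loc[g, lo] > 1):
            kept.append(g)
    if missing:
        logger.warning("%d predicted target(s) missing from the tables: %s",
                       len(missing), missing[:5])
    return kept
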