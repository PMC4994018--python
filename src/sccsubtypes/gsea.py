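"""Weighted Kolmogorov-Smirnov gene-set enrichment with sample-label
permutation.

Genes are ranked by a signal-to-noise contrast of one cluster versus the rest
(group sds floored GSEA-style); the enrichment score of a set is the signed
extremum of the running sum that adds |r|^p / sum(|r|^p over the set) at set
members and subtracts 1/(N - |S|) elsewhere.  Significance comes from
re-ranking under sample-label permutations: nominal p is the +1-smoothed
same-signed tail fraction, NES divides the observed ES by the mean magnitude
of same-signed permuted ES, and the FDR q is the standard ratio of permuted
to observed NES tail fractions, per sign.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["snr_rank_genes", "enrichment_score", "gsea_permutation_test"]


def _snr_scores(V: np.ndarray, in_cluster: np.ndarray) -> np.ndarray:
    a, b = V[:, in_cluster], V[:, ~in_cluster]
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    sd_a, sd_b = a.std(axis=1, ddof=1), b.std(axis=1, ddof=1)
    sd_a = np.maximum(sd_a, np.maximum(0.2 * np.abs(mu_a), 0.2))
    sd_b = np.maximum(sd_b, np.maximum(0.2 * np.abs(mu_b), 0.2))
    return (mu_a - mu_b) / (sd_a + sd_b)


def snr_rank_genes(X: pd.DataFrame, labels: pd.Series,
                   cluster_k: int) -> pd.Series:
    """Signal-to-noise ranking of genes for cluster ``cluster_k`` vs rest.

    Each group sd is floored at max(0.2*|group mean|, 0.2).  Returns a Series
    of scores indexed by gene, sorted descending with ties broken by gene id.
    """
    labels = labels.reindex(X.columns)
    if labels.isna().any():
        raise ValueError("every sample must be labeled")
    in_cluster = (labels == cluster_k).to_numpy()
    if in_cluster.sum() < 3 or (~in_cluster).sum() < 3:
        raise ValueError("cluster and rest each need >= 3 samples")
    r = _snr_scores(X.to_numpy(dtype=float), in_cluster)
    s = pd.Series(r, index=X.index, name="snr")
    order = np.lexsort((s.index.to_numpy(), -s.to_numpy()))
    return s.iloc[order]


def _running_es(scores: np.ndarray, hit: np.ndarray, weight: float) -> float:
    nh = int(hit.sum())
    N = scores.size
    w = np.abs(scores) ** weight
    denom = w[hit].sum()
    inc = np.where(hit, w / denom if denom > 0 else 1.0 / nh,
                   -1.0 / (N - nh))
    running = np.cumsum(inc)
    # the running sum is mathematically within [-1, 1]; clip float drift
    return float(np.clip(running[np.argmax(np.abs(running))], -1.0, 1.0))


def enrichment_score(ranked: pd.Series, gene_set: set[str] | list[str],
                     weight: float = 1.0) -> float:
    """ES of a gene set against a ranked (descending) score list.

    The set must be a non-empty proper subset of the ranked genes after
    restriction to measured genes.
    """
    members = set(gene_set) & set(ranked.index)
    if not members:
        raise ValueError("gene set has no measured genes")
    if len(members) == ranked.size:
        raise ValueError("gene set covers every ranked gene")
    hit = ranked.index.isin(members)
    return _running_es(ranked.to_numpy(dtype=float), hit, weight)


def _rank_and_es(V: np.ndarray, gene_ids: np.ndarray, in_cluster: np.ndarray,
                 hit_masks: list[np.ndarray], weight: float,
                 tie_order: np.ndarray) -> np.ndarray:
    r = _snr_scores(V, in_cluster)
    order = np.lexsort((tie_order, -r))
    rs = r[order]
    out = np.empty(len(hit_masks))
    for j, mask in enumerate(hit_masks):
        out[j] = _running_es(rs, mask[order], weight)
    return out


def gsea_permutation_test(X: pd.DataFrame, labels: pd.Series, cluster_k: int,
                          sets: dict[str, list[str]], n_perm: int = 1000,
                          seed: int = 0, weight: float = 1.0) -> pd.DataFrame:
    """Label-permutation GSEA for one cluster-vs-rest contrast.

    Returns one row per usable set: restricted size, ES, NES, nominal p
    (+1-smoothed, same-signed permutations only) and FDR q (tail-ratio of
    pooled permuted NES to observed NES, per sign).  Sets with no measured
    genes, or covering all genes, are skipped with a warning.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels = labels.reindex(X.columns)
    if labels.isna().any():
        raise ValueError("every sample must be labeled")
    in_cluster = (labels == cluster_k).to_numpy()
    if in_cluster.sum() < 3 or (~in_cluster).sum() < 3:
        raise ValueError("cluster and rest each need >= 3 samples")

    gene_ids = X.index.to_numpy()
    tie_order = np.argsort(np.argsort(gene_ids))  # lexicographic tie-break key
    usable, masks = [], []
    for name, genes in sets.items():
        mask = X.index.isin(set(genes))
        if mask.sum() == 0 or mask.all():
            warnings.warn(f"skipping unusable gene set {name!r}")
            continue
        usable.append(name)
        masks.append(mask)
    if not usable:
        raise ValueError("no usable gene sets")

    V = X.to_numpy(dtype=float)
    es_obs = _rank_and_es(V, gene_ids, in_cluster, masks, weight, tie_order)

    rng = np.random.default_rng(int(seed) % 2**31)
    es_perm = np.empty((n_perm, len(usable)))
    for b in range(n_perm):
        perm = rng.permutation(in_cluster)
        es_perm[b] = _rank_and_es(V, gene_ids, perm, masks, weight, tie_order)

    p = np.empty(len(usable))
    nes_obs = np.empty(len(usable))
    nes_perm = np.full_like(es_perm, np.nan)
    for j, es in enumerate(es_obs):
        same = es_perm[:, j] >= 0 if es >= 0 else es_perm[:, j] < 0
        n_same = int(same.sum())
        extreme = int((np.abs(es_perm[same, j]) >= abs(es)).sum())
        p[j] = (1 + extreme) / (1 + n_same)
        mean_same = np.abs(es_perm[same, j]).mean() if n_same else np.nan
        nes_obs[j] = es / mean_same if mean_same and mean_same > 0 else np.nan
        pos = es_perm[:, j] >= 0
        mp = np.abs(es_perm[pos, j]).mean() if pos.any() else np.nan
        mn = np.abs(es_perm[~pos, j]).mean() if (~pos).any() else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            nes_perm[pos, j] = es_perm[pos, j] / mp
            nes_perm[~pos, j] = es_perm[~pos, j] / mn

    q = _fdr_tail_ratio(nes_obs, nes_perm)
    return pd.DataFrame({
        "set": usable,
        "size": [int(m.sum()) for m in masks],
        "ES": es_obs, "NES": nes_obs, "p": p, "q": q,
    }).set_index("set")


def _fdr_tail_ratio(nes_obs: np.ndarray, nes_perm: np.ndarray) -> np.ndarray:
    """Subramanian-style FDR: permuted vs observed NES tail fractions."""
    pool = nes_perm[np.isfinite(nes_perm)]
    obs = nes_obs[np.isfinite(nes_obs)]
    q = np.full(nes_obs.shape, np.nan)
    for j, nes in enumerate(nes_obs):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            denom_pool = (pool >= 0).sum()
            num = (pool >= nes).sum() / denom_pool if denom_pool else np.nan
            dobs = (obs >= 0).sum()
            den = (obs >= nes).sum() / dobs if dobs else np.nan
        else:
            denom_pool = (pool < 0).sum()
            num = (pool <= nes).sum() / denom_pool if denom_pool else np.nan
            dobs = (obs < 0).sum()
            den = (obs <= nes).sum() / dobs if dobs else np.nan
        if den and np.isfinite(num):
            q[j] = min(1.0, num / den)
    return q
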