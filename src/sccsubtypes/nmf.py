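"""Consensus non-negative matrix factorization with cophenetic rank selection.

The subtype-discovery engine: the expression matrix V (features x samples,
log2 scale, low-expression rows removed and rows min-shifted to be
non-negative) is factorized as V ~ W H under the Kullback-Leibler objective

    D(V || WH) = sum_ij [ v_ij log(v_ij / (WH)_ij) - v_ij + (WH)_ij ]

with Brunet's multiplicative updates.  Many random restarts are summarized in
a sample-by-sample consensus matrix (co-clustering frequency of argmax-H
assignments); the stability of a rank k is measured by the cophenetic
correlation between consensus-derived distances and the ultrametric distances
of their average-linkage dendrogram.  Ranks are surveyed against a
row-permuted null of the same matrix to guard against reading structure into
noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

__all__ = [
    "FactorPair",
    "ConsensusResult",
    "RankSurvey",
    "filter_low_expression",
    "shift_nonnegative",
    "kl_divergence",
    "nmf_brunet",
    "consensus_cluster",
    "cophenetic_correlation",
    "rank_survey_with_null",
    "select_rank",
    "extract_metagene_features",
    "assign_samples_from_H",
    "DEFAULT_RANK_MARGIN",
]

_EPS = np.finfo(np.float64).tiny


@dataclass
class FactorPair:
    """One NMF solution: nonnegative basis W (features x k) and
    coefficients H (k x samples), with its final KL divergence."""

    W: np.ndarray
    H: np.ndarray
    divergence: float
    n_iter: int


@dataclass
class ConsensusResult:
    C: pd.DataFrame              # sample x sample co-clustering frequency
    rank: int
    n_runs: int
    cophenetic: float
    assignment: pd.Series        # sample -> label in 1..rank
    best_run: FactorPair | None = None


@dataclass
class RankSurvey:
    ranks: list[int]
    rho_real: list[float]
    rho_null: list[float]


def filter_low_expression(X: pd.DataFrame) -> pd.DataFrame:
    """Drop features expressed below log2 = 0 in every sample.

    A feature survives iff at least one sample has value >= 0 (exactly 0
    counts as expressed).  Feature order is preserved.
    """
    keep = (X.to_numpy() >= 0).any(axis=1)
    if not keep.any():
        raise ValueError("empty-after-filter: no feature has any value >= 0")
    return X.loc[keep]


def shift_nonnegative(X: pd.DataFrame) -> pd.DataFrame:
    """Min-shift rows containing negatives so every entry is >= 0.

    Per-feature shift preserves within-feature contrasts across samples,
    which is what the factorization clusters on.
    """
    V = X.to_numpy(dtype=float).copy()
    row_min = V.min(axis=1)
    neg = row_min < 0
    V[neg] -= row_min[neg, None]
    return pd.DataFrame(V, index=X.index, columns=X.columns)


def kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH) with the 0*log(0) = 0 convention."""
    WH = np.maximum(WH, _EPS)
    pos = V > 0
    out = WH.sum() - V.sum()
    out += float((V[pos] * np.log(V[pos] / WH[pos])).sum())
    return float(out)


def _init_factors(V: np.ndarray, k: int, rng: np.random.Generator):
    # i.i.d. uniform(0,1] entries scaled by mean(V)/k
    scale = max(V.mean() / k, _EPS)
    W = (1.0 - rng.random((V.shape[0], k))) * scale
    H = (1.0 - rng.random((k, V.shape[1]))) * scale
    return W, H


def nmf_brunet(
    V: np.ndarray | pd.DataFrame,
    k: int,
    seed: int | np.random.Generator = 0,
    max_iter: int = 2000,
    conv_checks: int | None = 40,
    check_interval: int = 10,
    callback: Callable[[np.ndarray, np.ndarray, int], None] | None = None,
) -> FactorPair:
    """KL-divergence NMF via multiplicative updates (Brunet variant).

    Stops when the sample connectivity pattern (argmax over H columns) has
    been unchanged for ``conv_checks`` consecutive checks spaced
    ``check_interval`` iterations apart, or at ``max_iter``.  Pass
    ``conv_checks=None`` to always run ``max_iter`` iterations.  ``callback``
    (if given) is invoked with (W, H, iteration) after every update, e.g. to
    trace the objective.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be 2-dimensional")
    if (V < 0).any():
        raise ValueError("V has negative entries; shift or clip upstream")
    if not 1 <= k <= min(V.shape):
        raise ValueError(f"rank k={k} out of range for shape {V.shape}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    W, H = _init_factors(V, k, rng)
    stable = 0
    conn = H.argmax(axis=0)
    it = 0
    # preallocated buffers; the loop is allocation-free
    WH = np.empty_like(V)
    R = np.empty_like(V)
    HN = np.empty_like(H)
    WN = np.empty_like(W)
    for it in range(1, max_iter + 1):
        np.dot(W, H, out=WH)
        np.maximum(WH, _EPS, out=WH)
        np.divide(V, WH, out=R)
        np.dot(W.T, R, out=HN)
        H *= HN
        H /= np.maximum(W.sum(axis=0), _EPS)[:, None]
        np.dot(W, H, out=WH)
        np.maximum(WH, _EPS, out=WH)
        np.divide(V, WH, out=R)
        np.dot(R, H.T, out=WN)
        W *= WN
        W /= np.maximum(H.sum(axis=1), _EPS)[None, :]
        if callback is not None:
            callback(W, H, it)
        if conv_checks is not None and it % check_interval == 0:
            new_conn = H.argmax(axis=0)
            if np.array_equal(new_conn, conn):
                stable += 1
                if stable >= conv_checks:
                    break
            else:
                stable = 0
                conn = new_conn
    return FactorPair(W=W, H=H, divergence=kl_divergence(V, W @ H), n_iter=it)


def assign_samples_from_H(H: np.ndarray,
                          sample_ids: Sequence[str] | None = None) -> pd.Series:
    """Sample -> 1-based metagene label by argmax coefficient.

    Ties resolve to the smallest metagene index (numpy argmax convention);
    an all-zero column is unassignable and raises.
    """
    H = np.asarray(H, dtype=float)
    if (H < 0).any():
        raise ValueError("H must be nonnegative")
    if (H.sum(axis=0) == 0).any():
        raise ValueError("unassignable sample: all-zero H column")
    labels = H.argmax(axis=0) + 1
    if sample_ids is None:
        sample_ids = [str(i) for i in range(H.shape[1])]
    return pd.Series(labels, index=list(sample_ids), name="cluster")


def _connectivity(H: np.ndarray) -> np.ndarray:
    lab = H.argmax(axis=0)
    return (lab[:, None] == lab[None, :]).astype(float)


def consensus_cluster(V: pd.DataFrame, k: int, n_runs: int,
                      seed: int = 0, max_iter: int = 2000,
                      conv_checks: int | None = 40) -> ConsensusResult:
    """Average the run connectivity matrices of ``n_runs`` seeded restarts.

    The reported assignment is the argmax-H labeling of the best-divergence
    run (deterministic given the seed).  The cophenetic correlation of the
    consensus matrix quantifies the stability of rank ``k``.
    """
    if k < 2:
        raise ValueError("consensus clustering needs k >= 2")
    if n_runs < 2:
        raise ValueError("need n_runs >= 2")
    if V.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    Va = V.to_numpy(dtype=float)
    ss = np.random.SeedSequence(int(seed) % 2**31)
    C = np.zeros((V.shape[1], V.shape[1]))
    best: FactorPair | None = None
    for child in ss.spawn(n_runs):
        fp = nmf_brunet(Va, k, seed=np.random.default_rng(child),
                        max_iter=max_iter, conv_checks=conv_checks)
        C += _connectivity(fp.H)
        if best is None or fp.divergence < best.divergence:
            best = fp
    C /= n_runs
    np.fill_diagonal(C, 1.0)
    rho = cophenetic_correlation(C)
    assignment = assign_samples_from_H(best.H, V.columns)
    Cdf = pd.DataFrame(C, index=V.columns, columns=V.columns)
    return ConsensusResult(C=Cdf, rank=k, n_runs=n_runs, cophenetic=rho,
                           assignment=assignment, best_run=best)


def cophenetic_correlation(C: np.ndarray | pd.DataFrame) -> float:
    """Pearson correlation between consensus distances (1 - C, off-diagonal)
    and the cophenetic distances of their average-linkage dendrogram."""
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    if C.shape[0] != C.shape[1] or n < 3:
        raise ValueError("undefined: need a square consensus matrix with >= 3 samples")
    if not np.allclose(C, C.T, atol=1e-12):
        raise ValueError("consensus matrix must be symmetric")
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    d = squareform(D, checks=False)
    Z = average(d)
    coph = cophenet(Z)
    if np.ptp(d) == 0 or np.ptp(coph) == 0:
        raise ValueError("degenerate: zero variance in distances")
    rho = pearsonr(d, coph).statistic
    return float(rho)


def _permute_rows(V: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(V)
    for i in range(V.shape[0]):
        out[i] = V[i, rng.permutation(V.shape[1])]
    return out


def rank_survey_with_null(V: pd.DataFrame, k_min: int = 2, k_max: int = 10,
                          n_runs: int = 50, seed: int = 0,
                          max_iter: int = 2000) -> RankSurvey:
    """Cophenetic correlation per rank on the data and on a row-permuted null.

    For each rank one null instance is built by independently permuting every
    feature row across samples (destroys sample structure, preserves feature
    marginals), then clustered with the same settings.
    """
    if k_max > min(V.shape) - 1:
        raise ValueError("k_max must be <= min(dims) - 1")
    ranks = list(range(k_min, k_max + 1))
    rho_real, rho_null = [], []
    Va = V.to_numpy(dtype=float)
    for k in ranks:
        res = consensus_cluster(V, k, n_runs, seed=seed * 1000 + k,
                                max_iter=max_iter)
        rho_real.append(res.cophenetic)
        rng = np.random.default_rng((seed * 1000 + 500 + k) % 2**31)
        Vn = pd.DataFrame(_permute_rows(Va, rng), index=V.index,
                          columns=V.columns)
        resn = consensus_cluster(Vn, k, n_runs, seed=seed * 1000 + 250 + k,
                                 max_iter=max_iter)
        rho_null.append(resn.cophenetic)
    return RankSurvey(ranks=ranks, rho_real=rho_real, rho_null=rho_null)


DEFAULT_RANK_MARGIN = 0.15
"""Minimum cophenetic-correlation excess over the permuted-data null for a
rank to qualify.  On structureless matrices the real and null cophenetic
correlations are draws from the same distribution, so a strict ``>`` test
"finds" a rank about half the time per rank surveyed.  The margin is set
above the sampling spread of the benchmark itself (|rho_real - rho_null|
stays near or below ~0.1 on permuted cohorts at 20 runs/rank) and well below
the excess genuine cluster structure produces (>= ~0.24 at the planted rank
on default synthetic cohorts), so the no-structure outcome is reachable
without costing detection."""


def select_rank(survey: RankSurvey,
                margin: float = DEFAULT_RANK_MARGIN) -> int | None:
    """Rank with the highest real cophenetic correlation among ranks beating
    the null by ``margin``; ties to smaller k; None means no structure."""
    best_k, best_rho = None, -np.inf
    for k, rr, rn in zip(survey.ranks, survey.rho_real, survey.rho_null):
        if rr > rn + margin and rr > best_rho:
            best_k, best_rho = k, rr
    return best_k


def extract_metagene_features(W: np.ndarray,
                              feature_ids: Sequence[str] | None = None,
                              tau: float = 0.75) -> pd.DataFrame:
    """Metagene-specific features from the basis matrix.

    Each feature goes to its argmax metagene; specificity is the argmax
    weight over the row sum (rows summing to 0 are dropped); features with
    specificity >= ``tau`` are retained, sorted by (metagene, weight desc).
    """
    W = np.asarray(W, dtype=float)
    if (W < 0).any():
        raise ValueError("W must be nonnegative")
    if W.shape[1] < 2:
        raise ValueError("need k >= 2 metagenes")
    if feature_ids is None:
        feature_ids = [str(i) for i in range(W.shape[0])]
    rowsum = W.sum(axis=1)
    if (rowsum == 0).all():
        raise ValueError("all rows of W are zero")
    nz = rowsum > 0
    weight = W[nz].max(axis=1)
    spec = weight / rowsum[nz]
    df = pd.DataFrame({
        "feature_id": np.asarray(list(feature_ids))[nz],
        "metagene": W[nz].argmax(axis=1) + 1,
        "weight": weight,
        "specificity": spec,
    })
    df = df[df["specificity"] >= tau]
    df = df.sort_values(["metagene", "weight"],
                        ascending=[True, False], kind="mergesort")
    return df.reset_index(drop=True)
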