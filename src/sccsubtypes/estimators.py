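"""scikit-learn style estimators wrapping the clustering and projection
stages, so they compose with sklearn pipelines and model selection.

Both follow the sklearn sample orientation: X is (n_samples, n_features),
the transpose of the feature-by-sample DataFrames used elsewhere in the
package.  ``labels_`` / ``predict`` outputs are 0-based like sklearn
clusterers; the library-level functions keep the 1-based cluster ids used in
reports.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import nmf as _nmf
from . import projection as _proj

__all__ = ["ConsensusNMFClusterer", "SubtypeProjector"]


class ConsensusNMFClusterer(ClusterMixin, BaseEstimator):
    """Consensus KL-NMF clustering of samples.

    Parameters
    ----------
    n_clusters : factorization rank k.
    n_runs : random restarts averaged into the consensus matrix.
    shift : min-shift rows containing negatives to zero before factorizing
        (log2 input may be negative).
    max_iter, conv_checks : per-run update budget and Brunet stall criterion.
    random_state : seed for all restarts.

    Attributes (after ``fit``)
    --------------------------
    labels_ : (n_samples,) 0-based cluster labels from the best-divergence run.
    consensus_matrix_ : (n_samples, n_samples) co-clustering frequencies.
    cophenetic_ : cophenetic correlation of the consensus matrix.
    W_, H_ : factors of the best-divergence run (features x k, k x samples).
    divergence_ : KL divergence of that run.
    """

    def __init__(self, n_clusters: int = 3, n_runs: int = 50,
                 shift: bool = True, max_iter: int = 2000,
                 conv_checks: int | None = 40, random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_runs = n_runs
        self.shift = shift
        self.max_iter = max_iter
        self.conv_checks = conv_checks
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        V = pd.DataFrame(X.T)  # features x samples
        if self.shift:
            V = _nmf.shift_nonnegative(V)
        res = _nmf.consensus_cluster(
            V, self.n_clusters, self.n_runs, seed=self.random_state,
            max_iter=self.max_iter, conv_checks=self.conv_checks)
        self.labels_ = res.assignment.to_numpy() - 1
        self.consensus_matrix_ = res.C.to_numpy()
        self.cophenetic_ = res.cophenetic
        self.W_ = res.best_run.W
        self.H_ = res.best_run.H
        self.divergence_ = res.best_run.divergence
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class SubtypeProjector(ClusterMixin, BaseEstimator):
    """Assign new samples to reference subtypes via signature-gene centroids.

    ``fit(X, y)`` learns per-subtype centroids from a reference cohort
    (X: samples x genes, y: 1-based subtype labels); ``predict(X_new)``
    assigns each new sample by nearest correlation centroid
    (``method='centroid'``) or by cutting an average-linkage correlation
    dendrogram of the whole batch and mapping groups to centroids greedily
    (``method='hierarchical'``, batch-dependent like the underlying
    procedure).  Predicted labels live in the label space of ``y``.
    """

    def __init__(self, method: str = "centroid",
                 signature_genes: list | None = None):
        self.method = method
        self.signature_genes = signature_genes

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y disagree on n_samples")
        cols = [str(i) for i in range(X.shape[1])]
        frame = pd.DataFrame(X.T, index=cols)
        labels = pd.Series(y, index=frame.columns)
        genes = [str(g) for g in (self.signature_genes or cols)]
        # one centroid per observed label over the signature genes
        Xs = _proj._zscore_rows(_proj._restrict_to_signature(frame, genes))
        cents = {int(c): Xs.loc[:, (labels == c).to_numpy()].mean(axis=1)
                 for c in np.unique(y)}
        self.centroids_ = pd.DataFrame(cents)
        self.signature_ = pd.DataFrame({
            "feature_id": list(Xs.index),
            "metagene": 1,
        })
        self.classes_ = np.array(sorted(cents))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "centroids_")
        X = check_array(X, dtype=float)
        cols = [str(i) for i in range(X.shape[1])]
        frame = pd.DataFrame(X.T, index=cols)
        frame.columns = [f"s{i}" for i in range(X.shape[0])]
        if self.method == "hierarchical":
            res = _proj.project_by_hierarchical_clustering(
                frame, self.signature_, self.centroids_,
                k=len(self.classes_))
            assign = res.assignment
        elif self.method == "centroid":
            assign = _proj.nearest_centroid_assign(
                frame, self.signature_, self.centroids_)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        return assign.to_numpy()
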