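"""Consensus NMF: objective monotonicity, exact low-rank recovery,
cophenetic correlation against a from-scratch UPGMA oracle, rank selection
and planted-structure recovery."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from sccsubtypes import nmf
from sccsubtypes.nmf import (RankSurvey, assign_samples_from_H,
                             consensus_cluster, cophenetic_correlation,
                             extract_metagene_features, filter_low_expression,
                             nmf_brunet, rank_survey_with_null, select_rank,
                             shift_nonnegative)


# ---------------------------------------------------------------- oracles

def kl_oracle(V, W, H):
    """Definition-level generalized KL divergence."""
    WH = W @ H
    total = 0.0
    for i in range(V.shape[0]):
        for j in range(V.shape[1]):
            v, wh = V[i, j], max(WH[i, j], 1e-300)
            total += (v * np.log(v / wh) if v > 0 else 0.0) - v + wh
    return total


def upgma_cophenetic_oracle(D):
    """Naive average-linkage agglomeration; returns the condensed cophenetic
    distance vector in scipy's condensed ordering."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                d = np.mean([D[x, y] for x in clusters[a] for y in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        for x in clusters[a]:
            for y in clusters[b]:
                coph[x, y] = coph[y, x] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    iu = np.triu_indices(n, 1)
    return coph[iu]


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def random_consensus(rng, n):
    A = rng.random((n, n))
    C = (A + A.T) / 2
    np.fill_diagonal(C, 1.0)
    return C


# ---------------------------------------------------------------- filter

def test_filter_keeps_any_row_reaching_zero():
    X = pd.DataFrame(
        [[-1.0, -1.0], [-1.0, 0.5], [0.0, 0.0], [-0.1, -0.001]],
        index=list("abcd"), columns=["s1", "s2"])
    out = filter_low_expression(X)
    assert list(out.index) == ["b", "c"]  # 0 is not < 0


def test_filter_matches_brute_force_scan(rng):
    X = pd.DataFrame(rng.normal(-0.5, 1.0, size=(100, 10)))
    out = filter_low_expression(X)
    survivors = [i for i in range(100)
                 if any(X.iloc[i, j] >= 0 for j in range(10))]
    assert list(out.index) == survivors


def test_filter_all_negative_errors():
    X = pd.DataFrame([[-1.0, -2.0]])
    with pytest.raises(ValueError, match="empty-after-filter"):
        filter_low_expression(X)


def test_shift_nonnegative_preserves_contrasts(rng):
    X = pd.DataFrame(rng.normal(size=(20, 6)))
    V = shift_nonnegative(X)
    assert (V.to_numpy() >= 0).all()
    np.testing.assert_allclose(np.diff(V.to_numpy(), axis=1),
                               np.diff(X.to_numpy(), axis=1), atol=1e-12)


# ---------------------------------------------------------------- nmf core

def test_exact_rank_one_matrix_recovered():
    V = np.outer([1.0, 2.0], [1.0, 1.0, 2.0])
    fp = nmf_brunet(V, k=1, seed=0, max_iter=2000, conv_checks=None)
    assert fp.divergence < 1e-8
    np.testing.assert_allclose(fp.W @ fp.H, V, atol=1e-4)


def test_divergence_monotone_under_updates(rng):
    V = rng.random((10, 8)) * 3
    trace = []
    nmf_brunet(V, k=3, seed=1, max_iter=300, conv_checks=None,
               callback=lambda W, H, it: trace.append(kl_oracle(V, W, H)))
    diffs = np.diff(trace)
    assert (diffs <= 1e-9).all()


def test_zero_row_yields_zero_basis_row_and_finite_divergence(rng):
    V = rng.random((6, 5))
    V[2] = 0.0
    fp = nmf_brunet(V, k=2, seed=0, max_iter=500, conv_checks=None)
    assert np.isfinite(fp.divergence)
    assert fp.W[2].max() < 1e-12


def test_negative_input_and_bad_rank_rejected():
    with pytest.raises(ValueError, match="negative"):
        nmf_brunet(np.array([[-1.0, 2.0]]), k=1)
    with pytest.raises(ValueError, match="rank"):
        nmf_brunet(np.ones((3, 3)), k=4)


def test_assignment_from_H_argmax_and_ties():
    H = np.array([[0.1, 0.5], [0.9, 0.5], [0.0, 0.0]])
    lab = assign_samples_from_H(H, ["a", "b"])
    assert lab["a"] == 2
    assert lab["b"] == 1  # tie goes to the smallest metagene index
    with pytest.raises(ValueError, match="unassignable"):
        assign_samples_from_H(np.array([[0.0], [0.0]]))


# ------------------------------------------------------------- cophenetic

def test_ideal_block_consensus_has_cophenetic_one():
    C = np.zeros((6, 6))
    C[:3, :3] = 1.0
    C[3:, 3:] = 1.0
    assert cophenetic_correlation(C) == pytest.approx(1.0, abs=1e-12)


def test_cophenetic_matches_upgma_oracle(rng):
    for _ in range(50):
        n = int(rng.integers(5, 15))
        C = random_consensus(rng, n)
        D = 1 - C
        np.fill_diagonal(D, 0)
        iu = np.triu_indices(n, 1)
        expected = pearson_oracle(D[iu], upgma_cophenetic_oracle(D))
        assert cophenetic_correlation(C) == pytest.approx(expected, abs=1e-10)


def test_cophenetic_small_or_degenerate_inputs_rejected():
    with pytest.raises(ValueError, match="undefined"):
        cophenetic_correlation(np.eye(2))
    with pytest.raises(ValueError, match="degenerate"):
        cophenetic_correlation(np.ones((4, 4)))


# --------------------------------------------------------------- consensus

def _two_block_matrix(rng, n_feat=40, n_per=6, delta=4.0, noise=0.2):
    lab = np.repeat([0, 1], n_per)
    X = rng.normal(2.0, noise, size=(n_feat, 2 * n_per))
    X[:20][:, lab == 0] += delta
    X[20:][:, lab == 1] += delta
    return pd.DataFrame(X), lab


def test_two_block_consensus_is_exact(rng):
    V, lab = _two_block_matrix(rng)
    res = consensus_cluster(V, k=2, n_runs=10, seed=3)
    C = res.C.to_numpy()
    same = lab[:, None] == lab[None, :]
    np.testing.assert_allclose(C[same], 1.0)
    np.testing.assert_allclose(C[~same], 0.0)
    assert adjusted_rand_score(lab, res.assignment.to_numpy()) == 1.0


def test_consensus_matrix_valid_and_deterministic(rng):
    V = pd.DataFrame(rng.random((30, 12)))
    r1 = consensus_cluster(V, k=3, n_runs=5, seed=9, max_iter=300)
    r2 = consensus_cluster(V, k=3, n_runs=5, seed=9, max_iter=300)
    C = r1.C.to_numpy()
    assert np.allclose(C, C.T)
    assert np.allclose(np.diag(C), 1.0)
    assert C.min() >= 0 and C.max() <= 1
    pd.testing.assert_frame_equal(r1.C, r2.C)
    pd.testing.assert_series_equal(r1.assignment, r2.assignment)


def test_permutation_of_samples_permutes_consensus(rng):
    # on well-separated data the consensus is exactly block structured, so
    # column permutation must permute C and the assignment partition
    V, lab = _two_block_matrix(rng)
    perm = rng.permutation(V.shape[1])
    Vp = V.iloc[:, perm]
    r = consensus_cluster(V, k=2, n_runs=8, seed=5)
    rp = consensus_cluster(Vp, k=2, n_runs=8, seed=5)
    np.testing.assert_allclose(rp.C.to_numpy(),
                               r.C.to_numpy()[np.ix_(perm, perm)])
    assert adjusted_rand_score(r.assignment.to_numpy()[perm],
                               rp.assignment.to_numpy()) == 1.0


def test_consensus_recovers_planted_clusters(small_study):
    V = shift_nonnegative(filter_low_expression(small_study.mrna))
    res = consensus_cluster(V, k=3, n_runs=10, seed=1)
    ari = adjusted_rand_score(small_study.truth.labels.to_numpy(),
                              res.assignment.to_numpy())
    assert ari == 1.0


# ------------------------------------------------------------ rank survey

def test_select_rank_rules():
    sv = RankSurvey(ranks=[2, 3, 4], rho_real=[0.7, 0.95, 0.8],
                    rho_null=[0.6, 0.6, 0.6])
    assert select_rank(sv) == 3
    sv2 = RankSurvey(ranks=[2, 3], rho_real=[0.5, 0.55],
                     rho_null=[0.6, 0.6])
    assert select_rank(sv2) is None
    # ties break toward smaller k
    sv3 = RankSurvey(ranks=[2, 3], rho_real=[0.9, 0.9],
                     rho_null=[0.5, 0.5])
    assert select_rank(sv3) == 2


def test_rank_survey_finds_structure_and_is_deterministic(small_study):
    # at this reduced scale the k=2 merge of two planted clusters can be as
    # stable as the true k=3 split (both rho ~ 1), so we assert the planted
    # rank clearly beats the permuted benchmark and that a rank is selected;
    # exact selection at full scale is covered by the acceptance suite
    V = shift_nonnegative(filter_low_expression(small_study.mrna))
    sv = rank_survey_with_null(V, 2, 4, n_runs=8, seed=2, max_iter=500)
    assert sv.rho_real[1] > 0.99
    assert sv.rho_real[1] > sv.rho_null[1] + nmf.DEFAULT_RANK_MARGIN
    assert sv.rho_real[1] > sv.rho_real[2]
    assert select_rank(sv) in (2, 3)
    sv2 = rank_survey_with_null(V, 2, 4, n_runs=8, seed=2, max_iter=500)
    assert sv.rho_real == sv2.rho_real and sv.rho_null == sv2.rho_null


# ------------------------------------------------- metagene feature calls

def test_extract_features_specificity_rules():
    W = np.array([[0.0, 0.0, 5.0],
                  [1.0, 1.0, 1.0],
                  [0.0, 0.0, 0.0],
                  [4.0, 1.0, 0.0]])
    out = extract_metagene_features(W, list("abcd"), tau=0.75)
    assert set(out["feature_id"]) == {"a", "d"}
    row = out.set_index("feature_id").loc["a"]
    assert row["metagene"] == 3 and row["specificity"] == 1.0
    with pytest.raises(ValueError):
        extract_metagene_features(np.zeros((3, 2)))


def test_extracted_features_recover_planted_signatures(small_config):
    # plain cohort: the appended miR-target rows are themselves cluster
    # -differential and would legitimately be retained
    from sccsubtypes.simulate import generate_multiomic_truth
    mrna, _, truth = generate_multiomic_truth(small_config)
    X = filter_low_expression(mrna)
    V = shift_nonnegative(X)
    res = consensus_cluster(V, k=3, n_runs=10, seed=1)
    sig = extract_metagene_features(res.best_run.W, X.index, tau=0.75)
    planted = {g for s in truth.signature_genes.values() for g in s}
    retained = set(sig["feature_id"])
    assert len(retained & planted) / len(retained) >= 0.9
    for mg in (1, 2, 3):
        assert (sig["metagene"] == mg).any()
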