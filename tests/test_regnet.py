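"""Master-list compilation, Welch-based TF upregulation calls, candidate
intersection, inverse-correlation screening and the direction filter."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sccsubtypes.diffexpr import diff_expr_table
from sccsubtypes.regnet import (compile_master_list, filter_candidate_targets,
                                intersect_tf_candidates,
                                inverse_correlation_screen, passing_tfs,
                                upregulated_tfs)


# ------------------------------------------------------------ master list

def test_master_list_is_union_of_annotated_tfs():
    ann = {"m1": {"TF1"}, "m2": {"TF1", "TF2"}}
    assert compile_master_list(ann, ["m1", "m2"]) == {"TF1", "TF2"}


def test_all_unannotated_mirs_rejected():
    with pytest.raises(ValueError):
        compile_master_list({"m1": {"TF1"}}, ["m3"])
    with pytest.raises(ValueError):
        compile_master_list({"m1": {"TF1"}}, [])


def test_planted_tf_lands_in_master_list(small_study):
    truth = small_study.truth
    ann = {m: set(g["tf_id"]) for m, g in small_study.tfbs.groupby("mir_id")}
    diff = [m for m, c, s in truth.mir_effects if c == 1 and s > 0]
    master = compile_master_list(ann, diff)
    assert truth.planted_tf[0] in master


# ----------------------------------------------------- upregulation calls

def test_flat_tf_fails_everywhere():
    rng = np.random.default_rng(0)
    X = pd.DataFrame([rng.normal(5, 0.3, 12)], index=["TF1"],
                     columns=[f"s{i}" for i in range(12)])
    labels = pd.Series([1] * 4 + [2] * 4 + [3] * 4, index=X.columns)
    res = upregulated_tfs(X, labels, 1, ["TF1"])
    assert passing_tfs(res) == set()


def test_welch_statistics_match_definition_oracle(rng):
    X = pd.DataFrame(rng.normal(size=(5, 12)),
                     index=[f"TF{i}" for i in range(5)],
                     columns=[f"s{i}" for i in range(12)])
    labels = pd.Series([1] * 4 + [2] * 4 + [3] * 4, index=X.columns)
    res = upregulated_tfs(X, labels, 1, list(X.index))
    lab = labels.to_numpy()
    for _, row in res.iterrows():
        a = X.loc[row["tf"]].to_numpy()[lab == 1]
        b = X.loc[row["tf"]].to_numpy()[lab == int(row["other_cluster"])]
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
        p = 2 * stats.t.sf(abs(t), df)
        assert row["t"] == pytest.approx(t, rel=1e-10)
        assert row["p"] == pytest.approx(p, rel=1e-10)


def test_planted_tf_called_and_decoys_rejected(small_study):
    truth = small_study.truth
    tf, cluster = truth.planted_tf
    tf_ids = sorted(set(small_study.tfbs["tf_id"]))
    for X, labels in ((small_study.mrna, truth.labels),
                      (small_study.mrna_cellline, truth.labels_cellline)):
        up = passing_tfs(upregulated_tfs(X, labels, cluster, tf_ids))
        assert tf in up


# ------------------------------------------------------------ Venn logic

def test_intersection_is_subset_and_monotone():
    master, upA, upB = {"a", "b", "c"}, {"b", "c", "d"}, {"c", "e"}
    got = intersect_tf_candidates(master, upA, upB)
    assert got == ["c"]
    assert intersect_tf_candidates(set(), upA, upB) == []
    # enlarging the master list never removes a candidate
    bigger = intersect_tf_candidates(master | {"e"}, upA, upB)
    assert set(got) <= set(bigger)


def test_twin_cohort_intersection_recovers_exactly_planted_tf(small_study):
    truth = small_study.truth
    tf, cluster = truth.planted_tf
    ann = {m: set(g["tf_id"]) for m, g in small_study.tfbs.groupby("mir_id")}
    diff = [m for m, c, s in truth.mir_effects]
    master = compile_master_list(ann, sorted(set(diff)))
    upA = passing_tfs(upregulated_tfs(small_study.mrna, truth.labels,
                                      cluster, sorted(master)))
    upB = passing_tfs(upregulated_tfs(small_study.mrna_cellline,
                                      truth.labels_cellline, cluster,
                                      sorted(master)))
    assert intersect_tf_candidates(master, upA, upB) == [tf]


# ------------------------------------------------- inverse-correlation

def test_perfect_inverse_fit():
    x = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                  index=[f"s{i}" for i in range(6)])
    X = pd.DataFrame([-2 * x.to_numpy()], index=["g1"], columns=x.index)
    res = inverse_correlation_screen(x, X)
    assert res.loc["g1", "slope"] == pytest.approx(-2.0)
    assert res.loc["g1", "r2"] == pytest.approx(1.0)
    assert res.loc["g1", "p"] < 1e-6
    assert bool(res.loc["g1", "inverse"])


def test_screen_matches_closed_form_oracle(rng):
    x = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
    X = pd.DataFrame(rng.normal(size=(100, 30)),
                     index=[f"g{i}" for i in range(100)], columns=x.index)
    res = inverse_correlation_screen(x, X)
    for g in list(X.index)[:25]:
        fit = stats.linregress(x.to_numpy(), X.loc[g].to_numpy())
        assert res.loc[g, "slope"] == pytest.approx(fit.slope, rel=1e-10)
        assert res.loc[g, "r2"] == pytest.approx(fit.rvalue ** 2, rel=1e-10)
        assert res.loc[g, "p"] == pytest.approx(fit.pvalue, rel=1e-10)


def test_decoy_pvalues_roughly_uniform_and_r2_small(rng):
    x = pd.Series(rng.normal(size=60), index=[f"s{i}" for i in range(60)])
    X = pd.DataFrame(rng.normal(size=(200, 60)),
                     index=[f"g{i}" for i in range(200)], columns=x.index)
    res = inverse_correlation_screen(x, X)
    assert abs(res["r2"].mean() - 1 / 59) < 3 * np.sqrt(2 / 59 ** 2 / 200) * 59
    assert stats.kstest(res["p"], "uniform").pvalue > 0.01


def test_constant_inputs_handled():
    x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
    X = pd.DataFrame([[5.0, 5.0, 5.0, 5.0]], index=["flat"], columns=x.index)
    res = inverse_correlation_screen(x, X)
    assert res.loc["flat", "r2"] == 0.0 and res.loc["flat", "p"] == 1.0
    with pytest.raises(ValueError, match="constant miR"):
        inverse_correlation_screen(pd.Series([1.0] * 4, index=list("abcd")), X)
    with pytest.raises(ValueError, match="4 samples"):
        inverse_correlation_screen(x.iloc[:3], X.iloc[:, :3])


def test_planted_target_ranks_first_among_decoys(small_study):
    truth = small_study.truth
    mir, gene, beta = truth.target_couplings[0]
    res = inverse_correlation_screen(small_study.mirna.loc[mir],
                                     small_study.mrna,
                                     truth.predicted_targets)
    assert res.index[0] == gene
    assert res.loc[gene, "slope"] < 0


# ------------------------------------------------------- direction filter

def test_direction_filter_logic():
    diffA = pd.DataFrame({"FC_1": [0.5, 2.0, 0.5], "FC_3": [2.0, 2.0, 0.5]},
                         index=["good", "up_in_high", "down_in_low"])
    diffB = diffA.copy()
    kept = filter_candidate_targets(["good", "up_in_high", "down_in_low"],
                                    diffA, diffB, 1, 3)
    assert kept == ["good"]


def test_planted_target_survives_direction_filter(small_study):
    truth = small_study.truth
    _, gene, _ = truth.target_couplings[0]
    diffA = diff_expr_table(small_study.mrna, truth.labels)
    diffB = diff_expr_table(small_study.mrna_cellline, truth.labels_cellline)
    kept = filter_candidate_targets(truth.predicted_targets, diffA, diffB,
                                    mir_high_cluster=1,
                                    mir_low_cluster=truth.k)
    assert gene in kept
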