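"""Feature summarization, ANOVA/Fisher statistics, integrated rank FDR, heatmap."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from alstrat.cohort import EARLY_WINDOW, FeatureDictionary, TimeWindow
from alstrat.features import (
    FeatureFDRResult,
    anova_statistic,
    feature_usage_by_group,
    feature_usage_tally,
    fisher_statistic,
    heatmap_matrix,
    integrated_rank_fdr,
    pairwise_ttest_fdr,
    summarize_features,
)

from conftest import make_table


def simple_dictionary():
    d = FeatureDictionary()
    d.add("lab", "continuous", "")
    d.add("site", "discrete", "")
    return d


def test_summarize_single_and_multiple_records():
    t = make_table(
        [
            ("s1", "lab", "5", 10),
            ("s2", "lab", "1", 5),
            ("s2", "lab", "2", 20),
            ("s2", "lab", "3", 80),
            ("s1", "site", "bulbar", 0),
        ]
    )
    sm = summarize_features(t, simple_dictionary(), windows=[EARLY_WINDOW])["0-3m"]
    assert sm.C.loc["lab:mean", "s1"] == 5 == sm.C.loc["lab:min", "s1"]
    assert sm.C.loc["lab:mean", "s2"] == 2
    assert sm.C.loc["lab:min", "s2"] == 1 and sm.C.loc["lab:max", "s2"] == 3
    assert sm.D.loc["site", "s1"] == "bulbar"
    assert pd.isna(sm.D.loc["site", "s2"])  # no in-window record → missing


def test_summarize_modal_value_and_tie_break():
    t = make_table(
        [
            ("s1", "site", "limb", 0),
            ("s1", "site", "limb", 10),
            ("s1", "site", "bulbar", 20),
            ("s2", "site", "limb", 0),
            ("s2", "site", "bulbar", 10),
        ]
    )
    d = simple_dictionary()
    sm = summarize_features(t, d, windows=[EARLY_WINDOW])["0-3m"]
    assert sm.D.loc["site", "s1"] == "limb"
    assert sm.D.loc["site", "s2"] == "bulbar"  # tie → lexicographically smallest


def test_summarize_matches_loop_oracle(rng):
    rows = []
    for s in range(6):
        for _ in range(int(rng.integers(0, 6))):
            rows.append((f"s{s}", "lab", str(int(rng.integers(0, 50))), int(rng.integers(0, 200))))
    rows.append(("s0", "site", "x", 0))
    t = make_table(rows)
    w = TimeWindow(0, 91)
    sm = summarize_features(t, simple_dictionary(), windows=[w])["0-3m"]
    present = set(t.subjects())
    for s in range(6):
        sid = f"s{s}"
        if sid not in present:
            continue
        vals = [
            float(v) for (sj, f, v, d) in rows if sj == sid and f == "lab" and 0 <= d <= 91
        ]
        if vals:
            assert sm.C.loc["lab:mean", sid] == pytest.approx(np.mean(vals))
            assert sm.C.loc["lab:min", sid] == min(vals)
            assert sm.C.loc["lab:max", sid] == max(vals)
        elif "lab:mean" in sm.C.index:
            assert np.isnan(sm.C.loc["lab:mean", sid])


def test_anova_equal_group_means_gives_zero():
    values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
    g = ["a", "a", "a", "b", "b", "b"]
    assert anova_statistic(values, g) == pytest.approx(0.0)


def test_anova_two_groups_equals_squared_t(rng):
    x = rng.normal(size=14)
    g = np.array(["a"] * 7 + ["b"] * 7)
    t, _ = scipy.stats.ttest_ind(x[:7], x[7:], equal_var=True)
    assert anova_statistic(x, g) == pytest.approx(t**2)


def test_anova_matches_scipy_oracle(rng):
    for _ in range(10):
        k = int(rng.integers(2, 5))
        g = rng.integers(0, k, size=30)
        x = rng.normal(size=30)
        if len(np.unique(g)) < 2:
            continue
        expected = scipy.stats.f_oneway(*(x[g == c] for c in np.unique(g))).statistic
        assert anova_statistic(x, g) == pytest.approx(expected)


def test_anova_undefined_for_single_cluster():
    assert np.isnan(anova_statistic([1.0, 2.0, 3.0], ["a", "a", "a"]))


def test_anova_ignores_missing(rng):
    x = np.array([1.0, np.nan, 2.0, 5.0, np.nan, 6.0])
    g = np.array(["a", "a", "a", "b", "b", "b"])
    expected = scipy.stats.f_oneway([1.0, 2.0], [5.0, 6.0]).statistic
    assert anova_statistic(x, g) == pytest.approx(expected)


def test_fisher_2x2_hand_example():
    # diagonal 5/0/0/5 table: two tables (itself and its mirror) at the
    # minimal probability 1/C(10,5) each → p = 2/252
    values = ["x"] * 5 + ["y"] * 5
    g = ["a"] * 5 + ["b"] * 5
    assert fisher_statistic(values, g) == pytest.approx(2 / 252)


def test_fisher_2x2_matches_scipy(rng):
    for _ in range(10):
        values = rng.choice(["x", "y"], size=20)
        g = rng.choice(["a", "b"], size=20)
        p = fisher_statistic(values, g)
        if np.isnan(p):
            continue
        tbl = pd.crosstab(pd.Series(values), pd.Series(g)).to_numpy()
        if tbl.shape != (2, 2):
            continue
        assert p == pytest.approx(scipy.stats.fisher_exact(tbl)[1])


def test_fisher_symmetric_swap_invariance():
    values = ["x", "x", "y", "y", "x", "y", "x", "x"]
    g = ["a", "a", "a", "b", "b", "b", "a", "b"]
    swapped = ["y" if v == "x" else "x" for v in values]
    assert fisher_statistic(values, g) == pytest.approx(fisher_statistic(swapped, g))


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_fisher_freeman_halton_matches_r():
    # 3×3 table, exact enumeration path; R's fisher.test is the oracle
    counts = np.array([[4, 1, 0], [1, 3, 1], [0, 2, 4]])
    values, g = [], []
    for i in range(3):
        for j in range(3):
            values += [f"cat{i}"] * counts[i, j]
            g += [f"cl{j}"] * counts[i, j]
    ours = fisher_statistic(values, g)
    r = subprocess.run(
        [
            "Rscript",
            "-e",
            "cat(fisher.test(matrix(c(4,1,0,1,3,1,0,2,4),nrow=3,byrow=TRUE))$p.value)",
        ],
        capture_output=True,
        text=True,
        check=True,
    )
    assert ours == pytest.approx(float(r.stdout.strip()), rel=1e-6)


def test_fisher_monte_carlo_close_to_exact():
    counts = np.array([[6, 1], [1, 6], [2, 5]])
    values, g = [], []
    for i in range(3):
        for j in range(2):
            values += [f"cat{i}"] * counts[i, j]
            g += [f"cl{j}"] * counts[i, j]
    exact = fisher_statistic(values, g)
    mc = fisher_statistic(values, g, seed=7, exact_limit=1, mc_iters=4000)
    assert mc == pytest.approx(exact, abs=0.03)


def planted_matrices(rng, n=80, k=3, n_null=30, shift=2.0):
    labels = {f"s{i}": (i % k) + 1 for i in range(n)}
    subjects = list(labels)
    g = np.array([labels[s] for s in subjects])
    rows = {"planted:mean": rng.normal((g == 1) * shift, 1.0)}
    for i in range(n_null):
        rows[f"null{i}:mean"] = rng.normal(size=n)
    C = pd.DataFrame(rows).T
    C.columns = subjects
    return C, labels


def test_planted_feature_detected_and_nulls_calibrated(rng):
    C, labels = planted_matrices(rng)
    res = integrated_rank_fdr(C, None, labels, n_perm=60, seed=0)
    t = res.global_table.set_index("feature")
    assert t.loc["planted:mean", "fdr"] < 0.05
    null_fdrs = t.drop("planted:mean")["fdr"]
    assert null_fdrs.median() > 0.5


def test_fdr_monotone_in_rank(rng):
    C, labels = planted_matrices(rng, n_null=20)
    res = integrated_rank_fdr(C, None, labels, n_perm=40, seed=1)
    t = res.global_table.sort_values("rank")
    assert (t["fdr"].diff().dropna() <= 1e-12).all()


def test_fdr_deterministic_under_seed(rng):
    C, labels = planted_matrices(rng, n=40, n_null=8)
    a = integrated_rank_fdr(C, None, labels, n_perm=30, seed=9).global_table
    b = integrated_rank_fdr(C, None, labels, n_perm=30, seed=9).global_table
    pd.testing.assert_frame_equal(a, b)


def test_fdr_without_discrete_family(rng):
    C, labels = planted_matrices(rng, n=40, n_null=5)
    res = integrated_rank_fdr(C, None, labels, n_perm=30, seed=2)
    assert set(res.global_table["family"]) == {"continuous"}


def test_undefined_feature_excluded(rng):
    C, labels = planted_matrices(rng, n=40, n_null=3)
    C.loc["broken:mean"] = np.nan
    res = integrated_rank_fdr(C, None, labels, n_perm=30, seed=3)
    assert "broken:mean" in res.excluded
    assert "broken:mean" not in set(res.global_table["feature"])


def test_pairwise_gating_and_direction(rng):
    C, labels = planted_matrices(rng, shift=3.0)
    res = integrated_rank_fdr(C, None, labels, n_perm=60, seed=4)
    res = pairwise_ttest_fdr(C, labels, res, n_perm=60, seed=4)
    pw = res.pairwise
    gated = set(res.significant_features(0.05, family="continuous"))
    assert set(pw["feature"]) <= gated
    planted = pw[pw["feature"] == "planted:mean"]
    sig = planted[planted["significant"]]
    # cluster 1 carries the shift: it must win every significant contrast it is in
    involved = sig[(sig["cluster_a"] == 1) | (sig["cluster_b"] == 1)]
    assert len(involved) > 0 and (involved["direction"] == 1).all()


def test_identical_clusters_never_significant_pairwise():
    # adjacent subject pairs share a value and land in different clusters,
    # so both clusters see the identical distribution
    C = pd.DataFrame(
        {f"s{i}": [float((i // 2) % 4)] for i in range(24)}, index=["flat:mean"]
    )
    labels = {f"s{i}": (i % 2) + 1 for i in range(24)}
    table = pd.DataFrame(
        {"feature": ["flat:mean"], "family": ["continuous"], "statistic": [0.0],
         "rank": [1.0], "fdr": [0.0]}
    )
    res = FeatureFDRResult(global_table=table, n_perm=30)
    res = pairwise_ttest_fdr(C, labels, res, n_perm=30, seed=5)
    row = res.pairwise.iloc[0]
    assert row["t"] == pytest.approx(0.0)
    assert not row["significant"]


def make_pairwise_result(rows):
    pw = pd.DataFrame(
        rows, columns=["feature", "cluster_a", "cluster_b", "t", "fdr", "direction", "significant"]
    )
    table = pd.DataFrame(
        {"feature": pw["feature"].unique(), "family": "continuous",
         "statistic": 1.0, "rank": 1.0, "fdr": 0.0}
    )
    return FeatureFDRResult(global_table=table, pairwise=pw, n_perm=10)


def test_heatmap_one_vs_rest_scaling():
    res = make_pairwise_result(
        [
            ("f", 1, 2, 5.0, 0.0, 1, True),
            ("f", 1, 3, 5.0, 0.0, 1, True),
            ("f", 2, 3, 0.1, 0.9, 2, False),
        ]
    )
    hm = heatmap_matrix(res)
    assert list(hm.loc["f"]) == [1.0, -1.0, -1.0]


def test_heatmap_no_significant_pairs_is_zero_row():
    res = make_pairwise_result([("f", 1, 2, 0.1, 0.9, 1, False)])
    assert list(heatmap_matrix(res).loc["f"]) == [0.0, 0.0]


def test_heatmap_two_clusters():
    res = make_pairwise_result([("f", 1, 2, 4.0, 0.01, 2, True)])
    assert list(heatmap_matrix(res).loc["f"]) == [-1.0, 1.0]


def test_feature_usage_tally():
    lists = {f"t{i}": ["age", "alsfrs"] if i < 3 else ["age"] for i in range(12)}
    tally = feature_usage_tally(lists)
    assert tally["age"] == 1.0
    assert tally["alsfrs"] == pytest.approx(0.25)
    assert "fvc" not in tally
    grouped = feature_usage_by_group({"prog": lists, "surv": {"t0": ["fvc"]}})
    assert grouped.loc["fvc", "prog"] == 0.0
    assert grouped.loc["fvc", "average"] == pytest.approx(0.5)


def test_feature_cap_enforced():
    with pytest.raises(ValueError, match="cap"):
        feature_usage_tally({"t": [f"f{i}" for i in range(7)]})
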