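"""Co-clustering matrix, pair FDR, significant-pair graph, consensus k-means."""

import math

import numpy as np
import pytest

from alstrat.consensus import (
    ClusterSet,
    CoClusterMatrix,
    PairFDRGraph,
    build_cocluster_matrix,
    consensus_kmeans,
    core_patients,
    pair_fdr,
    read_submissions,
    significant_pair_graph,
    suggest_k,
    write_submissions,
)


def cocluster_oracle(submissions, subjects):
    """Triple-loop evaluation of m_ij = Σ_s ln(p/c_s)."""
    p = len(subjects)
    M = np.zeros((p, p))
    for i, a in enumerate(subjects):
        for j, b in enumerate(subjects):
            if i == j:
                continue
            for sub in submissions:
                la, lb = sub.assignment.get(a), sub.assignment.get(b)
                if la is None or lb is None or la != lb:
                    continue
                c = sum(1 for l in sub.assignment.values() if l == la)
                M[i, j] += math.log(p / c)
    return M


def random_submissions(rng, subjects, n_subs):
    out = []
    for s in range(n_subs):
        k = int(rng.integers(1, 5))
        labels = rng.integers(0, k, size=len(subjects))
        out.append(
            ClusterSet(f"sub{s}", {subj: int(l) for subj, l in zip(subjects, labels)})
        )
    return out


def test_hand_example_two_pairs():
    sub = ClusterSet("x", {"A": 1, "B": 1, "C": 2, "D": 2})
    m = build_cocluster_matrix([sub], ["A", "B", "C", "D"])
    assert m.score("A", "B") == pytest.approx(math.log(2))
    assert m.score("C", "D") == pytest.approx(math.log(2))
    assert m.score("A", "C") == 0.0
    assert np.allclose(m.M, m.M.T)
    assert np.all(np.diag(m.M) == 0)


def test_trivial_one_cluster_contributes_nothing():
    subjects = ["A", "B", "C", "D"]
    base = [ClusterSet("x", {"A": 1, "B": 1, "C": 2, "D": 2})]
    trivial = ClusterSet("t", {s: 0 for s in subjects})
    m1 = build_cocluster_matrix(base, subjects)
    m2 = build_cocluster_matrix(base + [trivial], subjects)
    assert np.array_equal(m1.M, m2.M)


def test_matrix_matches_triple_loop_oracle(rng):
    for _ in range(15):
        p = int(rng.integers(3, 12))
        subjects = [f"p{i}" for i in range(p)]
        subs = random_submissions(rng, subjects, int(rng.integers(1, 6)))
        m = build_cocluster_matrix(subs, subjects)
        assert np.allclose(m.M, cocluster_oracle(subs, subjects))


def test_matrix_invariances(rng):
    subjects = [f"p{i}" for i in range(8)]
    subs = random_submissions(rng, subjects, 4)
    base = build_cocluster_matrix(subs, subjects).M
    reordered = build_cocluster_matrix(subs[::-1], subjects).M
    assert np.array_equal(base, reordered)
    renamed = [
        ClusterSet(s.submission_id, {k: f"label_{v}" for k, v in s.assignment.items()})
        for s in subs
    ]
    assert np.array_equal(base, build_cocluster_matrix(renamed, subjects).M)


def test_unknown_subject_rejected():
    sub = ClusterSet("x", {"A": 1, "Z": 1})
    with pytest.raises(ValueError, match="Z"):
        build_cocluster_matrix([sub], ["A", "B"])


def test_pair_fdr_separates_planted_pairs(rng):
    subjects = [f"p{i}" for i in range(12)]
    partition = {s: (0 if i < 6 else 1) for i, s in enumerate(subjects)}
    subs = [ClusterSet(f"s{j}", dict(partition)) for j in range(8)]
    m = build_cocluster_matrix(subs, subjects)
    res = pair_fdr(m, subs, n_perm=50, seed=0)
    idx = m.index()
    within = [res.fdr[idx["p0"], idx["p1"]], res.fdr[idx["p6"], idx["p7"]]]
    across = res.fdr[idx["p0"], idx["p6"]]
    assert max(within) < 0.05
    assert across > 0.05


def test_pair_fdr_zero_when_no_permutation_reaches_score(rng):
    # 6 subjects, tight pair {A,B} in a size-2 cluster across many submissions:
    # permuted matrices essentially never accumulate the same total weight
    subjects = list("ABCDEF")
    part = {"A": 0, "B": 0, "C": 1, "D": 1, "E": 1, "F": 1}
    subs = [ClusterSet(f"s{j}", dict(part)) for j in range(12)]
    m = build_cocluster_matrix(subs, subjects)
    res = pair_fdr(m, subs, n_perm=50, seed=1)
    idx = m.index()
    assert res.fdr[idx["A"], idx["B"]] == 0.0


def test_random_solver_calibration(rng):
    fracs = []
    for rep in range(5):
        subjects = [f"p{i}" for i in range(40)]
        subs = random_submissions(np.random.default_rng(100 + rep), subjects, 10)
        m = build_cocluster_matrix(subs, subjects)
        res = pair_fdr(m, subs, n_perm=40, seed=rep)
        pairs = res.pairs()
        fracs.append((pairs["fdr"] <= 0.05).mean())
    assert np.mean(fracs) <= 0.10


def test_graph_threshold_and_dot_round_trip(tmp_path, rng):
    subjects = [f"p{i}" for i in range(10)]
    part = {s: (0 if i < 5 else 1) for i, s in enumerate(subjects)}
    subs = [ClusterSet(f"s{j}", dict(part)) for j in range(6)]
    m = build_cocluster_matrix(subs, subjects)
    res = pair_fdr(m, subs, n_perm=30, seed=2)
    empty = significant_pair_graph(res, threshold=-1.0)
    assert empty.edges == set() and empty.n_components() == 0
    full = significant_pair_graph(res, threshold=1.0)
    assert len(full.edges) == sum(1 for _ in zip(*np.nonzero(np.triu(m.M))))
    g = significant_pair_graph(res, threshold=0.05)
    path = tmp_path / "g.dot"
    g.to_dot(path)
    assert PairFDRGraph.from_dot(path).edges == g.edges


def block_matrix(rng, sizes, strength=5.0, noise=0.2):
    p = sum(sizes)
    M = rng.normal(0, noise, size=(p, p))
    start = 0
    for size in sizes:
        M[start : start + size, start : start + size] += strength
        start += size
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0)
    subjects = [f"p{i}" for i in range(p)]
    return CoClusterMatrix(subjects=subjects, M=M)


def test_kmeans_recovers_planted_blocks(rng):
    m = block_matrix(rng, [10, 10])
    res = consensus_kmeans(m, 2, seed=0, n_restarts=5)
    first, second = set(res.labels[:10]), set(res.labels[10:])
    assert len(first) == 1 and len(second) == 1 and first != second


def test_kmeans_k1_and_duplicates(rng):
    m = block_matrix(rng, [6, 6])
    res1 = consensus_kmeans(m, 1, seed=0)
    assert set(res1.labels) == {1}
    # duplicated rows get identical labels: the metric is row-determined
    M = m.M.copy()
    M[3] = M[2]
    M[:, 3] = M[:, 2]
    dup = CoClusterMatrix(subjects=m.subjects, M=M)
    res = consensus_kmeans(dup, 2, seed=0, n_restarts=5)
    assert res.labels[2] == res.labels[3]


def test_kmeans_deterministic_and_reorder_invariant(rng):
    m = block_matrix(rng, [8, 8])
    a = consensus_kmeans(m, 2, seed=3)
    b = consensus_kmeans(m, 2, seed=3)
    assert np.array_equal(a.labels, b.labels)
    perm = rng.permutation(m.p)
    m2 = CoClusterMatrix(
        subjects=[m.subjects[i] for i in perm], M=m.M[np.ix_(perm, perm)]
    )
    c = consensus_kmeans(m2, 2, seed=4)
    from sklearn.metrics import adjusted_rand_score

    relabeled = [c.labels_dict()[s] for s in m.subjects]
    assert adjusted_rand_score(a.labels, relabeled) == 1.0


def test_core_patient_counts_and_outlier(rng):
    m = block_matrix(rng, [4, 4], strength=4.0, noise=0.05)
    m.M[3, :4] = 0.0  # make p3 an outlier of the first block
    m.M[:4, 3] = 0.0
    np.fill_diagonal(m.M, 0)
    res = consensus_kmeans(m, 2, seed=0, n_restarts=5)
    mask = core_patients(res)
    sizes = [np.sum(res.labels == c) for c in (1, 2)]
    assert mask.sum() == sum(math.ceil(s / 2) for s in sizes)
    if res.labels[3] == res.labels[0]:  # outlier stayed in its block
        assert not mask[3]


def test_core_tie_broken_by_subject_order():
    M = np.zeros((2, 2))
    M[0, 1] = M[1, 0] = 1.0
    res = consensus_kmeans(CoClusterMatrix(subjects=["a", "b"], M=M), 1, seed=0)
    assert list(res.core_mask) == [True, False]


def test_suggest_k_prefers_planted_block_count(rng):
    m = block_matrix(rng, [8, 8, 8, 8], strength=5.0, noise=0.3)
    diag = suggest_k(m, None, k_range=[2, 3, 4, 5, 6], seed=0)
    best = int(diag.loc[diag["mean_silhouette"].idxmax(), "k"])
    assert best == 4
    assert diag["graph_components"].eq(0).all()


def test_submissions_csv_round_trip(tmp_path, rng):
    subjects = [f"p{i}" for i in range(6)]
    subs = random_submissions(rng, subjects, 3)
    path = tmp_path / "subs.csv"
    write_submissions(subs, path)
    back = read_submissions(path)
    assert {s.submission_id for s in back} == {s.submission_id for s in subs}
    orig = {s.submission_id: {k: str(v) for k, v in s.assignment.items()} for s in subs}
    for s in back:
        assert s.assignment == orig[s.submission_id]
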