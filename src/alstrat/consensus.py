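"""Consensus clustering over many independent cluster-set submissions.

Each solver submits a partition of the subjects into clusters.  Evidence that
two subjects belong together is accumulated into a subject × subject
co-clustering matrix M with size-normalized weights,

    m_ij = Σ_s ln(p / c_s)   over submissions s co-clustering i and j,

where p is the cohort size and c_s the size of the shared cluster — smaller
clusters carry more weight, and the trivial one-cluster partition carries
none (ln 1 = 0).  Pair significance is assessed by permutation (subjects
reassigned to clusters of the original sizes) with a SAM-style FDR, the
significant pairs form a graph used to eyeball a plausible k, and the final
consensus labels come from k-means on the rows of M under the
1 − Pearson-correlation distance.  Core patients are the half of each cluster
closest to its centroid.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ClusterSet",
    "CoClusterMatrix",
    "PairFDR",
    "PairFDRGraph",
    "ConsensusResult",
    "build_cocluster_matrix",
    "pair_fdr",
    "significant_pair_graph",
    "consensus_kmeans",
    "core_patients",
    "suggest_k",
    "read_submissions",
    "write_submissions",
]


@dataclass
class ClusterSet:
    """One solver's partition: subject → opaque cluster label."""

    submission_id: str
    assignment: dict[str, object]

    def clusters(self) -> dict[object, list[str]]:
        out: dict[object, list[str]] = {}
        for subject, label in self.assignment.items():
            out.setdefault(label, []).append(subject)
        return out


@dataclass
class CoClusterMatrix:
    """Symmetric weighted co-clustering score matrix over an ordered subject list."""

    subjects: list[str]
    M: np.ndarray

    def __post_init__(self) -> None:
        p = len(self.subjects)
        if self.M.shape != (p, p):
            raise ValueError(f"matrix shape {self.M.shape} != ({p}, {p})")

    @property
    def p(self) -> int:
        return len(self.subjects)

    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.subjects)}

    def score(self, i: str, j: str) -> float:
        idx = self.index()
        return float(self.M[idx[i], idx[j]])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.M, index=self.subjects, columns=self.subjects).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CoClusterMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(subjects=[str(s) for s in df.index], M=df.to_numpy(dtype=float))


def _accumulate(
    M: np.ndarray, cluster_members: Iterable[Sequence[int]], p: int
) -> None:
    for idx in cluster_members:
        c = len(idx)
        if c < 2:
            continue
        w = math.log(p / c)
        if w == 0.0:
            continue
        ii = np.asarray(idx)
        M[np.ix_(ii, ii)] += w


def build_cocluster_matrix(
    submissions: Sequence[ClusterSet], subjects: Sequence[str]
) -> CoClusterMatrix:
    """Accumulate m_ij = Σ_s ln(p/c_s) over all submissions (natural log)."""
    if not submissions:
        raise ValueError("need at least one submission")
    subjects = list(subjects)
    known = set(subjects)
    index = {s: i for i, s in enumerate(subjects)}
    p = len(subjects)
    M = np.zeros((p, p))
    for sub in submissions:
        unknown = set(sub.assignment) - known
        if unknown:
            raise ValueError(
                f"submission {sub.submission_id}: unknown subjects {sorted(unknown)[:5]}"
            )
        _accumulate(
            M,
            ([index[s] for s in members] for members in sub.clusters().values()),
            p,
        )
    np.fill_diagonal(M, 0.0)
    return CoClusterMatrix(subjects=subjects, M=M)


@dataclass
class PairFDR:
    """Per-pair permutation FDR for the co-clustering scores."""

    matrix: CoClusterMatrix
    fdr: np.ndarray  # symmetric p×p, diagonal nan
    n_perm: int

    def pairs(self) -> pd.DataFrame:
        subs = self.matrix.subjects
        iu, ju = np.triu_indices(len(subs), k=1)
        return pd.DataFrame(
            {
                "subject_a": [subs[i] for i in iu],
                "subject_b": [subs[j] for j in ju],
                "score": self.matrix.M[iu, ju],
                "fdr": self.fdr[iu, ju],
            }
        )


def pair_fdr(
    matrix: CoClusterMatrix,
    submissions: Sequence[ClusterSet],
    n_perm: int = 100,
    seed: int | np.random.Generator | None = 0,
) -> PairFDR:
    """SAM-style FDR for every subject pair's co-clustering score.

    Each permutation reassigns every submission's subjects at random to
    clusters of the original sizes and recomputes M.  The FDR at an observed
    score m is (mean per-permutation count of permuted pair scores ≥ m) /
    (count of observed pair scores ≥ m), clipped to [0, 1]; each pair gets
    the FDR at its own score.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = matrix.p
    index = matrix.index()
    # fixed cluster-size layouts per submission
    layouts: list[tuple[np.ndarray, list[int]]] = []
    for sub in submissions:
        members = np.asarray([index[s] for s in sub.assignment], dtype=int)
        sizes = [len(m) for m in sub.clusters().values()]
        layouts.append((members, sizes))

    iu, ju = np.triu_indices(p, k=1)
    obs = matrix.M[iu, ju]
    perm_scores = np.empty(n_perm * len(obs))
    for b in range(n_perm):
        Mp = np.zeros((p, p))
        for members, sizes in layouts:
            shuffled = rng.permutation(members)
            groups, pos = [], 0
            for c in sizes:
                groups.append(shuffled[pos : pos + c])
                pos += c
            _accumulate(Mp, groups, p)
        np.fill_diagonal(Mp, 0.0)
        perm_scores[b * len(obs) : (b + 1) * len(obs)] = Mp[iu, ju]

    perm_sorted = np.sort(perm_scores)
    obs_sorted = np.sort(obs)
    n_false = len(perm_sorted) - np.searchsorted(perm_sorted, obs, side="left")
    n_true = len(obs_sorted) - np.searchsorted(obs_sorted, obs, side="left")
    fdr_flat = np.clip((n_false / n_perm) / np.maximum(n_true, 1), 0.0, 1.0)

    fdr = np.full((p, p), np.nan)
    fdr[iu, ju] = fdr_flat
    fdr[ju, iu] = fdr_flat
    return PairFDR(matrix=matrix, fdr=fdr, n_perm=n_perm)


@dataclass
class PairFDRGraph:
    """Graph whose edges are subject pairs co-clustered significantly often."""

    graph: nx.Graph
    threshold: float

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    def n_components(self) -> int:
        return nx.number_connected_components(self.graph) if self.graph.number_of_nodes() else 0

    def to_dot(self, path: str | Path | None = None) -> str:
        lines = ["graph cocluster {"]
        for a, b, data in sorted(self.graph.edges(data=True)):
            lines.append(f'  "{a}" -- "{b}" [fdr="{data.get("fdr", float("nan")):.6g}"];')
        lines.append("}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dot(cls, source: str | Path) -> "PairFDRGraph":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        g = nx.Graph()
        for m in re.finditer(r'"([^"]+)"\s*--\s*"([^"]+)"(?:\s*\[fdr="([^"]*)"\])?', text):
            a, b, f = m.groups()
            g.add_edge(a, b, fdr=float(f) if f else float("nan"))
        return cls(graph=g, threshold=float("nan"))

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)


def significant_pair_graph(result: PairFDR, threshold: float = 0.05) -> PairFDRGraph:
    """Edges = pairs with FDR ≤ threshold and a positive co-clustering score."""
    g = nx.Graph()
    subs = result.matrix.subjects
    iu, ju = np.triu_indices(len(subs), k=1)
    keep = (result.fdr[iu, ju] <= threshold) & (result.matrix.M[iu, ju] > 0)
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(subs[i], subs[j], fdr=float(result.fdr[i, j]), score=float(result.matrix.M[i, j]))
    return PairFDRGraph(graph=g, threshold=threshold)


# ---------------------------------------------------------------------------
# k-means on rows of M under the 1 - Pearson correlation distance


def _normalize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and L2-normalize rows; flag constant rows (undefined correlation)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    constant = norms == 0
    safe = np.where(constant, 1.0, norms)
    return Xc / safe[:, None], constant


def _corr_distance(Xn: np.ndarray, const_x: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Distance matrix 1 − corr(row, centroid); nan where undefined."""
    Cn, const_c = _normalize_rows(centroids)
    d = 1.0 - Xn @ Cn.T
    d[const_x, :] = np.nan
    d[:, const_c] = np.nan
    return d


@dataclass
class ConsensusResult:
    """Consensus labels (1..k), centroid rows of M, per-subject distances, core mask."""

    subjects: list[str]
    k: int
    labels: np.ndarray  # int array, values 1..k
    centroids: np.ndarray  # k × p rows in M-space
    distances: np.ndarray  # distance of each subject to its own centroid
    core_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def labels_dict(self) -> dict[str, int]:
        return {s: int(l) for s, l in zip(self.subjects, self.labels)}

    def core_dict(self) -> dict[str, bool]:
        return {s: bool(c) for s, c in zip(self.subjects, self.core_mask)}

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "subject_id": self.subjects,
                "cluster": self.labels,
                "distance": self.distances,
                "core": self.core_mask.astype(int),
            }
        ).to_csv(path, index=False)


def _assign_step(d: np.ndarray) -> np.ndarray:
    """Argmin distance per row with nan → tie-break to the lowest cluster index."""
    filled = np.where(np.isnan(d), np.inf, d)
    labels = np.argmin(filled, axis=1)
    labels[np.all(np.isinf(filled), axis=1)] = 0
    return labels


def consensus_kmeans(
    matrix: CoClusterMatrix,
    k: int,
    seed: int | None = 0,
    n_restarts: int = 10,
    max_iter: int = 100,
) -> ConsensusResult:
    """Lloyd k-means on rows of M with the 1 − Pearson correlation distance.

    Centroids are arithmetic means of member rows; the best of ``n_restarts``
    seeded initializations (total within-cluster distance) wins.  An emptied
    cluster is re-seeded from the subject farthest from its centroid; subjects
    with constant rows (undefined correlation) fall to the lowest cluster
    index.  Fully deterministic under a fixed seed.
    """
    p = matrix.p
    if not 1 <= k <= p:
        raise ValueError(f"k={k} out of range [1, {p}]")
    X = matrix.M
    Xn, const_x = _normalize_rows(X)
    rng = np.random.default_rng(seed)

    if k == 1:
        centroids = X.mean(axis=0, keepdims=True)
        d = _corr_distance(Xn, const_x, centroids)[:, 0]
        result = ConsensusResult(
            subjects=list(matrix.subjects),
            k=1,
            labels=np.ones(p, dtype=int),
            centroids=centroids,
            distances=np.nan_to_num(d, nan=1.0),
        )
        result.core_mask = core_patients(result)
        return result

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_restarts):
        centers = X[rng.choice(p, size=k, replace=False)].copy()
        labels = np.full(p, -1)
        for _ in range(max_iter):
            d = _corr_distance(Xn, const_x, centers)
            new_labels = _assign_step(d)
            # re-seed emptied clusters from the farthest subject
            for c in range(k):
                if not np.any(new_labels == c):
                    own = np.where(np.isnan(d), -np.inf, d)[np.arange(p), new_labels]
                    far = int(np.argmax(own))
                    centers[c] = X[far]
                    new_labels[far] = c
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for c in range(k):
                sel = labels == c
                if sel.any():  # re-seeding may have emptied another cluster
                    centers[c] = X[sel].mean(axis=0)
        d = _corr_distance(Xn, const_x, centers)
        own = np.nan_to_num(d[np.arange(p), labels], nan=1.0)
        cost = float(own.sum())
        if best is None or cost < best[0]:
            best = (cost, labels.copy(), centers.copy())

    cost, labels, centers = best
    d = _corr_distance(Xn, const_x, centers)
    own = np.nan_to_num(d[np.arange(p), labels], nan=1.0)
    result = ConsensusResult(
        subjects=list(matrix.subjects),
        k=k,
        labels=labels + 1,
        centroids=centers,
        distances=own,
    )
    result.core_mask = core_patients(result)
    return result


def core_patients(result: ConsensusResult) -> np.ndarray:
    """Flag, per cluster, the ⌈size/2⌉ subjects closest to their centroid.

    Distance ties are broken by subject order (stable sort).
    """
    mask = np.zeros(len(result.subjects), dtype=bool)
    for c in range(1, result.k + 1):
        idx = np.where(result.labels == c)[0]
        if len(idx) == 0:
            continue
        order = idx[np.argsort(result.distances[idx], kind="stable")]
        n_core = math.ceil(len(idx) / 2)
        mask[order[:n_core]] = True
    return mask


def suggest_k(
    matrix: CoClusterMatrix,
    graph: PairFDRGraph | None,
    k_range: Iterable[int],
    seed: int | None = 0,
    n_restarts: int = 5,
) -> pd.DataFrame:
    """Decision support for choosing k: FDR-graph components and silhouettes.

    Returns one row per candidate k with the connected-component count of the
    significant-pair graph (constant across k; 0 for an empty graph) and the
    mean silhouette under the correlation distance.  No automatic choice is
    made — k is picked by eye, as in the original analysis.
    """
    from sklearn.metrics import silhouette_score

    Xn, const_x = _normalize_rows(matrix.M)
    D = 1.0 - Xn @ Xn.T
    D[const_x, :] = 1.0
    D[:, const_x] = 1.0
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    n_comp = graph.n_components() if graph is not None else 0

    rows = []
    for k in k_range:
        res = consensus_kmeans(matrix, k, seed=seed, n_restarts=n_restarts)
        if k < 2 or len(set(res.labels)) < 2:
            sil = float("nan")
        else:
            sil = float(silhouette_score(D, res.labels, metric="precomputed"))
        rows.append({"k": k, "graph_components": n_comp, "mean_silhouette": sil})
    return pd.DataFrame(rows)


def read_submissions(path: str | Path) -> list[ClusterSet]:
    """Read a ``submission_id,subject_id,cluster_label`` CSV into ClusterSets."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for sid, grp in df.groupby("submission_id", sort=True):
        if grp["subject_id"].duplicated().any():
            raise ValueError(f"submission {sid}: duplicate subject")
        out.append(
            ClusterSet(
                submission_id=str(sid),
                assignment=dict(zip(grp["subject_id"], grp["cluster_label"])),
            )
        )
    return out


def write_submissions(submissions: Sequence[ClusterSet], path: str | Path) -> None:
    rows = [
        {"submission_id": sub.submission_id, "subject_id": s, "cluster_label": l}
        for sub in submissions
        for s, l in sub.assignment.items()
    ]
    pd.DataFrame(rows, columns=["submission_id", "subject_id", "cluster_label"]).to_csv(
        path, index=False
    )
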