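"""Assigning new patients to consensus clusters from clinical feature values.

The consensus clusters are defined by the solvers' partitions alone; this
module re-creates them from feature values: the most discriminating features
(default: top 20 at FDR ≤ 0.01%) are z-normalized against the training
cohort, each cluster gets the mean z-vector of its members as a profile, and
a new patient goes to the cluster whose profile has the highest uncentered
correlation

    u(x, y) = Σ xᵢ yᵢ / √(Σ xᵢ² · Σ yᵢ²)

with the patient's z-vector.  Ten-fold cross-validation — with feature
selection redone inside every training fold — estimates the assignment
accuracy.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureFDRResult, integrated_rank_fdr

__all__ = [
    "ProfileError",
    "ClusterProfile",
    "build_profiles",
    "uncentered_correlation",
    "assign",
    "crossval_accuracy",
]


class ProfileError(ValueError):
    """No usable discriminating features; relax fdr_cap or check the input."""


@dataclass
class ClusterProfile:
    """Discriminating features, training normalization and cluster centroids."""

    features: list[str]
    mean: pd.Series  # training mean per feature
    sd: pd.Series  # training SD per feature (all > 0)
    centroids: pd.DataFrame  # clusters × features, z-scale

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "features": self.features,
            "mean": self.mean.to_dict(),
            "sd": self.sd.to_dict(),
            "centroids": {str(c): row.to_dict() for c, row in self.centroids.iterrows()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ClusterProfile":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        feats = payload["features"]
        # JSON object keys are strings; restore integer cluster labels
        centroids = {
            (int(c) if c.lstrip("-").isdigit() else c): row
            for c, row in payload["centroids"].items()
        }
        return cls(
            features=feats,
            mean=pd.Series(payload["mean"]).reindex(feats),
            sd=pd.Series(payload["sd"]).reindex(feats),
            centroids=pd.DataFrame(centroids).T.reindex(columns=feats),
        )


def build_profiles(
    C: pd.DataFrame,
    labels: Mapping[str, object],
    fdr_result: FeatureFDRResult,
    max_features: int = 20,
    fdr_cap: float = 1e-4,
) -> ClusterProfile:
    """Select up to ``max_features`` features at FDR ≤ ``fdr_cap`` and profile clusters.

    Features are ranked by FDR, ties by descending statistic then name;
    zero-variance features are dropped with a warning (z-scores would be
    undefined).  Each feature is z-normalized by the training mean/SD over
    its non-missing values, and each cluster's centroid is the per-feature
    mean z of its members.
    """
    table = fdr_result.global_table
    cand = table[(table["family"] == "continuous") & (table["fdr"] <= fdr_cap)]
    cand = cand[cand["feature"].isin(C.index)]
    cand = cand.sort_values(
        ["fdr", "statistic", "feature"], ascending=[True, False, True], kind="stable"
    )
    selected: list[str] = []
    for feature in cand["feature"]:
        row = C.loc[feature].to_numpy(dtype=float)
        vals = row[~np.isnan(row)]
        if len(vals) < 2 or vals.std(ddof=1) == 0:
            warnings.warn(f"feature {feature!r} has zero variance; excluded from profiles")
            continue
        selected.append(feature)
        if len(selected) == max_features:
            break
    if not selected:
        raise ProfileError(
            f"no feature passes FDR ≤ {fdr_cap}; relax fdr_cap or lower max_features"
        )

    sub = C.loc[selected]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    Z = sub.sub(mean, axis=0).div(sd, axis=0)
    clusters = sorted(set(labels[str(s)] for s in C.columns))
    rows = {}
    for c in clusters:
        members = [s for s in C.columns if labels[str(s)] == c]
        rows[c] = Z[members].mean(axis=1)
    return ClusterProfile(
        features=selected,
        mean=mean,
        sd=sd,
        centroids=pd.DataFrame(rows).T.reindex(columns=selected),
    )


def uncentered_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Cosine-like similarity Σxy/√(Σx²Σy²) over pairwise-complete components."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    mask = ~(np.isnan(xa) | np.isnan(ya))
    if not mask.any():
        raise ValueError("no pairwise-complete components")
    xa, ya = xa[mask], ya[mask]
    nx, ny = np.sqrt(xa @ xa), np.sqrt(ya @ ya)
    if nx == 0 or ny == 0:
        raise ValueError("uncentered correlation undefined for a zero-norm vector")
    return float(xa @ ya / (nx * ny))


def assign(
    patient: Mapping[str, float] | pd.Series,
    profiles: ClusterProfile,
    min_coverage: float = 0.25,
) -> tuple[object | None, dict]:
    """Assign a patient to the highest-uncentered-correlation cluster.

    The patient's feature values are z-normalized with the *training*
    normalization.  At least ``min_coverage`` of the profile features must be
    observed, otherwise the patient is unassignable (``None``).  Correlation
    ties break to the lowest cluster index.
    """
    x = pd.Series(patient, dtype=float).reindex(profiles.features)
    observed = x.notna()
    if observed.sum() < max(1, math.ceil(min_coverage * len(profiles.features))):
        return None, {}
    z = ((x - profiles.mean) / profiles.sd).to_numpy(dtype=float)
    corrs: dict = {}
    for c in profiles.centroids.index:
        try:
            corrs[c] = uncentered_correlation(z, profiles.centroids.loc[c].to_numpy())
        except ValueError:
            continue
    if not corrs:
        return None, {}
    best = max(sorted(corrs), key=lambda c: corrs[c])  # ties → lowest cluster index
    return best, corrs


def _stratified_folds(
    subjects: Sequence[str],
    labels: Mapping[str, object],
    folds: int,
    rng: np.random.Generator,
) -> list[list[str]]:
    """Deal subjects into folds round-robin within each cluster (shuffled)."""
    out: list[list[str]] = [[] for _ in range(folds)]
    by_cluster: dict = {}
    for s in subjects:
        by_cluster.setdefault(labels[s], []).append(s)
    offset = 0
    for c in sorted(by_cluster):
        members = sorted(by_cluster[c])
        rng.shuffle(members)
        for i, s in enumerate(members):
            out[(offset + i) % folds].append(s)
        offset += len(members)
    return out


def crossval_accuracy(
    C: pd.DataFrame,
    labels: Mapping[str, object],
    D: pd.DataFrame | None = None,
    folds: int = 10,
    core_mask: Mapping[str, bool] | None = None,
    seed: int | None = 0,
    n_perm: int = 50,
    max_features: int = 20,
    fdr_cap: float = 1e-4,
    min_coverage: float = 0.25,
) -> tuple[float, pd.DataFrame]:
    """Cross-validated assignment accuracy against the consensus labels.

    Per fold, the held-out patients are removed *before* the differential
    features are determined: the rank FDR and the cluster profiles are rebuilt
    on the training subjects only, then the held-out patients are assigned.
    Folds are stratified by cluster; a fold whose training set misses a
    cluster is skipped with a warning.  With ``core_mask``, accuracy counts
    only core patients.  Returns (accuracy, per-subject detail).
    """
    if folds < 2:
        raise ValueError("folds must be at least 2")
    rng = np.random.default_rng(seed)
    subjects = [str(s) for s in C.columns]
    fold_sets = _stratified_folds(subjects, labels, folds, rng)
    all_clusters = set(labels[s] for s in subjects)

    records = []
    for fold_idx, test in enumerate(fold_sets):
        train = [s for s in subjects if s not in set(test)]
        if set(labels[s] for s in train) != all_clusters:
            warnings.warn(f"fold {fold_idx}: a cluster is absent from training; skipped")
            continue
        C_train = C[train]
        D_train = D[train] if D is not None else None
        g_train = {s: labels[s] for s in train}
        fdr_res = integrated_rank_fdr(
            C_train, D_train, g_train, n_perm=n_perm, seed=rng
        )
        try:
            profile = build_profiles(
                C_train, g_train, fdr_res, max_features=max_features, fdr_cap=fdr_cap
            )
        except ProfileError:
            warnings.warn(f"fold {fold_idx}: no discriminating feature; skipped")
            continue
        for s in test:
            predicted, _ = assign(C[s], profile, min_coverage=min_coverage)
            records.append(
                {
                    "subject_id": s,
                    "fold": fold_idx,
                    "true_cluster": labels[s],
                    "assigned_cluster": predicted,
                    "core": bool(core_mask[s]) if core_mask is not None else True,
                }
            )

    detail = pd.DataFrame(
        records,
        columns=["subject_id", "fold", "true_cluster", "assigned_cluster", "core"],
    )
    scored = detail[detail["core"] & detail["assigned_cluster"].notna()]
    if scored.empty:
        return float("nan"), detail
    accuracy = float(
        (scored["assigned_cluster"] == scored["true_cluster"]).mean()
    )
    return accuracy, detail
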