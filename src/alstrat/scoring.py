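"""Challenge scoring: raw metrics, permutation-null z-scores, combined scores.

Prediction sets are scored against ground truth with RMSD, Pearson correlation
and the concordance index (CI); survival predictions are scored by CI at the
12/18/24-month horizons.  Each raw metric is standardized against an empirical
null obtained by shuffling the assignment of ground-truth values to subjects
(100,000 shuffles by default), z = (score − null mean) / null SD, and combined

    z_slope    = z_CI + z_PCC − z_RMSD
    z_survival = z_12 + z_18 + z_24

Head-to-head comparison of two prediction sets uses the BT score: the
percentage of subject bootstrap resamples in which one set's combined z
strictly exceeds the other's (nulls held fixed at the full-set values).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "UndefinedMetricError",
    "SubjectMismatchError",
    "SlopePredictionSet",
    "SurvivalPredictionSet",
    "ScoreReport",
    "rmsd",
    "pearson",
    "concordance_index",
    "permutation_null",
    "combined_score",
    "bootstrap_compare",
    "read_slope_predictions",
    "read_survival_predictions",
]

SURVIVAL_HORIZONS_MONTHS = (12, 18, 24)

SlopePredictionSet = Mapping[str, float]
SurvivalPredictionSet = Mapping[str, tuple[float, float, float]]


class UndefinedMetricError(ValueError):
    """The metric is undefined on this input (constant vector, no comparable pairs...)."""


class SubjectMismatchError(ValueError):
    """Prediction and truth cover different subject sets."""


def _as_arrays(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pred, Mapping) or isinstance(truth, Mapping):
        if set(pred) != set(truth):
            raise SubjectMismatchError(
                f"subject sets differ: {sorted(set(pred) ^ set(truth))[:5]} ..."
            )
        subjects = sorted(pred)
        return (
            np.asarray([pred[s] for s in subjects], dtype=float),
            np.asarray([truth[s] for s in subjects], dtype=float),
        )
    p, t = np.asarray(pred, dtype=float), np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise SubjectMismatchError(f"length mismatch: {p.shape} vs {t.shape}")
    return p, t


def rmsd(pred, truth) -> float:
    """Root mean square deviation between predictions and truth."""
    p, t = _as_arrays(pred, truth)
    return float(np.sqrt(np.mean((p - t) ** 2)))


def pearson(pred, truth) -> float:
    """Pearson product-moment correlation; undefined for constant vectors."""
    p, t = _as_arrays(pred, truth)
    if len(p) < 2:
        raise UndefinedMetricError("need at least 2 subjects for correlation")
    if np.ptp(p) == 0 or np.ptp(t) == 0:
        raise UndefinedMetricError("correlation undefined for a constant vector")
    pc = p - p.mean()
    tc = t - t.mean()
    return float(pc @ tc / np.sqrt((pc @ pc) * (tc @ tc)))


def concordance_index(
    pred: Sequence[float],
    actual: Sequence[float],
    events: Sequence[bool] | None = None,
) -> float:
    """Concordance index with Harrell censoring and tie handling.

    A pair (i, j) is comparable when the actual times differ and, under
    censoring, the smaller time belongs to an event (a censored subject is
    only known to survive *past* its time).  A comparable pair scores 1 when
    predictions order the same way as the actual times, 0.5 on a prediction
    tie, 0 otherwise; the CI is the mean over comparable pairs.  Without
    censoring or ties this is exactly 2/(n(n−1)) Σ_{i<j} h(i, j).
    """
    p = np.asarray(pred, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise SubjectMismatchError(f"length mismatch: {p.shape} vs {a.shape}")
    n = len(p)
    if n < 2:
        raise UndefinedMetricError("need at least 2 subjects")
    adiff = a[:, None] - a[None, :]  # a_i - a_j
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    if events is None:
        comparable = upper & (adiff != 0)
    else:
        e = np.asarray(events, dtype=bool)
        # smaller actual time must be an event
        comparable = upper & (
            ((adiff < 0) & e[:, None]) | ((adiff > 0) & e[None, :])
        )
    m = int(comparable.sum())
    if m == 0:
        raise UndefinedMetricError("no comparable pairs")
    pdiff = p[:, None] - p[None, :]
    concordant = (np.sign(pdiff) == np.sign(adiff)) & (pdiff != 0)
    tied = pdiff == 0
    h = np.where(concordant, 1.0, np.where(tied, 0.5, 0.0))
    return float(h[comparable].sum() / m)


def permutation_null(
    metric: Callable[..., float],
    pred,
    truth,
    n_perm: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Mean and SD of ``metric`` over shuffles of the truth-to-subject assignment.

    ``truth`` may be a single array or a tuple of parallel arrays (e.g. times
    and event flags), shuffled jointly.  Shuffles on which the metric is
    undefined are dropped; more than 50% undefined is an error.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parts = truth if isinstance(truth, tuple) else (truth,)
    parts = tuple(np.asarray(t) for t in parts)
    n = len(parts[0])
    vals = np.empty(n_perm)
    bad = 0
    for b in range(n_perm):
        idx = rng.permutation(n)
        try:
            vals[b] = metric(pred, *(t[idx] for t in parts))
        except UndefinedMetricError:
            vals[b] = np.nan
            bad += 1
    if bad > n_perm // 2:
        raise UndefinedMetricError(
            f"metric undefined on {bad}/{n_perm} shuffles"
        )
    ok = vals[~np.isnan(vals)]
    return float(ok.mean()), float(ok.std(ddof=1))


@dataclass
class ScoreReport:
    """Raw metrics, permutation z-scores and the combined challenge score."""

    kind: str  # "slope" | "survival"
    metrics: dict[str, float]
    null_mean: dict[str, float]
    null_sd: dict[str, float]
    z: dict[str, float] = field(default_factory=dict)
    combined: float = float("nan")
    n_permutations: int = 0

    def finalize(self) -> "ScoreReport":
        for name, score in self.metrics.items():
            sd = self.null_sd[name]
            if sd == 0:
                raise UndefinedMetricError(f"null SD of {name} is zero")
            self.z[name] = (score - self.null_mean[name]) / sd
        self.combined = _combine(self.kind, self.z)
        return self

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kind": self.kind,
            "metrics": self.metrics,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "combined": self.combined,
            "n_permutations": self.n_permutations,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _combine(kind: str, z: Mapping[str, float]) -> float:
    if kind == "slope":
        return z["ci"] + z["pcc"] - z["rmsd"]
    if kind == "survival":
        return z["ci12"] + z["ci18"] + z["ci24"]
    raise ValueError(f"unknown score kind {kind!r}")


def _slope_raw(p: np.ndarray, t: np.ndarray) -> dict[str, float]:
    return {"rmsd": rmsd(p, t), "pcc": pearson(p, t), "ci": concordance_index(p, t)}


def _survival_raw(
    probs: np.ndarray, time: np.ndarray, event: np.ndarray
) -> dict[str, float]:
    return {
        f"ci{h}": concordance_index(probs[:, i], time, event)
        for i, h in enumerate(SURVIVAL_HORIZONS_MONTHS)
    }


def combined_score(
    kind: str,
    pred: SlopePredictionSet | SurvivalPredictionSet,
    truth: Mapping,
    n_perm: int = 100_000,
    seed: int | None = 0,
) -> ScoreReport:
    """Score one prediction set: raw metrics, permutation nulls, z, combined.

    For ``kind="slope"``, ``truth`` maps subject → slope; for
    ``kind="survival"`` it maps subject → (time_days, event).  All metrics
    share each shuffle, as the null is over truth-to-subject assignments.
    """
    if set(pred) != set(truth):
        raise SubjectMismatchError(
            f"subject sets differ: {sorted(set(pred) ^ set(truth))[:5]} ..."
        )
    subjects = sorted(pred)
    rng = np.random.default_rng(seed)
    if kind == "slope":
        p = np.asarray([pred[s] for s in subjects], dtype=float)
        t = np.asarray([truth[s] for s in subjects], dtype=float)
        raw = _slope_raw(p, t)
        draw = lambda idx: _slope_raw(p, t[idx])  # noqa: E731
    elif kind == "survival":
        probs = np.asarray([pred[s] for s in subjects], dtype=float)
        time = np.asarray([truth[s][0] for s in subjects], dtype=float)
        event = np.asarray([bool(truth[s][1]) for s in subjects])
        raw = _survival_raw(probs, time, event)
        draw = lambda idx: _survival_raw(probs, time[idx], event[idx])  # noqa: E731
    else:
        raise ValueError(f"unknown score kind {kind!r}")

    n = len(subjects)
    null = {name: np.empty(n_perm) for name in raw}
    for b in range(n_perm):
        sample = draw(rng.permutation(n))
        for name, v in sample.items():
            null[name][b] = v
    report = ScoreReport(
        kind=kind,
        metrics=raw,
        null_mean={k: float(v.mean()) for k, v in null.items()},
        null_sd={k: float(v.std(ddof=1)) for k, v in null.items()},
        n_permutations=n_perm,
    )
    return report.finalize()


def _combined_with_fixed_null(
    kind: str, raw: Mapping[str, float], report: ScoreReport
) -> float:
    z = {
        name: (raw[name] - report.null_mean[name]) / report.null_sd[name]
        for name in raw
    }
    return _combine(kind, z)


def bootstrap_compare(
    report_a: ScoreReport,
    report_b: ScoreReport,
    pred_a: Mapping,
    pred_b: Mapping,
    truth: Mapping,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> float:
    """BT score: % of subject bootstrap resamples where A's combined z > B's.

    The permutation nulls are held fixed at the full-set values from the two
    reports; only the raw metrics are recomputed per resample.  Resamples on
    which either side's metrics are undefined count as non-wins.
    """
    if report_a.kind != report_b.kind:
        raise ValueError("reports have different kinds")
    kind = report_a.kind
    subjects = sorted(truth)
    n = len(subjects)
    rng = np.random.default_rng(seed)
    if kind == "slope":
        pa = np.asarray([pred_a[s] for s in subjects], dtype=float)
        pb = np.asarray([pred_b[s] for s in subjects], dtype=float)
        t = np.asarray([truth[s] for s in subjects], dtype=float)
        raw_at = lambda p, idx: _slope_raw(p[idx], t[idx])  # noqa: E731
    else:
        pa = np.asarray([pred_a[s] for s in subjects], dtype=float)
        pb = np.asarray([pred_b[s] for s in subjects], dtype=float)
        time = np.asarray([truth[s][0] for s in subjects], dtype=float)
        event = np.asarray([bool(truth[s][1]) for s in subjects])
        raw_at = lambda p, idx: _survival_raw(p[idx], time[idx], event[idx])  # noqa: E731

    wins = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            za = _combined_with_fixed_null(kind, raw_at(pa, idx), report_a)
            zb = _combined_with_fixed_null(kind, raw_at(pb, idx), report_b)
        except UndefinedMetricError:
            continue
        if za > zb:
            wins += 1
    return 100.0 * wins / n_boot


def read_slope_predictions(path: str | Path) -> dict[str, float]:
    import pandas as pd

    df = pd.read_csv(path, dtype={"subject_id": str})
    return dict(zip(df["subject_id"], df["slope"].astype(float)))


def read_survival_predictions(path: str | Path) -> dict[str, tuple[float, float, float]]:
    import pandas as pd

    df = pd.read_csv(path, dtype={"subject_id": str})
    return {
        row.subject_id: (float(row.p12), float(row.p18), float(row.p24))
        for row in df.itertuples()
    }
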