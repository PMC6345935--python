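"""Synthetic longitudinal ALS cohorts and solver submissions with planted structure.

Real pooled clinical-trial and registry records are access-restricted, so
every other module is exercised on synthetic cohorts that emulate their
shape: long-format visit records with per-cluster linear ALSFRS-R
trajectories (clipped to the 0–48 scale), exponentially distributed survival
with administrative censoring, cluster-shifted continuous laboratory-style
features among null features, cluster-biased discrete features, jittered
visit schedules and record-level missingness.  Solver submissions are the
planted partition degraded by uniform relabeling noise, optional
split/merge distortions, plus fully random partitions.

The default parameters mirror the published cluster phenotypes: four
clusters with baseline total scores 40.25 / 40 / 29 / 35.75 and monthly
slopes −0.48 / −0.93 / −0.65 / −1.05 (slow, early-stage, late-stage and
fast progressors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import ClinicalTable, FeatureDictionary
from .consensus import ClusterSet

__all__ = [
    "CohortSpec",
    "SolverSpec",
    "SyntheticCohort",
    "generate_cohort",
    "generate_solver_submissions",
]

ALSFRS_FEATURE = "ALSFRS_R_Total"
DEATH_FEATURE = "death_days"
ALSFRS_MAX = 48.0


@dataclass
class CohortSpec:
    """Conditions for one synthetic cohort; defaults are the study conditions."""

    n_subjects: int = 400
    k_true: int = 4
    cluster_weights: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    baseline_alsfrs: Sequence[float] = (40.25, 40.0, 29.0, 35.75)
    slope_per_month: Sequence[float] = (-0.48, -0.93, -0.65, -1.05)
    residual_sd: float = 1.0
    # events/day; medians ≈ 3.8y / 2.5y / 1.5y / 1.2y, matching the spread of
    # published per-cluster survival
    hazard_per_day: Sequence[float] = (
        log(2) / 1400,
        log(2) / 900,
        log(2) / 550,
        log(2) / 440,
    )
    censor_day: int = 730
    n_planted_continuous: int = 5
    n_null_continuous: int = 50
    effect_size_sd: float = 1.0
    n_discrete: int = 5
    discrete_categories: int = 3
    discrete_bias: float = 0.6  # probability of the cluster-favored category
    visit_interval_days: float = 30.0
    visit_jitter_days: float = 5.0
    followup_days: int = 365
    missingness: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        k = self.k_true
        for name in ("cluster_weights", "baseline_alsfrs", "slope_per_month", "hazard_per_day"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} must have length k_true={k}")
        if abs(sum(self.cluster_weights) - 1.0) > 1e-9:
            raise ValueError("cluster_weights must sum to 1")
        if any(h < 0 for h in self.hazard_per_day):
            raise ValueError("hazards must be nonnegative")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must be in [0, 1)")


@dataclass
class SolverSpec:
    """Conditions for the ensemble of synthetic solver submissions."""

    n_solvers: int = 30
    label_noise: float = 0.2  # fraction of subjects relabeled uniformly
    split_merge_prob: float = 0.0
    n_random_solvers: int = 3
    seed: int = 0

    def validate(self) -> None:
        for name in ("label_noise", "split_merge_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its planted ground truth."""

    table: ClinicalTable
    dictionary: FeatureDictionary
    labels: dict[str, int]  # subject → planted cluster (1..k)
    slopes: dict[str, float]  # planted monthly slope per subject
    survival: dict[str, tuple[int, bool]]  # (time_days, event)
    planted_continuous: list[str] = field(default_factory=list)
    null_continuous: list[str] = field(default_factory=list)
    discrete_features: list[str] = field(default_factory=list)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.labels)


def _effect_pattern(feature_idx: int, k: int) -> np.ndarray:
    """Per-cluster mean shift pattern (in SD units, scaled by effect size later).

    Feature f elevates cluster ``f mod k`` against the rest — a one-vs-rest
    layout so every cluster is separable from every other on some feature.
    """
    pattern = -np.ones(k) / (k - 1) if k > 1 else np.zeros(1)
    pattern[feature_idx % k] = 1.0
    return pattern


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a long-format cohort with planted clusters; reproducible by seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    k = spec.k_true
    n = spec.n_subjects
    width = len(str(n))
    subjects = [f"S{i:0{width}d}" for i in range(1, n + 1)]
    clusters = rng.choice(k, size=n, p=np.asarray(spec.cluster_weights)) + 1

    dictionary = FeatureDictionary()
    dictionary.add(ALSFRS_FEATURE, "continuous", "points")
    dictionary.add(DEATH_FEATURE, "continuous", "days")
    planted = [f"lab_planted_{i:02d}" for i in range(spec.n_planted_continuous)]
    nulls = [f"lab_null_{i:02d}" for i in range(spec.n_null_continuous)]
    discretes = [f"cat_feature_{i:02d}" for i in range(spec.n_discrete)]
    for f in planted + nulls:
        dictionary.add(f, "continuous", "arbitrary")
    for f in discretes:
        dictionary.add(f, "discrete", "")

    rows: list[tuple[str, str, str, int]] = []
    labels: dict[str, int] = {}
    slopes: dict[str, float] = {}
    survival: dict[str, tuple[int, bool]] = {}

    for subject, cluster in zip(subjects, clusters):
        c = cluster - 1
        labels[subject] = int(cluster)
        slope = spec.slope_per_month[c]
        baseline = spec.baseline_alsfrs[c]
        slopes[subject] = float(slope)

        hazard = spec.hazard_per_day[c]
        death_day = int(np.ceil(rng.exponential(1 / hazard))) if hazard > 0 else None
        event = death_day is not None and death_day <= spec.censor_day

        # jittered visit schedule over the follow-up year, truncated at death
        horizon = spec.followup_days if not event else min(spec.followup_days, death_day)
        visit_days: list[int] = []
        day = 0.0
        while day <= horizon:
            visit_days.append(int(round(day)))
            step = rng.normal(spec.visit_interval_days, spec.visit_jitter_days)
            day += max(step, 7.0)
        for d in visit_days:
            value = baseline + slope * (d / 365 * 12)
            if spec.residual_sd > 0:
                value += rng.normal(0.0, spec.residual_sd)
            value = float(np.clip(value, 0.0, ALSFRS_MAX))
            rows.append((subject, ALSFRS_FEATURE, repr(value), d))

        if event:
            rows.append((subject, DEATH_FEATURE, str(death_day), death_day))
            survival[subject] = (death_day, True)
        else:
            survival[subject] = (max(visit_days), False)

        for i, feature in enumerate(planted):
            shift = spec.effect_size_sd * _effect_pattern(i, k)[c]
            value = rng.normal(shift, 1.0)
            rows.append((subject, feature, repr(float(value)), int(rng.integers(0, 92))))
        for feature in nulls:
            value = rng.normal(0.0, 1.0)
            rows.append((subject, feature, repr(float(value)), int(rng.integers(0, 92))))
        for i, feature in enumerate(discretes):
            favored = (c + i) % spec.discrete_categories
            probs = np.full(
                spec.discrete_categories,
                (1 - spec.discrete_bias) / (spec.discrete_categories - 1),
            )
            probs[favored] = spec.discrete_bias
            cat = rng.choice(spec.discrete_categories, p=probs)
            rows.append((subject, feature, f"level_{cat}", 0))

    if spec.missingness > 0:
        protected = {ALSFRS_FEATURE, DEATH_FEATURE}
        keep = rng.random(len(rows)) >= spec.missingness
        rows = [r for r, k_ in zip(rows, keep) if k_ or r[1] in protected]

    df = pd.DataFrame(rows, columns=["subject_id", "feature_name", "value", "delta_days"])
    return SyntheticCohort(
        table=ClinicalTable(df),
        dictionary=dictionary,
        labels=labels,
        slopes=slopes,
        survival=survival,
        planted_continuous=planted,
        null_continuous=nulls,
        discrete_features=discretes,
    )


def _split_or_merge(
    assignment: dict[str, int], rng: np.random.Generator
) -> dict[str, int]:
    labels = sorted(set(assignment.values()))
    if rng.random() < 0.5 and len(labels) >= 2:  # merge two random clusters
        a, b = rng.choice(labels, size=2, replace=False)
        return {s: (a if l == b else l) for s, l in assignment.items()}
    # split one random cluster into two halves
    target = int(rng.choice(labels))
    members = sorted(s for s, l in assignment.items() if l == target)
    rng.shuffle(members)
    new_label = max(labels) + 1
    moved = set(members[: len(members) // 2])
    return {s: (new_label if s in moved else l) for s, l in assignment.items()}


def generate_solver_submissions(
    labels: dict[str, int], spec: SolverSpec
) -> list[ClusterSet]:
    """Noisy copies of the planted partition plus fully random partitions."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    subjects = sorted(labels)
    k = len(set(labels.values()))
    out: list[ClusterSet] = []
    for i in range(spec.n_solvers):
        assignment = dict(labels)
        if spec.label_noise > 0:
            flip = rng.random(len(subjects)) < spec.label_noise
            new = rng.integers(1, k + 1, size=len(subjects))
            for s, f, l in zip(subjects, flip, new):
                if f:
                    assignment[s] = int(l)
        if spec.split_merge_prob > 0 and rng.random() < spec.split_merge_prob:
            assignment = _split_or_merge(assignment, rng)
        out.append(ClusterSet(submission_id=f"solver_{i + 1:02d}", assignment=assignment))
    for i in range(spec.n_random_solvers):
        random_labels = rng.integers(1, k + 1, size=len(subjects))
        out.append(
            ClusterSet(
                submission_id=f"random_{i + 1:02d}",
                assignment={s: int(l) for s, l in zip(subjects, random_labels)},
            )
        )
    return out
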