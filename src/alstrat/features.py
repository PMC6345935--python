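"""Discriminating clinical features across consensus clusters.

Longitudinal records are first summarized per patient and time window
(0–3 and 3–12 months): continuous features by mean/min/max, discrete ones by
the modal value.  Features differentially distributed across clusters are
then found with a permutation-rank FDR scheme:

1. per family, compute an observed statistic per feature (one-way ANOVA F for
   continuous rows, Fisher's exact test for discrete rows) plus the same
   statistic on 100 within-row value shuffles;
2. convert observed and permuted statistics to relative ranks within the
   family's pooled permutation distribution (higher = more extreme);
3. pool ranks across both families and estimate a SAM-style FDR:
   FDR(r) = (mean per-shuffle count of permuted ranks ≥ r) /
   (count of observed ranks ≥ r), monotonized q-value style.

Pairwise cluster contrasts (Welch t-tests, same permutation scheme) are run
only for globally significant continuous features — the "ANOVA trick" that
keeps the multiple-testing burden small — and collapsed into a per-cluster
rank heatmap: each significant win raises a cluster's rank by 1 and lowers
the loser's by 1, then every feature row is linearly rescaled to [−1, +1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .cohort import (
    ClinicalTable,
    EARLY_WINDOW,
    FeatureDictionary,
    OUTCOME_WINDOW,
    TimeWindow,
)

__all__ = [
    "FeatureSummaryMatrix",
    "FeatureFDRResult",
    "summarize_features",
    "anova_statistic",
    "fisher_statistic",
    "integrated_rank_fdr",
    "pairwise_ttest_fdr",
    "heatmap_matrix",
    "feature_usage_tally",
    "feature_usage_by_group",
]

DEFAULT_WINDOWS = (EARLY_WINDOW, OUTCOME_WINDOW)
DEFAULT_STATS = ("mean", "min", "max")


@dataclass
class FeatureSummaryMatrix:
    """Per-window patient summaries: C continuous rows, D discrete rows.

    Rows are features (continuous rows are named ``feature:stat``), columns
    are subjects; missing summaries are NaN.
    """

    C: pd.DataFrame
    D: pd.DataFrame
    window_tag: str

    def __post_init__(self) -> None:
        if len(self.C.columns) and len(self.D.columns):
            if list(self.C.columns) != list(self.D.columns):
                raise ValueError("C and D must share the subject ordering")

    @property
    def subjects(self) -> list[str]:
        cols = self.C.columns if len(self.C.columns) else self.D.columns
        return [str(c) for c in cols]


def _modal(values: pd.Series) -> object:
    """Most frequent value; ties broken by lexicographically smallest."""
    counts = values.value_counts()
    top = counts.max()
    return sorted(counts[counts == top].index)[0]


def summarize_features(
    table: ClinicalTable,
    dictionary: FeatureDictionary,
    windows: Sequence[TimeWindow] = DEFAULT_WINDOWS,
    stats: Sequence[str] = DEFAULT_STATS,
    exclude: Sequence[str] = (),
) -> dict[str, FeatureSummaryMatrix]:
    """Summarize longitudinal values per (window, patient); one matrix per window.

    Continuous features yield one row per (feature, stat) over in-window
    values; discrete features yield the modal in-window value.  Subjects with
    no in-window record are missing (NaN).
    """
    subjects = table.subjects()
    df = table.df[~table.df["feature_name"].isin(set(exclude))]
    out: dict[str, FeatureSummaryMatrix] = {}
    for w in windows:
        sub = df[(df["delta_days"] >= w.start_day) & (df["delta_days"] <= w.end_day)]
        cont_rows: dict[str, pd.Series] = {}
        disc_rows: dict[str, pd.Series] = {}
        for feature, grp in sub.groupby("feature_name", sort=True):
            feature = str(feature)
            if dictionary.is_continuous(feature):
                vals = grp.assign(v=pd.to_numeric(grp["value"]))
                agg = vals.groupby("subject_id")["v"].agg(list(stats))
                for stat in stats:
                    cont_rows[f"{feature}:{stat}"] = agg[stat]
            else:
                disc_rows[feature] = grp.groupby("subject_id")["value"].agg(_modal)
        C = pd.DataFrame(cont_rows).T.reindex(columns=subjects)
        D = pd.DataFrame(disc_rows, dtype=object).T.reindex(columns=subjects)
        out[w.tag] = FeatureSummaryMatrix(C=C, D=D, window_tag=w.tag)
    return out


# ---------------------------------------------------------------------------
# test statistics


def _design_codes(g: Mapping[str, object], subjects: Sequence[str]) -> tuple[np.ndarray, list]:
    clusters = sorted(set(g[s] for s in subjects))
    lookup = {c: i for i, c in enumerate(clusters)}
    return np.asarray([lookup[g[s]] for s in subjects]), clusters


def _batch_anova_f(V: np.ndarray, gcodes: np.ndarray) -> np.ndarray:
    """One-way ANOVA F per row of V (no missing values); rows share ``gcodes``.

    Groups are the distinct codes present; returns NaN where the F ratio is
    0/0 and +inf for perfect separation (zero within-group variance).
    """
    present = np.unique(gcodes)
    J = len(present)
    n = V.shape[1]
    if J < 2 or n - J < 1:
        return np.full(V.shape[0], np.nan)
    G = (gcodes[:, None] == present[None, :]).astype(float)  # n × J
    counts = G.sum(axis=0)
    sums = V @ G
    means = sums / counts
    grand = V.sum(axis=1) / n
    ssb = ((means - grand[:, None]) ** 2 * counts).sum(axis=1)
    sst = (V**2).sum(axis=1) - n * grand**2
    ssw = np.maximum(sst - ssb, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (J - 1)) / (ssw / (n - J))
    F[(ssw == 0) & (ssb > 0)] = np.inf
    F[(ssw == 0) & (ssb == 0)] = np.nan
    return F


def anova_statistic(values: Sequence[float], g: np.ndarray | Sequence) -> float:
    """Classical one-way ANOVA F on the non-missing entries of one feature row."""
    x = np.asarray(values, dtype=float)
    codes = np.asarray(pd.factorize(np.asarray(g))[0])
    obs = ~np.isnan(x)
    x, codes = x[obs], codes[obs]
    if len(np.unique(codes)) < 2:
        return float("nan")
    return float(_batch_anova_f(x[None, :], codes)[0])


def _table_logprob(tbl: np.ndarray) -> float:
    """Log hypergeometric probability of an R×C table given its margins."""
    r = tbl.sum(axis=1)
    c = tbl.sum(axis=0)
    n = tbl.sum()
    return float(
        gammaln(r + 1).sum()
        + gammaln(c + 1).sum()
        - gammaln(n + 1)
        - gammaln(tbl + 1).sum()
    )


def _enumeration_cost_ok(rows: np.ndarray, cols: np.ndarray, limit: int) -> bool:
    """Cheap bound on enumeration work: Π_j C(c_j + R − 1, R − 1) ≤ limit."""
    R = len(rows)
    log_bound = sum(
        gammaln(cj + R) - gammaln(cj + 1) - gammaln(R) for cj in cols[:-1]
    )
    return log_bound <= math.log(limit)


def _column_fills(remaining: list[int], total: int):
    """All ways to place ``total`` in a column without exceeding row remainders."""
    if len(remaining) == 1:
        if 0 <= total <= remaining[0]:
            yield (total,)
        return
    for x in range(min(remaining[0], total) + 1):
        for rest in _column_fills(remaining[1:], total - x):
            yield (x,) + rest


def _enumerate_logprobs(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Log probability of every table with the given margins (small tables)."""
    out: list[float] = []

    def recurse(rem_rows: list[int], rem_cols: list[int], acc: float) -> None:
        if len(rem_cols) == 1:
            tbl = np.asarray(rem_rows)
            acc2 = acc - gammaln(tbl + 1).sum()
            out.append(acc2)
            return
        for col in _column_fills(rem_rows, rem_cols[0]):
            recurse(
                [r - x for r, x in zip(rem_rows, col)],
                rem_cols[1:],
                acc - gammaln(np.asarray(col) + 1).sum(),
            )

    base = float(gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(rows.sum() + 1))
    recurse(list(rows), list(cols), base)
    return np.asarray(out)


class _FisherReference:
    """Reusable null for the Freeman–Halton p at fixed margins.

    Exact when the number of tables is tractable; otherwise a seeded Monte
    Carlo sample of tables drawn by permuting the design labels.  Margins are
    invariant under within-row value shuffles, so one reference serves a
    feature's observed statistic and all its permutations.
    """

    _TOL = 1e-9

    def __init__(
        self,
        x_codes: np.ndarray,
        n_cat: int,
        g_codes: np.ndarray,
        J: int,
        rng: np.random.Generator,
        exact_limit: int = 20_000,
        mc_iters: int = 2_000,
    ) -> None:
        self.n_cat, self.J = n_cat, J
        rows = np.bincount(x_codes, minlength=n_cat)
        cols = np.bincount(g_codes, minlength=J)
        self.exact = _enumeration_cost_ok(rows, cols, exact_limit)
        if self.exact:
            logps = _enumerate_logprobs(rows, cols)
            order = np.argsort(logps)
            self._logps = logps[order]
            self._cum = np.cumsum(np.exp(self._logps))
        else:
            sims = np.empty(mc_iters)
            for b in range(mc_iters):
                perm = rng.permutation(g_codes)
                tbl = np.bincount(x_codes * J + perm, minlength=n_cat * J).reshape(
                    n_cat, J
                )
                sims[b] = _table_logprob(tbl)
            self._sims = np.sort(sims)
            self._iters = mc_iters

    def p_value(self, logp_obs: float) -> float:
        if self.exact:
            i = np.searchsorted(self._logps, logp_obs + self._TOL, side="right")
            return float(min(self._cum[i - 1], 1.0)) if i > 0 else 0.0
        hits = np.searchsorted(self._sims, logp_obs + self._TOL, side="right")
        return float((1 + hits) / (1 + self._iters))


def fisher_statistic(
    values: Sequence,
    g: Sequence,
    seed: int | np.random.Generator | None = 0,
    exact_limit: int = 20_000,
    mc_iters: int = 2_000,
) -> float:
    """Fisher's exact test p-value on the category × cluster table of one row.

    Two-sided by table probability (the Freeman–Halton convention): the
    p-value sums the probabilities of all tables with the observed margins
    that are no more probable than the observed one.  For margins with an
    intractable table count, a seeded Monte Carlo estimate of the same
    quantity is returned.  Missing values are dropped pairwise.
    """
    vals = pd.Series(list(values), dtype=object)
    mask = vals.notna().to_numpy()
    codes_g = np.asarray(pd.factorize(np.asarray(g))[0])[mask]
    codes_x, cats = pd.factorize(vals[mask].astype(str), sort=True)
    n_cat, J = len(cats), len(np.unique(codes_g))
    if n_cat < 2 or J < 2:
        return float("nan")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ref = _FisherReference(codes_x, n_cat, codes_g, J, rng, exact_limit, mc_iters)
    tbl = np.bincount(codes_x * J + codes_g, minlength=n_cat * J).reshape(n_cat, J)
    return ref.p_value(_table_logprob(tbl))


# ---------------------------------------------------------------------------
# integrated permutation-rank FDR


def _relative_ranks(stats: np.ndarray, pooled_sorted: np.ndarray) -> np.ndarray:
    """Fraction of the pooled permutation distribution strictly below each value.

    Strict counting lets a statistic beyond the whole permuted pool reach
    rank 1.0 while the pool's own maximum stays below it, so such features
    can attain FDR 0 rather than being capped by a self-tie at the top.
    """
    return np.searchsorted(pooled_sorted, stats, side="left") / len(pooled_sorted)


def _sam_fdr(obs: np.ndarray, perm: np.ndarray, n_perm: int) -> np.ndarray:
    """SAM-style FDR per observed value, monotonized q-value style.

    ``perm`` is the flat pool of permuted values (n_features × n_perm draws).
    Raw FDR at threshold t = (count permuted ≥ t / n_perm) / (count observed
    ≥ t); each observation then takes the minimum raw FDR over all observed
    thresholds at or below its own value (rejection sets are nested), which
    makes the result non-increasing in the threshold.
    """
    perm_sorted = np.sort(perm)
    obs_sorted = np.sort(obs)
    n_false = len(perm_sorted) - np.searchsorted(perm_sorted, obs, side="left")
    n_true = len(obs_sorted) - np.searchsorted(obs_sorted, obs, side="left")
    raw = np.clip((n_false / n_perm) / np.maximum(n_true, 1), 0.0, 1.0)
    order = np.argsort(obs, kind="stable")  # ascending threshold
    fdr = np.empty_like(raw)
    fdr[order] = np.minimum.accumulate(raw[order])
    return fdr


@dataclass
class FeatureFDRResult:
    """Global and pairwise differential-feature calls.

    ``global_table`` has one row per testable feature with its family
    statistic, pooled relative rank and FDR; ``pairwise`` (populated by
    :func:`pairwise_ttest_fdr`) has one row per gated feature × cluster pair.
    """

    global_table: pd.DataFrame
    excluded: list[str] = field(default_factory=list)
    pairwise: pd.DataFrame | None = None
    pairwise_skipped: list[tuple] = field(default_factory=list)
    n_perm: int = 0

    def significant_features(self, alpha: float = 0.05, family: str | None = None) -> list[str]:
        t = self.global_table
        if family is not None:
            t = t[t["family"] == family]
        return t.loc[t["fdr"] < alpha, "feature"].tolist()


def _permuted_rows(x: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Stack of the observed row followed by n_perm within-row shuffles."""
    V = np.tile(x, (n_perm + 1, 1))
    V[1:] = rng.permuted(V[1:], axis=1)
    return V


def integrated_rank_fdr(
    C: pd.DataFrame | None,
    D: pd.DataFrame | None,
    g: Mapping[str, object],
    n_perm: int = 100,
    seed: int | np.random.Generator | None = 0,
    exact_limit: int = 20_000,
    mc_iters: int = 2_000,
) -> FeatureFDRResult:
    """Differential features across clusters via the integrated rank FDR.

    Permutations shuffle each feature row's non-missing values across its
    non-missing subjects against the fixed design ``g``; statistics with an
    undefined value on the observed data exclude the feature (reported in
    ``excluded``).  Deterministic under a fixed seed.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    families: list[tuple[str, list[str], np.ndarray, np.ndarray]] = []
    excluded: list[str] = []

    if C is not None and len(C):
        subjects = [str(c) for c in C.columns]
        gcodes, _ = _design_codes(g, subjects)
        names, obs_list, perm_list = [], [], []
        for feature, row in C.iterrows():
            x = row.to_numpy(dtype=float)
            mask = ~np.isnan(x)
            if mask.sum() < 3 or len(np.unique(gcodes[mask])) < 2:
                excluded.append(str(feature))
                continue
            V = _permuted_rows(x[mask], n_perm, rng)
            F = _batch_anova_f(V, gcodes[mask])
            if np.isnan(F[0]):
                excluded.append(str(feature))
                continue
            names.append(str(feature))
            obs_list.append(F[0])
            perm_list.append(F[1:])
        if names:
            families.append(
                ("continuous", names, np.asarray(obs_list), np.vstack(perm_list))
            )

    if D is not None and len(D):
        subjects = [str(c) for c in D.columns]
        gcodes, _ = _design_codes(g, subjects)
        names, obs_list, perm_list = [], [], []
        for feature, row in D.iterrows():
            vals = row
            mask = vals.notna().to_numpy()
            codes_g = gcodes[mask]
            codes_x, cats = pd.factorize(vals[mask].astype(str), sort=True)
            n_cat, J = len(cats), len(np.unique(codes_g))
            if mask.sum() < 3 or n_cat < 2 or J < 2:
                excluded.append(str(feature))
                continue
            ref = _FisherReference(
                codes_x, n_cat, codes_g, J, rng, exact_limit, mc_iters
            )
            stats = np.empty(n_perm + 1)
            xc = codes_x.copy()
            for b in range(n_perm + 1):
                if b > 0:
                    xc = rng.permutation(codes_x)
                tbl = np.bincount(xc * J + codes_g, minlength=n_cat * J).reshape(n_cat, J)
                stats[b] = -np.log(max(ref.p_value(_table_logprob(tbl)), 1e-300))
            names.append(str(feature))
            obs_list.append(stats[0])
            perm_list.append(stats[1:])
        if names:
            families.append(
                ("discrete", names, np.asarray(obs_list), np.vstack(perm_list))
            )

    if not families:
        return FeatureFDRResult(
            global_table=pd.DataFrame(
                columns=["feature", "family", "statistic", "rank", "fdr"]
            ),
            excluded=excluded,
            n_perm=n_perm,
        )

    all_rows = []
    obs_ranks_all, perm_ranks_all = [], []
    for fam, names, obs, perm in families:
        pooled = np.sort(perm.ravel())
        r_obs = _relative_ranks(obs, pooled)
        r_perm = _relative_ranks(perm.ravel(), pooled).reshape(perm.shape)
        obs_ranks_all.append(r_obs)
        perm_ranks_all.append(r_perm)
        for name, stat, r in zip(names, obs, r_obs):
            all_rows.append({"feature": name, "family": fam, "statistic": stat, "rank": r})

    obs_ranks = np.concatenate(obs_ranks_all)
    perm_ranks = np.vstack(perm_ranks_all)
    fdr = _sam_fdr(obs_ranks, perm_ranks.ravel(), n_perm)
    table = pd.DataFrame(all_rows)
    table["fdr"] = fdr
    return FeatureFDRResult(global_table=table, excluded=excluded, n_perm=n_perm)


def pairwise_ttest_fdr(
    C: pd.DataFrame,
    g: Mapping[str, object],
    global_result: FeatureFDRResult,
    n_perm: int = 100,
    seed: int | np.random.Generator | None = 0,
    alpha: float = 0.05,
) -> FeatureFDRResult:
    """Welch t-tests for every cluster pair, gated on global significance.

    Only continuous features with global FDR < ``alpha`` are tested (the
    "ANOVA trick").  |t| statistics from the same within-row permutation
    scheme feed a SAM-style FDR pooled over all (feature, pair) tests; the
    direction records which cluster has the higher mean.  Cluster pairs with
    fewer than two non-missing values in either cluster are skipped and
    reported.  Returns ``global_result`` with ``pairwise`` filled in.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gated = set(global_result.significant_features(alpha, family="continuous"))
    subjects = [str(c) for c in C.columns]
    gcodes, clusters = _design_codes(g, subjects)
    J = len(clusters)

    keys, obs_t, perm_t, means_a, means_b = [], [], [], [], []
    skipped: list[tuple] = []
    for feature, row in C.iterrows():
        feature = str(feature)
        if feature not in gated:
            continue
        x = row.to_numpy(dtype=float)
        mask = ~np.isnan(x)
        xo, go = x[mask], gcodes[mask]
        V = _permuted_rows(xo, n_perm, rng)
        # per-cluster first/second moments for every permutation at once
        stats_by_cluster = {}
        for c in range(J):
            sel = go == c
            n_c = int(sel.sum())
            if n_c < 2:
                stats_by_cluster[c] = None
                continue
            s = V[:, sel].sum(axis=1)
            q = (V[:, sel] ** 2).sum(axis=1)
            mean = s / n_c
            var = (q - n_c * mean**2) / (n_c - 1)
            stats_by_cluster[c] = (n_c, mean, np.maximum(var, 0.0))
        for a in range(J):
            for b in range(a + 1, J):
                sa, sb = stats_by_cluster[a], stats_by_cluster[b]
                if sa is None or sb is None:
                    skipped.append((feature, clusters[a], clusters[b]))
                    continue
                (na, ma, va), (nb, mb, vb) = sa, sb
                with np.errstate(divide="ignore", invalid="ignore"):
                    t = (ma - mb) / np.sqrt(va / na + vb / nb)
                t = np.abs(np.nan_to_num(t, nan=0.0, posinf=np.inf))
                keys.append((feature, clusters[a], clusters[b]))
                obs_t.append(t[0])
                perm_t.append(t[1:])
                means_a.append(ma[0])
                means_b.append(mb[0])

    if keys:
        obs = np.asarray(obs_t)
        fdr = _sam_fdr(obs, np.vstack(perm_t).ravel(), n_perm)
        pairwise = pd.DataFrame(
            {
                "feature": [k[0] for k in keys],
                "cluster_a": [k[1] for k in keys],
                "cluster_b": [k[2] for k in keys],
                "t": obs,
                "fdr": fdr,
                "direction": [
                    a if ma > mb else b
                    for (f, a, b), ma, mb in zip(keys, means_a, means_b)
                ],
                "significant": fdr < alpha,
            }
        )
    else:
        pairwise = pd.DataFrame(
            columns=["feature", "cluster_a", "cluster_b", "t", "fdr", "direction", "significant"]
        )
    global_result.pairwise = pairwise
    global_result.pairwise_skipped = skipped
    return global_result


def heatmap_matrix(
    result: FeatureFDRResult, clusters: Sequence | None = None
) -> pd.DataFrame:
    """Rank-order heatmap: net significant wins per (feature, cluster), in [−1, +1].

    A significant pairwise contrast raises the higher cluster's rank by 1 and
    lowers the other's by 1; each feature row is then min–max rescaled to
    [−1, +1] (all-zero rows stay 0).
    """
    if result.pairwise is None:
        raise ValueError("run pairwise_ttest_fdr first")
    pw = result.pairwise
    if clusters is None:
        clusters = sorted(set(pw["cluster_a"]) | set(pw["cluster_b"]))
    features = list(dict.fromkeys(pw["feature"]))
    mat = pd.DataFrame(0.0, index=features, columns=list(clusters))
    for row in pw.itertuples():
        if not row.significant:
            continue
        loser = row.cluster_b if row.direction == row.cluster_a else row.cluster_a
        mat.loc[row.feature, row.direction] += 1
        mat.loc[row.feature, loser] -= 1
    scaled = mat.to_numpy()
    lo, hi = scaled.min(axis=1, keepdims=True), scaled.max(axis=1, keepdims=True)
    span = hi - lo
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(span > 0, 2 * (scaled - lo) / span - 1, 0.0)
    return pd.DataFrame(out, index=mat.index, columns=mat.columns)


def feature_usage_tally(
    feature_lists: Mapping[str, Sequence[str]], max_features: int = 6
) -> pd.Series:
    """Fraction of submissions selecting each feature.

    ``feature_lists`` maps submission id → its (de-duplicated) feature list;
    lists longer than ``max_features`` are a validation error, mirroring the
    challenge's cap on predictive features.
    """
    for sid, feats in feature_lists.items():
        if len(set(feats)) > max_features:
            raise ValueError(
                f"submission {sid}: {len(set(feats))} features exceeds the cap of {max_features}"
            )
    n = len(feature_lists)
    counts: dict[str, int] = {}
    for feats in feature_lists.values():
        for f in set(feats):
            counts[f] = counts.get(f, 0) + 1
    return pd.Series(
        {f: c / n for f, c in counts.items()}, name="selection_probability"
    ).sort_values(ascending=False)


def feature_usage_by_group(
    groups: Mapping[str, Mapping[str, Sequence[str]]], max_features: int = 6
) -> pd.DataFrame:
    """Per-group selection probabilities plus their average, rank-ordered.

    ``groups`` maps a group name (e.g. a sub-challenge) to its submissions'
    feature lists.  Features unused in a group get probability 0.
    """
    cols = {name: feature_usage_tally(lists, max_features) for name, lists in groups.items()}
    df = pd.DataFrame(cols).fillna(0.0)
    df["average"] = df[list(groups)].mean(axis=1)
    return df.sort_values("average", ascending=False)
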