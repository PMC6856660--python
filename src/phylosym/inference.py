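"""Permutation and rank tests on community distance matrices.

ANOSIM and PERMANOVA are implemented here directly (rather than delegated)
so that every permutation draw is controlled by an explicit seed and every
p-value uses the add-one rule p = (1 + #{permuted >= observed}) / (m + 1),
which is unbiased and never zero. The sequential (Type-I) PERMANOVA
partitions the Gower-centered distance matrix with nested hat-matrix
projections, mirroring a `dist ~ A + B + C` model-formula fit in which term
order matters whenever factors are correlated (e.g. host species nested in
locality).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .containers import TestResult

__all__ = [
    "anosim",
    "permanova",
    "permanova_sequential",
    "kruskal_wallis",
    "nonparametric_t_test",
    "bh_fdr",
    "pairwise_groups",
]


def _grouping_array(dm: DistanceMatrix, grouping) -> np.ndarray:
    if isinstance(grouping, pd.Series):
        missing = [i for i in dm.ids if i not in grouping.index]
        if missing:
            raise ValueError(f"grouping missing samples: {missing[:5]}")
        return grouping.loc[list(dm.ids)].to_numpy()
    arr = np.asarray(grouping)
    if arr.shape[0] != len(dm.ids):
        raise ValueError("grouping length must match distance matrix")
    return arr


def _check_group_sizes(labels: np.ndarray, min_size: int = 2) -> None:
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    small = uniq[counts < min_size]
    if small.size:
        raise ValueError(f"groups with fewer than {min_size} samples: {list(small)}")


def _add_one_p(perm_stats: np.ndarray, observed: float) -> float:
    return float((1 + np.sum(perm_stats >= observed - 1e-12)) / (len(perm_stats) + 1))


def anosim(dm: DistanceMatrix, grouping, n_perm: int = 999, seed: int | None = None) -> TestResult:
    """Analysis of similarities: R = (rB - rW) / (M/2) on ranked distances.

    rB/rW are the mean ranks of between- and within-group distances over all
    M = n(n-1)/2 pairs; the permutation null shuffles group labels.
    """
    labels = _grouping_array(dm, grouping)
    _check_group_sizes(labels)
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    d = dm.data[iu, ju]
    ranks = stats.rankdata(d)
    denom = len(d) / 2.0

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu] == lab[ju]
        if within.all() or not within.any():  # pragma: no cover
            return 0.0
        return float((ranks[~within].mean() - ranks[within].mean()) / denom)

    observed = r_stat(labels)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for b in range(n_perm):
        perm[b] = r_stat(labels[rng.permutation(n)])
    return TestResult("R", observed, _add_one_p(perm, observed), n_perm, seed=seed)


def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances, per group partition."""
    n = d2.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    ss_total = d2[iu, ju].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(dm: DistanceMatrix, grouping, n_perm: int = 999, seed: int | None = None) -> TestResult:
    """One-way PERMANOVA: pseudo-F on the Gower-centered distance matrix,
    with R^2 = SS_between / SS_total as effect size."""
    labels = _grouping_array(dm, grouping)
    _check_group_sizes(labels)
    n = len(labels)
    a = len(np.unique(labels))
    d2 = dm.data**2

    def f_stat(lab: np.ndarray) -> tuple[float, float]:
        ss_total, ss_within = _permanova_ss(d2, lab)
        ss_between = ss_total - ss_within
        if ss_within <= 0:
            return np.inf if ss_between > 0 else 0.0, ss_between / ss_total if ss_total > 0 else 0.0
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
        r2 = ss_between / ss_total if ss_total > 0 else 0.0
        return float(f), float(r2)

    observed, r2 = f_stat(labels)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for b in range(n_perm):
        perm[b] = f_stat(labels[rng.permutation(n)])[0]
    return TestResult("pseudo_F", observed, _add_one_p(perm, observed), n_perm,
                      effect_size=r2, seed=seed)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    # pseudo-inverse projection; robust to rank-deficient dummy codings
    return x @ np.linalg.pinv(x)


def permanova_sequential(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    factor_order: Sequence[str] = ("locality", "microhabitat", "species"),
    n_perm: int = 999,
    seed: int | None = None,
) -> list[TestResult]:
    """Sequential (Type-I) PERMANOVA over an ordered list of factors.

    Term sums of squares come from nested hat-matrix projections on the
    Gower-centered matrix; p-values from free permutation of the observation
    rows. A term whose columns are fully aliased by earlier terms gets df 0
    and no test. Because species may be nested in locality/microhabitat,
    term R^2 generally depends on the order given.
    """
    for f in factor_order:
        if f not in metadata.columns:
            raise ValueError(f"factor {f!r} not in metadata")
    md = metadata.loc[list(dm.ids)]
    n = len(dm.ids)
    g = _gower_center(dm.data)
    ss_total = np.trace(g)

    # nested design matrices: intercept, then cumulative dummy blocks
    designs = [np.ones((n, 1))]
    for f in factor_order:
        dummies = pd.get_dummies(md[f].astype(str), drop_first=False).to_numpy(dtype=float)
        designs.append(np.hstack([designs[-1], dummies]))
    hats = [_hat(x) for x in designs]
    ranks = [int(round(np.trace(h))) for h in hats]
    df_terms = [ranks[k + 1] - ranks[k] for k in range(len(factor_order))]
    df_res = n - ranks[-1]
    h_full = hats[-1]

    def term_stats(gp: np.ndarray) -> tuple[np.ndarray, float]:
        tr = np.array([np.sum(h * gp) for h in hats])  # tr(H G)
        ss_terms = np.diff(tr)
        ss_res = np.trace(gp) - tr[-1]
        return ss_terms, ss_res

    ss_terms, ss_res = term_stats(g)

    def f_of(ss_t: np.ndarray, ss_r: float) -> np.ndarray:
        out = np.full(len(ss_t), np.nan)
        for k, df in enumerate(df_terms):
            if df > 0 and df_res > 0 and ss_r > 1e-12:
                out[k] = (ss_t[k] / df) / (ss_r / df_res)
            elif df > 0:
                out[k] = np.inf if ss_t[k] > 1e-12 else 0.0
        return out

    f_obs = f_of(ss_terms, ss_res)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(factor_order))
    tested = [k for k, df in enumerate(df_terms) if df > 0]
    for _ in range(n_perm):
        p = rng.permutation(n)
        gp = g[np.ix_(p, p)]
        f_p = f_of(*term_stats(gp))
        for k in tested:
            if f_p[k] >= f_obs[k] - 1e-12:
                exceed[k] += 1

    results = []
    for k, f in enumerate(factor_order):
        df = df_terms[k]
        r2 = float(ss_terms[k] / ss_total) if ss_total > 0 else 0.0
        if df == 0:
            res = TestResult("pseudo_F", float("nan"), None, 0, effect_size=r2, seed=seed,
                             extras={"term": f, "df": 0, "aliased": True})
        else:
            p_val = float((1 + exceed[k]) / (n_perm + 1))
            res = TestResult("pseudo_F", float(f_obs[k]), p_val, n_perm, effect_size=r2,
                             seed=seed, extras={"term": f, "df": df, "df_residual": df_res})
        results.append(res)
    return results


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H (tie-corrected) with chi-square p on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least three observations in total")
    pooled = np.concatenate(groups)
    if np.allclose(pooled, pooled[0]):
        return TestResult("H", 0.0, 1.0, 0)
    h, p = stats.kruskal(*groups)
    return TestResult("H", float(h), float(p), 0)


def nonparametric_t_test(
    x: Sequence[float], y: Sequence[float], n_perm: int = 999, seed: int | None = None
) -> TestResult:
    """Two-sample t statistic with a two-sided permutation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least two observations")
    pooled = np.concatenate([x, y])
    nx, ny = len(x), len(y)

    def t_stat(a: np.ndarray, b: np.ndarray) -> float:
        va, vb = a.var(ddof=1), b.var(ddof=1)
        sp2 = ((nx - 1) * va + (ny - 1) * vb) / (nx + ny - 2)
        if sp2 <= 0:
            return 0.0 if a.mean() == b.mean() else np.inf
        return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny)))

    observed = t_stat(x, y)
    if np.allclose(pooled, pooled[0]):
        return TestResult("t", 0.0, 1.0, n_perm, seed=seed)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for b in range(n_perm):
        sh = pooled[rng.permutation(nx + ny)]
        perm[b] = t_stat(sh[:nx], sh[nx:])
    p = _add_one_p(np.abs(perm), abs(observed))
    return TestResult("t", observed, p, n_perm, seed=seed)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, original order kept."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


_TESTS: dict[str, Callable] = {"anosim": anosim, "permanova": permanova}


def pairwise_groups(
    dm: DistanceMatrix,
    grouping,
    test: str = "anosim",
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Post hoc battery: the chosen test on every pair of groups, with
    BH-FDR q-values over all pairs.

    Returns a frame with columns (group_a, group_b, statistic, p, q, error);
    pairs that cannot be tested (e.g. singleton groups) record the error.
    """
    if test not in _TESTS:
        raise ValueError(f"test must be one of {sorted(_TESTS)}")
    labels = _grouping_array(dm, grouping)
    uniq = sorted(map(str, np.unique(labels)))
    labels = labels.astype(str)
    ids = np.asarray(dm.ids)
    func = _TESTS[test]
    seeds = np.random.SeedSequence(seed).spawn(len(uniq) * (len(uniq) - 1) // 2)

    rows = []
    k = 0
    for i, ga in enumerate(uniq):
        for gb in uniq[i + 1:]:
            sub_seed = int(seeds[k].generate_state(1)[0] % (2**31))
            k += 1
            keep = ids[(labels == ga) | (labels == gb)]
            sub = dm.filter(keep)
            sub_labels = pd.Series(labels, index=ids).loc[list(sub.ids)]
            try:
                res = func(sub, sub_labels, n_perm=n_perm, seed=sub_seed)
                rows.append((ga, gb, res.statistic, res.p_value, ""))
            except ValueError as exc:
                rows.append((ga, gb, np.nan, np.nan, str(exc)))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p", "error"])
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    return out[["group_a", "group_b", "statistic", "p", "q", "error"]]
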