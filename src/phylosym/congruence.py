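"""Host-phylogeny congruence battery.

Tests whether hosts that are close on their phylogeny carry similar skin
communities: group-collapsed UPGMA dendrograms of UniFrac distances (with
jackknife support), rooted normalized Robinson-Foulds distance to the host
tree with a uniform random-topology null, partial Mantel of host patristic
distances against community distances controlling for locality, and
phylogenetic eigenvector regression (PVR) of dendrogram structure followed
by MANOVA on locality/microhabitat.

Conventions: dendrograms are rooted, so RF is clade-based (nontrivial clades
only; max 2(n-2) for binary trees) and normalized by the two trees' total
clade count. The random-tree null draws rooted binary topologies uniformly
(PDA, random stepwise addition). UPGMA merge heights are half the average
inter-cluster distance, so cophenetic distances reproduce an ultrametric
input exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode

from .containers import OtuTable, TestResult, group_labels
from .diversity import beta_diversity_matrix

__all__ = [
    "Dendrogram",
    "CongruenceResult",
    "collapse_by_group",
    "upgma",
    "jackknife_support",
    "robinson_foulds_normalized",
    "random_tree_topology",
    "random_tree_null",
    "patristic_distances",
    "partial_mantel",
    "pvr_manova",
    "congruence_pipeline",
]


@dataclass
class Dendrogram:
    """Rooted ultrametric grouping tree with optional jackknife supports."""

    tree: TreeNode
    supports: dict[frozenset, float] | None = None

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def newick(self) -> str:
        t = self.tree.copy()
        if self.supports is not None:
            for node in t.non_tips(include_self=False):
                clade = frozenset(x.name for x in node.tips())
                if clade in self.supports:
                    node.name = f"{self.supports[clade]:.2f}"
        return str(t)


@dataclass
class CongruenceResult:
    """Observed normalized RF against a random-topology null."""

    nrf_observed: float
    n_random: int
    p_value: float
    null_distribution: list[float] = field(repr=False, default_factory=list)


def collapse_by_group(
    table: OtuTable, metadata: pd.DataFrame, group_factor: str = "group", mode: str = "mean"
) -> pd.DataFrame:
    """Group-level relative-abundance profiles (rows sum to 1).

    ``mode='mean'`` averages per-sample relative-abundance vectors (equal
    weight per individual); ``mode='pooled'`` pools raw counts first.
    """
    if group_factor == "group" and "group" not in metadata.columns:
        groups = group_labels(metadata)
    else:
        if group_factor not in metadata.columns:
            raise ValueError(f"factor {group_factor!r} not in metadata")
        groups = metadata.loc[metadata.index, group_factor].dropna().astype(str)
    groups = groups[groups.index.isin(table.sample_ids)]
    unmapped = set(table.sample_ids) - set(groups.index)
    if unmapped and group_factor != "group":
        raise ValueError(f"samples without a group: {sorted(unmapped)[:5]}")
    if groups.empty:
        raise ValueError("no samples mapped to any group")
    if mode == "mean":
        rel = table.relative_abundance().loc[groups.index]
        out = rel.groupby(groups).mean()
    elif mode == "pooled":
        pooled = table.counts.loc[groups.index].groupby(groups).sum()
        out = pooled.div(pooled.sum(axis=1), axis=0)
    else:
        raise ValueError("mode must be 'mean' or 'pooled'")
    if (out.sum(axis=1) <= 0).any():
        raise ValueError("a group has zero total abundance")
    return out


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration; merge height is half the average
    inter-cluster distance (cophenetic distance equals the average distance).

    Labels are sorted before clustering so distance ties break
    lexicographically.
    """
    if np.isnan(dm.data).any():
        raise ValueError("distance matrix contains NaN")
    ids = sorted(dm.ids)
    if len(ids) < 2:
        raise ValueError("need at least two labels")
    d = dm.filter(ids)
    z = hierarchy.linkage(squareform(d.data, checks=False), method="average")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    heights = [0.0] * len(ids)
    for a, b, dist, _ in z:
        h = dist / 2.0
        left, right = nodes[int(a)], nodes[int(b)]
        left.length = h - heights[int(a)]
        right.length = h - heights[int(b)]
        parent = TreeNode(children=[left, right])
        nodes.append(parent)
        heights.append(h)
    return Dendrogram(tree=nodes[-1])


def _clade_sets(tree: TreeNode) -> set[frozenset]:
    """Nontrivial clades of a rooted tree (excluding root and single tips)."""
    all_tips = frozenset(t.name for t in tree.tips())
    clades = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if 1 < len(clade) < len(all_tips):
            clades.add(clade)
    return clades


def robinson_foulds_normalized(tree_a: TreeNode, tree_b: TreeNode) -> float:
    """Rooted clade-based RF distance normalized to [0, 1]:
    |C_a symdiff C_b| / (|C_a| + |C_b|)."""
    tips_a = {t.name for t in tree_a.tips()}
    tips_b = {t.name for t in tree_b.tips()}
    if tips_a != tips_b:
        raise ValueError(
            f"tip sets differ: only in first {sorted(tips_a - tips_b)}, "
            f"only in second {sorted(tips_b - tips_a)}"
        )
    if len(tips_a) < 3:
        raise ValueError("need at least 3 shared tips")
    ca, cb = _clade_sets(tree_a), _clade_sets(tree_b)
    denom = len(ca) + len(cb)
    if denom == 0:
        return 0.0
    return len(ca ^ cb) / denom


def random_tree_topology(labels: Sequence[str], rng: np.random.Generator) -> TreeNode:
    """Uniform rooted binary labeled topology via random stepwise addition.

    Leaf k+1 attaches above any of the 2k-1 existing nodes (edges, counting
    the root stem) with equal probability, which makes every (2n-3)!! rooted
    topology equally likely.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    order = rng.permutation(len(labels))
    root = TreeNode(name=labels[order[0]])
    nodes = [root]
    for k in order[1:]:
        target = nodes[int(rng.integers(len(nodes)))]
        new_leaf = TreeNode(name=labels[k])
        new_internal = TreeNode()
        parent = target.parent
        if parent is not None:
            parent.remove(target)
        new_internal.append(target)
        new_internal.append(new_leaf)
        if parent is not None:
            parent.append(new_internal)
        else:
            root = new_internal
        nodes.extend([new_leaf, new_internal])
    return root


def random_tree_null(
    reference_tree: TreeNode,
    observed_nrf: float,
    n_random: int = 1000,
    seed: int | None = None,
) -> CongruenceResult:
    """Probability of a random topology matching the reference at least as
    well as the observed dendrogram: p = (1 + #{null nRF <= observed}) /
    (n_random + 1)."""
    if not 0 <= observed_nrf <= 1:
        raise ValueError("observed_nrf must lie in [0, 1]")
    labels = [t.name for t in reference_tree.tips()]
    if len(labels) < 3:
        raise ValueError("reference tree needs at least 3 tips")
    rng = np.random.default_rng(seed)
    null = [
        robinson_foulds_normalized(random_tree_topology(labels, rng), reference_tree)
        for _ in range(n_random)
    ]
    hits = sum(1 for v in null if v <= observed_nrf + 1e-12)
    return CongruenceResult(
        nrf_observed=float(observed_nrf),
        n_random=n_random,
        p_value=(1 + hits) / (n_random + 1),
        null_distribution=null,
    )


def patristic_distances(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip path-length (patristic) distance matrix."""
    for node in tree.traverse(include_self=False):
        if node.length is None:
            tipset = ",".join(sorted(t.name for t in node.tips())) or node.name or "?"
            raise ValueError(f"missing branch length on edge above ({tipset})")
    return tree.tip_tip_distances()


def _offdiag(dm: DistanceMatrix) -> np.ndarray:
    iu, ju = np.triu_indices(dm.shape[0], k=1)
    return dm.data[iu, ju]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def partial_mantel(
    d_xy_target: DistanceMatrix,
    d_xy_other: DistanceMatrix,
    d_control: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "pearson",
) -> TestResult:
    """Partial Mantel correlation of two distance matrices controlling for a
    third, with a one-sided (positive association) permutation p-value from
    permuting the first matrix's rows/columns."""
    ids = list(d_xy_target.ids)
    if set(ids) != set(d_xy_other.ids) or set(ids) != set(d_control.ids):
        raise ValueError("all three matrices must share the same labels")
    b = d_xy_other.filter(ids)
    c = d_control.filter(ids)
    rank = stats.rankdata if method == "spearman" else (lambda v: v)

    xa = rank(_offdiag(d_xy_target))
    xb = rank(_offdiag(b))
    xc = rank(_offdiag(c))

    r_bc = _pearson(xb, xc)
    if abs(r_bc) >= 1 - 1e-12:
        raise ValueError("degenerate: |r| = 1 between second and control matrices")

    def r_partial(a_vec: np.ndarray) -> float:
        r_ab = _pearson(a_vec, xb)
        r_ac = _pearson(a_vec, xc)
        if abs(r_ac) >= 1 - 1e-12:
            raise ValueError("degenerate: |r| = 1 between first and control matrices")
        return (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))

    observed = r_partial(xa)
    rng = np.random.default_rng(seed)
    n = len(ids)
    a_data = d_xy_target.data
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        ap = a_data[np.ix_(p, p)]
        iu, ju = np.triu_indices(n, k=1)
        if r_partial(rank(ap[iu, ju])) >= observed - 1e-12:
            count += 1
    return TestResult("r_partial", float(observed), (1 + count) / (n_perm + 1), n_perm, seed=seed)


def _pillai_manova(y: np.ndarray, factor: pd.Series) -> TestResult:
    """MANOVA of multivariate responses on one factor: Pillai's trace with
    its standard F approximation."""
    levels = sorted(factor.unique())
    a = len(levels)
    n, p = y.shape
    df_h = a - 1
    df_e = n - a
    if df_e < 1 or df_h < 1:
        raise ValueError("insufficient residual degrees of freedom for MANOVA")
    x = np.column_stack([np.ones(n)] + [(factor == lv).to_numpy(float) for lv in levels[:-1]])
    x0 = np.ones((n, 1))
    proj = lambda m: m @ np.linalg.pinv(m)
    h_mat = y.T @ (proj(x) - proj(x0)) @ y
    e_mat = y.T @ (np.eye(n) - proj(x)) @ y
    v = float(np.trace(h_mat @ np.linalg.pinv(h_mat + e_mat)))
    s = min(p, df_h)
    m = (abs(p - df_h) - 1) / 2.0
    nn = (df_e - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    if df2 <= 0:
        raise ValueError("insufficient residual degrees of freedom for MANOVA")
    if v >= s - 1e-9:
        # responses separate the groups perfectly in-sample: F diverges
        return TestResult("pillai", float(v), 0.0, 0,
                          extras={"F": float("inf"), "df1": df1, "df2": df2,
                                  "n_responses": p, "perfect_separation": True})
    f = (df2 / df1) * (v / (s - v))
    p_val = float(stats.f.sf(f, df1, df2))
    return TestResult("pillai", v, p_val, 0,
                      extras={"F": float(f), "df1": df1, "df2": df2, "n_responses": p})


def pvr_manova(
    dendrogram: Dendrogram | TreeNode,
    group_factors: pd.DataFrame,
    variance_cutoff: float = 0.95,
) -> list[TestResult]:
    """Phylogenetic eigenvector regression of a dendrogram, then MANOVA of
    the retained coordinates on each factor (one at a time).

    The dendrogram's cophenetic (patristic) distances are double-centered
    and eigendecomposed; positive-eigenvalue coordinates are retained up to
    ``variance_cutoff`` cumulative variance, capped at n_tips - levels - 1
    for the factor under test.
    """
    tree = dendrogram.tree if isinstance(dendrogram, Dendrogram) else dendrogram
    dm = patristic_distances(tree)
    tips = list(dm.ids)
    missing = set(tips) - set(group_factors.index)
    if missing:
        raise ValueError(f"factors missing for tips: {sorted(missing)}")
    n = len(tips)
    a_mat = -0.5 * dm.data**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a_mat @ j
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10 * max(eigvals.max(), 1.0)
    eigvals, eigvecs = eigvals[pos], eigvecs[:, pos]
    if eigvals.size == 0:
        raise ValueError("dendrogram has no positive eigenvalues (degenerate)")
    coords = eigvecs * np.sqrt(eigvals)
    cum = np.cumsum(eigvals) / eigvals.sum()
    k95 = int(np.searchsorted(cum, variance_cutoff) + 1)

    results = []
    for factor_name in group_factors.columns:
        factor = group_factors.loc[tips, factor_name].astype(str)
        levels = factor.nunique()
        if n < levels + 2:
            raise ValueError(
                f"factor {factor_name!r}: need at least {levels + 2} tips, have {n}"
            )
        k = max(1, min(k95, n - levels - 1))
        res = _pillai_manova(coords[:, :k], factor)
        res.extras["term"] = factor_name
        res.extras["n_components"] = k
        results.append(res)
    return results


def _subsample_table(table: OtuTable, depth: int, rng: np.random.Generator) -> OtuTable:
    out = np.empty_like(table.counts.to_numpy())
    for i, s in enumerate(table.sample_ids):
        row = table.counts.loc[s].to_numpy()
        tot = int(row.sum())
        if tot <= depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return OtuTable(pd.DataFrame(out, index=table.sample_ids, columns=table.otu_ids),
                    table.taxonomy)


def jackknife_support(
    table: OtuTable,
    metadata: pd.DataFrame,
    group_factor: str,
    tree: TreeNode,
    metric: str = "unweighted_unifrac",
    depth_fraction: float = 0.75,
    n_reps: int = 100,
    seed: int | None = None,
) -> Dendrogram:
    """UPGMA dendrogram of group UniFrac distances with jackknife supports.

    Each replicate subsamples every sample without replacement to
    ``floor(depth_fraction x its rarefied depth)``, recollapses by group,
    recomputes the group distance matrix, and rebuilds the UPGMA tree; the
    support of each full-data clade is the fraction of replicate trees
    containing it.
    """
    if not 0 < depth_fraction <= 1:
        raise ValueError("depth_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    collapsed = collapse_by_group(table, metadata, group_factor)
    full = upgma(beta_diversity_matrix(collapsed, tree, metric))
    clades = _clade_sets(full.tree)
    counts = {c: 0 for c in clades}
    depth = int(np.floor(depth_fraction * table.sample_totals().min()))
    for _ in range(n_reps):
        sub = _subsample_table(table, depth, rng)
        rep_collapsed = collapse_by_group(sub, metadata, group_factor)
        rep = upgma(beta_diversity_matrix(rep_collapsed, tree, metric))
        rep_clades = _clade_sets(rep.tree)
        for c in clades:
            if c in rep_clades:
                counts[c] += 1
    full.supports = {c: counts[c] / n_reps for c in clades}
    return full


def _group_design(metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-group (species, locality, microhabitat) lookup from skin samples."""
    skin = metadata[metadata["sample_type"] == "skin"].copy()
    skin["group"] = group_labels(metadata)
    design = skin.groupby("group")[["species", "locality", "microhabitat"]].agg(
        lambda s: s.iloc[0]
    )
    return design


def congruence_pipeline(
    table: OtuTable,
    metadata: pd.DataFrame,
    bacterial_tree: TreeNode,
    host_tree: TreeNode,
    metrics: Sequence[str] = ("unweighted_unifrac", "weighted_unifrac"),
    n_perm: int = 999,
    n_random: int = 1000,
    jackknife_reps: int = 100,
    depth_fraction: float = 0.75,
    seed: int | None = None,
    exclude_groups: Sequence[str] = (),
) -> dict:
    """Full congruence battery on a rarefied skin table.

    Per metric: collapse by species-x-locality group, UPGMA (+jackknife),
    per-locality normalized RF against the pruned host tree with a
    random-topology null, partial Mantel of host patristic vs community
    distances controlling for locality (binary 0/1 control matrix), and
    PVR-MANOVA on locality and microhabitat. ``exclude_groups`` supports
    leave-one-group-out reanalysis without re-simulation.
    """
    seeds = np.random.SeedSequence(seed).spawn(2 * len(metrics))
    design = _group_design(metadata)
    design = design.drop(index=[g for g in exclude_groups if g in design.index])
    if design.empty:
        raise ValueError("no groups left after exclusion")
    host_tips = {t.name for t in host_tree.tips()}
    missing = set(design["species"]) - host_tips
    if missing:
        raise ValueError(f"host tree missing species: {sorted(missing)}")

    skin_meta = metadata[metadata["sample_type"] == "skin"].copy()
    skin_meta["group"] = group_labels(metadata)
    skin_meta = skin_meta[skin_meta["group"].isin(design.index)]
    skin_ids = [s for s in table.sample_ids if s in skin_meta.index]
    skin_table = table.select_samples(skin_ids)

    # host patristic distances expanded to groups (two populations of one
    # species are phylogenetically identical: distance 0)
    host_dm = patristic_distances(host_tree)
    groups = list(design.index)
    hp = np.zeros((len(groups), len(groups)))
    for i, ga in enumerate(groups):
        for jj, gb in enumerate(groups):
            if i < jj:
                sa, sb = design.loc[ga, "species"], design.loc[gb, "species"]
                hp[i, jj] = hp[jj, i] = 0.0 if sa == sb else host_dm[sa, sb]
    host_groups_dm = DistanceMatrix(hp, ids=groups)
    loc = design["locality"]
    ctrl = np.array([[0.0 if loc[a] == loc[b] else 1.0 for b in groups] for a in groups])
    control_dm = DistanceMatrix(ctrl, ids=groups)

    report: dict = {"groups": groups, "excluded": list(exclude_groups), "metrics": {}}
    for mi, metric in enumerate(metrics):
        dendro = jackknife_support(
            skin_table, metadata, "group", bacterial_tree, metric,
            depth_fraction=depth_fraction, n_reps=jackknife_reps,
            seed=int(seeds[2 * mi].generate_state(1)[0] % (2**31)),
        )
        group_dm = beta_diversity_matrix(
            collapse_by_group(skin_table, metadata, "group"), bacterial_tree, metric
        ).filter(groups)

        null_seed = np.random.SeedSequence(
            int(seeds[2 * mi + 1].generate_state(1)[0] % (2**31))
        ).spawn(len(set(loc)) + 1)
        per_locality = {}
        for li, locality in enumerate(sorted(set(loc))):
            sub_groups = [g for g in groups if loc[g] == locality]
            if len(sub_groups) < 3:
                per_locality[locality] = {"n_groups": len(sub_groups), "skipped": True}
                continue
            species_of = design.loc[sub_groups, "species"]
            if species_of.duplicated().any():
                raise ValueError(f"duplicate species within locality {locality}")
            sub_dendro = upgma(group_dm.filter(sub_groups))
            renamed = sub_dendro.tree.copy()
            for t in renamed.tips():
                t.name = species_of[t.name]
            pruned_host = host_tree.shear(list(species_of))
            nrf = robinson_foulds_normalized(renamed, pruned_host)
            null = random_tree_null(
                pruned_host, nrf, n_random=n_random,
                seed=int(null_seed[li].generate_state(1)[0] % (2**31)),
            )
            per_locality[locality] = {
                "n_groups": len(sub_groups),
                "nrf": null.nrf_observed,
                "p_value": null.p_value,
                "n_random": null.n_random,
            }

        mantel = partial_mantel(
            group_dm, host_groups_dm, control_dm, n_perm=n_perm,
            seed=int(null_seed[-1].generate_state(1)[0] % (2**31)),
        )
        manova = pvr_manova(dendro, design[["locality", "microhabitat"]])
        report["metrics"][metric] = {
            "dendrogram": dendro.newick(),
            "jackknife_supports": {
                "|".join(sorted(c)): v for c, v in (dendro.supports or {}).items()
            },
            "per_locality_nrf": per_locality,
            "partial_mantel": mantel.to_dict(),
            "pvr_manova": {r.extras["term"]: r.to_dict() for r in manova},
        }
    return report
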