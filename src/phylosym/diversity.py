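"""Alpha and phylogenetic beta diversity.

Thin, validated wrappers around scikit-bio's implementations, pinned to the
conventions used throughout this pipeline: Shannon entropy in bits (log base
2) by default, root-inclusive Faith's PD (the minimal spanning subtree always
includes the root, so single-tip PD is the root-to-tip path), and weighted
UniFrac in its raw (unnormalized) form unless asked otherwise. Multifurcating
trees are fine everywhere; all quantities are defined over tree edges.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity as _skbio_beta
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd
from skbio.diversity.alpha import shannon as _skbio_shannon

from .containers import OtuTable

__all__ = [
    "shannon",
    "faith_pd",
    "unweighted_unifrac",
    "weighted_unifrac",
    "beta_diversity_matrix",
    "alpha_diversity_frame",
    "pcoa",
]

METRICS = ("unweighted_unifrac", "weighted_unifrac")


def shannon(counts: Sequence[float], log_base: float = 2) -> float:
    """Shannon diversity H = -sum p_i log(p_i) of a count vector."""
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1 or (arr < 0).any():
        raise ValueError("counts must be a 1-D non-negative vector")
    if arr.sum() <= 0:
        raise ValueError("counts sum to zero")
    return float(_skbio_shannon(arr, base=log_base))


def _check_tips(names: Iterable[str], tree: TreeNode) -> None:
    tips = {t.name for t in tree.tips()}
    for n in names:
        if n not in tips:
            raise ValueError(f"tip {n!r} not found in tree")


def _check_lengths(tree: TreeNode) -> None:
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError("tree has branches without lengths")


def faith_pd(presence_set: Iterable[str], tree: TreeNode) -> float:
    """Faith's phylogenetic diversity: total branch length of the minimal
    root-inclusive subtree spanning the present tips."""
    present = list(dict.fromkeys(presence_set))
    if not present:
        raise ValueError("presence_set is empty")
    _check_tips(present, tree)
    return float(_skbio_faith_pd([1] * len(present), taxa=present, tree=tree))


def _pair_counts(
    sample_a: Mapping[str, float] | Iterable[str],
    sample_b: Mapping[str, float] | Iterable[str],
) -> tuple[list[str], np.ndarray, np.ndarray]:
    a = dict(sample_a) if isinstance(sample_a, Mapping) else {k: 1.0 for k in sample_a}
    b = dict(sample_b) if isinstance(sample_b, Mapping) else {k: 1.0 for k in sample_b}
    taxa = sorted(set(a) | set(b))
    u = np.array([a.get(t, 0.0) for t in taxa])
    v = np.array([b.get(t, 0.0) for t in taxa])
    return taxa, u, v


def unweighted_unifrac(
    sample_a: Iterable[str], sample_b: Iterable[str], tree: TreeNode
) -> float:
    """Fraction of the union subtree's branch length unique to one sample.

    Samples are presence sets (or mappings, where positive values mean
    present) of OTU ids that must be tips of ``tree``.
    """
    taxa, u, v = _pair_counts(sample_a, sample_b, )
    if u.sum() == 0 and v.sum() == 0:
        raise ValueError("both samples are empty")
    _check_tips(taxa, tree)
    _check_lengths(tree)
    dm = _skbio_beta("unweighted_unifrac", np.vstack([u, v]), ids=["a", "b"],
                     taxa=taxa, tree=tree, validate=False)
    return float(dm["a", "b"])


def weighted_unifrac(
    sample_a: Mapping[str, float],
    sample_b: Mapping[str, float],
    tree: TreeNode,
    normalized: bool = False,
) -> float:
    """Abundance-weighted UniFrac: sum over branches of b_i |p_i^A - p_i^B|.

    ``normalized=True`` divides by sum b_i (p_i^A + p_i^B), bounding the
    distance by 1.
    """
    taxa, u, v = _pair_counts(sample_a, sample_b)
    if u.sum() <= 0 or v.sum() <= 0:
        raise ValueError("each sample must have positive total count")
    _check_tips(taxa, tree)
    _check_lengths(tree)
    dm = _skbio_beta("weighted_unifrac", np.vstack([u, v]), ids=["a", "b"],
                     taxa=taxa, tree=tree, normalized=normalized, validate=False)
    return float(dm["a", "b"])


def beta_diversity_matrix(
    table: OtuTable | pd.DataFrame,
    tree: TreeNode,
    metric: str,
    normalized: bool = False,
) -> DistanceMatrix:
    """Pairwise UniFrac distance matrix over the table's samples.

    Accepts an :class:`OtuTable` or a plain samples-x-OTUs frame (float
    relative abundances are fine, e.g. group-collapsed profiles).
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    frame = table.counts if isinstance(table, OtuTable) else table
    if frame.shape[0] == 0:
        raise ValueError("table has no samples")
    data = frame.to_numpy(dtype=float)
    if not np.allclose(data, np.round(data)):
        # relative-abundance input: UniFrac depends on per-sample fractions
        # only, so rescale to a fine integer grid (1e9) for the backend
        data = np.round(data * 1e9)
    _check_tips((str(o) for o in frame.columns), tree)
    _check_lengths(tree)
    kwargs = {"normalized": normalized} if metric == "weighted_unifrac" else {}
    return _skbio_beta(
        metric,
        data,
        ids=[str(s) for s in frame.index],
        taxa=[str(o) for o in frame.columns],
        tree=tree,
        validate=False,
        **kwargs,
    )


def alpha_diversity_frame(table: OtuTable, tree: TreeNode, log_base: float = 2) -> pd.DataFrame:
    """Per-sample Faith's PD and Shannon index."""
    rows = {}
    for s in table.sample_ids:
        row = table.counts.loc[s]
        present = list(row.index[row > 0])
        rows[s] = {
            "faith_pd": faith_pd(present, tree) if present else 0.0,
            "shannon": shannon(row.to_numpy(), log_base=log_base) if row.sum() > 0 else 0.0,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Classical scaling (principal coordinate analysis) of a distance matrix.

    Returns ``(coordinates, eigenvalues)`` with eigenvalues sorted
    descending. ``n_axes`` beyond n-1 is clamped with a warning.
    """
    n = dm.shape[0]
    if n_axes is None:
        n_axes = max(n - 1, 1)
    if n_axes > n - 1:
        warnings.warn(f"n_axes={n_axes} clamped to {max(n - 1, 1)}")
        n_axes = max(n - 1, 1)
    from skbio.stats.ordination import pcoa as _skbio_pcoa

    res = _skbio_pcoa(dm, number_of_dimensions=n_axes)
    coords = res.samples.iloc[:, :n_axes]
    coords.index = list(dm.ids)
    return coords, res.eigvals
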