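"""Discriminant taxa (LDA effect size) and core-microbiota extraction.

The discriminant procedure is a deliberately simplified reimplementation of
the LEfSe idea for a design with a single class factor and no subclasses:
stage 1 screens each OTU with a Kruskal-Wallis test across classes; stage 2
scores survivors by a bootstrapped one-dimensional linear discriminant. For
a single feature the discriminant axis coincides with the feature axis, so
the projected between-class mean difference reduces to the largest pairwise
difference of class means. Abundances are scaled to parts-per-million before
taking log10, putting the conventional score threshold of 3.0 on its usual
scale (a 3.0 score ~ a 1e3 ppm = 0.1% absolute difference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OtuTable

__all__ = ["DiscriminantFeature", "CoreSet", "lda_effect_size", "core_otus"]

PPM = 1e6


@dataclass
class DiscriminantFeature:
    otu_id: str
    enriched_class: str
    lda_score: float  # log10 scale
    kw_p: float


@dataclass
class CoreSet:
    """OTUs present in at least ``prevalence_threshold`` of a category's samples."""

    category_label: str
    otu_ids: set[str]
    prevalence_threshold: float


def lda_effect_size(
    table: OtuTable,
    metadata: pd.DataFrame,
    class_factor: str,
    alpha: float = 0.05,
    threshold: float = 3.0,
    n_boot: int = 30,
    seed: int | None = None,
) -> list[DiscriminantFeature]:
    """Class-discriminant OTUs with bootstrap LDA scores above ``threshold``.

    Only OTUs passing the Kruskal-Wallis screen (p < alpha) are scored;
    classes with fewer than 3 samples are excluded with a warning. Reported
    features satisfy ``lda_score > threshold`` strictly.
    """
    if class_factor not in metadata.columns:
        raise ValueError(f"factor {class_factor!r} not in metadata")
    md = metadata.loc[table.sample_ids]
    classes = md[class_factor].dropna().astype(str)
    sizes = classes.value_counts()
    small = sorted(sizes.index[sizes < 3])
    if small:
        warnings.warn(f"classes with fewer than 3 samples excluded: {small}")
        classes = classes[~classes.isin(small)]
    levels = sorted(classes.unique())
    if len(levels) < 2:
        raise ValueError("need at least two classes with >= 3 samples")

    rel = table.relative_abundance().loc[classes.index] * PPM
    by_class = {c: rel.loc[classes.index[classes == c]].to_numpy() for c in levels}

    # stage 1: Kruskal-Wallis screen per OTU
    kw_p = np.ones(rel.shape[1])
    for j in range(rel.shape[1]):
        cols = [by_class[c][:, j] for c in levels]
        pooled = np.concatenate(cols)
        if np.allclose(pooled, pooled[0]):
            continue
        kw_p[j] = stats.kruskal(*cols)[1]
    surviving = np.flatnonzero(kw_p < alpha)

    # stage 2: bootstrap one-dimensional discriminant effect size
    rng = np.random.default_rng(seed)
    feats: list[DiscriminantFeature] = []
    for j in surviving:
        effects = np.empty(n_boot)
        for b in range(n_boot):
            means = []
            for c in levels:
                col = by_class[c][:, j]
                draw = col[rng.integers(len(col), size=len(col))]
                means.append(draw.mean())
            means = np.asarray(means)
            effects[b] = means.max() - means.min()
        score = float(np.log10(max(effects.mean(), 1e-12)))
        if score > threshold:
            full_means = {c: by_class[c][:, j].mean() for c in levels}
            enriched = max(full_means, key=full_means.get)
            feats.append(DiscriminantFeature(rel.columns[j], enriched, score, float(kw_p[j])))
    feats.sort(key=lambda f: -f.lda_score)
    return feats


def core_otus(
    table: OtuTable,
    metadata: pd.DataFrame,
    category_factor: str,
    prevalence: float = 0.90,
) -> list[CoreSet]:
    """Per-category core OTUs (within-category prevalence >= ``prevalence``,
    inclusive), plus the intersection across all categories (labelled
    ``__all__``)."""
    if category_factor not in metadata.columns:
        raise ValueError(f"factor {category_factor!r} not in metadata")
    md = metadata.loc[table.sample_ids]
    cats = md[category_factor].dropna().astype(str)
    if cats.empty:
        raise ValueError("no samples carry the category factor")
    presence = table.counts > 0
    sets: list[CoreSet] = []
    shared: set[str] | None = None
    for c in sorted(cats.unique()):
        ids = cats.index[cats == c]
        if len(ids) == 0:
            raise ValueError(f"category {c!r} is empty")
        prev = presence.loc[ids].mean(axis=0)
        core = set(prev.index[prev >= prevalence])
        sets.append(CoreSet(c, core, prevalence))
        shared = core if shared is None else shared & core
    sets.append(CoreSet("__all__", shared or set(), prevalence))
    return sets


def discriminant_table(feats: list[DiscriminantFeature], table: OtuTable) -> pd.DataFrame:
    """Tabular view (otu_id, taxonomy, enriched_class, lda_score, kw_p)."""
    rows = [
        (
            f.otu_id,
            ";".join(table.taxonomy.get(f.otu_id, ())),
            f.enriched_class,
            f.lda_score,
            f.kw_p,
        )
        for f in feats
    ]
    return pd.DataFrame(rows, columns=["otu_id", "taxonomy", "enriched_class", "lda_score", "kw_p"])
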