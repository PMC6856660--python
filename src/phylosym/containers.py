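"""Shared data containers for the pipeline.

The community data flows through the whole analysis as a single
:class:`OtuTable` (integer counts, samples x OTUs, with per-OTU taxonomy),
accompanied by a plain :class:`pandas.DataFrame` of per-sample metadata.
Phylogenies are :class:`skbio.TreeNode` objects and distances are
:class:`skbio.DistanceMatrix` objects throughout; this module only adds the
thin structures the pipeline itself needs (test results, pairwise tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "TestResult",
    "REQUIRED_METADATA_COLUMNS",
    "validate_metadata",
    "group_labels",
]

#: Columns every sample-metadata frame must carry.  ``sample_type`` is one of
#: ``skin``, ``environment`` or ``control``; ``species``/``microhabitat`` may
#: be missing (NaN) for non-skin samples.
REQUIRED_METADATA_COLUMNS = ("sample_type", "species", "locality", "microhabitat")

SAMPLE_TYPES = ("skin", "environment", "control")


class OtuTable:
    """Integer OTU count table (samples x OTUs) with per-OTU taxonomy.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts; index = sample ids, columns = OTU ids.
    taxonomy : mapping of otu_id -> sequence of rank strings, optional
        Ordered taxonomy ranks (kingdom ... species); may be partial and may
        cover only a subset of OTUs.
    """

    def __init__(self, counts: pd.DataFrame, taxonomy: Mapping[str, Sequence[str]] | None = None):
        if not isinstance(counts, pd.DataFrame):
            raise TypeError("counts must be a pandas DataFrame (samples x OTUs)")
        if counts.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate OTU ids")
        values = counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("counts must be non-negative")
        if values.size and not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        self.counts = counts.astype(np.int64)
        taxonomy = dict(taxonomy or {})
        unknown = set(taxonomy) - set(counts.columns)
        if unknown:
            raise ValueError(f"taxonomy keys not in otu_ids: {sorted(unknown)[:5]}")
        self.taxonomy = {k: tuple(v) for k, v in taxonomy.items()}

    # -- basic views -------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def otu_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1; zero-total rows stay 0)."""
        totals = self.counts.sum(axis=1).to_numpy(dtype=float)
        totals[totals == 0] = 1.0
        return self.counts.div(totals, axis=0)

    # -- derived tables ----------------------------------------------------

    def _subset_taxonomy(self, otus: Sequence[str]) -> dict[str, tuple[str, ...]]:
        keep = set(otus)
        return {k: v for k, v in self.taxonomy.items() if k in keep}

    def keep_otus(self, otus: Sequence[str]) -> "OtuTable":
        otus = [o for o in self.otu_ids if o in set(otus)]
        return OtuTable(self.counts[otus], self._subset_taxonomy(otus))

    def drop_otus(self, otus: Sequence[str]) -> "OtuTable":
        drop = set(otus)
        keep = [o for o in self.otu_ids if o not in drop]
        return OtuTable(self.counts[keep], self._subset_taxonomy(keep))

    def select_samples(self, samples: Sequence[str]) -> "OtuTable":
        missing = [s for s in samples if s not in self.counts.index]
        if missing:
            raise KeyError(f"samples not in table: {missing[:5]}")
        return OtuTable(self.counts.loc[list(samples)], self.taxonomy)

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write OTUs-as-rows TSV with a trailing semicolon-joined taxonomy column."""
        out = self.counts.T.copy()
        out.index.name = "otu_id"
        out["taxonomy"] = [";".join(self.taxonomy.get(o, ())) for o in out.index]
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "OtuTable":
        raw = pd.read_csv(path, sep="\t", index_col=0)
        taxonomy: dict[str, tuple[str, ...]] = {}
        if "taxonomy" in raw.columns:
            tax = raw.pop("taxonomy")
            for otu, s in tax.items():
                if isinstance(s, str) and s:
                    taxonomy[str(otu)] = tuple(t.strip() for t in s.split(";"))
        counts = raw.T
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)
        return cls(counts, taxonomy)

    def __repr__(self) -> str:  # pragma: no cover
        n, m = self.shape
        return f"<OtuTable {n} samples x {m} OTUs>"


@dataclass
class TestResult:
    """Outcome of a single (permutation) test.

    ``statistic_name`` is one of ``R`` (ANOSIM), ``pseudo_F`` (PERMANOVA),
    ``H`` (Kruskal-Wallis), ``t``, ``r_partial`` (partial Mantel) or
    ``pillai`` (MANOVA). ``effect_size`` carries R^2 for PERMANOVA terms.
    """

    statistic_name: str
    statistic: float
    p_value: float | None
    n_permutations: int = 0
    effect_size: float | None = None
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.p_value is not None and self.n_permutations > 0:
            floor = 1.0 / (self.n_permutations + 1)
            if self.p_value < floor - 1e-12:
                raise ValueError("permutation p-value below add-one floor")

    def to_dict(self) -> dict:
        d = {
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "effect_size": self.effect_size,
            "seed": self.seed,
        }
        d.update(self.extras)
        return d


def validate_metadata(metadata: pd.DataFrame, table: OtuTable | None = None) -> None:
    """Check the metadata frame carries the required factor columns.

    If ``table`` is given, additionally require every table sample to be
    present in the metadata index.
    """
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if metadata.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    bad = set(metadata["sample_type"].dropna()) - set(SAMPLE_TYPES)
    if bad:
        raise ValueError(f"unknown sample_type values: {sorted(bad)}")
    if table is not None:
        absent = set(table.sample_ids) - set(metadata.index)
        if absent:
            raise ValueError(f"samples missing from metadata: {sorted(absent)[:5]}")


def group_labels(metadata: pd.DataFrame, sep: str = "|") -> pd.Series:
    """Species-by-locality group label per sample (skin samples only).

    A species present at two localities yields two groups, mirroring a host
    sampled at both sites being treated as two populations.
    """
    skin = metadata[metadata["sample_type"] == "skin"]
    return skin["species"].astype(str) + sep + skin["locality"].astype(str)
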