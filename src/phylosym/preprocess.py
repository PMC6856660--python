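"""OTU-table filters applied ahead of all diversity analyses.

Stage order used by the pipeline: organelle removal -> rare-OTU removal ->
control-based contaminant removal -> rarefaction. Each stage takes and
returns a valid :class:`~phylosym.containers.OtuTable`.

The contaminant rule compares, per OTU, prevalence and per-sample relative
abundance between negative-control samples and skin samples: an OTU observed
in at least one control is flagged when it is at least as prevalent in
controls AND either its mean relative abundance in controls is at least that
in skin, or a Kruskal-Wallis test on per-sample relative abundances is
significant with controls ranking higher. OTUs absent from every control are
never flagged (cross-contamination from study samples into controls is
expected, so presence in a control alone is not disqualifying).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OtuTable, validate_metadata

__all__ = [
    "ORGANELLE_TOKENS",
    "ContaminantReport",
    "remove_organelle_otus",
    "remove_rare_otus",
    "identify_contaminants",
    "remove_contaminants",
    "rarefy",
    "preprocess_pipeline",
]

#: Case-insensitive substrings marking organelle-derived 16S sequences at any
#: taxonomy rank ("mitochondri" covers mitochondria/mitochondrion).
ORGANELLE_TOKENS = ("chloroplast", "mitochondri")


@dataclass
class ContaminantReport:
    """Per-OTU decontamination evidence and the flagged set."""

    flagged: set[str]
    per_otu: pd.DataFrame = field(repr=False)
    alpha: float = 0.05

    COLUMNS = (
        "prevalence_control",
        "prevalence_skin",
        "mean_relabund_control",
        "mean_relabund_skin",
        "kw_statistic",
        "kw_p",
        "flagged",
        "reason",
    )

    def to_tsv(self, path) -> None:
        self.per_otu.to_csv(path, sep="\t", index_label="otu_id")

    @classmethod
    def from_tsv(cls, path, alpha: float = 0.05) -> "ContaminantReport":
        per_otu = pd.read_csv(path, sep="\t", index_col=0)
        flagged = set(per_otu.index[per_otu["flagged"].astype(bool)])
        return cls(flagged=flagged, per_otu=per_otu, alpha=alpha)


def remove_organelle_otus(table: OtuTable) -> OtuTable:
    """Drop OTUs whose taxonomy contains a chloroplast/mitochondrial token."""
    drop = []
    for otu, ranks in table.taxonomy.items():
        joined = ";".join(ranks).lower()
        if any(tok in joined for tok in ORGANELLE_TOKENS):
            drop.append(otu)
    return table.drop_otus(drop) if drop else table


def remove_rare_otus(table: OtuTable, min_fraction: float = 1e-5) -> OtuTable:
    """Drop OTUs representing strictly less than ``min_fraction`` of the
    grand total count (default 0.001%)."""
    totals = table.otu_totals()
    grand = int(totals.sum())
    if grand == 0:
        raise ValueError("table grand total is zero")
    frac = totals / grand
    drop = list(totals.index[frac < min_fraction])
    return table.drop_otus(drop) if drop else table


def identify_contaminants(
    table: OtuTable, metadata: pd.DataFrame, alpha: float = 0.05
) -> ContaminantReport:
    """Flag likely contaminant OTUs by comparing controls against skin."""
    validate_metadata(metadata, table)
    stype = metadata.loc[table.sample_ids, "sample_type"]
    control_ids = list(stype.index[stype == "control"])
    skin_ids = list(stype.index[stype == "skin"])
    if not control_ids:
        raise ValueError("no control samples present in table")
    if not skin_ids:
        raise ValueError("no skin samples present in table")

    rel = table.relative_abundance()
    rel_c = rel.loc[control_ids].to_numpy()
    rel_s = rel.loc[skin_ids].to_numpy()
    cnt_c = table.counts.loc[control_ids].to_numpy()
    cnt_s = table.counts.loc[skin_ids].to_numpy()

    prev_c = (cnt_c > 0).mean(axis=0)
    prev_s = (cnt_s > 0).mean(axis=0)
    mean_c = rel_c.mean(axis=0)
    mean_s = rel_s.mean(axis=0)

    rows = []
    flagged: set[str] = set()
    for j, otu in enumerate(table.otu_ids):
        if prev_c[j] == 0:
            continue  # absent from all controls: never flagged
        kw_h = np.nan
        kw_p = np.nan
        reason = ""
        is_flagged = False
        if prev_c[j] >= prev_s[j]:
            if mean_c[j] >= mean_s[j]:
                is_flagged = True
                reason = "prevalence+abundance"
            else:
                x, y = rel_c[:, j], rel_s[:, j]
                if not np.allclose(np.concatenate([x, y]), x[0]):
                    kw_h, kw_p = stats.kruskal(x, y)
                    ranks = stats.rankdata(np.concatenate([x, y]))
                    ctrl_higher = ranks[: len(x)].mean() > ranks[len(x):].mean()
                    if kw_p < alpha and ctrl_higher:
                        is_flagged = True
                        reason = "prevalence+kw"
        if is_flagged:
            flagged.add(otu)
        rows.append(
            (otu, prev_c[j], prev_s[j], mean_c[j], mean_s[j], kw_h, kw_p, is_flagged, reason)
        )

    per_otu = pd.DataFrame(
        rows, columns=("otu_id",) + ContaminantReport.COLUMNS
    ).set_index("otu_id")
    return ContaminantReport(flagged=flagged, per_otu=per_otu, alpha=alpha)


def remove_contaminants(table: OtuTable, report: ContaminantReport) -> OtuTable:
    """Drop the flagged OTU columns; samples are preserved."""
    unknown = report.flagged - set(table.otu_ids)
    if unknown:
        raise ValueError(f"report references OTUs not in table: {sorted(unknown)[:5]}")
    return table.drop_otus(report.flagged) if report.flagged else table


def rarefy(table: OtuTable, depth: int = 3000, seed: int | None = None) -> OtuTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped (low-coverage loss).
    Deterministic for a fixed ``seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = [s for s in table.sample_ids if totals[s] >= depth]
    out = np.empty((len(keep), len(table.otu_ids)), dtype=np.int64)
    for i, s in enumerate(keep):
        row = table.counts.loc[s].to_numpy()
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    counts = pd.DataFrame(out, index=keep, columns=table.otu_ids)
    return OtuTable(counts, table.taxonomy)


def preprocess_pipeline(
    table: OtuTable,
    metadata: pd.DataFrame,
    min_fraction: float = 1e-5,
    alpha: float = 0.05,
    depth: int = 3000,
    seed: int | None = None,
) -> tuple[OtuTable, ContaminantReport]:
    """Run all four filters in the pipeline's canonical order.

    Returns the rarefied table (controls keep their place in earlier stages
    but typically drop out at rarefaction due to low depth) and the
    contaminant report.
    """
    table = remove_organelle_otus(table)
    table = remove_rare_otus(table, min_fraction=min_fraction)
    report = identify_contaminants(table, metadata, alpha=alpha)
    table = remove_contaminants(table, report)
    table = rarefy(table, depth=depth, seed=seed)
    return table, report
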