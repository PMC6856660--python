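"""End-to-end orchestration of the study-shaped analysis.

``run_pipeline`` executes: simulate-or-load -> preprocess (organelle, rare,
contaminant, rarefy) -> alpha/beta diversity -> permutation inference
(skin vs environment, locality / microhabitat / species effects, sequential
model, pairwise batteries) -> discriminant & core taxa -> host-phylogeny
congruence. Every stage writes its artifact under ``output_dir`` and the
manifest records parameters and the seed, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import OtuTable, group_labels, validate_metadata
from .congruence import congruence_pipeline
from .diversity import alpha_diversity_frame, beta_diversity_matrix, pcoa
from .features import core_otus, discriminant_table, lda_effect_size
from .inference import (
    anosim,
    kruskal_wallis,
    nonparametric_t_test,
    pairwise_groups,
    permanova,
    permanova_sequential,
)
from .preprocess import preprocess_pipeline
from .simulate import SimulationConfig, simulate_community

logger = logging.getLogger("phylosym")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of a full run; defaults follow the pipeline's conventions
    (rarefaction 3000, 999 permutations, 1000 random trees, LDA > 3.0,
    core prevalence >= 0.90)."""

    output_dir: str = "phylosym_out"
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    otu_table: str | None = None
    metadata: str | None = None
    bacterial_tree: str | None = None
    host_tree: str | None = None
    rarefaction_depth: int = 3000
    permutations: int = 999
    random_trees: int = 1000
    jackknife_reps: int = 100
    lda_threshold: float = 3.0
    core_prevalence: float = 0.90
    alpha: float = 0.05
    rare_fraction: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.core_prevalence <= 1:
            raise ValueError("core_prevalence must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        if self.permutations < 1 or self.random_trees < 1:
            raise ValueError("permutations and random_trees must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim:
            cfg.simulation = SimulationConfig(**sim)
        return cfg


def _seed_for(base: int, stage: str) -> int:
    # zlib.crc32 is stable across processes (str hash() is salted)
    import zlib

    h = np.random.SeedSequence([base, zlib.crc32(stage.encode()) % (2**31)])
    return int(h.generate_state(1)[0] % (2**31))


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        ds = simulate_community(config.simulation)
        return ds.otu_table, ds.metadata, ds.bacterial_tree, ds.host_tree, ds
    for name in ("otu_table", "metadata", "bacterial_tree", "host_tree"):
        if getattr(config, name) is None:
            raise ValueError(f"simulate=false requires input path {name!r}")
    table = OtuTable.from_tsv(config.otu_table)
    metadata = pd.read_csv(config.metadata, sep="\t", index_col=0)
    btree = TreeNode.read(config.bacterial_tree)
    htree = TreeNode.read(config.host_tree)
    return table, metadata, btree, htree, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the report dict (also written as JSON)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    report: dict = {"version": __version__, "seed": config.seed}

    def stage(name):
        logger.info("stage: %s", name)

    stage("inputs")
    table, metadata, btree, htree, dataset = _load_inputs(config)
    validate_metadata(metadata, table)
    if dataset is not None:
        dataset.write(out / "simulated")

    stage("preprocess")
    rarefied, contam_report = preprocess_pipeline(
        table, metadata, min_fraction=config.rare_fraction, alpha=config.alpha,
        depth=config.rarefaction_depth, seed=_seed_for(config.seed, "rarefy"),
    )
    contam_report.to_tsv(out / "contaminants.tsv")
    rarefied.to_tsv(out / "rarefied_table.tsv")
    report["preprocess"] = {
        "n_input_otus": len(table.otu_ids),
        "n_flagged_contaminants": len(contam_report.flagged),
        "n_otus_after_filters": len(rarefied.otu_ids),
        "n_samples_retained": len(rarefied.sample_ids),
        "n_samples_dropped_low_coverage": len(table.sample_ids) - len(rarefied.sample_ids),
    }

    md = metadata.loc[rarefied.sample_ids]
    skin_env_ids = list(md.index[md["sample_type"].isin(["skin", "environment"])])
    work = rarefied.select_samples(skin_env_ids)
    md = md.loc[skin_env_ids]

    stage("alpha")
    alpha = alpha_diversity_frame(work, btree)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", index_label="sample_id")
    pd_skin = alpha.loc[md["sample_type"] == "skin", "faith_pd"]
    pd_env = alpha.loc[md["sample_type"] == "environment", "faith_pd"]
    report["alpha"] = {
        "mean_pd_skin": float(pd_skin.mean()),
        "mean_pd_env": float(pd_env.mean()) if len(pd_env) else None,
    }
    if len(pd_env) >= 2 and len(pd_skin) >= 2:
        t_res = nonparametric_t_test(
            pd_env, pd_skin, n_perm=config.permutations, seed=_seed_for(config.seed, "pd_t")
        )
        report["alpha"]["skin_vs_env_t"] = t_res.to_dict()
    skin_md = md[md["sample_type"] == "skin"]
    skin_alpha = alpha.loc[skin_md.index, "faith_pd"]
    species_groups = [skin_alpha[skin_md["species"] == s].to_numpy()
                      for s in sorted(skin_md["species"].dropna().unique())]
    if len(species_groups) >= 2:
        report["alpha"]["pd_species_kw"] = kruskal_wallis(species_groups).to_dict()

    stage("beta")
    report["beta"] = {}
    skin_ids = list(skin_md.index)
    skin_table = work.select_samples(skin_ids)
    groups = group_labels(metadata).loc[skin_ids]
    for metric in ("unweighted_unifrac", "weighted_unifrac"):
        dm = beta_diversity_matrix(work, btree, metric)
        dm.write(str(out / f"{metric}.tsv"))
        coords, eigvals = pcoa(dm, n_axes=3)
        coords.to_csv(out / f"pcoa_{metric}.tsv", sep="\t", index_label="sample_id")
        entry: dict = {}
        entry["skin_vs_env_anosim"] = anosim(
            dm, md["sample_type"], n_perm=config.permutations,
            seed=_seed_for(config.seed, f"se_{metric}"),
        ).to_dict()
        skin_dm = dm.filter(skin_ids)
        for factor in ("locality", "microhabitat", "species"):
            entry[f"{factor}_anosim"] = anosim(
                skin_dm, skin_md[factor], n_perm=config.permutations,
                seed=_seed_for(config.seed, f"a_{factor}_{metric}"),
            ).to_dict()
            entry[f"{factor}_permanova"] = permanova(
                skin_dm, skin_md[factor], n_perm=config.permutations,
                seed=_seed_for(config.seed, f"p_{factor}_{metric}"),
            ).to_dict()
        entry["sequential_permanova"] = [
            r.to_dict()
            for r in permanova_sequential(
                skin_dm, skin_md, ("locality", "microhabitat", "species"),
                n_perm=config.permutations, seed=_seed_for(config.seed, f"seq_{metric}"),
            )
        ]
        pw = pairwise_groups(
            skin_dm, groups, test="anosim", n_perm=config.permutations,
            seed=_seed_for(config.seed, f"pw_{metric}"),
        )
        pw.to_csv(out / f"pairwise_{metric}.tsv", sep="\t", index=False)
        entry["n_pairwise"] = int(len(pw))
        report["beta"][metric] = entry

    stage("discriminants")
    skin_meta = metadata.loc[skin_ids].copy()
    feats = lda_effect_size(
        skin_table, skin_meta, "locality", alpha=config.alpha,
        threshold=config.lda_threshold, seed=_seed_for(config.seed, "lefse"),
    )
    discriminant_table(feats, skin_table).to_csv(out / "discriminant_taxa.tsv", sep="\t", index=False)
    skin_meta["group"] = group_labels(metadata).loc[skin_ids]
    cores = core_otus(skin_table, skin_meta, "group", prevalence=config.core_prevalence)
    with open(out / "core_otus.json", "w") as fh:
        json.dump({c.category_label: sorted(c.otu_ids) for c in cores}, fh, indent=1)
    report["features"] = {
        "n_locality_discriminant": len(feats),
        "core_sizes": {c.category_label: len(c.otu_ids) for c in cores},
    }

    stage("congruence")
    report["congruence"] = congruence_pipeline(
        skin_table, metadata, btree, htree,
        n_perm=config.permutations, n_random=config.random_trees,
        jackknife_reps=config.jackknife_reps, seed=_seed_for(config.seed, "congruence"),
    )

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items() if k != "simulation"},
        "simulation": asdict(config.simulation) if config.simulate else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True, default=str))
    return report
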