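"""Synthetic community generator emulating a two-locality, multi-host
skin-microbiome survey.

The generator starts at the OTU-table level (no sequence simulation): it
draws a Yule host phylogeny and a Yule bacterial phylogeny, builds per-host
expected relative-abundance profiles from a log-normal OTU baseline modulated
by species-, locality- and host-phylogeny effects, and draws multinomial
counts per sample. Environmental samples draw from a larger OTU pool than
skin (higher expected richness), and low-depth control samples carry injected
contaminant OTUs that also leak at a low level into skin samples — the hard
case for control-based decontamination. A ``truth`` record of every injected
effect accompanies the dataset so downstream stages can be scored against
ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import OtuTable

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "SimulationTruth",
    "simulate_host_tree",
    "simulate_bacterial_tree",
    "simulate_community",
    "DEFAULT_SPECIES_TO_LOCALITY",
    "DEFAULT_SPECIES_TO_MICROHABITAT",
]

# Default design: seven congeneric hosts at two nearby localities, one
# generalist present at both sites, nocturnal microhabitat per species.
DEFAULT_SPECIES_TO_LOCALITY: dict[str, tuple[str, ...]] = {
    "E_brittoni": ("CharcoAzul",),
    "E_coqui": ("CharcoAzul", "Quebrada"),
    "E_locustus": ("CharcoAzul",),
    "E_wightmanae": ("CharcoAzul",),
    "E_portoricensis": ("CharcoAzul",),
    "E_richmondi": ("Quebrada",),
    "E_cooki": ("Quebrada",),
}

DEFAULT_SPECIES_TO_MICROHABITAT: dict[str, str] = {
    "E_brittoni": "herbaceous",
    "E_coqui": "arboreal",
    "E_locustus": "arboreal",
    "E_wightmanae": "terrestrial",
    "E_portoricensis": "arboreal",
    "E_richmondi": "terrestrial",
    "E_cooki": "cave_rock",
}


def _as_loc_tuple(v) -> tuple[str, ...]:
    if isinstance(v, str):
        return (v,)
    return tuple(v)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic survey.

    ``locality_effect`` is the fraction of skin-pool OTUs whose presence is
    restricted to a home locality (composition effect); ``species_effect`` is
    the log-scale s.d. of per-species abundance multipliers (structure
    effect); ``phylosymbiosis_strength`` scales Brownian-motion offsets
    evolved on the host tree (applied to a designated OTU subset, on log
    abundance and — via a presence threshold — on composition).
    """

    n_species: int = 7
    localities: tuple[str, ...] = ("CharcoAzul", "Quebrada")
    species_to_locality: Mapping[str, tuple[str, ...] | str] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_TO_LOCALITY)
    )
    species_to_microhabitat: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_TO_MICROHABITAT)
    )
    samples_per_group: int = 15
    n_environment_samples: int = 40
    n_control_samples: int = 8
    n_otus: int = 300
    environment_extra_otus: int = 150
    depth_mean: int = 4000
    control_depth_mean: int = 300
    locality_effect: float = 0.25
    species_effect: float = 0.4
    phylosymbiosis_strength: float = 0.3
    phylosymbiosis_fraction: float = 0.5
    presence_threshold: float = -0.5
    n_contaminants: int = 10
    contaminant_boost: float = 50.0
    contaminant_leak: float = 0.1
    control_carryover: float = 0.15
    base_log_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        self.species_to_locality = {k: _as_loc_tuple(v) for k, v in self.species_to_locality.items()}
        if self.n_species != len(self.species_to_locality):
            raise ValueError("n_species must equal len(species_to_locality)")
        if self.samples_per_group < 1:
            raise ValueError("samples_per_group must be >= 1")
        if self.n_otus < 2:
            raise ValueError("n_otus must be >= 2")
        if self.depth_mean <= 0 or self.control_depth_mean <= 0:
            raise ValueError("depth means must be positive")
        if self.n_contaminants > 0 and self.contaminant_boost <= 1:
            raise ValueError("contaminant_boost must be > 1")
        for s, locs in self.species_to_locality.items():
            if s not in self.species_to_microhabitat:
                raise ValueError(f"species {s!r} has no microhabitat")
            if not locs or any(l not in self.localities for l in locs):
                raise ValueError(f"species {s!r} maps to unknown locality")
        for f in ("locality_effect", "species_effect", "phylosymbiosis_strength"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if not 0 <= self.locality_effect <= 1:
            raise ValueError("locality_effect is a fraction in [0, 1]")

    @property
    def species(self) -> list[str]:
        return list(self.species_to_locality)

    @property
    def groups(self) -> list[tuple[str, str]]:
        """(species, locality) sampling groups — a species at two localities
        yields two groups (two host populations)."""
        return [(s, l) for s, locs in self.species_to_locality.items() for l in locs]


@dataclass
class SimulationTruth:
    """Ground truth of injected effects, for scoring downstream stages."""

    contaminant_ids: list[str]
    locality_restricted: dict[str, str]  # otu_id -> home locality
    phylo_otu_ids: list[str]
    species_log_offsets: pd.DataFrame  # species x skin-pool OTUs

    def to_json(self, path) -> None:
        payload = {
            "contaminant_ids": self.contaminant_ids,
            "locality_restricted": self.locality_restricted,
            "phylo_otu_ids": self.phylo_otu_ids,
            "species_log_offsets": self.species_log_offsets.to_dict(orient="index"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SyntheticDataset:
    otu_table: OtuTable
    metadata: pd.DataFrame
    bacterial_tree: TreeNode
    host_tree: TreeNode
    truth: SimulationTruth
    config: SimulationConfig

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.otu_table.to_tsv(out / "otu_table.tsv")
        self.metadata.to_csv(out / "metadata.tsv", sep="\t", index_label="sample_id")
        self.bacterial_tree.write(str(out / "bacterial_tree.nwk"))
        self.host_tree.write(str(out / "host_tree.nwk"))
        self.truth.to_json(out / "truth.json")


def _yule_tree(n_tips: int, labels: Sequence[str], rng: np.random.Generator, rate: float = 1.0) -> TreeNode:
    """Forward pure-birth simulation; ultrametric, binary, rooted."""
    root = TreeNode()
    birth = {id(root): 0.0}
    active: list[TreeNode] = [root]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (rate * k))
        i = rng.integers(k)
        node = active.pop(i)
        node.length = t - birth.pop(id(node))
        for _ in range(2):
            child = TreeNode()
            birth[id(child)] = t
            node.append(child)
            active.append(child)
    t_end = t + rng.exponential(1.0 / (rate * n_tips))
    order = rng.permutation(n_tips)
    for leaf, j in zip(active, order):
        leaf.length = t_end - birth[id(leaf)]
        leaf.name = labels[j]
    root.length = None
    return root


def simulate_host_tree(n_species: int, seed: int, labels: Sequence[str] | None = None) -> TreeNode:
    """Random ultrametric host phylogeny (Yule / pure-birth process)."""
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if labels is None:
        labels = [f"sp{i + 1:02d}" for i in range(n_species)]
    if len(labels) != n_species:
        raise ValueError("labels length must equal n_species")
    rng = np.random.default_rng(seed)
    return _yule_tree(n_species, list(labels), rng)


def simulate_bacterial_tree(n_otus: int, seed: int, labels: Sequence[str] | None = None) -> TreeNode:
    """Random ultrametric bacterial phylogeny over OTU tips (pure birth)."""
    if n_otus < 2:
        raise ValueError("n_otus must be >= 2")
    if labels is None:
        labels = [f"OTU_{i + 1:04d}" for i in range(n_otus)]
    rng = np.random.default_rng(seed)
    return _yule_tree(n_otus, list(labels), rng)


def _bm_covariance(tree: TreeNode, tips: Sequence[str]) -> np.ndarray:
    """Shared-path (MRCA depth) covariance of Brownian motion on ``tree``,
    normalized to unit height so tip marginals have variance 1."""
    tree = tree.copy()
    depth = {}
    for node in tree.preorder(include_self=True):
        parent_depth = depth.get(id(node.parent), 0.0)
        depth[id(node)] = parent_depth + (node.length or 0.0)
    tip_nodes = {t.name: t for t in tree.tips()}
    height = max(depth[id(t)] for t in tip_nodes.values())
    n = len(tips)
    cov = np.zeros((n, n))
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            if i <= j:
                lca = tip_nodes[a] if a == b else tree.lowest_common_ancestor([a, b])
                cov[i, j] = cov[j, i] = depth[id(lca)] if a != b else depth[id(tip_nodes[a])]
    return cov / height


_TAX_PHYLA = [
    ("p__Proteobacteria", "c__Gammaproteobacteria", "g__Pseudomonas"),
    ("p__Proteobacteria", "c__Betaproteobacteria", "g__Janthinobacterium"),
    ("p__Proteobacteria", "c__Alphaproteobacteria", "g__Sphingomonas"),
    ("p__Bacteroidetes", "c__Sphingobacteriia", "g__Mucilaginibacter"),
    ("p__Bacteroidetes", "c__Cytophagia", "g__Hymenobacter"),
    ("p__Actinobacteria", "c__Actinobacteria", "g__Mycobacterium"),
    ("p__Acidobacteria", "c__Acidobacteriia", "g__Terriglobus"),
    ("p__Firmicutes", "c__Bacilli", "g__Bacillus"),
]


def _taxonomy_for(otu_ids: Sequence[str], rng: np.random.Generator) -> dict[str, tuple[str, ...]]:
    tax = {}
    for o in otu_ids:
        p, c, g = _TAX_PHYLA[rng.integers(len(_TAX_PHYLA))]
        tax[o] = ("k__Bacteria", p, c, "o__", "f__", g)
    return tax


def simulate_community(config: SimulationConfig) -> SyntheticDataset:
    """Draw a full synthetic survey (skin + environment + control samples).

    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    species = config.species
    n_skin_pool = config.n_otus
    n_env_extra = config.environment_extra_otus
    n_cont = config.n_contaminants
    n_total = n_skin_pool + n_env_extra + n_cont

    otu_ids = [f"OTU_{i + 1:04d}" for i in range(n_total)]
    skin_pool = otu_ids[:n_skin_pool]
    env_extra = otu_ids[n_skin_pool:n_skin_pool + n_env_extra]
    contaminants = otu_ids[n_skin_pool + n_env_extra:]

    host_tree = simulate_host_tree(config.n_species, int(rng.integers(2**31)), labels=species)
    bact_tree = simulate_bacterial_tree(n_total, int(rng.integers(2**31)), labels=otu_ids)

    # log-normal baseline over the skin pool; environment extras get their own
    base = rng.normal(0.0, config.base_log_sd, size=n_skin_pool)
    base_extra = rng.normal(0.0, config.base_log_sd, size=n_env_extra)

    # per-species abundance multipliers (structure effect)
    sp_mult = rng.normal(0.0, config.species_effect, size=(len(species), n_skin_pool)) \
        if config.species_effect > 0 else np.zeros((len(species), n_skin_pool))

    # Brownian-motion offsets on the host tree for a designated OTU subset
    n_phylo = int(round(config.phylosymbiosis_fraction * n_skin_pool))
    phylo_idx = np.sort(rng.choice(n_skin_pool, size=n_phylo, replace=False))
    z = np.zeros((len(species), n_skin_pool))
    if config.phylosymbiosis_strength > 0 and n_phylo:
        cov = _bm_covariance(host_tree, species)
        draws = rng.multivariate_normal(np.zeros(len(species)), cov, size=n_phylo)
        z[:, phylo_idx] = draws.T  # standardized (unit variance at tips)

    # locality-restricted OTUs (composition effect)
    n_restricted = int(round(config.locality_effect * n_skin_pool))
    restricted_idx = np.sort(rng.choice(n_skin_pool, size=n_restricted, replace=False))
    homes = rng.integers(len(config.localities), size=n_restricted)
    locality_restricted = {skin_pool[i]: config.localities[h] for i, h in zip(restricted_idx, homes)}

    # expected skin profile per (species, locality) group
    log_w = base[None, :] + sp_mult + config.phylosymbiosis_strength * z
    weights_by_species = np.exp(log_w)
    if config.phylosymbiosis_strength > 0 and n_phylo:
        # presence threshold on the standardized Brownian offset (composition)
        weights_by_species[:, phylo_idx] *= (z[:, phylo_idx] >= config.presence_threshold)

    def skin_profile(sp_i: int, locality: str) -> np.ndarray:
        w = weights_by_species[sp_i].copy()
        for idx, h in zip(restricted_idx, homes):
            if config.localities[h] != locality:
                w[idx] = 0.0
        p = np.zeros(n_total)
        tot = w.sum()
        if tot <= 0:
            raise ValueError("degenerate profile: all OTU weights zero")
        p[:n_skin_pool] = w / tot
        return p

    # control profile: near-empty base plus boosted contaminants. Carry-over
    # from study samples into blanks is sporadic: each control sees only a
    # random sliver (``control_carryover``) of the mean skin community, so
    # most real OTUs have low prevalence across controls. The expected
    # profile below drives the leak of contaminants back into skin samples.
    mean_skin = np.zeros(n_total)
    for i, sp in enumerate(species):
        for loc in config.species_to_locality[sp]:
            mean_skin += skin_profile(i, loc)
    mean_skin /= mean_skin.sum()
    contaminant_w = np.zeros(n_total)
    if n_cont:
        contaminant_w[n_skin_pool + n_env_extra:] = config.contaminant_boost / n_skin_pool
    expected_control_w = config.control_carryover * mean_skin + contaminant_w
    control_p = expected_control_w / expected_control_w.sum()

    def control_profile() -> np.ndarray:
        keep = rng.random(n_total) < config.control_carryover
        w = np.where(keep, mean_skin, 0.0) + contaminant_w
        if w.sum() <= 0:
            w[int(rng.integers(n_skin_pool))] = 1.0
        return w / w.sum()

    def leak_contaminants(p: np.ndarray) -> np.ndarray:
        if not n_cont or config.contaminant_leak <= 0:
            return p
        t = config.contaminant_leak * control_p[n_skin_pool + n_env_extra:]
        out = p * (1.0 - t.sum())
        out[n_skin_pool + n_env_extra:] = t
        return out

    # environment profile per locality: full pool, higher richness than skin
    env_base = np.concatenate([base + rng.normal(0.0, 0.5, size=n_skin_pool), base_extra])

    def env_profile(locality: str) -> np.ndarray:
        w = np.exp(env_base).copy()
        for idx, h in zip(restricted_idx, homes):
            if config.localities[h] != locality:
                w[idx] = 0.0
        p = np.zeros(n_total)
        p[:n_skin_pool + n_env_extra] = w / w.sum()
        return p

    rows, meta_rows, ids = [], [], []

    for sp_i, sp in enumerate(species):
        for loc in config.species_to_locality[sp]:
            p = leak_contaminants(skin_profile(sp_i, loc))
            for k in range(config.samples_per_group):
                depth = rng.poisson(config.depth_mean)
                rows.append(rng.multinomial(depth, p))
                ids.append(f"skin_{sp}_{loc}_{k + 1:02d}")
                meta_rows.append(("skin", sp, loc, config.species_to_microhabitat[sp]))

    n_loc = len(config.localities)
    per_loc = [config.n_environment_samples // n_loc] * n_loc
    for i in range(config.n_environment_samples - sum(per_loc)):
        per_loc[i] += 1
    for loc, n_env in zip(config.localities, per_loc):
        p = env_profile(loc)
        for k in range(n_env):
            depth = rng.poisson(config.depth_mean)
            rows.append(rng.multinomial(depth, p))
            ids.append(f"env_{loc}_{k + 1:02d}")
            meta_rows.append(("environment", None, loc, None))

    for k in range(config.n_control_samples):
        depth = rng.poisson(config.control_depth_mean)
        rows.append(rng.multinomial(depth, control_profile()))
        ids.append(f"ctrl_{k + 1:02d}")
        meta_rows.append(("control", None, None, None))

    counts = pd.DataFrame(np.asarray(rows, dtype=np.int64), index=ids, columns=otu_ids)
    metadata = pd.DataFrame(
        meta_rows, index=ids, columns=["sample_type", "species", "locality", "microhabitat"]
    )
    taxonomy = _taxonomy_for(otu_ids, rng)

    truth = SimulationTruth(
        contaminant_ids=list(contaminants),
        locality_restricted=locality_restricted,
        phylo_otu_ids=[skin_pool[i] for i in phylo_idx],
        species_log_offsets=pd.DataFrame(
            sp_mult + config.phylosymbiosis_strength * z, index=species, columns=skin_pool
        ),
    )
    return SyntheticDataset(
        otu_table=OtuTable(counts, taxonomy),
        metadata=metadata,
        bacterial_tree=bact_tree,
        host_tree=host_tree,
        truth=truth,
        config=config,
    )
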