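import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from phylosym.containers import OtuTable
from phylosym.simulate import SimulationConfig, simulate_community


@pytest.fixture
def four_tip_tree():
    return TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1);"])


@pytest.fixture
def small_table():
    counts = pd.DataFrame(
        [[10, 5, 0, 1], [0, 8, 2, 0], [3, 3, 3, 3]],
        index=["s1", "s2", "s3"],
        columns=["O1", "O2", "O3", "O4"],
    )
    taxonomy = {
        "O1": ("k__Bacteria", "p__Proteobacteria"),
        "O2": ("k__Bacteria", "c__Chloroplast"),
        "O3": ("k__Bacteria", "f__mitochondria"),
        "O4": ("k__Bacteria", "p__Firmicutes"),
    }
    return OtuTable(counts, taxonomy)


def small_config(**overrides) -> SimulationConfig:
    """Scaled-down survey used across tests: 3 species at 2 localities."""
    base = dict(
        n_species=3,
        localities=("L1", "L2"),
        species_to_locality={"spA": ("L1",), "spB": ("L1",), "spC": ("L2",)},
        species_to_microhabitat={"spA": "arboreal", "spB": "terrestrial", "spC": "arboreal"},
        samples_per_group=5,
        n_environment_samples=6,
        n_control_samples=4,
        n_otus=80,
        environment_extra_otus=40,
        depth_mean=1500,
        control_depth_mean=150,
        locality_effect=0.2,
        species_effect=0.3,
        phylosymbiosis_strength=0.0,
        n_contaminants=5,
        seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def null_config(**overrides) -> SimulationConfig:
    """All effects off: exchangeable skin samples, no contaminants."""
    return small_config(
        locality_effect=0.0,
        species_effect=0.0,
        phylosymbiosis_strength=0.0,
        n_contaminants=0,
        **overrides,
    )


@pytest.fixture
def small_dataset():
    return simulate_community(small_config(seed=11))
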