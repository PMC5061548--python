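import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from retroexpand.config import SimulationConfig, derive_rng
from retroexpand import simulate as sim
from retroexpand.trees import build_species_tree


@pytest.fixture(scope="session")
def paenungulata():
    return build_species_tree("paenungulata")


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def reference_family():
    """Deterministic 19-copy reference family: dated gene tree, sequences
    (copies + parent gene), per-gene truth. Shared across tests."""
    cfg = SimulationConfig(seed=0)
    tree = sim.reference_gene_tree()
    seqset = sim.evolve_sequences(tree, cfg, origin_age=65.0, seed=101)
    return cfg, tree, seqset


def make_orthologs(seqset, gene_ids, divergence_my, cfg, seed, prefix="focal__"):
    """Focal-genome ortholog sequences: each reference gene evolved for an
    extra 2 * divergence_my of independent history."""
    rng = derive_rng(seed, "orthologs")
    out = {}
    for g in gene_ids:
        arr = sim.encode(seqset.sequences[g])
        out[prefix + g] = sim.decode(
            sim._mutate_k2p(arr, 2 * divergence_my, cfg.substitution_rate,
                            cfg.kappa, rng))
    return out


def make_controls(n, length, seed):
    rng = derive_rng(seed, "controls")
    return {f"control_{i + 1}": sim.decode(rng.integers(0, 4, length).astype(np.uint8))
            for i in range(n)}
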