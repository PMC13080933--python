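import numpy as np
import pytest

from pocketformer import (BackboneConfig, InteractionModel, SyntheticSpec,
                          generate_complex)


@pytest.fixture
def tiny_spec():
    """Small complexes so joint graphs stay under ~24 atoms."""
    return SyntheticSpec(n_pocket_atoms=14, n_ligand_atoms=6, seed=7)


@pytest.fixture
def tiny_pair(tiny_spec):
    return generate_complex(tiny_spec, np.random.default_rng(7))


@pytest.fixture
def f64_config():
    """Double-precision config for oracle-equivalence comparisons."""
    return BackboneConfig(layers=2, heads=2, atom_dim=8, ffn_dim=16,
                          rbf_kernels=4, dtype="float64")


@pytest.fixture
def f64_model(f64_config):
    return InteractionModel(f64_config, proj_dim=6, seed=11)


@pytest.fixture
def desk_model():
    return InteractionModel(BackboneConfig(), seed=3)


def random_rigid(rng):
    """A uniformly random rotation matrix and a translation."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=np.random.RandomState(
        int(rng.integers(2 ** 31)))).as_matrix()
    t = rng.normal(0, 5.0, 3)
    return R, t


def apply_rigid(graph, R, t):
    from dataclasses import replace
    return replace(graph, coords=graph.coords @ R.T + t)
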