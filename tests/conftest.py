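import numpy as np
import pytest

import invfold as iv
from invfold.backbone import BackboneStructure, compute_virtual_cb


@pytest.fixture(scope="session")
def helix10() -> BackboneStructure:
    return iv.make_backbone(iv.SyntheticSpec(kind="helix", length=10))


@pytest.fixture(scope="session")
def hairpin14() -> BackboneStructure:
    return iv.make_backbone(
        iv.SyntheticSpec(kind="two_helix_hairpin", length=14, jitter_std=0.2, seed=3))


@pytest.fixture(scope="session")
def tiny_config() -> iv.ModelConfig:
    return iv.ModelConfig(n_encoder_layers=1, n_decoder_layers=2, hidden_dim=8,
                          dropout=0.0, featurizer=iv.FeaturizerConfig(k_neighbors=6))


@pytest.fixture(scope="session")
def tiny_params(tiny_config) -> iv.ModelParams:
    return iv.init_params(tiny_config, seed=11)


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random proper rotation and a translation."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q, rng.normal(scale=25.0, size=3)


def apply_rigid(structure: BackboneStructure, rot: np.ndarray,
                trans: np.ndarray) -> BackboneStructure:
    out = structure.copy()
    out.coords = structure.coords @ rot.T + trans
    out.cb = compute_virtual_cb(out.coords, out.residue_mask)
    return out


def make_tiny_chain(n: int) -> BackboneStructure:
    """A small single-chain fragment built from the synthetic helix trace."""
    full = iv.make_backbone(iv.SyntheticSpec(kind="helix", length=max(n, 5)))
    coords = full.coords[:n].copy()
    mask = np.ones(n, dtype=bool)
    return BackboneStructure(
        chain_ids=["A"],
        residue_numbers=[[str(i + 1) for i in range(n)]],
        coords=coords,
        cb=compute_virtual_cb(coords, mask),
        atom_mask=np.ones((n, 4), dtype=bool),
        residue_mask=mask,
        chain_index=np.zeros(n, dtype=np.int64),
        chain_pos=np.arange(n, dtype=np.int64),
    )
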