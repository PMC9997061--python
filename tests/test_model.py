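"""Encoder-decoder network: parameter accounting, invariances, autoregression."""

import dataclasses

import numpy as np
import pytest

import invfold as iv
from invfold import nn
from invfold.errors import ConfigurationError
from invfold.model import attend_from_ranks

from conftest import apply_rigid, make_tiny_chain, random_rigid_transform


def _random_order_attend(batch, n, seed):
    perm = np.random.default_rng(seed).permutation(n)
    ranks = np.empty(n, dtype=np.int64)
    ranks[perm] = np.arange(n)
    return perm, ranks, attend_from_ranks(ranks[None], batch.neighbor_index)


class TestParameterAccounting:
    def test_count_matches_enumeration_random_configs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            cfg = iv.ModelConfig(
                n_encoder_layers=int(rng.integers(1, 4)),
                n_decoder_layers=int(rng.integers(1, 4)),
                hidden_dim=int(rng.integers(2, 24)),
                ffn_multiplier=int(rng.integers(1, 5)),
                vocab=int(rng.integers(3, 25)),
                edge_updates=bool(rng.integers(0, 2)),
                featurizer=iv.FeaturizerConfig(n_rbf=int(rng.integers(2, 20))),
            )
            params = iv.init_params(cfg, seed=1)
            # brute force: enumerate every scalar in the instantiated params
            enumerated = sum(t.data.size for t in params.tensors.values())
            assert enumerated == iv.count_parameters(cfg) == params.total_count

    def test_toy_config_enumeration(self):
        cfg = iv.ModelConfig(n_encoder_layers=1, n_decoder_layers=1, hidden_dim=2,
                             ffn_multiplier=1, vocab=3)
        params = iv.init_params(cfg, 0)
        assert iv.count_parameters(cfg) == sum(t.data.size for t in params.tensors.values())

    def test_edge_update_toggle_delta(self):
        with_updates = iv.ModelConfig(edge_updates=True)
        without = iv.ModelConfig(edge_updates=False)
        delta = iv.count_parameters(with_updates) - iv.count_parameters(without)
        # 3 encoder layers x ((3*128+1)*128 + 2*(128+1)*128 + 2*128)
        assert delta == 3 * ((3 * 128 + 1) * 128 + 2 * (128 + 1) * 128 + 2 * 128)
        assert delta == 247_680

    def test_edge_input_widening_delta(self):
        # widening the raw edge features by 384 dimensions costs exactly
        # 384 * hidden through the bias-free input projection
        narrow = iv.ModelConfig()
        wide = iv.ModelConfig(featurizer=iv.FeaturizerConfig(cap=32 + 192))
        assert wide.featurizer.edge_width - narrow.featurizer.edge_width == 384
        assert iv.count_parameters(wide) - iv.count_parameters(narrow) == 384 * 128
        assert 384 * 128 == 49_152


class TestInitParams:
    def test_seed_reproducibility(self, tiny_config):
        a = iv.init_params(tiny_config, 5)
        b = iv.init_params(tiny_config, 5)
        c = iv.init_params(tiny_config, 6)
        assert all(np.array_equal(a[k].data, b[k].data) for k in a.tensors)
        assert any(not np.array_equal(a[k].data, c[k].data) for k in a.tensors)

    def test_norm_gains_one_offsets_zero(self, tiny_config):
        p = iv.init_params(tiny_config, 0)
        assert np.array_equal(p["enc0.norm1.gain"].data, np.ones(8))
        assert np.array_equal(p["enc0.norm1.offset"].data, np.zeros(8))


class TestEncoder:
    def test_zero_weight_params_finite(self, tiny_config, helix10):
        params = iv.init_params(tiny_config, 0)
        for t in params.tensors.values():
            t.data[:] = 0
        batch = iv.GraphBatch.from_graph(iv.featurize(helix10, tiny_config.featurizer))
        h_v, h_e = iv.encode(batch, params, tiny_config)
        assert np.isfinite(h_v.data).all() and np.isfinite(h_e.data).all()
        assert np.abs(h_v.data).max() == 0.0  # zero stream through zero offsets

    def test_permutation_equivariance(self, tiny_config, tiny_params):
        s = iv.make_backbone(iv.SyntheticSpec(kind="helix", length=9,
                                              jitter_std=0.2, seed=4))
        g = iv.featurize(s, tiny_config.featurizer)
        batch = iv.GraphBatch.from_graph(g)
        h_v, _ = iv.encode(batch, tiny_params, tiny_config)
        perm = np.random.default_rng(0).permutation(9)
        inv = np.argsort(perm)
        g2 = dataclasses.replace(
            g,
            neighbor_index=inv[g.neighbor_index[perm]],
            edge_features=g.edge_features[perm],
            edge_mask=g.edge_mask[perm],
            node_mask=g.node_mask[perm],
        )
        h_v2, _ = iv.encode(iv.GraphBatch.from_graph(g2), tiny_params, tiny_config)
        assert np.abs(h_v2.data[0] - h_v.data[0][perm]).max() < 1e-5

    def test_rigid_motion_invariance_end_to_end(self, tiny_config, tiny_params, hairpin14):
        rng = np.random.default_rng(1)
        rot, trans = random_rigid_transform(rng)
        moved = apply_rigid(hairpin14, rot, trans)
        b0 = iv.GraphBatch.from_graph(iv.featurize(hairpin14, tiny_config.featurizer))
        b1 = iv.GraphBatch.from_graph(iv.featurize(moved, tiny_config.featurizer))
        h0, _ = iv.encode(b0, tiny_params, tiny_config)
        h1, _ = iv.encode(b1, tiny_params, tiny_config)
        assert np.abs(h0.data - h1.data).max() < 1e-5

    def test_shape_mismatch_rejected(self, tiny_params, tiny_config, helix10):
        other = dataclasses.replace(tiny_config,
                                    featurizer=iv.FeaturizerConfig(n_rbf=4))
        batch = iv.GraphBatch.from_graph(iv.featurize(helix10, other.featurizer))
        with pytest.raises(ConfigurationError):
            iv.encode(batch, tiny_params, tiny_config)


class TestDecoder:
    def test_first_position_independent_of_all_tokens(self, tiny_config, tiny_params, helix10):
        batch = iv.GraphBatch.from_graph(iv.featurize(helix10, tiny_config.featurizer))
        h_v, h_e = iv.encode(batch, tiny_params, tiny_config)
        perm, ranks, att = _random_order_attend(batch, 10, seed=3)
        tok = np.random.default_rng(0).integers(0, 21, 10)
        l1 = iv.decode_logits(h_v, h_e, batch, tok[None], att, tiny_params, tiny_config)
        l2 = iv.decode_logits(h_v, h_e, batch, ((tok + 9) % 21)[None], att,
                              tiny_params, tiny_config)
        assert np.array_equal(l1.data[0, perm[0]], l2.data[0, perm[0]])

    def test_no_sensitivity_to_later_tokens(self, tiny_config, tiny_params, helix10):
        batch = iv.GraphBatch.from_graph(iv.featurize(helix10, tiny_config.featurizer))
        h_v, h_e = iv.encode(batch, tiny_params, tiny_config)
        perm, ranks, att = _random_order_attend(batch, 10, seed=7)
        tok = np.random.default_rng(1).integers(0, 21, 10)
        base = iv.decode_logits(h_v, h_e, batch, tok[None], att,
                                tiny_params, tiny_config).data[0]
        for i in range(10):
            later = perm[np.nonzero(ranks[perm] > ranks[i])[0]]
            if later.size == 0:
                continue
            tok2 = tok.copy()
            tok2[later] = (tok2[later] + 5) % 21
            pert = iv.decode_logits(h_v, h_e, batch, tok2[None], att,
                                    tiny_params, tiny_config).data[0]
            assert np.array_equal(base[i], pert[i])  # exactly zero sensitivity

    def test_sensitive_to_earlier_neighbor_token(self, tiny_config, tiny_params, helix10):
        batch = iv.GraphBatch.from_graph(iv.featurize(helix10, tiny_config.featurizer))
        h_v, h_e = iv.encode(batch, tiny_params, tiny_config)
        perm, ranks, att = _random_order_attend(batch, 10, seed=5)
        last = perm[-1]
        earlier_nb = [int(j) for j in batch.neighbor_index[0, last]
                      if ranks[j] < ranks[last]]
        assert earlier_nb
        tok = np.random.default_rng(2).integers(0, 21, 10)
        base = iv.decode_logits(h_v, h_e, batch, tok[None], att,
                                tiny_params, tiny_config).data[0]
        tok2 = tok.copy()
        tok2[earlier_nb[0]] = (tok2[earlier_nb[0]] + 11) % 21
        pert = iv.decode_logits(h_v, h_e, batch, tok2[None], att,
                                tiny_params, tiny_config).data[0]
        assert not np.allclose(base[last], pert[last])

    def test_eval_mode_bit_deterministic(self, tiny_config, tiny_params, helix10):
        batch = iv.GraphBatch.from_graph(iv.featurize(helix10, tiny_config.featurizer))
        h_v, h_e = iv.encode(batch, tiny_params, tiny_config)
        _, _, att = _random_order_attend(batch, 10, seed=0)
        tok = np.zeros(10, dtype=np.int64)
        a = iv.decode_logits(h_v, h_e, batch, tok[None], att, tiny_params, tiny_config)
        b = iv.decode_logits(h_v, h_e, batch, tok[None], att, tiny_params, tiny_config)
        assert np.array_equal(a.data, b.data)

    def test_training_dropout_seed_reproducible(self, helix10):
        cfg = iv.ModelConfig(n_encoder_layers=1, n_decoder_layers=1, hidden_dim=8,
                             dropout=0.3, featurizer=iv.FeaturizerConfig(k_neighbors=6))
        params = iv.init_params(cfg, 0)
        batch = iv.GraphBatch.from_graph(iv.featurize(helix10, cfg.featurizer))
        _, _, att = _random_order_attend(batch, 10, seed=0)
        tok = np.zeros(10, dtype=np.int64)

        def run(seed):
            h_v, h_e = iv.encode(batch, params, cfg, train=True,
                                 rng=np.random.default_rng(seed))
            return iv.decode_logits(h_v, h_e, batch, tok[None], att, params, cfg,
                                    train=True, rng=np.random.default_rng(seed + 100)).data

        assert np.array_equal(run(1), run(1))
        assert not np.array_equal(run(1), run(2))


class TestCheckpoint:
    def test_roundtrip(self, tmp_path, tiny_config, tiny_params):
        path = tmp_path / "m.ckpt"
        iv.save_checkpoint(tiny_params, tiny_config, path)
        params, config = iv.load_checkpoint(path)
        assert config == tiny_config
        assert all(np.array_equal(params[k].data, tiny_params[k].data)
                   for k in tiny_params.tensors)

    def test_schema_guard(self, tmp_path, tiny_config, tiny_params):
        import json
        import zipfile

        path = tmp_path / "bad.ckpt"
        iv.save_checkpoint(tiny_params, tiny_config, path)
        with zipfile.ZipFile(path) as zf:
            weights = zf.read("weights.npz")
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps({"schema_version": 999, "model": {}}))
            zf.writestr("weights.npz", weights)
        with pytest.raises(ConfigurationError):
            iv.load_checkpoint(path)
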