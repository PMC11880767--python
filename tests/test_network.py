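"""Model wiring: fusion mechanics, forward determinism, mode invariances."""

import numpy as np
import pytest

from kcatnet.autodiff import Tensor
from kcatnet.errors import ConfigError, FusionError, InputError
from kcatnet.features import build_vocabularies, featurize_records
from kcatnet.network import FusionParams, KcatNetwork, ModelConfig, fuse_and_attend
from kcatnet.synthetic import make_synthetic_dataset
from kcatnet.training import TrainConfig, train


@pytest.fixture(scope="module")
def tiny_dataset():
    records, structures = make_synthetic_dataset(12, seed=21)
    return records, structures


def _featurize(records, structures, config):
    seq_vocab, env_vocab = build_vocabularies(records, config)
    feats = featurize_records(records, seq_vocab, env_vocab, config, structures=structures)
    return seq_vocab, env_vocab, feats


class TestFuseAndAttend:
    def test_zero_weights_give_half_attention(self):
        d = 4
        params = FusionParams(w_inter=Tensor(np.zeros((d, d))), b=Tensor(np.zeros(d)))
        C = np.random.default_rng(0).normal(size=(6, d))
        y = np.ones(d)
        _, a = fuse_and_attend(C, y, None, params, mode="sequence_only")
        assert np.allclose(a.numpy(), 0.5)

    def test_one_dimensional_hand_case(self):
        # W=1, b=0, y=2, c=3 (ReLU active): a = sigmoid(2*3)
        params = FusionParams(w_inter=Tensor(np.array([[1.0]])), b=Tensor(np.array([0.0])))
        _, a = fuse_and_attend(np.array([[3.0]]), np.array([2.0]), None, params, mode="sequence_only")
        assert a.numpy()[0] == pytest.approx(1 / (1 + np.exp(-6)), abs=1e-9)

    def test_attention_weights_strictly_in_unit_interval(self, rng):
        # moderate scale: avoids float64 sigmoid saturation at |x| ≳ 37
        d = 8
        params = FusionParams(
            w_inter=Tensor(rng.normal(scale=0.3, size=(d, d))),
            b=Tensor(rng.normal(scale=0.3, size=d)),
        )
        for _ in range(10):
            C = rng.normal(size=(int(rng.integers(1, 20)), d))
            _, a = fuse_and_attend(C, rng.normal(size=d), rng.normal(size=d), params, mode="full")
            values = a.numpy()
            assert np.all(values > 0) and np.all(values < 1)

    def test_empty_sequence_set_rejected(self):
        d = 2
        params = FusionParams(w_inter=Tensor(np.eye(d)), b=Tensor(np.zeros(d)))
        with pytest.raises(FusionError):
            fuse_and_attend(np.zeros((0, d)), np.ones(d), None, params, mode="full")

    def test_fused_width_by_mode(self, rng):
        d = 4
        params = FusionParams(w_inter=Tensor(np.eye(d)), b=Tensor(np.zeros(d)))
        C, y, s = rng.normal(size=(3, d)), rng.normal(size=d), rng.normal(size=d)
        widths = {
            "full": 3 * d,
            "sequence_only": 2 * d,
            "structure_only": 2 * d,
            "substrate_only": d,
        }
        for mode, width in widths.items():
            fused, _ = fuse_and_attend(C, y, s, params, mode=mode)
            assert fused.shape == (1, width)


class TestModelConfig:
    def test_invalid_mode(self):
        with pytest.raises(ConfigError):
            ModelConfig(mode="nonsense")

    def test_head_divisibility(self):
        with pytest.raises(ConfigError):
            ModelConfig(d_model=30, n_heads=4)

    def test_roundtrip(self):
        cfg = ModelConfig(d_model=16, n_heads=2, mode="sequence_only")
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg


class TestForward:
    def test_deterministic_and_finite(self, tiny_dataset):
        records, structures = tiny_dataset
        config = ModelConfig(seed=5)
        seq_vocab, env_vocab, feats = _featurize(records, structures, config)
        net_a = KcatNetwork(config, seq_vocab, env_vocab)
        net_b = KcatNetwork(config, seq_vocab, env_vocab)
        preds_a = net_a.predict(feats)
        preds_b = net_b.predict(feats)
        assert np.all(np.isfinite(preds_a))
        assert np.allclose(preds_a, net_a.predict(feats), atol=1e-12)  # re-run
        assert np.allclose(preds_a, preds_b, atol=1e-12)  # re-init, same seed

    def test_attention_weight_count_is_window_count(self, tiny_dataset):
        records, structures = tiny_dataset
        config = ModelConfig(seed=5)
        seq_vocab, env_vocab, feats = _featurize(records, structures, config)
        net = KcatNetwork(config, seq_vocab, env_vocab)
        for feat in feats[:3]:
            _, a = net.forward(feat)
            assert len(a.numpy()) == len(feat.token_ids)

    def test_token_permutation_changes_output(self, tiny_dataset):
        # positional encodings break permutation symmetry
        records, structures = tiny_dataset
        config = ModelConfig(seed=5)
        seq_vocab, env_vocab, feats = _featurize(records, structures, config)
        net = KcatNetwork(config, seq_vocab, env_vocab)
        feat = feats[0]
        base = net.predict_one(feat)
        flipped = type(feat)(**{**feat.__dict__, "token_ids": feat.token_ids[::-1].copy()})
        assert net.predict_one(flipped) != pytest.approx(base, abs=1e-9)

    def test_sequence_only_invariant_to_contact_map(self, tiny_dataset):
        records, structures = tiny_dataset
        config = ModelConfig(seed=5, mode="sequence_only")
        seq_vocab, env_vocab, feats = _featurize(records, structures, config)
        net = KcatNetwork(config, seq_vocab, env_vocab)
        feat = feats[0]
        base = net.predict_one(feat)
        # attach a bogus contact map: prediction must not move
        n = len(records[0].sequence)
        perturbed = type(feat)(**{
            **feat.__dict__,
            "contact_adjacency": np.zeros((n, n), dtype=np.int8),
        })
        assert net.predict_one(perturbed) == pytest.approx(base, abs=1e-12)

    def test_structure_only_invariant_to_token_ids(self, tiny_dataset):
        records, structures = tiny_dataset
        config = ModelConfig(seed=5, mode="structure_only")
        seq_vocab, env_vocab, feats = _featurize(records, structures, config)
        net = KcatNetwork(config, seq_vocab, env_vocab)
        feat = feats[0]
        base = net.predict_one(feat)
        perturbed = type(feat)(**{
            **feat.__dict__,
            "token_ids": np.zeros(7, dtype=np.intp),
        })
        assert net.predict_one(perturbed) == pytest.approx(base, abs=1e-12)

    def test_structure_stream_is_live_after_training(self, tiny_dataset):
        records, structures = tiny_dataset
        config = ModelConfig(seed=5)
        seq_vocab, env_vocab, feats = _featurize(records, structures, config)
        net = KcatNetwork(config, seq_vocab, env_vocab)
        train(net, feats[:8], None, TrainConfig(epochs=5, batch_size=8, seed=5))
        feat = feats[0]
        base = net.predict_one(feat)
        n = feat.contact_adjacency.shape[0]
        zeroed = type(feat)(**{
            **feat.__dict__,
            "contact_adjacency": np.zeros((n, n), dtype=np.int8),
            "protein_propagator": None,
        })
        assert net.predict_one(zeroed) != pytest.approx(base, abs=1e-9)

    def test_missing_structure_in_structure_mode(self, tiny_dataset):
        records, structures = tiny_dataset
        config = ModelConfig(seed=5)
        seq_vocab, env_vocab, feats = _featurize(records, structures, config)
        net = KcatNetwork(config, seq_vocab, env_vocab)
        feat = feats[0]
        broken = type(feat)(**{**feat.__dict__, "contact_adjacency": None})
        with pytest.raises(InputError):
            net.forward(broken)


class TestCheckpoint:
    def test_save_load_preserves_predictions(self, tiny_dataset, tmp_path):
        records, structures = tiny_dataset
        config = ModelConfig(seed=9)
        seq_vocab, env_vocab, feats = _featurize(records, structures, config)
        net = KcatNetwork(config, seq_vocab, env_vocab)
        train(net, feats, None, TrainConfig(epochs=2, seed=9))
        path = tmp_path / "model.ckpt.npz"
        net.save(path)
        restored = KcatNetwork.load(path)
        assert restored.config == net.config
        assert restored.seq_vocab.token_to_id == net.seq_vocab.token_to_id
        assert np.allclose(restored.predict(feats), net.predict(feats), atol=1e-12)

    def test_missing_checkpoint_error(self):
        with pytest.raises(InputError):
            KcatNetwork.load("/nonexistent/model.npz")


def test_sequence_structure_length_mismatch_is_hard_error(tiny_dataset):
    records, structures = tiny_dataset
    config = ModelConfig(seed=5)
    record = records[0]
    bad = type(record)(
        record_id=record.record_id,
        sequence=record.sequence + "AAA",
        smiles=record.smiles,
        kcat=record.kcat,
    )
    seq_vocab, env_vocab = build_vocabularies([bad], config)
    with pytest.raises(InputError, match="does not match"):
        featurize_records([bad], seq_vocab, env_vocab, config, structures={record.record_id: structures[record.record_id]})
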