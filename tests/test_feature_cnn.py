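"""Feature-extraction CNN: architecture, training, feature maps, checkpoints."""

import numpy as np
import pytest

from conftest import tiny_config

from genomicstyle import feature_cnn as fc
from genomicstyle import synthetic
from genomicstyle.seqio import DnaSequence, one_hot_encode


class TestConfig:
    def test_requires_eight_modules(self):
        with pytest.raises(ValueError, match="8"):
            fc.FeatureCnnConfig(
                modules=tuple(fc.ConvModuleSpec(4, 3) for _ in range(7)),
                n_classes=2,
            )

    def test_spatial_collapse_rejected(self):
        with pytest.raises(ValueError, match="collapses"):
            fc.FeatureCnnConfig(
                modules=tuple(fc.ConvModuleSpec(4, 3, pool_size=4) for _ in range(8)),
                n_classes=2,
                input_length=1024,  # 1024 / 4^8 < 1
            )

    def test_default_shapes(self):
        cfg = fc.FeatureCnnConfig.default(n_classes=5)
        assert len(cfg.modules) == 8
        assert all(m.n_filters == 64 for m in cfg.modules)
        assert cfg.modules[0].filter_size == 8

    def test_dict_round_trip(self):
        cfg = tiny_config(n_classes=4, seed=9)
        assert fc.FeatureCnnConfig.from_dict(cfg.to_dict()) == cfg


class TestBuildAndForward:
    def test_same_seed_identical_weights(self):
        a = fc.build_model(tiny_config(seed=7))
        b = fc.build_model(tiny_config(seed=7))
        for la, lb in zip(a.layers(), b.layers()):
            for k in la.params():
                assert np.array_equal(la.params()[k], lb.params()[k])

    def test_forward_shapes(self, tiny_model):
        x = np.zeros((2, 4, 256), dtype=np.float32)
        logits, maps = tiny_model.forward(x)
        assert logits.shape == (2, 3)
        assert len(maps) == 8
        assert maps[0].shape == (2, 4, 256)
        assert maps[1].shape == (2, 4, 128)

    def test_zero_input_layer1_is_constant_activation(self, tiny_model):
        """Convolving zeros leaves only the bias: every layer-1 feature map is
        a constant (the activated, normalized bias) across positions."""
        maps = fc.extract_feature_maps(tiny_model, np.zeros((4, 256)), upto_layer=1)
        m = maps[0]
        assert np.allclose(m, m[:, :1])
        assert (m >= 0).all()

    def test_feature_maps_nonnegative(self, tiny_model, rng):
        from conftest import random_dna

        win = one_hot_encode(DnaSequence("x", random_dna(rng, 256)))
        maps = fc.extract_feature_maps(tiny_model, win)
        assert all((m >= 0).all() for m in maps)

    def test_determinism(self, tiny_model, rng):
        from conftest import random_dna

        win = one_hot_encode(DnaSequence("x", random_dna(rng, 256)))
        a = fc.extract_feature_maps(tiny_model, win)
        b = fc.extract_feature_maps(tiny_model, win)
        for ma, mb in zip(a, b):
            assert np.array_equal(ma, mb)

    def test_wrong_shape_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="expected windows"):
            fc.extract_feature_maps(tiny_model, np.zeros((4, 100)))

    def test_layer1_matches_triple_loop_cross_correlation(self, rng):
        """Layer-1 feature maps equal a direct sliding-inner-product
        implementation (same padding, stride 1) followed by the inference
        batch-norm affine and ReLU."""
        cfg = fc.FeatureCnnConfig(
            modules=tuple(fc.ConvModuleSpec(2, 5, pool_size=1) for _ in range(8)),
            n_classes=2,
            input_length=20,
            seed=13,
        )
        model = fc.build_model(cfg)
        from conftest import random_dna

        win = one_hot_encode(DnaSequence("x", random_dna(rng, 20)))
        got = fc.extract_feature_maps(model, win, upto_layer=1)[0]

        conv, bn = model.convs[0], model.bns[0]
        d, pad = 5, 2
        padded = np.zeros((4, 20 + d - 1))
        padded[:, pad : pad + 20] = win
        expected = np.zeros((2, 20))
        for k in range(2):  # filter
            for t in range(20):  # position
                acc = conv.b[k]
                for j in range(d):  # tap
                    for c in range(4):  # channel
                        acc += conv.W[j, c, k] * padded[c, t + j]
                z = (acc - bn.running_mean[k]) / np.sqrt(bn.running_var[k] + bn.eps)
                expected[k, t] = max(bn.gamma[k] * z + bn.beta[k], 0.0)
        np.testing.assert_allclose(got, expected, atol=1e-5)


class TestTrain:
    def test_two_species_gc_task_learns(self, gc2_model, gc2_training_set):
        X, y, _ = fc.encode_dataset(gc2_training_set, 1024)
        assert fc.holdout_accuracy(gc2_model, X, y) > 0.95

    def test_epochs_zero_is_noop(self, gc2_training_set):
        model = fc.build_model(fc.FeatureCnnConfig.default(n_classes=2, seed=1, n_filters=4))
        before = [p.copy() for l in model.layers() for p in l.params().values()]
        model, log = fc.train(model, gc2_training_set, epochs=0, seed=1)
        after = [p for l in model.layers() for p in l.params().values()]
        assert log == []
        assert all(np.array_equal(b, a) for b, a in zip(before, after))

    def test_single_class_rejected(self, species_pair):
        ds = synthetic.make_pretraining_set(species_pair, 10, seed=1, genome_length=5000)
        ds_one = synthetic.LabeledDataset(ds.sequences, ["only"] * len(ds))
        model = fc.build_model(fc.FeatureCnnConfig.default(n_classes=2, seed=1, n_filters=4))
        with pytest.raises(ValueError, match="2 classes"):
            fc.train(model, ds_one, epochs=1)

    def test_training_log_monotone_trend(self, gc2_training_set):
        model = fc.build_model(fc.FeatureCnnConfig.default(n_classes=2, seed=3, n_filters=8))
        model, log = fc.train(model, gc2_training_set, epochs=3, batch_size=32, seed=5)
        assert len(log) == 3
        assert log[-1].train_loss < log[0].train_loss

    def test_shuffle_stability(self, gc2_training_set):
        """Same init, different shuffling: holdout accuracy moves < 5 points."""
        X, y, _ = fc.encode_dataset(gc2_training_set, 1024)
        accs = []
        for shuffle_seed in (5, 6):
            model = fc.build_model(
                fc.FeatureCnnConfig.default(n_classes=2, seed=3, n_filters=8)
            )
            model, _ = fc.train(model, gc2_training_set, epochs=3, batch_size=32,
                                seed=shuffle_seed)
            accs.append(fc.holdout_accuracy(model, X, y))
        assert abs(accs[0] - accs[1]) < 0.05


class TestCheckpoint:
    def test_round_trip_bit_identical(self, gc2_model, tmp_path, rng):
        from conftest import random_dna

        path = tmp_path / "model.ckpt"
        fc.save_checkpoint(gc2_model, path)
        loaded = fc.load_checkpoint(path)
        win = one_hot_encode(DnaSequence("x", random_dna(rng, 1024)))
        a, _ = gc2_model.forward(win[None])
        b, _ = loaded.forward(win[None])
        assert np.array_equal(a, b)
        assert loaded.class_names == gc2_model.class_names

    def test_config_stored(self, tiny_model, tmp_path):
        path = tmp_path / "model.ckpt"
        fc.save_checkpoint(tiny_model, path)
        assert fc.load_checkpoint(path).config == tiny_model.config

    def test_n_classes_mismatch(self, tiny_model, tmp_path):
        path = tmp_path / "model.ckpt"
        fc.save_checkpoint(tiny_model, path)
        with pytest.raises(ValueError, match="n_classes"):
            fc.load_checkpoint(path, expected_n_classes=7)

    def test_corrupted_file(self, tmp_path):
        path = tmp_path / "model.ckpt"
        path.write_bytes(b"not a checkpoint at all")
        with pytest.raises(ValueError, match="corrupt"):
            fc.load_checkpoint(path)
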