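import dataclasses

import numpy as np
import pytest
from scipy import stats

from throatsense import nn, synthgen
from throatsense.io import build_feature_dataset
from throatsense.recognizer import (
    DualPrediction,
    FeatureDataset,
    ModelConfig,
    TrainedModel,
    build_model,
    predict,
    predict_labels,
    train,
)

SMALL = ModelConfig(seed=3)


@pytest.fixture(scope="module")
def model():
    m = build_model(SMALL)
    m.eval()
    return m


@pytest.fixture(scope="module")
def batch():
    return np.random.default_rng(0).standard_normal((8, 40, 128)).astype(np.float32)


class TestForward:
    def test_output_head_sizes(self, model, batch):
        le, lt = model.forward(batch)
        assert le.shape == (8, 6)
        assert lt.shape == (8, 5)

    def test_softmax_simplex(self, model, batch):
        le, lt = model.forward(batch)
        for logits, n in ((le, 6), (lt, 5)):
            p = nn.softmax(logits).data
            assert np.all(p >= 0)
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_wrong_shape_rejected(self, model):
        with pytest.raises(ValueError, match="40, 128"):
            model.forward(np.zeros((2, 39, 128), dtype=np.float32))

    def test_batch_permutation_equivariance(self, model, batch):
        le1, _ = model.forward(batch)
        perm = np.array([3, 1, 7, 0, 2, 6, 4, 5])
        le2, _ = model.forward(batch[perm])
        np.testing.assert_allclose(le2.data, le1.data[perm], atol=1e-4)

    def test_single_matrix_accepted(self, model):
        le, lt = model.forward(np.zeros((40, 128), dtype=np.float32))
        assert le.shape == (1, 6)


class TestConfig:
    def test_head_sizes_fixed(self):
        with pytest.raises(ValueError):
            ModelConfig(n_emotions=7)

    def test_attention_divisibility(self):
        with pytest.raises(ValueError):
            ModelConfig(attention_heads=7)

    def test_paper_defaults(self):
        c = ModelConfig()
        assert c.conv_channels == (32, 64)
        assert c.lstm_layers == 2 and c.lstm_units == 128
        assert c.lstm_dropout == 0.3 and c.fc_dropout == 0.5
        assert c.attention_heads == 8 and c.attention_width == 128
        assert c.learning_rate == 0.001 and c.batch_size == 64
        assert c.early_stopping_patience == 10


class TestDualPrediction:
    def test_valid(self):
        p = DualPrediction(np.full(6, 1 / 6), np.full(5, 0.2))
        assert p.emotion in synthgen.EMOTIONS
        assert 0 <= p.sentence_id < 5

    def test_invalid_sum(self):
        with pytest.raises(ValueError):
            DualPrediction(np.full(6, 0.5), np.full(5, 0.2))

    def test_invalid_shape(self):
        with pytest.raises(ValueError):
            DualPrediction(np.full(5, 0.2), np.full(5, 0.2))


@pytest.fixture(scope="module")
def planted_30():
    """One recording per (emotion, sentence) cell from a single subject."""
    recs, manifest = synthgen.generate_corpus(1, 1, master_seed=77)
    return build_feature_dataset(recs, manifest)


def _as_val(ds: FeatureDataset) -> FeatureDataset:
    """Anonymous copy usable as a validation set in deliberate-overlap tests."""
    return FeatureDataset(
        features=ds.features, emotion_labels=ds.emotion_labels,
        text_labels=ds.text_labels, subject_ids=ds.subject_ids,
    )


class TestTraining:
    def test_overfits_tiny_planted_dataset(self, planted_30):
        config = dataclasses.replace(SMALL, max_epochs=200, early_stopping_patience=200)
        model = build_model(config)
        trained = train(model, planted_30, _as_val(planted_30), config)
        pe, pt = predict_labels(trained, planted_30.features)
        assert np.mean(pe == planted_30.emotion_labels) == 1.0
        assert np.mean(pt == planted_30.text_labels) == 1.0

    def test_label_conflict_bounds_val_accuracy(self, planted_30):
        conflicted = FeatureDataset(
            features=planted_30.features.copy(),
            emotion_labels=(planted_30.emotion_labels + 1) % 6,
            text_labels=planted_30.text_labels,
            subject_ids=planted_30.subject_ids,
        )
        config = dataclasses.replace(SMALL, max_epochs=12)
        trained = train(build_model(config), planted_30, conflicted, config)
        final = [e for e in trained.training_log if "val_acc_emotion" in e][-1]
        assert final["val_acc_emotion"] < 1.0

    def test_seeded_training_reproducible(self, planted_30):
        config = dataclasses.replace(SMALL, max_epochs=3)
        t1 = train(build_model(config), planted_30, _as_val(planted_30), config)
        t2 = train(build_model(config), planted_30, _as_val(planted_30), config)
        l1 = [e["val_loss"] for e in t1.training_log if "val_loss" in e]
        l2 = [e["val_loss"] for e in t2.training_log if "val_loss" in e]
        np.testing.assert_allclose(l1, l2, rtol=1e-5)

    def test_empty_split_rejected(self, planted_30):
        empty = planted_30.subset(np.array([], dtype=int))
        with pytest.raises(ValueError):
            train(build_model(SMALL), empty, planted_30, SMALL)

    def test_loss_additivity(self, model, batch):
        ye = np.arange(8) % 6
        yt = np.arange(8) % 5
        le, lt = model.forward(batch)
        total = nn.cross_entropy(le, ye) + nn.cross_entropy(lt, yt)
        parts = float(nn.cross_entropy(le, ye).data) + float(nn.cross_entropy(lt, yt).data)
        assert float(total.data) == pytest.approx(parts, rel=1e-12)


@pytest.fixture(scope="module")
def trained(planted_30):
    config = dataclasses.replace(SMALL, max_epochs=60, early_stopping_patience=60)
    return train(build_model(config), planted_30, _as_val(planted_30), config)


class TestPredict:
    def test_inference_deterministic(self, trained, planted_30):
        p1 = predict(trained, planted_30.features[:4])
        p2 = predict(trained, planted_30.features[:4])
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.emotion_probs, b.emotion_probs)

    def test_batch_order_preserved(self, trained, planted_30):
        preds = predict(trained, planted_30.features)
        assert len(preds) == len(planted_30)

    def test_above_chance_binomial(self, trained, planted_30):
        # in-sample here; the cross-subject case is covered by acceptance
        pe, _ = predict_labels(trained, planted_30.features)
        k = int(np.sum(pe == planted_30.emotion_labels))
        pval = stats.binomtest(k, len(pe), 1 / 6, alternative="greater").pvalue
        assert pval < 0.01

    def test_checkpoint_roundtrip(self, trained, planted_30, tmp_path):
        path = tmp_path / "model.npz"
        trained.save(path)
        back = TrainedModel.load(path)
        p1 = predict(trained, planted_30.features[:3])
        p2 = predict(back, planted_30.features[:3])
        for a, b in zip(p1, p2):
            np.testing.assert_allclose(a.emotion_probs, b.emotion_probs, atol=1e-6)
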