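import numpy as np
import pytest

from chirplearn.augment import AugmentationConfig
from chirplearn.evaluate import predict_recording
from chirplearn.models import (BandTemplateModel, TinyCNN, TinyTransformer,
                               parameter_checksum, set_trainable_scope)
from chirplearn.labels import ClassVocabulary
from chirplearn.synth import (SceneConfig, generate_corpus,
                              make_template_teacher, to_training_examples)
from chirplearn.transfer import (DistillationConfig, TrainConfig,
                                 distillation_loss, ground_truth_loss,
                                 total_distill_loss, train)


class TestGroundTruthLoss:
    def test_uniform_softmax_is_log_k(self):
        logits = np.zeros(3)
        target = np.array([1.0, 0.0, 0.0])
        assert ground_truth_loss(logits, target) == \
            pytest.approx(np.log(3), abs=1e-12)

    def test_confident_correct_approaches_zero(self):
        logits = np.array([50.0, 0.0, 0.0])
        target = np.array([1.0, 0.0, 0.0])
        assert ground_truth_loss(logits, target) < 1e-12

    def test_three_class_scalar_oracle(self):
        # independent scalar computation: ln(e + 1 + 1/e) - 1
        logits = np.array([1.0, 0.0, -1.0])
        target = np.array([1.0, 0.0, 0.0])
        assert ground_truth_loss(logits, target) == \
            pytest.approx(0.40760596444438035, abs=1e-12)

    def test_bce_matches_scalar_formula(self, rng):
        z = rng.normal(0, 2, 6)
        t = rng.uniform(0, 1, 6)
        p = 1 / (1 + np.exp(-z))
        expected = -np.mean(t * np.log(p + 1e-10)
                            + (1 - t) * np.log(1 - p + 1e-10))
        got = ground_truth_loss(z, t, "binary_cross_entropy")
        assert got == pytest.approx(expected, abs=1e-12)

    def test_target_out_of_range(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            ground_truth_loss(np.zeros(3), np.array([1.5, 0, 0]))

    def test_nonnegative_finite(self, rng):
        for _ in range(100):
            z = rng.normal(0, 10, 5)
            t = np.zeros(5)
            t[rng.integers(5)] = 1.0
            loss = ground_truth_loss(z, t)
            assert np.isfinite(loss) and loss >= 0


class TestDistillationLoss:
    def test_identical_logits_zero_kl(self, rng):
        z = rng.normal(0, 3, 7)
        assert distillation_loss(z, z) == pytest.approx(0.0, abs=1e-8)

    def test_large_temperature_gives_uniform_teacher(self):
        student = np.array([1.0, 0.0])
        teacher = np.array([5.0, -5.0])
        cfg = DistillationConfig(temperature=1e9)
        # closed form: KL(uniform || softmax(student))
        p_s = np.exp(student) / np.exp(student).sum()
        expected = np.sum(0.5 * np.log(0.5 / p_s))
        assert distillation_loss(student, teacher, cfg) == \
            pytest.approx(expected, abs=1e-8)

    def test_kl_two_class_closed_form(self):
        # teacher (2, 0), student (0, 0), tau = 1:
        # p_t = (e^2, 1)/(e^2+1), p_s = (1/2, 1/2);
        # KL = sum p_t * ln(p_t / p_s) = 0.32781332547273767
        p1 = np.exp(2) / (np.exp(2) + 1)
        oracle = p1 * np.log(p1 / 0.5) + (1 - p1) * np.log((1 - p1) / 0.5)
        got = distillation_loss(np.array([0.0, 0.0]), np.array([2.0, 0.0]))
        assert got == pytest.approx(oracle, abs=1e-8)
        assert got == pytest.approx(0.32781332547273767, abs=1e-8)

    def test_temperature_divides_teacher_only(self):
        student = np.array([1.0, -1.0])
        teacher = np.array([4.0, 0.0])
        cfg = DistillationConfig(temperature=2.0)
        direct = distillation_loss(student, teacher / 2.0)
        assert distillation_loss(student, teacher, cfg) == \
            pytest.approx(direct, abs=1e-12)

    def test_bce_distillation_soft_targets(self, rng):
        z_s, z_t = rng.normal(0, 2, 5), rng.normal(0, 2, 5)
        cfg = DistillationConfig(distillation_loss="binary_cross_entropy")
        soft = 1 / (1 + np.exp(-z_t))
        expected = ground_truth_loss(z_s, soft, "binary_cross_entropy")
        assert distillation_loss(z_s, z_t, cfg) == \
            pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="shapes"):
            distillation_loss(np.zeros(3), np.zeros(4))

    def test_kl_nonnegative_property(self, rng):
        for _ in range(1000):
            z_s = rng.normal(0, 5, rng.integers(2, 10))
            z_t = rng.normal(0, 5, len(z_s))
            assert distillation_loss(z_s, z_t) >= -1e-9


class TestTotalDistillLoss:
    def test_lambda_one_reduces_to_ground_truth(self, rng):
        z_s, z_t = rng.normal(0, 2, 5), rng.normal(0, 2, 5)
        t = np.zeros(5)
        t[2] = 1.0
        cfg = DistillationConfig(lam_weight=1.0)
        assert total_distill_loss(z_s, z_t, t, cfg) == \
            ground_truth_loss(z_s, t)  # bit-exact

    def test_lambda_zero_identical_models(self, rng):
        z = rng.normal(0, 2, 5)
        t = np.zeros(5)
        t[0] = 1.0
        cfg = DistillationConfig(lam_weight=0.0)
        assert total_distill_loss(z, z, t, cfg) == pytest.approx(0.0, abs=1e-8)

    def test_weighted_arithmetic(self, rng):
        z_s, z_t = rng.normal(0, 2, 4), rng.normal(0, 2, 4)
        t = np.zeros(4)
        t[1] = 1.0
        cfg = DistillationConfig(lam_weight=0.5)
        expected = (0.5 * ground_truth_loss(z_s, t)
                    + 0.5 * distillation_loss(z_s, z_t, cfg))
        assert total_distill_loss(z_s, z_t, t, cfg) == \
            pytest.approx(expected, abs=1e-12)

    def test_invalid_lambda(self):
        with pytest.raises(ValueError, match="lam_weight"):
            DistillationConfig(lam_weight=1.5)


class TestConfigs:
    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=-1)
        with pytest.raises(ValueError):
            TrainConfig(optimizer_kind="sgd")

    def test_distill_config_validation(self):
        with pytest.raises(ValueError):
            DistillationConfig(temperature=0)
        with pytest.raises(ValueError):
            DistillationConfig(ground_truth_loss="hinge")


# ---------------------------------------------------------------------------
# training procedures


class TestTrain:
    def test_shallow_finetune_separable(self, small_corpus):
        """Head-only training solves a task sklearn confirms is separable."""
        from sklearn.linear_model import LogisticRegression
        from chirplearn.frontend import compute_mel
        corpus = small_corpus
        dataset = to_training_examples(corpus, "train", "single")
        model = BandTemplateModel(corpus.vocab, seed=5)
        feats = np.array([BandTemplateModel.features(
            compute_mel(clip, model.mel_config).standardized())
            for clip, _ in dataset])
        labels = np.array([int(np.argmax(t)) for _, t in dataset])
        oracle = LogisticRegression(max_iter=2000).fit(feats, labels)
        assert oracle.score(feats, labels) >= 0.95  # separability oracle

        cfg = TrainConfig(epochs=50, batch_size=16, learning_rate=5e-2, seed=5)
        model, log = train("shallow_finetune", model, None, dataset, cfg)
        logits = model.forward_batch(
            np.array([compute_mel(c, model.mel_config).standardized()
                      for c, _ in dataset])).data
        acc = np.mean(np.argmax(logits, axis=1) == labels)
        assert acc >= 0.95
        # sanity contract: loss broadly non-increasing on a separable task
        losses = log.epoch_losses
        assert losses[-1] < losses[0]
        assert max(np.diff(losses)) < 0.05

    def test_distill_pure_teacher_agreement(self, flat_corpus):
        """lam = 0 distillation: student mimics a near-optimal teacher."""
        corpus = flat_corpus
        teacher = make_template_teacher(corpus)
        dataset = to_training_examples(corpus, "train", "single")
        student = TinyCNN(corpus.vocab, seed=11)
        cfg = TrainConfig(epochs=25, batch_size=16, learning_rate=2e-3, seed=11)
        student, _ = train("distill", student, teacher, dataset, cfg,
                           DistillationConfig(lam_weight=0.0))
        agree = 0
        test_items = corpus.split_items("test")
        for rid, clip, ann in test_items:
            ps = predict_recording(student, clip, rid).scores
            pt = predict_recording(teacher, clip, rid).scores
            agree += int(np.argmax(ps) == np.argmax(pt))
        assert agree / len(test_items) >= 0.9

    def test_zero_learning_rate_null_update(self, small_corpus):
        corpus = small_corpus
        dataset = to_training_examples(corpus, "train", "single")[:8]
        model = TinyCNN(corpus.vocab, seed=2)
        before = parameter_checksum(model.parameters())
        cfg = TrainConfig(epochs=3, batch_size=4, learning_rate=0.0, seed=2)
        model, log = train("deep_finetune", model, None, dataset, cfg)
        assert parameter_checksum(model.parameters()) == before
        assert np.ptp(log.epoch_losses) < 1e-12

    def test_deep_finetune_changes_backbone(self, small_corpus):
        dataset = to_training_examples(small_corpus, "train", "single")[:8]
        model = TinyCNN(small_corpus.vocab, seed=2)
        before = parameter_checksum(model.backbone_parameters())
        cfg = TrainConfig(epochs=1, batch_size=4, learning_rate=1e-3, seed=2)
        model, _ = train("deep_finetune", model, None, dataset, cfg)
        assert parameter_checksum(model.backbone_parameters()) != before

    def test_shallow_finetune_freezes_backbone(self, small_corpus):
        dataset = to_training_examples(small_corpus, "train", "single")[:16]
        model = TinyCNN(small_corpus.vocab, seed=4)
        before = parameter_checksum(model.backbone_parameters())
        cfg = TrainConfig(epochs=2, batch_size=8, learning_rate=1e-2, seed=4)
        head_before = parameter_checksum(model.head_parameters())
        model, _ = train("shallow_finetune", model, None, dataset, cfg)
        assert parameter_checksum(model.backbone_parameters()) == before
        assert parameter_checksum(model.head_parameters()) != head_before

    def test_teacher_frozen_through_distillation(self, small_corpus):
        corpus = small_corpus
        teacher = make_template_teacher(corpus)
        before = parameter_checksum(teacher.parameters())
        dataset = to_training_examples(corpus, "train", "single")[:16]
        student = TinyCNN(corpus.vocab, seed=3)
        cfg = TrainConfig(epochs=2, batch_size=8, learning_rate=1e-3, seed=3)
        train("distill", student, teacher, dataset, cfg, DistillationConfig())
        assert parameter_checksum(teacher.parameters()) == before
        assert teacher.trainable_scope == "frozen"

    def test_consistent_teaching_identical_inputs(self, small_corpus,
                                                  monkeypatch):
        corpus = small_corpus
        teacher = make_template_teacher(corpus)
        student = TinyCNN(corpus.vocab, seed=6)
        seen = {"student": [], "teacher": []}
        for name, model in (("student", student), ("teacher", teacher)):
            orig = model.forward_batch

            def spy(x, _orig=orig, _name=name):
                seen[_name].append(id(x))
                return _orig(x)

            monkeypatch.setattr(model, "forward_batch", spy)
        dataset = to_training_examples(corpus, "train", "single")[:16]
        cfg = TrainConfig(epochs=2, batch_size=8, learning_rate=1e-3, seed=6,
                          augmentation=AugmentationConfig(rng_seed=6))
        train("distill", student, teacher, dataset, cfg, DistillationConfig(),
              noise_pool=corpus.noise_pool())
        assert seen["student"] == seen["teacher"]  # same array objects
        assert len(seen["student"]) > 0

    def test_cross_architecture_distillation(self, small_corpus):
        corpus = small_corpus
        dataset = to_training_examples(corpus, "train", "single")[:24]
        cfg = TrainConfig(epochs=4, batch_size=8, learning_rate=1e-3, seed=8)
        cnn = TinyCNN(corpus.vocab, seed=8)
        tfm = TinyTransformer(corpus.vocab, seed=8)
        # CNN -> transformer
        _, log1 = train("distill", TinyTransformer(corpus.vocab, seed=9), cnn,
                        dataset, cfg, DistillationConfig())
        # transformer -> CNN
        _, log2 = train("distill", TinyCNN(corpus.vocab, seed=9), tfm,
                        dataset, cfg, DistillationConfig())
        assert log1.epoch_losses[-1] < log1.epoch_losses[0]
        assert log2.epoch_losses[-1] < log2.epoch_losses[0]

    def test_distill_requires_teacher(self, small_corpus):
        dataset = to_training_examples(small_corpus, "train", "single")[:4]
        with pytest.raises(ValueError, match="teacher"):
            train("distill", TinyCNN(small_corpus.vocab), None, dataset,
                  TrainConfig(epochs=1))

    def test_vocabulary_mismatch(self, small_corpus):
        other_vocab = ClassVocabulary.from_species(["x", "y"])
        dataset = to_training_examples(small_corpus, "train", "single")[:4]
        with pytest.raises(ValueError, match="vocabular"):
            train("distill", TinyCNN(small_corpus.vocab),
                  TinyCNN(other_vocab), dataset, TrainConfig(epochs=1))

    def test_unknown_strategy(self, small_corpus):
        dataset = to_training_examples(small_corpus, "train", "single")[:4]
        with pytest.raises(ValueError, match="strategy"):
            train("finetune", TinyCNN(small_corpus.vocab), None, dataset,
                  TrainConfig(epochs=1))

    def test_log_artifacts(self, small_corpus, tmp_path):
        dataset = to_training_examples(small_corpus, "train", "single")[:8]
        model = TinyCNN(small_corpus.vocab, seed=1)
        cfg = TrainConfig(epochs=2, batch_size=4, learning_rate=1e-3, seed=1)
        _, log = train("deep_finetune", model, None, dataset, cfg)
        log.write_csv(tmp_path / "log.csv")
        log.write_manifest(tmp_path / "manifest.json")
        import pandas as pd
        df = pd.read_csv(tmp_path / "log.csv")
        assert set(df.columns) >= {"epoch", "total_loss", "ground_truth_loss",
                                   "backbone_checksum", "head_checksum"}
        import json
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["strategy"] == "deep_finetune"
        assert manifest["train_config"]["seed"] == 1
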