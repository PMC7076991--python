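"""Transfer-learning heads: build/copy contracts, training, prediction."""

import numpy as np
import pytest

from methylearn import (
    EncoderTopology,
    FineTuneModel,
    PredictionTask,
    TrainConfig,
    build_finetune_model,
    generate_age_dataset,
    generate_mixture_dataset,
    train_finetune,
    train_mlp_baseline,
    train_test_val_split,
)
from methylearn.errors import ConfigError, ContractError, DataError

CLASS_TASK = PredictionTask("classification", ["class"], 3)


class TestBuild:
    def test_encoder_copied_exactly(self, small_vae, cluster_split):
        split, _ = cluster_split
        model = build_finetune_model(small_vae, [16], CLASS_TASK, seed=0)
        assert np.allclose(model.embed(split.test),
                           small_vae.transform(split.test))

    def test_head_topology(self, small_vae):
        model = build_finetune_model(small_vae, [32], CLASS_TASK, seed=0)
        assert len(model.net.head_Ws) == 1  # one hidden prediction layer
        assert model.net.W_out.shape == (32, 3)

    def test_mutation_does_not_touch_source_vae(self, small_vae, cluster_split):
        split, _ = cluster_split
        before = small_vae.net_.W_mu.copy()
        model = build_finetune_model(small_vae, [16], CLASS_TASK, seed=0)
        model.net.W_mu += 100.0
        assert (small_vae.net_.W_mu == before).all()

    def test_untrained_vae_rejected(self):
        from methylearn import VAEEmbedder

        with pytest.raises(ConfigError):
            build_finetune_model(VAEEmbedder(), [16], CLASS_TASK)

    def test_non_numeric_regression_target_rejected(self, small_vae, cluster_split):
        split, _ = cluster_split
        task = PredictionTask("regression", ["class"], 1)
        model = build_finetune_model(small_vae, [8], task, seed=0)
        with pytest.raises((DataError, ValueError)):
            model.fit(split.train, split.val, TrainConfig(max_epochs=1))


class TestTraining:
    def test_fresh_classifier_starts_near_uniform(self, small_vae, cluster_split):
        """Initial validation cross-entropy of an untrained head ~ ln k."""
        split, _ = cluster_split
        model = build_finetune_model(small_vae, [16], CLASS_TASK, seed=0)
        Y = model._targets(split.val, fit_scaler=True)
        loss, _ = model.net.loss(split.val.values, Y)
        assert loss == pytest.approx(np.log(3), rel=0.1)

    def test_classification_recovery(self, small_vae, cluster_split):
        split, _ = cluster_split
        model = build_finetune_model(small_vae, [16], CLASS_TASK, seed=0)
        config = TrainConfig(learning_rate=2e-3, beta_kl=0.0, max_epochs=40,
                             patience=40, batch_size=32, seed=0)
        train_finetune(model, split.train, split.val, config)
        preds = model.predict(split.test)
        acc = np.mean(preds.labels == split.test.pheno["class"].to_numpy())
        assert acc > 0.9

    def test_snapshot_is_min_val_loss(self, small_vae, cluster_split):
        split, _ = cluster_split
        model = build_finetune_model(small_vae, [16], CLASS_TASK, seed=0)
        model.fit(split.train, split.val, TrainConfig(max_epochs=10, seed=1))
        vals = [e["val_loss"] for e in model.training_log_]
        assert vals[model.best_epoch_] == min(vals)

    def test_seed_reproducibility(self, small_vae, cluster_split):
        split, _ = cluster_split
        logs = []
        for _ in range(2):
            m = build_finetune_model(small_vae, [16], CLASS_TASK, seed=4)
            m.fit(split.train, split.val, TrainConfig(max_epochs=3, seed=4))
            logs.append([e["val_loss"] for e in m.training_log_])
        assert logs[0] == logs[1]

    def test_nan_targets_listed(self, small_vae, cluster_split):
        split, _ = cluster_split
        bad = split.train
        bad.pheno.loc[bad.sample_ids[0], "y"] = np.nan
        bad.pheno["y"] = bad.pheno["y"].astype(float)
        task = PredictionTask("regression", ["y"], 1)
        model = build_finetune_model(small_vae, [8], task, seed=0)
        with pytest.raises(DataError, match=bad.sample_ids[0]):
            model.fit(bad, bad, TrainConfig(max_epochs=1))
        bad.pheno.drop(columns=["y"], inplace=True)


class TestPredictionContracts:
    @pytest.fixture
    def trained(self, small_vae, cluster_split):
        split, _ = cluster_split
        model = build_finetune_model(small_vae, [16], CLASS_TASK, seed=0)
        model.fit(split.train, split.val,
                  TrainConfig(learning_rate=2e-3, max_epochs=20, seed=0))
        return model, split

    def test_probability_rows_sum_to_one(self, trained):
        model, split = trained
        probs = model.predict_proba(split.test)
        assert np.abs(probs.sum(axis=1) - 1).max() < 1e-6

    def test_predict_deterministic(self, trained):
        model, split = trained
        a = model.predict(split.test)
        b = model.predict(split.test)
        assert (a.values == b.values).all()

    def test_dimension_mismatch(self, trained):
        model, split = trained
        with pytest.raises(ContractError):
            model.predict(split.test.subset_cpgs(split.test.cpg_ids[:5]))

    def test_checkpoint_roundtrip(self, trained, tmp_path):
        model, split = trained
        path = str(tmp_path / "ft.h5")
        model.save(path)
        loaded = FineTuneModel.load(path)
        assert np.allclose(loaded.predict_proba(split.test),
                           model.predict_proba(split.test))
        assert list(loaded.classes_) == list(model.classes_)


class TestRegressionHead:
    def test_age_recovery(self, tmp_path):
        arr, _ = generate_age_dataset(n_samples=400, n_cpgs=300,
                                      n_informative=40, noise_sd=0.3, seed=3)
        split = train_test_val_split(arr, seed=1)
        from methylearn import train_vae

        vae = train_vae(split.train, split.val, EncoderTopology([64], 12),
                        TrainConfig(learning_rate=5e-3, beta_kl=0.1,
                                    max_epochs=30, patience=30, seed=0))
        task = PredictionTask("regression", ["age"], 1)
        model = build_finetune_model(vae, [16], task, seed=0)
        model.fit(split.train, split.val,
                  TrainConfig(learning_rate=2e-3, max_epochs=60, patience=60,
                              seed=0))
        pred = model.predict(split.test).values.ravel()
        y = split.test.pheno["age"].to_numpy()
        r2 = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 > 0.8
        # predictions come back on the original scale (years)
        assert 10 < pred.mean() < 100


class TestSimplexHead:
    def test_deconvolution_output_on_simplex(self):
        arr, truth = generate_mixture_dataset(
            n_samples=200, n_cpgs=200, n_celltypes=4, divergence=3.0,
            noise_sd=0.02, seed=2,
        )
        split = train_test_val_split(arr, seed=0)
        from methylearn import train_vae

        vae = train_vae(split.train, split.val, EncoderTopology([64], 8),
                        TrainConfig(learning_rate=5e-3, beta_kl=0.1,
                                    max_epochs=20, patience=20, seed=1))
        cts = list(truth.proportions.columns)
        task = PredictionTask("multi_output", cts, 4, simplex_constrain=True)
        model = build_finetune_model(vae, [16], task, seed=0)
        model.fit(split.train, split.val,
                  TrainConfig(learning_rate=2e-3, max_epochs=40, patience=40,
                              seed=0))
        out = model.predict(split.test).values
        assert (out >= 0).all()
        assert np.abs(out.sum(axis=1) - 1).max() < 1e-6
        # predicted proportions track the truth
        true = split.test.pheno[cts].to_numpy()
        assert np.abs(out - true).mean() < 0.1


class TestBaseline:
    def test_interface_parity_and_determinism(self, cluster_split):
        split, _ = cluster_split
        topo = EncoderTopology([32], 8)
        config = TrainConfig(learning_rate=2e-3, max_epochs=5, seed=0)
        a = train_mlp_baseline(split.train, split.val, topo, CLASS_TASK, config)
        b = train_mlp_baseline(split.train, split.val, topo, CLASS_TASK, config)
        assert not a.pretrained
        assert [e["val_loss"] for e in a.training_log_] == \
               [e["val_loss"] for e in b.training_log_]
        probs = a.predict_proba(split.test)
        assert np.abs(probs.sum(axis=1) - 1).max() < 1e-6

    def test_pretraining_reaches_target_loss_no_later_than_baseline(
            self, cluster_split):
        """Few labels, plenty of unlabeled data: a VAE-warm-started model
        reaches the cold-started baseline's best validation loss in no more
        epochs than the baseline itself (median over 5 seeds)."""
        from methylearn import train_vae

        split, _ = cluster_split
        topo = EncoderTopology([32], 8)
        small_train = split.train.subset_samples(split.train.sample_ids[:30])
        epochs_pre, epochs_base = [], []
        for seed in range(5):
            vae = train_vae(split.train, split.val, topo,
                            TrainConfig(learning_rate=5e-3, beta_kl=0.1,
                                        max_epochs=40, patience=40, seed=seed))
            cfg = TrainConfig(learning_rate=2e-3, max_epochs=60, patience=60,
                              seed=seed)
            pre = build_finetune_model(vae, [16], CLASS_TASK, seed=seed)
            pre.fit(small_train, split.val, cfg)
            base = train_mlp_baseline(small_train, split.val, topo, CLASS_TASK,
                                      cfg, head_widths=[16])
            target = min(e["val_loss"] for e in base.training_log_)
            def first_epoch_at(log):
                for e in log:
                    if e["val_loss"] <= target:
                        return e["epoch"]
                return len(log)
            epochs_pre.append(first_epoch_at(pre.training_log_))
            epochs_base.append(first_epoch_at(base.training_log_))
        assert np.median(epochs_pre) <= np.median(epochs_base)
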