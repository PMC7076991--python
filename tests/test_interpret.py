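"""Shapley estimators and downstream attribution analyses.

The exact estimator is itself validated against analytic results (linear
models, one-player games, symmetry/dummy axioms) and then serves as the
brute-force oracle for the kernel and expected-gradients approximations.
"""

import numpy as np
import pandas as pd
import pytest

from methylearn import (
    GroupAttribution,
    PredictionTask,
    ShapleyData,
    aggregate_by_group,
    attribution_dendrogram,
    build_finetune_model,
    exact_shapley,
    generate_mixture_dataset,
    gradient_shapley,
    kernel_shapley,
    linkage_to_newick,
    produce_shapley_data,
    rank_concordance,
    top_k_overlap,
    train_test_val_split,
    train_vae,
)
from methylearn.errors import ConfigError, ContractError, InsufficientOverlapError
from methylearn.vae import EncoderTopology, TrainConfig


def linear(w):
    w = np.asarray(w, dtype=float)
    return lambda X: X @ w


class TestExactShapley:
    def test_linear_model_analytic(self):
        """f = 2x1 + 3x2, background mean (0.5, 0.5), x = (1, 0):
        phi = (w_j * (x_j - mean b_j)) = (1.0, -1.5); base = 2.5."""
        f = linear([2.0, 3.0])
        phi, base = exact_shapley(f, [1.0, 0.0], [[0.5, 0.5], [0.5, 0.5]])
        assert phi == pytest.approx([1.0, -1.5])
        assert base == pytest.approx(2.5)
        assert base + phi.sum() == pytest.approx(2.0)  # local accuracy

    def test_one_player_game(self):
        f = lambda X: np.sin(X[:, 0] * 3)
        x = np.array([0.7])
        bg = np.array([[0.1], [0.4], [0.9]])
        phi, base = exact_shapley(f, x, bg)
        assert phi[0] == pytest.approx(float(f(x[None])[0]) - base)

    def test_symmetry_axiom(self):
        # x1 and x2 enter interchangeably
        f = lambda X: (X[:, 0] + X[:, 1]) ** 2 + X[:, 2]
        x = np.array([0.6, 0.6, 0.3])
        bg = np.random.default_rng(0).uniform(size=(6, 3))
        bg[:, 1] = bg[:, 0]  # identical background marginals too
        phi, _ = exact_shapley(f, x, bg)
        assert phi[0] == pytest.approx(phi[1], rel=1e-9)

    def test_dummy_axiom(self):
        f = lambda X: 5.0 * X[:, 0]
        phi, _ = exact_shapley(f, [0.8, 0.3], [[0.2, 0.9], [0.4, 0.1]])
        assert phi[1] == pytest.approx(0.0, abs=1e-12)

    def test_combinatorial_guard(self):
        with pytest.raises(ConfigError):
            exact_shapley(linear(np.ones(25)), np.ones(25), np.ones((2, 25)))


class TestApproximationsAgainstExactOracle:
    """Kernel and expected-gradients converge to full enumeration."""

    @pytest.fixture
    def toy(self):
        # multilinear 5-feature model: nonlinear but gradient-exact territory
        def f(X):
            return (2 * X[:, 0] + X[:, 1] * X[:, 2]
                    - 3 * X[:, 3] * X[:, 4] + X[:, 1])
        rng = np.random.default_rng(7)
        x = rng.uniform(size=5)
        bg = rng.uniform(size=(10, 5))
        return f, x, bg

    def test_kernel_matches_exact(self, toy):
        f, x, bg = toy
        phi_e, base_e = exact_shapley(f, x, bg)
        phi_k, base_k = kernel_shapley(f, x, bg)
        assert base_k == pytest.approx(base_e)
        assert phi_k == pytest.approx(phi_e, rel=5e-2, abs=1e-6)

    def test_gradient_matches_exact(self, toy):
        f, x, bg = toy
        phi_e, _ = exact_shapley(f, x, bg)
        phi_g, _ = gradient_shapley(f, None, x, bg, n_draws=4000, seed=0)
        assert np.abs(phi_g - phi_e).max() < 0.05 * max(1.0, np.abs(phi_e).max())

    def test_local_accuracy_exact_and_kernel(self, toy):
        f, x, bg = toy
        fx = float(f(x[None])[0])
        for est in (exact_shapley, kernel_shapley):
            phi, base = est(f, x, bg)
            assert base + phi.sum() == pytest.approx(fx, abs=1e-3)

    def test_gradient_seeded(self, toy):
        f, x, bg = toy
        a, _ = gradient_shapley(f, None, x, bg, n_draws=50, seed=3)
        b, _ = gradient_shapley(f, None, x, bg, n_draws=50, seed=3)
        assert (a == b).all()


@pytest.fixture(scope="module")
def model_and_split(small_vae, cluster_split):
    split, _ = cluster_split
    task = PredictionTask("classification", ["class"], 3)
    model = build_finetune_model(small_vae, [16], task, seed=0)
    model.fit(split.train, split.val,
              TrainConfig(learning_rate=2e-3, max_epochs=20, seed=0))
    return model, split


class TestProduceShapleyData:
    def test_gradient_scores_shape_and_finiteness(self, model_and_split):
        model, split = model_and_split
        test = split.test.subset_samples(split.test.sample_ids[:8])
        sd = produce_shapley_data(model, test, "gradient", split.train,
                                  n_background=20, seed=0, group_col="class",
                                  n_draws=60)
        assert sd.scores.shape == (8, split.test.n_cpgs)
        assert np.isfinite(sd.scores).all()
        assert sd.group_col == "class"

    def test_exact_refuses_wide_arrays(self, model_and_split):
        model, split = model_and_split
        with pytest.raises(ConfigError):
            produce_shapley_data(model, split.test, "exact", split.train)

    def test_empty_background_rejected(self, model_and_split):
        model, split = model_and_split
        empty = split.train.subset_samples([])
        with pytest.raises(ConfigError):
            produce_shapley_data(model, split.test, "gradient", empty)

    def test_save_load_roundtrip(self, model_and_split, tmp_path):
        from methylearn.interpret import load_shapley_data

        model, split = model_and_split
        test = split.test.subset_samples(split.test.sample_ids[:4])
        sd = produce_shapley_data(model, test, "gradient", split.train,
                                  n_background=10, seed=0, group_col="class",
                                  n_draws=30)
        path = str(tmp_path / "shap.h5")
        sd.save(path)
        loaded = load_shapley_data(path)
        assert loaded.cpg_ids == sd.cpg_ids
        assert np.allclose(loaded.scores, sd.scores, atol=1e-6)


class TestAggregation:
    def _shap(self, scores, samples, cpgs):
        return ShapleyData(scores=np.asarray(scores, dtype=float),
                           base_values=0.0, cpg_ids=cpgs, sample_ids=samples)

    def test_single_group_is_global_mean(self):
        sd = self._shap([[1, 2], [3, 4]], ["a", "b"], ["c1", "c2"])
        ga = aggregate_by_group(sd, ["g", "g"])
        assert ga.table.loc["g"].tolist() == [2.0, 3.0]

    def test_singleton_groups_identity(self):
        sd = self._shap([[1, 2], [3, 4]], ["a", "b"], ["c1", "c2"])
        ga = aggregate_by_group(sd, ["x", "y"])
        assert ga.table.loc["x"].tolist() == [1.0, 2.0]
        assert ga.table.loc["y"].tolist() == [3.0, 4.0]

    def test_hand_built_means(self):
        scores = [[1, 0, 2], [3, 2, 2], [0, 0, 0], [4, 4, 4]]
        sd = self._shap(scores, list("abcd"), ["c1", "c2", "c3"])
        ga = aggregate_by_group(sd, ["g1", "g1", "g2", "g2"])
        assert ga.table.loc["g1"].tolist() == [2.0, 1.0, 2.0]
        assert ga.table.loc["g2"].tolist() == [2.0, 2.0, 2.0]
        assert ga.group_labels == ["g1", "g2"]  # first-appearance order


class TestTopKOverlap:
    @pytest.fixture
    def ga(self):
        table = pd.DataFrame([[5.0, 4.0, 1.0, 0.0]], index=["g"],
                             columns=["a", "b", "c", "d"])
        return GroupAttribution(table=table)

    def test_full_capture(self, ga):
        assert top_k_overlap(ga, "g", 2, {"a", "b"}) == 1.0

    def test_no_capture(self, ga):
        assert top_k_overlap(ga, "g", 2, {"c", "d"}) == 0.0

    def test_partial(self, ga):
        assert top_k_overlap(ga, "g", 2, {"b", "c", "d"}) == pytest.approx(1 / 3)

    def test_empty_reference(self, ga):
        with pytest.raises(ConfigError):
            top_k_overlap(ga, "g", 2, set())

    def test_abs_ranking_option(self):
        table = pd.DataFrame([[-9.0, 1.0, 0.5]], index=["g"],
                             columns=["a", "b", "c"])
        ga = GroupAttribution(table=table)
        assert top_k_overlap(ga, "g", 1, {"a"}, ranking="abs") == 1.0
        assert top_k_overlap(ga, "g", 1, {"a"}, ranking="signed") == 0.0


class TestDendrogram:
    def test_identical_rows_merge_first(self):
        table = pd.DataFrame(
            [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, -1.0, 0.5]],
            index=["g1", "g2", "g3"], columns=["a", "b", "c"])
        Z, labels = attribution_dendrogram(GroupAttribution(table))
        # first merge joins the perfectly correlated pair at distance 0
        assert {labels[int(Z[0, 0])], labels[int(Z[0, 1])]} == {"g1", "g2"}
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_two(self):
        table = pd.DataFrame([[1.0, 2.0, 3.0], [-1.0, -2.0, -3.0]],
                             index=["g1", "g2"], columns=["a", "b", "c"])
        Z, _ = attribution_dendrogram(GroupAttribution(table))
        assert Z[0, 2] == pytest.approx(2.0)

    def test_zero_variance_row_warns_max_distance(self):
        table = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]],
                             index=["g1", "flat"], columns=["a", "b", "c"])
        with pytest.warns(UserWarning):
            Z, _ = attribution_dendrogram(GroupAttribution(table))
        assert Z[0, 2] == pytest.approx(2.0)

    def test_newick_export(self):
        table = pd.DataFrame([[1.0, 2.0], [2.0, 1.0], [1.0, 2.1]],
                             index=["x", "y", "z"], columns=["a", "b"])
        Z, labels = attribution_dendrogram(GroupAttribution(table))
        nwk = linkage_to_newick(Z, labels)
        assert nwk.endswith(";") and all(l in nwk for l in labels)

    def test_lineage_recovery_on_mixtures(self, small_vae):
        """Sibling cell types' attribution profiles merge before cousins
        (majority over 3 seeds), mirroring lineage structure.  Uses the
        near-identical-sibling regime (strong lineage-divergence decay)."""
        wins = 0
        for seed in range(3):
            arr, truth = generate_mixture_dataset(
                n_samples=150, n_cpgs=120, n_celltypes=4, divergence=3.0,
                noise_sd=0.02, seed=seed, level_decay=0.1)
            split = train_test_val_split(arr, seed=seed)
            vae = train_vae(split.train, split.val, EncoderTopology([48], 8),
                            TrainConfig(learning_rate=5e-3, beta_kl=0.1,
                                        max_epochs=20, patience=20, seed=seed))
            cts = list(truth.proportions.columns)
            task = PredictionTask("multi_output", cts, 4, simplex_constrain=True)
            model = build_finetune_model(vae, [16], task, seed=seed)
            model.fit(split.train, split.val,
                      TrainConfig(learning_rate=2e-3, max_epochs=30,
                                  patience=30, seed=seed))
            # attribute each cell-type output over the test set
            rows = {}
            test = split.test
            bg = split.train.values[:40]
            from methylearn.interpret import gradient_shapley
            for k, ct in enumerate(cts):
                phis = []
                for i in range(min(10, test.n_samples)):
                    def f(M, _k=k):
                        return model.raw_outputs(M)[:, _k]
                    def g(M, _k=k):
                        return model.input_gradients(M, _k)
                    phi, _ = gradient_shapley(f, g, test.values[i], bg,
                                              n_draws=40, seed=seed + i)
                    phis.append(phi)
                rows[ct] = np.mean(phis, axis=0)
            table = pd.DataFrame.from_dict(rows, orient="index",
                                           columns=test.cpg_ids)
            Z, labels = attribution_dendrogram(GroupAttribution(table))
            first = {labels[int(Z[0, 0])], labels[int(Z[0, 1])]}
            # siblings under the depth-2 tree: (ct0, ct1) and (ct2, ct3)
            if first in ({"ct0", "ct1"}, {"ct2", "ct3"}):
                wins += 1
        assert wins >= 2


class TestRankConcordance:
    def _shap_with_scores(self, per_cpg):
        scores = np.array([per_cpg, per_cpg], dtype=float)
        cpgs = [f"cg{i}" for i in range(len(per_cpg))]
        return ShapleyData(scores=scores, base_values=0.0, cpg_ids=cpgs,
                           sample_ids=["s1", "s2"])

    def test_identical_ranking(self):
        sd = self._shap_with_scores([4.0, 3.0, 2.0, 1.0])
        r, p = rank_concordance(sd, ["cg0", "cg1", "cg2", "cg3"])
        assert r == pytest.approx(1.0)

    def test_reversed_ranking(self):
        sd = self._shap_with_scores([4.0, 3.0, 2.0, 1.0])
        r, _ = rank_concordance(sd, ["cg3", "cg2", "cg1", "cg0"])
        assert r == pytest.approx(-1.0)

    def test_insufficient_overlap(self):
        sd = self._shap_with_scores([1.0, 2.0])
        with pytest.raises(InsufficientOverlapError):
            rank_concordance(sd, ["cg0", "cg1"])

    def test_dict_ranking_accepted(self):
        sd = self._shap_with_scores([1.0, 2.0, 3.0])
        r, _ = rank_concordance(sd, {"cg0": 3, "cg1": 2, "cg2": 1})
        assert r == pytest.approx(1.0)
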