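"""AUC, replicate evaluation, jackknife and permutation importance."""

import numpy as np
import pandas as pd
import pytest

import riversdm as r
from riversdm.evaluation import (auc, jackknife_auc, permutation_importance,
                                 prune_and_refit, replicate_evaluation,
                                 response_curve)
from riversdm.stack import EnvStack


@pytest.fixture(scope="module")
def noisy_landscape(landscape):
    """Session landscape plus a pure-noise predictor."""
    stack = landscape["stack"]
    rng = np.random.default_rng(99)
    noise = rng.normal(size=stack.geometry.shape)
    layers = dict(stack.layers) | {"noise": noise}
    kinds = dict(stack.kinds) | {"noise": "continuous"}
    return EnvStack(layers, kinds, stack.geometry)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_all_ties_is_half(self):
        assert auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_exhaustive_pair_counting(self):
        pres, bg = [0.7, 0.4], [0.5, 0.3]
        wins = ties = 0
        for p in pres:
            for b in bg:
                if p > b:
                    wins += 1
                elif p == b:
                    ties += 1
        oracle = (wins + 0.5 * ties) / (len(pres) * len(bg))
        assert oracle == 0.75
        assert auc(pres, bg) == pytest.approx(oracle)

    def test_random_pairs_match_pair_counting(self):
        rng = np.random.default_rng(3)
        pres = np.round(rng.uniform(0, 1, 15), 1)   # rounding forces ties
        bg = np.round(rng.uniform(0, 1, 25), 1)
        wins = sum((p > b) + 0.5 * (p == b) for p in pres for b in bg)
        assert auc(pres, bg) == pytest.approx(wins / (15 * 25))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        pres, bg = rng.normal(1, 1, 20), rng.normal(0, 1, 30)
        a = auc(pres, bg)
        for f in (np.exp, np.tanh, lambda x: 3 * x - 7):
            assert auc(f(pres), f(bg)) == pytest.approx(a)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            auc([], [0.5])


class TestReplicateEvaluation:
    @pytest.fixture(scope="class")
    def report(self, landscape):
        # 20 replicates: the train-vs-test AUC gap is ~0.003–0.01 here, so
        # resolving its sign needs more than a handful of splits
        return replicate_evaluation(landscape["occurrences"].cells,
                                    landscape["stack"],
                                    landscape["background"],
                                    replicates=20, seed=21)

    def test_strong_niche_recovered(self, report):
        assert report.mean_test_auc > 0.9

    def test_train_exceeds_test_on_average(self, report):
        assert report.mean_train_auc > report.mean_test_auc

    def test_mean_map_within_unit_interval(self, report, landscape):
        vals = report.mean_map.data[landscape["stack"].validity_mask]
        assert np.all((vals > 0) & (vals < 1))

    def test_same_master_seed_identical_report(self, landscape):
        runs = [replicate_evaluation(landscape["occurrences"].cells,
                                     landscape["stack"],
                                     landscape["background"],
                                     replicates=3, seed=33)
                for _ in range(2)]
        pd.testing.assert_frame_equal(runs[0].replicates, runs[1].replicates)
        np.testing.assert_array_equal(runs[0].mean_map.data,
                                      runs[1].mean_map.data)

    def test_null_scores_give_half_auc(self):
        """Uniform-random scores: AUC within 3 SD of 0.5."""
        rng = np.random.default_rng(10)
        aucs = [auc(rng.uniform(size=50), rng.uniform(size=200))
                for _ in range(200)]
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se

    def test_too_few_presences_rejected(self, landscape):
        with pytest.raises(ValueError):
            replicate_evaluation(landscape["occurrences"].cells[:2],
                                 landscape["stack"],
                                 landscape["background"], replicates=2)


class TestJackknife:
    @pytest.fixture(scope="class")
    def table(self, noisy_landscape, landscape):
        return jackknife_auc(landscape["occurrences"].cells, noisy_landscape,
                             landscape["background"], seed=5)

    def test_driver_alone_close_to_full(self, table):
        # the niche is driven by bio_1 and bio_12 jointly; each alone must
        # carry far more signal than noise alone
        full = table.loc[table["variable"] == "__full__", "auc_only"].iloc[0]
        only = table.set_index("variable")["auc_only"]
        assert only["bio_1"] > only["noise"]
        assert only["bio_12"] > only["noise"]
        assert max(only["bio_1"], only["bio_12"]) > full - 0.12

    def test_noise_alone_near_half(self, table):
        only_noise = table.set_index("variable")["auc_only"]["noise"]
        assert abs(only_noise - 0.5) < 0.1

    def test_removing_noise_preserves_auc(self, table):
        rows = table.set_index("variable")
        full = rows.loc["__full__", "auc_only"]
        assert rows.loc["noise", "auc_without"] == pytest.approx(full,
                                                                 abs=0.03)

    def test_duplicated_variable_is_redundant(self, landscape):
        stack = landscape["stack"]
        dup = EnvStack({"bio_1": stack.layers["bio_1"],
                        "copy": stack.layers["bio_1"].copy()},
                       {"bio_1": "continuous", "copy": "continuous"},
                       stack.geometry)
        table = jackknife_auc(landscape["occurrences"].cells, dup,
                              landscape["background"], seed=5)
        rows = table.set_index("variable")
        full = rows.loc["__full__", "auc_only"]
        assert rows.loc["bio_1", "auc_without"] == pytest.approx(full,
                                                                 abs=0.02)

    def test_single_variable_rejected(self, landscape):
        with pytest.raises(ValueError, match="at least 2"):
            jackknife_auc(landscape["occurrences"].cells,
                          landscape["stack"].subset(["bio_1"]),
                          landscape["background"])


class TestPermutationImportance:
    @pytest.fixture(scope="class")
    def noisy_model(self, noisy_landscape, landscape):
        occ = landscape["occurrences"]
        bg = landscape["background"]
        feats = r.build_features(noisy_landscape, occ.cells, bg)
        return r.fit(feats, occ.cells, bg, noisy_landscape)

    def test_importances_sum_to_100(self, noisy_model, noisy_landscape,
                                    landscape):
        imp = permutation_importance(noisy_model,
                                     landscape["occurrences"].cells,
                                     landscape["background"],
                                     noisy_landscape, seed=1)
        if (imp["auc_drop"] > 0).any():
            assert imp["importance_pct"].sum() == pytest.approx(100.0,
                                                                abs=1e-9)
        assert (imp["importance_pct"] >= 0).all()

    def test_noise_variable_unimportant(self, noisy_model, noisy_landscape,
                                        landscape):
        imp = permutation_importance(noisy_model,
                                     landscape["occurrences"].cells,
                                     landscape["background"],
                                     noisy_landscape, seed=1)
        rows = imp.set_index("variable")["importance_pct"]
        assert rows["noise"] < min(rows["bio_1"], rows["bio_12"])
        assert rows["noise"] < 5.0

    def test_single_driver_takes_all(self):
        """One informative layer and one all-zero-weight companion."""
        from riversdm.grid import GridGeometry
        rng = np.random.default_rng(17)
        geom = GridGeometry(west=0, north=1, cellsize=0.02, nrows=50,
                            ncols=50)
        driver = np.linspace(0, 1, 2500).reshape(50, 50)
        stack = EnvStack({"driver": driver,
                          "dead": rng.normal(size=(50, 50))},
                         {"driver": "continuous", "dead": "continuous"},
                         geom)
        cells = stack.valid_cells()
        # presences in the top decile of the driver
        pres = cells[driver.ravel() > 0.9][
            rng.choice((driver.ravel() > 0.9).sum(), 40, replace=False)]
        bg = r.sample_background(stack, 1500, seed=2)
        feats = r.build_features(stack, pres, bg, classes=("linear",))
        model = r.fit(feats, pres, bg, stack)
        imp = permutation_importance(model, pres, bg, stack, seed=3)
        rows = imp.set_index("variable")["importance_pct"]
        assert rows["driver"] > 95.0
        # a variable whose every feature has zero weight cannot drop AUC
        dead_weight = [model.lam[j]
                       for j, f in enumerate(model.features.features)
                       if f.layer == "dead"]
        if all(abs(w) < 1e-12 for w in dead_weight):
            assert imp.set_index("variable")["auc_drop"]["dead"] == 0.0


class TestPruneAndRefit:
    def test_informative_variables_survive(self, landscape):
        stack, refit, imp = prune_and_refit(landscape["occurrences"].cells,
                                            landscape["stack"],
                                            landscape["background"], seed=6)
        assert set(stack.names) == {"bio_1", "bio_12"}
        assert not imp["pruned"].any()

    def test_noise_variable_pruned(self, noisy_landscape, landscape):
        stack, refit, imp = prune_and_refit(landscape["occurrences"].cells,
                                            noisy_landscape,
                                            landscape["background"], seed=6)
        rows = imp.set_index("variable")
        if rows.loc["noise", "importance_pct"] < 1.0:
            assert "noise" not in stack.names
            assert "noise" not in refit.features.layer_names

    def test_zero_threshold_never_removes(self, noisy_landscape, landscape):
        stack, _, imp = prune_and_refit(landscape["occurrences"].cells,
                                        noisy_landscape,
                                        landscape["background"],
                                        threshold_pct=0.0, seed=6)
        assert set(stack.names) == set(noisy_landscape.names)
        assert not imp["pruned"].any()


class TestResponseCurve:
    def test_flat_curve_for_uniform_model(self, landscape):
        occ = landscape["occurrences"]
        stack = landscape["stack"]
        bg = landscape["background"]
        feats = r.build_features(stack, occ.cells, bg, classes=("linear",))
        feats.beta[:] = 10.0          # forces all weights to zero
        model = r.fit(feats, occ.cells, bg, stack)
        curve = response_curve(model, "bio_1", stack, bg, grid_points=20)
        np.testing.assert_allclose(curve["mean_p"], 0.5, atol=1e-9)

    def test_positive_linear_weight_gives_monotone_curve(self):
        from riversdm.grid import GridGeometry
        rng = np.random.default_rng(23)
        geom = GridGeometry(west=0, north=1, cellsize=0.02, nrows=50,
                            ncols=50)
        driver = np.linspace(0, 1, 2500).reshape(50, 50)
        stack = EnvStack({"driver": driver}, {"driver": "continuous"}, geom)
        cells = stack.valid_cells()
        pres = cells[driver.ravel() > 0.8][
            rng.choice((driver.ravel() > 0.8).sum(), 30, replace=False)]
        bg = r.sample_background(stack, 1000, seed=3)
        feats = r.build_features(stack, pres, bg, classes=("linear",))
        model = r.fit(feats, pres, bg, stack)
        assert model.lam[0] > 0
        curve = response_curve(model, "driver", stack, bg, grid_points=30)
        assert np.all(np.diff(curve["mean_p"]) >= -1e-12)

    def test_niche_optimum_recovered(self):
        """A smooth quadratic fit on a single-driver Gaussian niche puts
        the curve maximum within one grid step of the true optimum."""
        from riversdm.grid import GridGeometry
        rng = np.random.default_rng(31)
        geom = GridGeometry(west=0, north=1, cellsize=0.02, nrows=50,
                            ncols=50)
        driver = np.linspace(0, 10, 2500).reshape(50, 50)
        stack = EnvStack({"driver": driver}, {"driver": "continuous"}, geom)
        cells = stack.valid_cells()
        v_star = 6.0
        weight = np.exp(-((driver.ravel() - v_star) / 1.0) ** 2)
        pres = np.unique(cells[rng.choice(2500, size=200, replace=True,
                                          p=weight / weight.sum())], axis=0)
        bg = r.sample_background(stack, 1500, seed=4)
        # a light penalty keeps the mean-matching tight enough for the
        # Gibbs fit to localise the Gaussian niche
        feats = r.build_features(stack, pres, bg,
                                 classes=("linear", "quadratic"),
                                 beta_multiplier=0.05)
        model = r.fit(feats, pres, bg, stack)
        curve = response_curve(model, "driver", stack, bg, grid_points=50)
        best = curve.loc[curve["mean_p"].idxmax(), "value"]
        step = float(curve["value"].diff().mean())
        assert abs(best - v_star) <= step

    def test_full_model_curve_peaks_near_true_optimum(self, fitted_model,
                                                      landscape):
        """The hinge-rich full model is wigglier; its peak still sits close
        to the generator's 17 °C optimum."""
        curve = response_curve(fitted_model, "bio_1", landscape["stack"],
                               landscape["background"], grid_points=60)
        best = curve.loc[curve["mean_p"].idxmax(), "value"]
        assert abs(best - 17.0) <= 1.0

    def test_unknown_variable_rejected(self, fitted_model, landscape):
        with pytest.raises(KeyError):
            response_curve(fitted_model, "nope", landscape["stack"],
                           landscape["background"])
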