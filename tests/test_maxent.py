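"""Maximum-entropy core: feature expansion, fitting, KKT certificates,
and brute-force oracle equivalence on tiny instances."""

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import spearmanr

import riversdm as r
from riversdm.grid import GridGeometry
from riversdm.maxent import Feature, build_features, fit, predict, sample_background
from riversdm.stack import EnvStack


def line_stack(values, name="x", extra=None):
    """1×n stack holding given cell values (plus optional second layer)."""
    values = np.asarray(values, float)
    geom = GridGeometry(west=0, north=1, cellsize=1, nrows=1,
                        ncols=len(values))
    layers = {name: values.reshape(1, -1)}
    kinds = {name: "continuous"}
    if extra is not None:
        for k, v in extra.items():
            layers[k] = np.asarray(v, float).reshape(1, -1)
            kinds[k] = "continuous"
    return EnvStack(layers, kinds, geom)


def all_cells(stack):
    return stack.valid_cells()


def penalized_objective(X_bg, emp, beta, lam):
    """The quantity fit() maximizes, evaluated directly."""
    return float(emp @ lam - logsumexp(X_bg @ lam) - beta @ np.abs(lam))


class TestBuildFeatures:
    def test_linear_only_single_layer(self):
        stack = line_stack([0.0, 1.0, 2.0])
        cells = all_cells(stack)
        fs = build_features(stack, cells[:1], cells, classes=("linear",))
        assert len(fs) == 1 and fs.features[0].kind == "linear"

    def test_combinatorial_count_two_layers(self):
        stack = line_stack([0, 1, 2, 3], extra={"y": [3, 1, 0, 2]})
        cells = all_cells(stack)
        fs = build_features(stack, cells[:2], cells,
                            classes=("linear", "quadratic", "product"))
        # 2 linear + 2 quadratic + 1 product
        assert len(fs) == 5

    def test_hinge_features_match_formula_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 10, 200)
        stack = line_stack(vals)
        cells = all_cells(stack)
        fs = build_features(stack, cells[:5], cells, classes=("hinge",),
                            hinge_knots=10)
        forward = [f for f in fs.features if f.forward]
        reverse = [f for f in fs.features if not f.forward]
        assert len(forward) == 10 and len(reverse) == 10
        X = fs.design_matrix(r.extract(stack, cells))
        lo, hi = vals.min(), vals.max()
        for j, f in enumerate(fs.features):
            if f.forward:
                oracle = np.maximum(0.0, (vals - f.knot) / (hi - f.knot))
            else:
                oracle = np.maximum(0.0, (f.knot - vals) / (f.knot - lo))
            np.testing.assert_allclose(X[:, j], np.clip(oracle, 0, 1),
                                       atol=1e-12)

    def test_constant_layer_features_dropped_with_warning(self):
        stack = line_stack([2.0, 2.0, 2.0], extra={"y": [0, 1, 2]})
        cells = all_cells(stack)
        with pytest.warns(UserWarning, match="constant"):
            fs = build_features(stack, cells[:1], cells, classes=("linear",))
        assert [f.layer for f in fs.features] == ["y"]


class TestSampleBackground:
    def test_all_cells_when_n_large(self, small_geometry):
        stack = EnvStack({"x": np.ones((10, 10))}, {"x": "continuous"},
                         small_geometry)
        bg = sample_background(stack, 1000, seed=0)
        assert len(bg) == 100

    def test_same_seed_same_sample(self, small_geometry):
        stack = EnvStack({"x": np.ones((10, 10))}, {"x": "continuous"},
                         small_geometry)
        a = sample_background(stack, 30, seed=42)
        b = sample_background(stack, 30, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_inclusion_frequency_binomial(self):
        geom = GridGeometry(west=0, north=1, cellsize=0.1, nrows=1, ncols=10)
        stack = EnvStack({"x": np.ones((1, 10))}, {"x": "continuous"}, geom)
        reps = 1000
        counts = np.zeros(10)
        for s in range(reps):
            bg = sample_background(stack, 5, seed=s)
            counts[bg[:, 1]] += 1
        freq = counts / reps
        sd = np.sqrt(0.5 * 0.5 / reps)
        # 4 SD: the familywise bound across 10 cells (3 SD per cell trips
        # with probability ~3% somewhere)
        assert np.all(np.abs(freq - 0.5) < 4 * sd)


class TestFit:
    def test_no_signal_gives_uniform_model(self):
        rng = np.random.default_rng(6)
        stack = line_stack(rng.uniform(0, 1, 50))
        cells = all_cells(stack)
        presences = cells[rng.choice(50, size=20, replace=False)]
        fs = build_features(stack, presences, cells, classes=("linear",))
        fs.beta[:] = 1.0          # heavy penalty: any β above the gap
        model = fit(fs, presences, cells, stack)
        assert np.all(model.lam == 0)
        np.testing.assert_allclose(model.q_background,
                                   1.0 / len(cells), atol=1e-12)
        smap = predict(model, stack)
        np.testing.assert_allclose(smap.data[0], 0.5, atol=1e-12)

    def test_single_feature_matches_1d_brute_force(self):
        # presence mass concentrated on the x=1 cell, no penalty: λ solves
        # mean-matching 1 = E_q f; compare with a dense 1-D lattice search
        stack = line_stack([0.0, 0.5, 1.0])
        cells = all_cells(stack)
        presences = np.array([[0, 2], [0, 2]])
        fs = build_features(stack, presences, cells, classes=("linear",))
        fs.beta[:] = 0.0
        model = fit(fs, presences, cells, stack, tol=1e-7)
        X = fs.design_matrix(r.extract(stack, cells))
        emp = np.array([1.0])
        lams = np.linspace(-5, 40, 200001)
        objs = [penalized_objective(X, emp, np.zeros(1), np.array([l]))
                for l in lams]
        best = lams[int(np.argmax(objs))]
        ours = penalized_objective(X, emp, np.zeros(1), model.lam)
        assert ours >= max(objs) - 1e-6
        # λ is large (pushes all mass to x=1) but finite under the optimizer
        assert model.lam[0] > best * 0.5 or ours > max(objs) - 1e-6

    def test_kkt_certificate_holds(self, fitted_model, landscape):
        model = fitted_model
        np.testing.assert_allclose(model.q_background.sum(), 1.0, atol=1e-9)
        assert model.entropy >= 0
        beta = model.features.beta
        assert np.all(model.kkt_gap <= beta + 1e-4)
        # active features bind their constraint
        active = np.abs(model.lam) > 1e-8
        if active.any():
            np.testing.assert_allclose(model.kkt_gap[active], beta[active],
                                       atol=1e-4)

    @pytest.mark.parametrize("two_layers,classes,n_features", [
        (True, ("linear",), 2),
        (False, ("linear", "quadratic"), 2),
        (True, ("linear", "quadratic"), 4),
    ])
    def test_optimum_matches_brute_force_on_tiny_instances(self, two_layers,
                                                           classes,
                                                           n_features):
        """Penalized optimum within 1e-4 of iteratively-refined grid search
        on ≤4-feature, ≤30-background-cell instances."""
        rng = np.random.default_rng(n_features)
        n_cells = 30
        extra = {"y": rng.uniform(0, 1, n_cells)} if two_layers else None
        stack = line_stack(rng.uniform(0, 1, n_cells), extra=extra)
        cells = all_cells(stack)
        presences = cells[rng.choice(n_cells, size=8, replace=False)]
        fs = build_features(stack, presences, cells, classes=classes)
        model = fit(fs, presences, cells, stack, tol=1e-7)
        X = fs.design_matrix(r.extract(stack, cells))
        emp = fs.design_matrix(r.extract(stack, presences)).mean(axis=0)
        beta = fs.beta
        k = X.shape[1]
        assert k == n_features <= 4
        # iteratively refined dense grid: 9 points per axis, shrink ×0.3
        center = np.zeros(k)
        width = 8.0
        best_obj, best_lam = -np.inf, center
        for _ in range(12):
            axes = [center[j] + np.linspace(-width, width, 9)
                    for j in range(k)]
            grids = np.meshgrid(*axes, indexing="ij")
            lam_all = np.stack([g.ravel() for g in grids], axis=1)
            objs = (lam_all @ emp - logsumexp(lam_all @ X.T, axis=1)
                    - np.abs(lam_all) @ beta)
            i = int(np.argmax(objs))
            if objs[i] > best_obj:
                best_obj, best_lam = float(objs[i]), lam_all[i]
            center, width = lam_all[i], width * 0.3
        ours = penalized_objective(X, emp, beta, model.lam)
        assert abs(ours - best_obj) <= 1e-4

    def test_regularization_path_monotone(self):
        rng = np.random.default_rng(11)
        stack = line_stack(rng.uniform(0, 1, 40),
                           extra={"y": rng.uniform(0, 1, 40)})
        cells = all_cells(stack)
        presences = cells[rng.choice(40, size=12, replace=False)]
        fs = build_features(stack, presences, cells,
                            classes=("linear", "quadratic", "product"))
        base_beta = fs.beta.copy()
        nnz = []
        for mult in [0.1, 1.0, 10.0, 1000.0]:
            fs.beta = base_beta * mult
            model = fit(fs, presences, cells, stack)
            nnz.append(int(np.sum(np.abs(model.lam) > 1e-8)))
        assert nnz == sorted(nnz, reverse=True)
        assert nnz[-1] == 0

    def test_affine_layer_rescaling_leaves_q_unchanged(self):
        rng = np.random.default_rng(12)
        vals = rng.uniform(5, 15, 60)
        presences_idx = rng.choice(60, size=15, replace=False)
        qs = []
        for a, b in [(1.0, 0.0), (3.5, -20.0)]:
            stack = line_stack(a * vals + b)
            cells = all_cells(stack)
            presences = cells[presences_idx]
            fs = build_features(stack, presences, cells,
                                classes=("linear", "quadratic"))
            qs.append(fit(fs, presences, cells, stack).q_background)
        np.testing.assert_allclose(qs[0], qs[1], atol=1e-5)

    def test_single_presence_rejected(self):
        stack = line_stack([0.0, 1.0])
        cells = all_cells(stack)
        fs = build_features(stack, cells[:1], cells, classes=("linear",))
        with pytest.raises(ValueError, match="at least 2"):
            fit(fs, cells[:1], cells, stack)


class TestPredict:
    def test_training_background_reproduces_q(self, fitted_model, landscape):
        smap = predict(fitted_model, landscape["stack"], output="raw")
        bg = fitted_model.background
        # q renormalized over the full prediction region keeps background
        # ratios; compare on the background cells after renormalization
        q_pred = smap.data[bg[:, 0], bg[:, 1]]
        q_pred = q_pred / q_pred.sum()
        np.testing.assert_allclose(q_pred, fitted_model.q_background,
                                   rtol=1e-8)

    def test_raw_and_logistic_rank_identical(self, fitted_model, landscape):
        raw = predict(fitted_model, landscape["stack"], output="raw")
        logi = predict(fitted_model, landscape["stack"], output="logistic")
        mask = landscape["stack"].validity_mask
        rho = spearmanr(raw.data[mask], logi.data[mask]).statistic
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_missing_layer_rejected(self, fitted_model):
        geom = GridGeometry(west=0, north=1, cellsize=1, nrows=1, ncols=3)
        stack = EnvStack({"unrelated": np.ones((1, 3))},
                         {"unrelated": "continuous"}, geom)
        with pytest.raises(KeyError, match="lacks layers"):
            predict(fitted_model, stack)

    def test_logistic_values_strictly_inside_unit_interval(self, fitted_model,
                                                           landscape):
        smap = predict(fitted_model, landscape["stack"])
        vals = smap.data[landscape["stack"].validity_mask]
        assert np.all((vals > 0) & (vals < 1))
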