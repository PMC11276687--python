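import warnings

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import spearmanr

import grasshab as gh


def tiny_universe(columns: dict, presence_cells: list, fc="L", n_knots=5):
    """A 1-row universe with every cell as background; returns
    (stack, occ, bg, features)."""
    n = len(next(iter(columns.values())))
    grid = gh.GridSpec(nrows=1, ncols=n, xmin=0.0, ymax=1.0, cell=1.0)
    stack = gh.EnvStack(grid)
    for name, vals in columns.items():
        kind = "categorical" if name.startswith("cat") else "continuous"
        stack.add(name, np.asarray(vals, dtype=float).reshape(1, n), kind)
    occ = gh.OccurrenceSet(
        x=np.array([grid.cell_center(0, c)[0] for c in presence_cells]),
        y=np.array([grid.cell_center(0, c)[1] for c in presence_cells]),
        density=np.full(len(presence_cells), np.nan),
        rows=np.zeros(len(presence_cells), dtype=int),
        cols=np.array(presence_cells),
    )
    bg = gh.sample_background(stack, n, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        features = gh.build_features(stack, occ, bg, fc=fc, n_knots=n_knots)
    return stack, occ, bg, features


class TestBuildFeatures:
    def test_feature_counts_linear_plus_categorical(self):
        cols = {"a": [0, 1, 2, 3], "b": [3, 1, 0, 2], "c": [1, 3, 2, 0],
                "cat": [1, 2, 1, 2]}
        _, _, _, fs = tiny_universe(cols, [1, 2], fc="L")
        kinds = [f.fclass for f in fs.features]
        assert kinds.count("linear") == 3
        assert kinds.count("categorical") == 2  # one per observed level

    def test_feature_counts_lq(self):
        cols = {"a": [0, 1, 2, 3], "b": [3, 1, 0, 2], "c": [1, 3, 2, 0]}
        _, _, _, fs = tiny_universe(cols, [1, 2], fc="LQ")
        assert len(fs.features) == 6

    def test_constant_variable_dropped_with_warning(self):
        cols = {"a": [0, 1, 2, 3], "flat": [2, 2, 2, 2]}
        n = 4
        grid = gh.GridSpec(nrows=1, ncols=n, xmin=0.0, ymax=1.0, cell=1.0)
        stack = gh.EnvStack(grid)
        for name, vals in cols.items():
            stack.add(name, np.asarray(vals, dtype=float).reshape(1, n))
        occ = gh.OccurrenceSet(x=np.array([1.5]), y=np.array([0.5]),
                               density=np.array([np.nan]),
                               rows=np.array([0]), cols=np.array([1]))
        bg = gh.sample_background(stack, n, seed=0)
        with pytest.warns(UserWarning, match="constant"):
            fs = gh.build_features(stack, occ, bg, fc="L")
        assert fs.dropped_constant == ["flat"]
        assert all("flat" not in f.variables for f in fs.features)

    def test_out_of_extent_occurrences_rejected(self, small_stack, small_bg):
        occ = gh.OccurrenceSet(
            x=np.array([25.0, -100.0]), y=np.array([25.0, 25.0]),
            density=np.array([np.nan, np.nan]),
            rows=np.array([0, 0]), cols=np.array([0, 0]))
        with pytest.warns(UserWarning, match="rejected 1"):
            fs = gh.build_features(small_stack, occ, small_bg, fc="L")
        assert fs.n_rejected == 1
        assert fs.n_presence == 1

    def test_duplicate_presences_collapsed(self, small_stack, small_bg):
        occ = gh.OccurrenceSet(
            x=np.array([25.5, 25.5, 30.5]), y=np.array([25.5, 25.5, 30.5]),
            density=np.full(3, np.nan),
            rows=np.zeros(3, dtype=int), cols=np.zeros(3, dtype=int))
        with pytest.warns(UserWarning, match="collapsed 1"):
            fs = gh.build_features(small_stack, occ, small_bg, fc="L")
        assert fs.n_presence == 2

    def test_features_scaled_to_unit_interval(self, lqh_features):
        assert lqh_features.Fb.min() >= 0.0
        assert lqh_features.Fb.max() <= 1.0
        assert (lqh_features.beta > 0).all()


class TestFit:
    def test_presence_equal_background_gives_uniform(self):
        """When presences replicate the background, the max-entropy
        solution is the uniform distribution (all weights zero)."""
        cols = {"a": [0.0, 1.0, 2.0, 3.0], "b": [2.0, 0.0, 3.0, 1.0]}
        _, _, _, fs = tiny_universe(cols, [0, 1, 2, 3], fc="LQ")
        model = gh.fit(fs, rm=1.0)
        assert model.n_active == 0
        raw = gh.predict_raw(model, fs.background_table)
        np.testing.assert_allclose(raw, 0.25, atol=1e-12)

    def test_one_feature_matches_1d_newton_oracle(self):
        """4-cell universe, single linear feature, vanishing penalty:
        the weight must satisfy the moment-matching condition, solved
        independently by 1-D Newton iteration."""
        cols = {"a": [0.0, 1.0, 2.0, 3.0]}
        _, _, _, fs = tiny_universe(cols, [2, 3], fc="L")
        model = gh.fit(fs, rm=1e-8)
        f = fs.Fb[:, 0]
        pbar = fs.Fp[:, 0].mean()

        wj = 0.0
        for _ in range(100):
            p = np.exp(wj * f - logsumexp(wj * f))
            grad = p @ f - pbar
            hess = p @ f**2 - (p @ f) ** 2
            wj -= grad / hess
        assert model.weights[0] == pytest.approx(wj, abs=1e-6)

    def test_kkt_conditions_at_convergence(self, lqh_model, lqh_features):
        """Regularization bound holds for all features, with equality on
        the active set."""
        q = gh.predict_raw(lqh_model, lqh_features.background_table)
        g = q @ lqh_features.Fb - lqh_features.Fp.mean(axis=0)
        lam = lqh_model.rm * lqh_features.beta
        assert (np.abs(g) <= lam + 1e-6).all()
        active = lqh_model.weights != 0
        assert active.any()
        np.testing.assert_allclose(np.abs(g[active]), lam[active], atol=1e-6)

    def test_matches_brute_force_optimizer_small_universe(self):
        """<=30-cell universe, L features, rm -> 0: weights agree with an
        independent quasi-Newton minimization of the bare objective."""
        rng = np.random.default_rng(12)
        n = 30
        cols = {"a": rng.uniform(0, 1, n), "b": rng.uniform(0, 1, n),
                "c": rng.uniform(0, 1, n)}
        presence = sorted(rng.choice(n, size=12, replace=False).tolist())
        _, _, _, fs = tiny_universe(cols, presence, fc="L")
        model = gh.fit(fs, rm=1e-7)

        Fb, Fp = fs.Fb, fs.Fp
        pbar = Fp.mean(axis=0)

        def loss(w):
            return logsumexp(Fb @ w) - pbar @ w

        def grad(w):
            e = Fb @ w
            p = np.exp(e - logsumexp(e))
            return p @ Fb - pbar

        res = minimize(loss, np.zeros(Fb.shape[1]), jac=grad, method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 2000})
        np.testing.assert_allclose(model.weights, res.x, atol=1e-4)

    def test_background_raw_sums_to_one(self, lqh_model, lqh_features):
        raw = gh.predict_raw(lqh_model, lqh_features.background_table)
        assert raw.sum() == pytest.approx(1.0, abs=1e-9)

    def test_gain_monotone_in_regularization(self, lqh_features):
        """Stronger L1 penalties can only reduce the penalized training
        gain."""
        gains = []
        for rm in (0.5, 1.0, 2.0, 4.0):
            m = gh.fit(lqh_features, rm=rm, trace_contributions=False)
            gains.append(gh.training_gain(m, lqh_features))
        assert all(g1 >= g2 - 1e-6 for g1, g2 in zip(gains, gains[1:]))

    def test_rejects_bad_arguments(self, lqh_features):
        with pytest.raises(ValueError):
            gh.fit(lqh_features, rm=0.0)


class TestPrediction:
    def test_zero_weights_give_equal_raw(self):
        cols = {"a": [0.0, 1.0, 2.0, 3.0]}
        _, _, _, fs = tiny_universe(cols, [0, 1, 2, 3], fc="L")
        model = gh.fit(fs, rm=1.0)
        raw = gh.predict_raw(model, {"a": np.array([0.5, 2.5, 1.0])})
        assert np.ptp(raw) == pytest.approx(0.0, abs=1e-15)

    def test_log_ratio_identity(self, lqh_model, lqh_features):
        """Raw-score ratios equal exp of linear-predictor differences."""
        table = {v: vals[:10] for v, vals in
                 lqh_features.background_table.items()}
        raw = gh.predict_raw(lqh_model, table)
        eta = lqh_model.linear_predictor(table)
        for i in range(1, 10):
            assert raw[i] / raw[0] == pytest.approx(
                np.exp(eta[i] - eta[0]), rel=1e-9)

    def test_logistic_midpoint_and_range(self, lqh_model, lqh_features):
        raw = gh.predict_raw(lqh_model, lqh_features.background_table)
        logi = gh.predict_logistic(lqh_model, lqh_features.background_table)
        assert ((logi > 0) & (logi < 1)).all()
        # A point with raw = e^{-H} maps to exactly 0.5.
        s = raw * np.exp(lqh_model.entropy)
        np.testing.assert_allclose(logi, s / (1 + s), atol=1e-12)

    def test_logistic_preserves_raw_ranking(self, lqh_model, lqh_features):
        raw = gh.predict_raw(lqh_model, lqh_features.background_table)
        logi = gh.predict_logistic(lqh_model, lqh_features.background_table)
        rho = spearmanr(raw, logi).statistic
        assert rho == pytest.approx(1.0)

    def test_entropy_non_negative(self, lqh_model):
        assert lqh_model.entropy >= 0.0

    def test_model_file_roundtrip(self, tmp_path, lqh_model, lqh_features):
        path = tmp_path / "model.txt"
        gh.write_model(lqh_model, path)
        back = gh.read_model(path)
        r1 = gh.predict_logistic(lqh_model, lqh_features.background_table)
        r2 = gh.predict_logistic(back, lqh_features.background_table)
        np.testing.assert_allclose(r1, r2, rtol=1e-12)


class TestResponseCurve:
    def test_flat_for_null_model(self):
        cols = {"a": [0.0, 1.0, 2.0, 3.0], "b": [1.0, 3.0, 0.0, 2.0]}
        _, _, _, fs = tiny_universe(cols, [0, 1, 2, 3], fc="L")
        model = gh.fit(fs, rm=1.0)
        curve = gh.response_curve(model, fs, "a", n_grid=20)
        assert np.ptp(curve["suitability_mean"]) == pytest.approx(0, abs=1e-12)

    def test_monotone_for_positive_linear_weight(self):
        cols = {"a": np.linspace(0, 1, 12).tolist()}
        _, _, _, fs = tiny_universe(cols, [8, 9, 10, 11], fc="L")
        model = gh.fit(fs, rm=0.5)
        assert model.weights[0] > 0
        curve = gh.response_curve(model, fs, "a", n_grid=30)
        assert (np.diff(curve["suitability_mean"]) >= -1e-12).all()

    def test_unknown_variable_rejected(self, lqh_model, lqh_features):
        with pytest.raises(ValueError, match="not in the model"):
            gh.response_curve(lqh_model, lqh_features, "nope")

    def test_hinge_truth_recovered_across_seeds(self):
        """The fitted response rises where the generative hinge rises: the
        fitted curve's high region overlaps the true plateau in >= 8/10
        seeds."""
        hits = 0
        for seed in range(10):
            cfg = gh.SimConfig(nrows=40, ncols=40, n_occurrences=60,
                               seed=seed, categorical={})
            stack = gh.generate_env_stack(cfg)
            truth = gh.TrueResponseModel(
                terms=(gh.ResponseTerm("fvc", "hinge", 6.0, knot=0.5),),
                intercept=-3.0)
            occ = gh.sample_occurrences(stack, truth, cfg)
            bg = gh.sample_background(stack, 1000, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fs = gh.build_features(stack, occ, bg, fc="LQH", n_knots=8)
            model = gh.fit(fs, rm=1.0, trace_contributions=False)
            curve = gh.response_curve(model, fs, "fvc", n_grid=50)
            argmax_value = curve["value"][curve["suitability_mean"].idxmax()]
            lo, hi = np.nanmin(stack.layer("fvc")), np.nanmax(
                stack.layer("fvc"))
            plateau_start = lo + 0.5 * (hi - lo)
            hits += argmax_value >= plateau_start
        assert hits >= 8


class TestImportance:
    def test_single_variable_model_gets_full_importance(self):
        cols = {"a": np.linspace(0, 1, 10).tolist()}
        _, _, _, fs = tiny_universe(cols, [7, 8, 9], fc="L")
        model = gh.fit(fs, rm=0.5)
        imp = gh.permutation_importance(model, fs, seed=0)
        assert imp["permutation_importance"].iloc[0] == pytest.approx(100.0)
        contrib = gh.percent_contribution(model)
        assert contrib["percent_contribution"].iloc[0] == pytest.approx(100.0)

    def test_importances_normalized(self, lqh_model, lqh_features):
        imp = gh.permutation_importance(lqh_model, lqh_features, seed=1)
        assert imp["permutation_importance"].sum() == pytest.approx(
            100.0, abs=0.01)
        contrib = gh.percent_contribution(lqh_model)
        assert contrib["percent_contribution"].sum() == pytest.approx(
            100.0, abs=0.01)

    def test_zero_weight_variable_unimportant(self):
        rng = np.random.default_rng(4)
        cols = {"a": np.linspace(0, 1, 20).tolist(),
                "noise": rng.uniform(0, 1, 20).tolist()}
        _, _, _, fs = tiny_universe(cols, [15, 16, 17, 18, 19], fc="L")
        model = gh.fit(fs, rm=1.0)
        imp = gh.permutation_importance(model, fs, seed=0)
        row = imp.set_index("variable")["permutation_importance"]
        if model.weights[[f.variables[0] == "noise"
                          for f in model.features]].sum() == 0:
            assert row["noise"] == pytest.approx(0.0, abs=1e-9)

    def test_contribution_requires_trace(self, lqh_features):
        model = gh.fit(lqh_features, rm=1.0, trace_contributions=False)
        with pytest.raises(ValueError, match="tracing"):
            gh.percent_contribution(model)

    def test_driver_ranks_first_across_seeds(self):
        """Percent contribution identifies the single generative driver."""
        hits = 0
        for seed in range(10):
            cfg = gh.SimConfig(nrows=40, ncols=40, n_occurrences=60,
                               seed=seed, categorical={})
            stack = gh.generate_env_stack(cfg)
            truth = gh.TrueResponseModel(
                terms=(gh.ResponseTerm("dem", "linear", 5.0),),
                intercept=-3.5)
            occ = gh.sample_occurrences(stack, truth, cfg)
            bg = gh.sample_background(stack, 1000, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fs = gh.build_features(stack, occ, bg, fc="LQ")
            model = gh.fit(fs, rm=1.0)
            contrib = gh.percent_contribution(model)
            hits += contrib["variable"].iloc[0] == "dem"
        assert hits >= 8


class TestJackknife:
    def test_redundant_variable_leaves_gain_unchanged(self):
        vals = np.linspace(0, 1, 12).tolist()
        cols = {"a": vals, "twin": vals}
        _, _, _, fs = tiny_universe(cols, [8, 9, 10, 11], fc="L")
        jk = gh.jackknife_gains(fs, rm=0.5)
        full = jk.attrs["full_gain"]
        for _, row in jk.iterrows():
            assert row["gain_without"] == pytest.approx(full, abs=1e-3)

    def test_full_gain_dominates_leave_one_out(self, lqh_features):
        jk = gh.jackknife_gains(lqh_features, rm=1.0)
        full = jk.attrs["full_gain"]
        assert (jk["gain_without"] <= full + 1e-6).all()

    def test_driver_gain_beats_noise_across_seeds(self):
        hits = 0
        for seed in range(10):
            cfg = gh.SimConfig(nrows=40, ncols=40, n_occurrences=60,
                               seed=seed, categorical={})
            stack = gh.generate_env_stack(cfg)
            truth = gh.TrueResponseModel(
                terms=(gh.ResponseTerm("precip", "linear", 5.0),),
                intercept=-3.5)
            occ = gh.sample_occurrences(stack, truth, cfg)
            bg = gh.sample_background(stack, 1000, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fs = gh.build_features(stack, occ, bg, fc="L")
            jk = gh.jackknife_gains(fs, rm=1.0).set_index("variable")
            hits += (jk.loc["precip", "gain_only"]
                     > jk.loc["dem", "gain_only"])
        assert hits >= 9
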