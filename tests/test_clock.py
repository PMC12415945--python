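"""Elastic-net solver contracts, tuning determinism, metrics and I/O.

The solver is cross-checked against an independent proximal-gradient (ISTA)
oracle and closed forms (orthonormal soft-thresholding, ridge normal
equations); tuning utilities are checked for determinism and their defining
argmin/sparsity properties.
"""

import numpy as np
import pandas as pd
import pytest

from methclock.clock import (
    ClockHyperparams,
    MissingSitesError,
    _lambda_grid,
    _standardize,
    alpha_sweep,
    fit_elastic_net,
    lambda_path_cv,
    load_model,
    loocv_evaluate,
    mad,
    pearson_ci,
    predict_age,
    save_model,
    train_clock,
)


# ---------------------------------------------------------------------------
# independent proximal-gradient oracle
# ---------------------------------------------------------------------------

def enet_prox_oracle(Xs, yc, alpha, lam, n_iter=200_000, tol=1e-13):
    """ISTA on the glmnet objective; independent of coordinate descent."""
    n, p = Xs.shape
    w = np.zeros(p)
    lip = np.linalg.norm(Xs, 2) ** 2 / n + lam * (1 - alpha)
    step = 1.0 / lip
    thr = step * lam * alpha
    for _ in range(n_iter):
        grad = Xs.T @ (Xs @ w - yc) / n + lam * (1 - alpha) * w
        z = w - step * grad
        w_new = np.sign(z) * np.maximum(np.abs(z) - thr, 0.0)
        if np.max(np.abs(w_new - w)) < tol:
            return w_new
        w = w_new
    return w


def random_instance(rng, n=8, p=5):
    X = pd.DataFrame(
        rng.normal(size=(n, p)),
        index=[f"S{i}" for i in range(n)],
        columns=[f"c{j}" for j in range(p)],
    )
    y = pd.Series(
        X.to_numpy()[:, 0] - 0.5 * X.to_numpy()[:, 1] + rng.normal(size=n),
        index=X.index,
    )
    return X, y


class TestFitElasticNet:
    def test_full_shrinkage_limit(self):
        rng = np.random.default_rng(0)
        X, y = random_instance(rng)
        model = fit_elastic_net(X, y, alpha=0.5, lam=1e6)
        assert len(model.coef) == 0
        assert model.intercept == pytest.approx(float(y.mean()))
        assert model.predict(X.iloc[0]) == pytest.approx(float(y.mean()))

    def test_unpenalised_exact_fit(self):
        y = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        X = pd.DataFrame({"c": y * 2.0 + 1.0})
        model = fit_elastic_net(X, y, alpha=0.5, lam=0.0)
        preds = model.predict(X)
        assert np.allclose(preds, y, atol=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_proximal_gradient_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X, y = random_instance(rng)
        alpha, lam = 0.2, 0.1
        model = fit_elastic_net(X, y, alpha=alpha, lam=lam)
        Xs, _, _ = _standardize(X.to_numpy())
        yc = y.to_numpy() - y.mean()
        w_oracle = enet_prox_oracle(Xs, yc, alpha, lam)
        w_fit = pd.Series(0.0, index=X.columns)
        w_fit[model.coef.index] = model.coef
        assert np.allclose(w_fit.to_numpy(), w_oracle, atol=1e-6)
        assert model.kkt_violation < 1e-6

    def test_orthonormal_soft_thresholding(self):
        # columns orthogonal with population SD 1 -> X'X/n = I and the lasso
        # solution is coordinatewise soft-thresholding of x_j'y/n
        n = 8
        base = np.array([[1, 1, 1, 1, -1, -1, -1, -1],
                         [1, 1, -1, -1, 1, 1, -1, -1],
                         [1, -1, 1, -1, 1, -1, 1, -1]], dtype=float).T
        X = pd.DataFrame(base, columns=list("abc"))
        rng = np.random.default_rng(1)
        y = pd.Series(base @ np.array([1.0, 0.3, 0.02]) + rng.normal(0, 0.1, n))
        lam, alpha = 0.2, 1.0
        model = fit_elastic_net(X, y, alpha=alpha, lam=lam)
        c = base.T @ (y - y.mean()).to_numpy() / n
        expected = np.sign(c) * np.maximum(np.abs(c) - lam, 0.0)
        w = pd.Series(0.0, index=X.columns)
        w[model.coef.index] = model.coef
        assert np.allclose(w.to_numpy(), expected, atol=1e-7)

    def test_ridge_limit_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        X, y = random_instance(rng, n=12, p=4)
        lam = 0.3
        model = fit_elastic_net(X, y, alpha=0.0, lam=lam)
        Xs, _, _ = _standardize(X.to_numpy())
        yc = y.to_numpy() - y.mean()
        n, p = Xs.shape
        w = np.linalg.solve(Xs.T @ Xs / n + lam * np.eye(p), Xs.T @ yc / n)
        w_fit = pd.Series(0.0, index=X.columns)
        w_fit[model.coef.index] = model.coef
        assert np.allclose(w_fit.to_numpy(), w, atol=1e-6)

    def test_constant_response_rejected(self):
        X, _ = random_instance(np.random.default_rng(0))
        with pytest.raises(ValueError, match="constant"):
            fit_elastic_net(X, np.ones(len(X)), alpha=0.2, lam=0.1)

    def test_constant_column_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(0)
        X, y = random_instance(rng)
        X["flat"] = 1.0
        with caplog.at_level("WARNING"):
            model = fit_elastic_net(X, y, alpha=0.2, lam=0.01)
        assert "constant" in caplog.text
        assert "flat" not in model.coef.index

    def test_raw_coefficients_reproduce_predictions(self):
        rng = np.random.default_rng(2)
        X, y = random_instance(rng, n=10, p=3)
        model = fit_elastic_net(X, y, alpha=0.2, lam=0.05)
        b0, b = model.raw_coefficients()
        manual = b0 + X[b.index] @ b
        assert np.allclose(model.predict(X), manual)


class TestLambdaPath:
    def test_lambda_max_closed_form(self):
        # 5x2 instance: lambda_max = max_j |<x_j, y - ybar>| / (n * alpha)
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        Xs, _, _ = _standardize(X)
        yc = y - y.mean()
        alpha = 0.4
        grid = _lambda_grid(Xs, yc, alpha, 10)
        by_hand = max(
            abs(float(Xs[:, j] @ yc)) for j in range(2)
        ) / (5 * alpha)
        assert grid[0] == pytest.approx(by_hand, rel=1e-12)

    def test_lambda_min_beats_grid_end_on_noise(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(30, 15)))
        y = pd.Series(rng.normal(size=30))
        path = lambda_path_cv(X, y, alpha=0.2, cv_folds=5, seed=0)
        assert path.cv_mse.min() <= path.cv_mse[-1]
        assert path.lambda_min == path.lambdas[np.argmin(path.cv_mse)]

    def test_identical_seed_identical_path(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(20, 10)))
        y = pd.Series(X.iloc[:, 0] + rng.normal(size=20))
        a = lambda_path_cv(X, y, 0.2, 5, seed=42)
        b = lambda_path_cv(X, y, 0.2, 5, seed=42)
        assert a.lambda_min == b.lambda_min
        assert np.array_equal(a.cv_mse, b.cv_mse)

    def test_sparsity_non_increasing_along_path(self):
        from sklearn.linear_model import enet_path

        rng = np.random.default_rng(7)
        Xs, _, _ = _standardize(rng.normal(size=(25, 12)))
        y = Xs[:, 0] + 0.5 * Xs[:, 1] + rng.normal(0, 0.3, 25)
        yc = y - y.mean()
        lambdas = _lambda_grid(Xs, yc, 1.0, 40)
        _, coefs, _ = enet_path(Xs, yc, l1_ratio=1.0, alphas=lambdas, tol=1e-10)
        nnz = (np.abs(coefs) > 1e-12).sum(axis=0)
        # active set grows (nnz non-decreasing) as lambda shrinks, up to
        # small coordinate-descent jitter
        assert np.all(np.diff(nnz) >= -1)


class TestAlphaSweep:
    def test_single_alpha_single_row(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(15, 6)))
        y = pd.Series(X.iloc[:, 0] + rng.normal(0, 0.5, 15))
        table = alpha_sweep(X, y, ClockHyperparams(
            sweep_alphas=(0.0,), sweep_iterations=2, cv_folds=5
        ))
        assert len(table) == 1 and table.loc[0, "alpha"] == 0.0

    def test_lasso_sparser_than_near_ridge(self):
        # correlated predictors: alpha = 1 retains no more CpGs than 0.1
        rng = np.random.default_rng(9)
        z = rng.normal(size=(40, 1))
        X = pd.DataFrame(z + 0.3 * rng.normal(size=(40, 12)))
        y = pd.Series(z[:, 0] + rng.normal(0, 0.5, 40))
        table = alpha_sweep(X, y, ClockHyperparams(
            sweep_alphas=(0.1, 1.0), sweep_iterations=5, cv_folds=5, seed=3
        )).set_index("alpha")
        assert table.loc[1.0, "mean_n_nonzero"] <= table.loc[0.1, "mean_n_nonzero"]

    def test_sweep_deterministic(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(15, 5)))
        y = pd.Series(X.iloc[:, 0] + rng.normal(0, 0.4, 15))
        hp = ClockHyperparams(sweep_alphas=(0.2, 0.8), sweep_iterations=3,
                              cv_folds=5, seed=1)
        pd.testing.assert_frame_equal(alpha_sweep(X, y, hp), alpha_sweep(X, y, hp))

    def test_empty_grid_rejected(self):
        rng = np.random.default_rng(0)
        X, y = random_instance(rng)
        with pytest.raises(ValueError, match="empty alpha grid"):
            alpha_sweep(X, y, ClockHyperparams(sweep_alphas=()))


class TestLoocv:
    def test_noiseless_single_cpg_recovery(self):
        y = pd.Series(np.arange(1.0, 13.0), index=[f"S{i}" for i in range(12)])
        X = pd.DataFrame({"chr1:1": (y - y.min()) / (y.max() - y.min())})
        rng = np.random.default_rng(1)
        X["chr1:3"] = rng.normal(size=12)  # one distractor
        report = loocv_evaluate(X, y, alpha=0.2, cv_folds=5, seed=0)
        assert report.pearson_r >= 0.99
        assert report.mad <= 0.2

    def test_predictions_invariant_to_sample_order(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(
            rng.normal(size=(12, 8)), index=[f"S{i}" for i in range(12)]
        )
        y = pd.Series(X.iloc[:, 0] * 2 + rng.normal(0, 0.3, 12), index=X.index)
        a = loocv_evaluate(X, y, alpha=0.2, cv_folds=4, seed=5)
        perm = rng.permutation(X.index)
        b = loocv_evaluate(X.loc[perm], y.loc[perm], alpha=0.2, cv_folds=4, seed=5)
        pd.testing.assert_series_equal(
            a.predictions["predicted"].sort_index(),
            b.predictions["predicted"].sort_index(),
        )

    def test_metrics_recomputable_from_prediction_table(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(10, 4)))
        y = pd.Series(X.iloc[:, 0] + rng.normal(0, 0.4, 10))
        rep = loocv_evaluate(X, y, alpha=0.5, cv_folds=5, seed=2)
        t = rep.predictions
        assert rep.mad == mad(t["predicted"], t["age"])
        r = np.corrcoef(t["age"], t["predicted"])[0, 1]
        assert rep.pearson_r == pytest.approx(r)
        assert (rep.r_ci_low, rep.r_ci_high) == pearson_ci(rep.pearson_r, len(t))

    def test_too_few_samples_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            loocv_evaluate(X, [1.0, 2.0], alpha=0.2)


class TestMetrics:
    def test_pearson_ci_printed_values(self):
        assert tuple(round(v, 2) for v in pearson_ci(0.84, 122)) == (0.78, 0.89)
        assert tuple(round(v, 2) for v in pearson_ci(0.89, 67)) == (0.83, 0.93)

    def test_pearson_ci_symmetric_at_zero(self):
        lo, hi = pearson_ci(0.0, 103)
        assert lo == pytest.approx(-hi)
        assert hi == pytest.approx(0.1935, abs=1e-3)

    def test_pearson_ci_degenerate_at_unit_r(self):
        assert pearson_ci(1.0, 10) == (1.0, 1.0)

    def test_mad_examples(self):
        assert mad([1.0, 1.0], [1.0, 1.0]) == 0.0
        assert mad([1, 2, 4], [1, 1, 1]) == 1.0
        assert mad([0, 2], [0, 0]) == 1.0  # even-n midpoint convention

    def test_mad_length_mismatch(self):
        with pytest.raises(ValueError):
            mad([1.0], [1.0, 2.0])


class TestPredictAndSerialization:
    def make_model(self, n_sites=3):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(
            rng.uniform(0.1, 0.9, size=(20, n_sites)),
            columns=[f"chr1:{10 * j + 1}" for j in range(n_sites)],
        )
        y = pd.Series(X.iloc[:, 0] * 5 + rng.normal(0, 0.1, 20))
        return fit_elastic_net(X, y, alpha=0.2, lam=0.01)

    def test_linear_form(self):
        model = self.make_model()
        model.coef[:] = [1.0] + [0.0] * (len(model.coef) - 1)
        model.intercept = 2.0
        site = model.coef.index[0]
        model.mean[:] = 0.0
        model.sd[:] = 1.0
        sample = {s: 0.0 for s in model.coef.index}
        sample[site] = 0.5
        assert predict_age(model, sample) == pytest.approx(2.5)

    def test_training_means_predict_intercept(self):
        model = self.make_model()
        assert model.predict(model.mean.to_dict()) == pytest.approx(model.intercept)

    def test_missing_site_refused_and_named(self):
        model = self.make_model()
        sample = model.mean.to_dict()
        gone = model.coef.index[0]
        del sample[gone]
        with pytest.raises(MissingSitesError, match=str(gone)):
            model.predict(sample)

    def test_round_trip_identical_predictions(self, tmp_path):
        model = self.make_model()
        rng = np.random.default_rng(14)
        sample = {
            s: float(v)
            for s, v in zip(model.coef.index, rng.uniform(0, 1, len(model.coef)))
        }
        save_model(model, tmp_path / "clock.tsv")
        back = load_model(tmp_path / "clock.tsv")
        assert back.predict(sample) == model.predict(sample)
        assert back.alpha == model.alpha and back.n_train == model.n_train

    def test_empty_model_predicts_intercept(self, tmp_path):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(8, 3)))
        y = pd.Series(rng.normal(size=8))
        model = fit_elastic_net(X, y, alpha=0.5, lam=1e6)
        save_model(model, tmp_path / "m.tsv")
        back = load_model(tmp_path / "m.tsv")
        assert back.predict({}) == pytest.approx(float(y.mean()))

    def test_truncated_file_rejected(self, tmp_path):
        model = self.make_model()
        save_model(model, tmp_path / "m.tsv")
        text = (tmp_path / "m.tsv").read_text().splitlines()
        (tmp_path / "broken.tsv").write_text("\n".join(text[:3]) + "\n")
        with pytest.raises(ValueError, match="truncated|header"):
            load_model(tmp_path / "broken.tsv")

    def test_wrong_format_rejected(self, tmp_path):
        (tmp_path / "x.tsv").write_text("site\tweight\n")
        with pytest.raises(ValueError, match="not a methclock model"):
            load_model(tmp_path / "x.tsv")


class TestTrainClock:
    def test_kkt_satisfied_and_lambda_from_path(self):
        rng = np.random.default_rng(15)
        X = pd.DataFrame(rng.uniform(size=(25, 10)))
        y = pd.Series(X.iloc[:, 0] * 3 + rng.normal(0, 0.2, 25))
        model = train_clock(X, y, alpha=0.2, cv_folds=5, seed=0)
        assert model.kkt_violation < 1e-6
        path = lambda_path_cv(X, y, 0.2, 5, seed=0)
        assert model.lam == path.lambda_min
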