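"""Elastic-net epigenetic clocks: fitting, tuning, LOOCV and prediction.

A clock is a penalised linear model predicting age from methylation ratios at
a CpG panel.  With predictors standardized to zero mean and unit SD, the
fitted model minimises

    (1 / 2n) * sum_i (y_i - b0 - x_i' b)^2
        + lambda * (alpha * ||b||_1 + (1 - alpha) * ||b||_2^2 / 2)

which is the glmnet-style elastic net: ``alpha`` mixes ridge (0) and lasso
(1), ``lambda`` scales the penalty.  scikit-learn's coordinate-descent solver
(`ElasticNet` / `enet_path`) minimises exactly this objective with
``alpha_sklearn = lambda`` and ``l1_ratio = alpha``.

Tuning follows the standard clock recipe: a geometric lambda grid descending
from the smallest lambda that zeroes every coefficient, k-fold
cross-validation along the path, ``lambda_min`` at the minimum mean CV MSE,
and an alpha sweep (grid 0..1 in 0.1 steps, many fold-randomisation
iterations) summarising the error/sparsity trade-off per alpha.  Accuracy is
reported from leave-one-out cross-validation as Pearson r (with a Fisher-z
95% CI) and the median absolute deviation between predicted and
chronological age.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, enet_path

__all__ = [
    "ClockHyperparams",
    "ClockModel",
    "EvaluationReport",
    "LambdaPath",
    "MissingSitesError",
    "fit_elastic_net",
    "lambda_path_cv",
    "alpha_sweep",
    "loocv_evaluate",
    "train_clock",
    "pearson_ci",
    "mad",
    "predict_age",
    "save_model",
    "load_model",
    "plot_predictions",
]

logger = logging.getLogger(__name__)

# smallest alpha used in the lambda_max formula; pure ridge has no finite
# zeroing penalty, so the grid anchor substitutes this (glmnet convention)
_RIDGE_ALPHA_FLOOR = 1e-3
_MODEL_FORMAT = "methclock_model\tv1"


class MissingSitesError(KeyError):
    """A sample lacks ratios for one or more clock CpGs."""

    def __init__(self, missing: Sequence[str]):
        self.missing = list(missing)
        super().__init__(
            f"sample is missing {len(self.missing)} clock CpG(s): "
            + ", ".join(map(str, self.missing[:10]))
            + ("..." if len(self.missing) > 10 else "")
        )


@dataclass(frozen=True)
class ClockHyperparams:
    """Hyperparameters of clock construction."""

    alpha: float = 0.2
    lam: float | None = None  # None selects lambda_min by internal CV
    cv_folds: int = 10
    sweep_alphas: tuple[float, ...] = tuple(np.round(np.arange(0, 1.01, 0.1), 1))
    sweep_iterations: int = 100
    n_lambda: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class ClockModel:
    """A fitted clock: intercept plus sparse standardized-scale weights.

    ``coef`` holds only nonzero weights, on the standardized-predictor scale;
    ``mean``/``sd`` are the training standardization parameters of those
    sites.  Predicted age for a sample with ratio vector x is

        intercept + sum_j coef_j * (x_j - mean_j) / sd_j

    Raw-scale coefficients (applying directly to unstandardized ratios) are
    available via :meth:`raw_coefficients`.
    """

    intercept: float
    coef: pd.Series
    mean: pd.Series
    sd: pd.Series
    alpha: float
    lam: float
    n_train: int
    age_unit: str = "years"
    kkt_violation: float = float("nan")

    @property
    def sites(self) -> list[str]:
        return list(self.coef.index)

    def raw_coefficients(self) -> tuple[float, pd.Series]:
        """(intercept, weights) applying to unstandardized ratios."""
        raw = self.coef / self.sd
        return float(self.intercept - (raw * self.mean).sum()), raw

    def predict(self, samples: pd.DataFrame | pd.Series | Mapping[str, float]):
        """Predict age for one sample (Series/mapping) or many (DataFrame
        with sites as columns).

        Raises :class:`MissingSitesError` if any clock CpG is absent or NaN —
        the clock is only applicable to samples in which every retained CpG
        was detected.
        """
        one = not isinstance(samples, pd.DataFrame)
        frame = (
            pd.DataFrame([pd.Series(samples)]) if one else samples
        )
        missing = [s for s in self.coef.index if s not in frame.columns]
        if not missing:
            sub = frame[self.coef.index]
            na = sub.isna().any(axis=0)
            missing = list(na.index[na])
        if missing:
            raise MissingSitesError(missing)
        z = (sub - self.mean) / self.sd
        pred = self.intercept + z.to_numpy() @ self.coef.to_numpy()
        if one:
            return float(pred[0])
        return pd.Series(pred, index=frame.index, name="predicted_age")


@dataclass(frozen=True)
class EvaluationReport:
    """LOOCV predictions and summary accuracy metrics."""

    predictions: pd.DataFrame  # index sample; columns age, predicted
    pearson_r: float
    r_ci_low: float
    r_ci_high: float
    mad: float
    age_unit: str = "years"
    group: str | None = None

    def summary(self) -> str:
        return (
            f"n={len(self.predictions)}  r={self.pearson_r:.2f} "
            f"(95% CI {self.r_ci_low:.2f}-{self.r_ci_high:.2f})  "
            f"MAD={self.mad:.3g} {self.age_unit}"
        )


@dataclass(frozen=True)
class LambdaPath:
    """Cross-validated regularisation path."""

    lambdas: np.ndarray
    cv_mse: np.ndarray
    lambda_min: float

    @property
    def min_mse(self) -> float:
        return float(self.cv_mse.min())


# ---------------------------------------------------------------------------
# standardization and fold helpers
# ---------------------------------------------------------------------------

def _as_xy(X: pd.DataFrame, y) -> tuple[pd.DataFrame, pd.Series]:
    X = pd.DataFrame(X)
    y = pd.Series(np.asarray(y, dtype=float), index=X.index, name="age")
    if X.isna().any().any() or y.isna().any():
        raise ValueError("X and y must be complete (no missing entries)")
    return X, y


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-standardize with the population (1/n) SD, glmnet-style.

    Constant columns get SD 1 so they standardize to all-zeros and simply
    attract zero coefficients.
    """
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd < 1e-12, 1.0, sd)
    return (X - mean) / sd_safe, mean, sd_safe


def _fold_ids(ids: Sequence, cv_folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic fold assignment keyed to sorted sample ids.

    Sorting before permuting makes folds invariant to the row order of the
    input matrix: the same (ids, seed) always gives the same folds.
    """
    ordered = np.array(sorted(map(str, ids)), dtype=object)
    rng = np.random.default_rng(seed)
    return [np.asarray(f) for f in np.array_split(rng.permutation(ordered), cv_folds)]


def _derive_seed(*parts) -> int:
    """Stable 31-bit seed from arbitrary labelled parts (crc32 of the text)."""
    return zlib.crc32(":".join(map(str, parts)).encode()) & 0x7FFFFFFF


def _lambda_grid(
    Xs: np.ndarray, yc: np.ndarray, alpha: float, n_lambda: int
) -> np.ndarray:
    """Geometric grid from lambda_max = max|<x_j, y - ybar>| / (n * alpha).

    The lower end follows the glmnet rule: lambda_max * 1e-4 when n > p,
    lambda_max * 1e-2 otherwise.
    """
    n, p = Xs.shape
    lmax = float(np.max(np.abs(Xs.T @ yc)) / (n * max(alpha, _RIDGE_ALPHA_FLOOR)))
    if lmax <= 0:
        lmax = 1e-3
    eps = 1e-4 if n > p else 1e-2
    return np.geomspace(lmax, lmax * eps, n_lambda)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_elastic_net(
    X: pd.DataFrame,
    y,
    alpha: float = 0.2,
    lam: float = 0.0,
    age_unit: str = "years",
) -> ClockModel:
    """Fit one elastic-net clock at fixed (alpha, lambda).

    Predictors are standardized internally; the returned model keeps only the
    nonzero coefficients together with their standardization parameters.  A
    KKT-condition residual is computed after fitting and stored on the model
    (``kkt_violation``); values above 1e-6 are logged as warnings.

    Raises ``ValueError`` for constant ``y``; constant predictor columns are
    dropped with a warning.
    """
    X, y = _as_xy(X, y)
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need at least 2 samples and 1 site")
    if float(np.std(y)) == 0.0:
        raise ValueError("constant response: ages carry no signal to fit")
    sds = X.to_numpy().std(axis=0)
    constant = sds < 1e-12
    if constant.any():
        dropped = list(X.columns[constant])
        logger.warning("dropping %d constant predictor column(s): %s",
                       len(dropped), dropped[:5])
        X = X.loc[:, ~constant]
    Xs, mean, sd = _standardize(X.to_numpy(dtype=float))
    ybar = float(y.mean())
    yc = y.to_numpy() - ybar
    n = Xs.shape[0]
    if lam == 0.0:
        w = np.linalg.lstsq(Xs, yc, rcond=None)[0]
    else:
        est = ElasticNet(
            alpha=lam, l1_ratio=alpha, fit_intercept=False,
            max_iter=100_000, tol=1e-8,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(Xs, yc)
        w = est.coef_
    kkt = _kkt_violation(Xs, yc, w, alpha, lam)
    if kkt > 1e-6:
        logger.warning("KKT residual %.2e above tolerance after fit", kkt)
    nz = np.abs(w) > 0
    return ClockModel(
        intercept=ybar,
        coef=pd.Series(w[nz], index=X.columns[nz], name="weight"),
        mean=pd.Series(mean[nz], index=X.columns[nz], name="train_mean"),
        sd=pd.Series(sd[nz], index=X.columns[nz], name="train_sd"),
        alpha=float(alpha),
        lam=float(lam),
        n_train=n,
        age_unit=age_unit,
        kkt_violation=kkt,
    )


def _kkt_violation(
    Xs: np.ndarray, yc: np.ndarray, w: np.ndarray, alpha: float, lam: float
) -> float:
    """Max violation of the elastic-net subgradient optimality conditions."""
    n = Xs.shape[0]
    g = Xs.T @ (Xs @ w - yc) / n
    if lam == 0.0:
        return float(np.max(np.abs(g))) if g.size else 0.0
    nz = w != 0
    v_nz = np.abs(g[nz] + lam * (1 - alpha) * w[nz] + lam * alpha * np.sign(w[nz]))
    v_z = np.maximum(np.abs(g[~nz]) - lam * alpha, 0.0)
    parts = [v for v in (v_nz, v_z) if v.size]
    return float(max(np.max(v) for v in parts)) if parts else 0.0


# ---------------------------------------------------------------------------
# lambda path cross-validation
# ---------------------------------------------------------------------------

# coordinate-descent tolerance for CV paths: only the shape of the CV-MSE
# curve matters here, so this is looser than the final refit tolerance in
# fit_elastic_net, where coefficients must satisfy KKT to high precision
_PATH_TOL = 1e-3


def _cv_mse_path(
    X: pd.DataFrame,
    y: pd.Series,
    alpha: float,
    lambdas: np.ndarray,
    folds: list[np.ndarray],
) -> np.ndarray:
    """Pooled CV mean squared error at each lambda of a fixed grid."""
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    ids = X.index.astype(str)
    sq_err = np.zeros(lambdas.size)
    n_total = 0
    for test_ids in folds:
        if len(test_ids) == 0:
            continue
        test_mask = np.asarray(ids.isin(test_ids))
        X_tr, y_tr = Xv[~test_mask], yv[~test_mask]
        X_te, y_te = Xv[test_mask], yv[test_mask]
        if float(np.std(y_tr)) == 0.0:
            raise ValueError("constant response within a CV training fold")
        Xs_tr, mean, sd = _standardize(X_tr)
        ybar = float(y_tr.mean())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            _, coefs, _ = enet_path(
                Xs_tr, y_tr - ybar,
                l1_ratio=alpha, alphas=lambdas, tol=_PATH_TOL,
            )
        Xs_te = (X_te - mean) / sd
        preds = ybar + Xs_te @ coefs  # (n_test, n_lambda)
        sq_err += ((preds - y_te[:, None]) ** 2).sum(axis=0)
        n_total += len(y_te)
    return sq_err / n_total


def lambda_path_cv(
    X: pd.DataFrame,
    y,
    alpha: float = 0.2,
    cv_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
) -> LambdaPath:
    """Cross-validate a descending lambda grid and locate ``lambda_min``.

    The grid descends geometrically from the closed-form lambda_max (the
    smallest penalty zeroing all coefficients).  Folds are deterministic in
    (sample ids, seed).  ``lambda_min`` minimises the pooled CV MSE; ties go
    to the larger lambda.
    """
    X, y = _as_xy(X, y)
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    if X.shape[0] < cv_folds:
        raise ValueError("need at least cv_folds samples")
    Xs, _, _ = _standardize(X.to_numpy(dtype=float))
    lambdas = _lambda_grid(Xs, y.to_numpy() - y.mean(), alpha, n_lambda)
    folds = _fold_ids(X.index, cv_folds, seed)
    mse = _cv_mse_path(X, y, alpha, lambdas, folds)
    return LambdaPath(
        lambdas=lambdas, cv_mse=mse, lambda_min=float(lambdas[int(np.argmin(mse))])
    )


def alpha_sweep(
    X: pd.DataFrame,
    y,
    hyperparams: ClockHyperparams = ClockHyperparams(),
) -> pd.DataFrame:
    """Summarise the error/sparsity trade-off across the alpha grid.

    For each alpha, the lambda path is cross-validated ``sweep_iterations``
    times with fresh fold randomisations (seeds derived from the master seed,
    alpha and iteration); the table reports the mean and SD of the minimum CV
    MSE and of the nonzero-coefficient count at each iteration's lambda_min.
    Choosing alpha from the table is left to the caller — lower error and
    more retained CpGs generally pull in opposite directions.
    """
    X, y = _as_xy(X, y)
    if not hyperparams.sweep_alphas:
        raise ValueError("empty alpha grid")
    Xs, _, _ = _standardize(X.to_numpy(dtype=float))
    yc = y.to_numpy() - float(y.mean())
    rows = []
    for a in hyperparams.sweep_alphas:
        lambdas = _lambda_grid(Xs, yc, a, hyperparams.n_lambda)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            _, full_coefs, _ = enet_path(
                Xs, yc, l1_ratio=a, alphas=lambdas, tol=_PATH_TOL
            )
        nnz_at = (np.abs(full_coefs) > 0).sum(axis=0)
        mses, nnzs = [], []
        for it in range(hyperparams.sweep_iterations):
            folds = _fold_ids(
                X.index, hyperparams.cv_folds,
                _derive_seed(hyperparams.seed, "alpha", a, "iter", it),
            )
            mse = _cv_mse_path(X, y, a, lambdas, folds)
            k = int(np.argmin(mse))
            mses.append(float(mse[k]))
            nnzs.append(int(nnz_at[k]))
        rows.append(
            {
                "alpha": a,
                "mean_cv_mse": float(np.mean(mses)),
                "sd_cv_mse": float(np.std(mses, ddof=1)) if len(mses) > 1 else 0.0,
                "mean_n_nonzero": float(np.mean(nnzs)),
                "sd_n_nonzero": float(np.std(nnzs, ddof=1)) if len(nnzs) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LOOCV evaluation and final training
# ---------------------------------------------------------------------------

def loocv_evaluate(
    X: pd.DataFrame,
    y,
    alpha: float = 0.2,
    cv_folds: int = 10,
    seed: int = 0,
    fixed_lambda: float | None = None,
    n_lambda: int = 100,
    age_unit: str = "years",
) -> EvaluationReport:
    """Leave-one-out evaluation of a clock at fixed alpha.

    For each sample, a clock is trained on all others — with lambda
    re-selected by internal ``cv_folds``-fold CV inside the training fold
    (or held at ``fixed_lambda``) — and the held-out sample's age predicted.
    Internal fold seeds are keyed to the held-out sample id, so per-sample
    predictions are invariant to the row order of ``X``.

    Returns the per-sample prediction table with Pearson r, its Fisher-z 95%
    CI and the MAD.  If the predictions are (numerically) constant, r is
    reported as 0: a degenerate clock has no age association.
    """
    X, y = _as_xy(X, y)
    if X.shape[0] < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    preds = {}
    for sid in X.index:
        X_tr = X.drop(index=sid)
        y_tr = y.drop(index=sid)
        if float(np.std(y_tr)) == 0.0:
            raise ValueError(f"constant ages in the training fold for {sid}")
        if fixed_lambda is None:
            path = lambda_path_cv(
                X_tr, y_tr, alpha, cv_folds,
                seed=_derive_seed(seed, "loocv", sid), n_lambda=n_lambda,
            )
            lam = path.lambda_min
        else:
            lam = fixed_lambda
        model = fit_elastic_net(X_tr, y_tr, alpha, lam, age_unit=age_unit)
        preds[sid] = model.predict(X.loc[sid])
    table = pd.DataFrame({"age": y, "predicted": pd.Series(preds)})
    return evaluation_report(table, age_unit=age_unit)


def evaluation_report(
    predictions: pd.DataFrame, age_unit: str = "years", group: str | None = None
) -> EvaluationReport:
    """Assemble metrics from a per-sample (age, predicted) table."""
    age = predictions["age"].to_numpy(dtype=float)
    pred = predictions["predicted"].to_numpy(dtype=float)
    if np.std(pred) < 1e-12 or np.std(age) < 1e-12:
        r = 0.0
    else:
        r = float(stats.pearsonr(age, pred).statistic)
    lo, hi = pearson_ci(r, len(age))
    return EvaluationReport(
        predictions=predictions,
        pearson_r=r,
        r_ci_low=lo,
        r_ci_high=hi,
        mad=mad(pred, age),
        age_unit=age_unit,
        group=group,
    )


def train_clock(
    X: pd.DataFrame,
    y,
    alpha: float = 0.2,
    cv_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    age_unit: str = "years",
) -> ClockModel:
    """Fit the final clock on all samples at alpha, lambda = lambda_min
    from a full-data internal cross-validation."""
    path = lambda_path_cv(X, y, alpha, cv_folds, seed=seed, n_lambda=n_lambda)
    return fit_elastic_net(X, y, alpha, path.lambda_min, age_unit=age_unit)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def pearson_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation.

    z = atanh(r) with standard error 1/sqrt(n - 3); the interval is
    tanh(z -/+ z_crit / sqrt(n - 3)).  For |r| = 1 the interval degenerates
    to (r, r).
    """
    if n < 4:
        raise ValueError("Fisher-z interval requires n >= 4")
    if abs(r) >= 1.0:
        return (float(r), float(r))
    zcrit = float(stats.norm.ppf(0.5 + level / 2))
    z = np.arctanh(r)
    hw = zcrit / np.sqrt(n - 3)
    return (float(np.tanh(z - hw)), float(np.tanh(z + hw)))


def mad(predicted, chronological) -> float:
    """Median absolute deviation between predicted and chronological age.

    The plain median of |predicted - chronological| — no robust-dispersion
    consistency constant.
    """
    p = np.asarray(predicted, dtype=float)
    c = np.asarray(chronological, dtype=float)
    if p.shape != c.shape or p.ndim != 1 or p.size == 0:
        raise ValueError("predicted and chronological must be equal-length, nonempty")
    return float(np.median(np.abs(p - c)))


def predict_age(model: ClockModel, sample) -> float:
    """Predict one sample's age; every clock CpG must carry a ratio."""
    return model.predict(sample)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: ClockModel, path: str | Path) -> None:
    """Write a clock as TSV: '#'-prefixed metadata then one row per CpG."""
    with open(path, "w") as fh:
        fh.write(f"#{_MODEL_FORMAT}\n")
        fh.write(f"#alpha\t{float(model.alpha)!r}\n")
        fh.write(f"#lambda\t{float(model.lam)!r}\n")
        fh.write(f"#intercept\t{float(model.intercept)!r}\n")
        fh.write(f"#n_train\t{model.n_train}\n")
        fh.write(f"#age_unit\t{model.age_unit}\n")
        fh.write("site\tweight\ttrain_mean\ttrain_sd\n")
        for site in model.coef.index:
            fh.write(
                f"{site}\t{float(model.coef[site])!r}\t{float(model.mean[site])!r}"
                f"\t{float(model.sd[site])!r}\n"
            )


def load_model(path: str | Path) -> ClockModel:
    """Read a clock written by :func:`save_model`; load ∘ save = identity."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[str, float, float, float]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != f"#{_MODEL_FORMAT}":
        raise ValueError(f"{path}: not a methclock model file (or wrong version)")
    body_start = None
    for i, line in enumerate(lines[1:], start=1):
        if line.startswith("#"):
            key, _, val = line[1:].partition("\t")
            meta[key] = val
        else:
            body_start = i
            break
    required = {"alpha", "lambda", "intercept", "n_train", "age_unit"}
    if not required <= set(meta):
        raise ValueError(f"{path}: truncated model file, missing {required - set(meta)}")
    if body_start is None or lines[body_start] != "site\tweight\ttrain_mean\ttrain_sd":
        raise ValueError(f"{path}: missing coefficient table header")
    for lineno, line in enumerate(lines[body_start + 1:], start=body_start + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"{path}: line {lineno}: malformed coefficient row")
        try:
            rows.append((fields[0], float(fields[1]), float(fields[2]), float(fields[3])))
        except ValueError:
            raise ValueError(f"{path}: line {lineno}: non-numeric coefficient") from None
    idx = pd.Index([r[0] for r in rows], name="site")
    return ClockModel(
        intercept=float(meta["intercept"]),
        coef=pd.Series([r[1] for r in rows], index=idx, name="weight"),
        mean=pd.Series([r[2] for r in rows], index=idx, name="train_mean"),
        sd=pd.Series([r[3] for r in rows], index=idx, name="train_sd"),
        alpha=float(meta["alpha"]),
        lam=float(meta["lambda"]),
        n_train=int(meta["n_train"]),
        age_unit=meta["age_unit"],
    )


def plot_predictions(report: EvaluationReport, path: str | Path) -> None:
    """Scatter of predicted vs chronological age with identity and
    least-squares regression lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    age = report.predictions["age"].to_numpy(dtype=float)
    pred = report.predictions["predicted"].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(age, pred, s=18, alpha=0.7, edgecolor="none")
    lims = [min(age.min(), pred.min()), max(age.max(), pred.max())]
    ax.plot(lims, lims, ls=":", c="grey", label="identity")
    if np.std(age) > 0:
        b1, b0 = np.polyfit(age, pred, 1)
        xs = np.linspace(lims[0], lims[1], 50)
        ax.plot(xs, b0 + b1 * xs, c="tab:blue", label="regression")
    ax.set_xlabel(f"chronological age ({report.age_unit})")
    ax.set_ylabel(f"epigenetic age ({report.age_unit})")
    ax.set_title(report.summary(), fontsize=9)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
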