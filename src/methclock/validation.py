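"""Treatment effects on epigenetic age: mixed model, marginal means, letters.

An experimental validation of a clock asks whether a treatment (here brood-
size manipulation: control / enlarged / reduced) shifts the estimated
epigenetic age.  Nestlings sharing a brood are not independent, so the model
is a linear mixed model fitted by REML:

    epigenetic_age ~ treatment (fixed, reference-coded) + (1 | brood)

Estimated marginal means per treatment are the model-implied group means
(intercept + treatment effect under reference coding with a single fixed
factor); pairwise contrasts use unadjusted p-values (Fisher's least
significant difference convention) with a residual-degrees-of-freedom t
reference.  A compact letter display summarises which treatments are
mutually indistinguishable at the chosen alpha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TreatmentAnalysis", "fit_treatment_model", "compact_letters",
           "plot_group_means"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TreatmentAnalysis:
    """Mixed-model fit summary for a treatment validation.

    ``fixed_effects``: index = [Intercept, <level> ...] with estimate, se, t.
    ``emmeans``: per treatment level: emmean, se, ci_low, ci_high, letter.
    ``contrasts``: per pair: estimate, se, t, p (unadjusted).
    """

    fixed_effects: pd.DataFrame
    brood_variance: float
    residual_variance: float
    emmeans: pd.DataFrame
    contrasts: pd.DataFrame
    reference: str
    df_resid: float
    method: str  # "mixed" or "ols"


def fit_treatment_model(
    data: pd.DataFrame,
    response: str = "epi_age",
    treatment: str = "treatment",
    brood: str = "brood",
    reference: str = "control",
    alpha: float = 0.05,
) -> TreatmentAnalysis:
    """Fit the brood-random-intercept treatment model and post hoc contrasts.

    Parameters
    ----------
    data
        One row per individual with the response, treatment and brood
        columns.
    reference
        Treatment level coded as the intercept (defaults to "control").
    alpha
        Significance level of the compact letter display and emmean CIs.

    A single brood degrades the random intercept to nothing: the function
    warns and falls back to an ordinary linear model.  An empty treatment
    level raises.
    """
    import statsmodels.formula.api as smf

    df = data[[response, treatment, brood]].copy()
    if df.isna().any().any():
        raise ValueError("missing values in response/treatment/brood")
    levels = sorted(df[treatment].unique())
    if len(levels) < 2:
        raise ValueError("need at least two treatment levels")
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not present in data")
    counts = df[treatment].value_counts()
    if (counts < 1).any():  # pragma: no cover - value_counts omits empties
        raise ValueError("empty treatment level")
    ordered = [reference] + [l for l in levels if l != reference]
    df[treatment] = pd.Categorical(df[treatment], categories=ordered)
    n_broods = df[brood].nunique()
    formula = f"{response} ~ C({treatment})"

    if n_broods < 2:
        logger.warning(
            "only one brood present: falling back to an ordinary linear model"
        )
        fit = smf.ols(formula, data=df).fit()
        fe = _fixed_effects_frame(fit.params, fit.bse, fit.tvalues, ordered, treatment)
        cov = fit.cov_params().to_numpy()
        var_brood = 0.0
        var_resid = float(fit.mse_resid)
        df_resid = float(fit.df_resid)
        method = "ols"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data=df, groups=df[brood])
            fit = model.fit(reml=True)
        params = fit.fe_params
        fe = _fixed_effects_frame(
            params, fit.bse_fe, params / fit.bse_fe, ordered, treatment
        )
        cov = fit.cov_params().to_numpy()[: len(params), : len(params)]
        var_brood = float(fit.cov_re.iloc[0, 0])
        var_resid = float(fit.scale)
        # residual-df approximation: observations minus fixed-effect params
        df_resid = float(len(df) - len(params))
        method = "mixed"

    k = len(ordered)
    # design rows mapping fixed effects to level means (reference coding,
    # single fixed factor: mean_level = intercept + effect_level)
    L = np.zeros((k, k))
    L[:, 0] = 1.0
    for i in range(1, k):
        L[i, i] = 1.0
    est = fe["estimate"].to_numpy()
    means = L @ est
    se_means = np.sqrt(np.einsum("ij,jk,ik->i", L, cov, L))
    tcrit = float(stats.t.ppf(1 - alpha / 2, df_resid))
    emmeans = pd.DataFrame(
        {
            "treatment": ordered,
            "emmean": means,
            "se": se_means,
            "ci_low": means - tcrit * se_means,
            "ci_high": means + tcrit * se_means,
        }
    )

    rows = []
    for i, j in combinations(range(k), 2):
        ell = L[i] - L[j]
        diff = float(ell @ est)
        se = float(np.sqrt(ell @ cov @ ell))
        t = diff / se
        p = float(2 * stats.t.sf(abs(t), df_resid))
        rows.append(
            {"a": ordered[i], "b": ordered[j], "estimate": diff,
             "se": se, "t": t, "p": p}
        )
    contrasts = pd.DataFrame(rows)
    emmeans["letter"] = emmeans["treatment"].map(
        compact_letters(contrasts, ordered, alpha=alpha)
    )
    return TreatmentAnalysis(
        fixed_effects=fe,
        brood_variance=var_brood,
        residual_variance=var_resid,
        emmeans=emmeans,
        contrasts=contrasts,
        reference=reference,
        df_resid=df_resid,
        method=method,
    )


def _fixed_effects_frame(params, bse, tvals, ordered, treatment) -> pd.DataFrame:
    names = ["Intercept"] + ordered[1:]
    return pd.DataFrame(
        {
            "term": names,
            "estimate": np.asarray(params, dtype=float),
            "se": np.asarray(bse, dtype=float),
            "t": np.asarray(tvals, dtype=float),
        }
    )


def compact_letters(
    contrasts: pd.DataFrame,
    levels: list[str] | None = None,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb procedure.

    Treatments sharing a letter are not significantly different at ``alpha``.
    ``contrasts`` needs columns ``a``, ``b``, ``p`` covering every pair.
    """
    if levels is None:
        levels = sorted(set(contrasts["a"]) | set(contrasts["b"]))
    signif = {
        frozenset((row["a"], row["b"]))
        for _, row in contrasts.iterrows()
        if row["p"] < alpha
    }
    # start from one group holding everything; split on each significant pair
    groups: list[set[str]] = [set(levels)]
    for pair in sorted(signif, key=sorted):
        x, y = sorted(pair)
        new: list[set[str]] = []
        for g in groups:
            if x in g and y in g:
                new.append(g - {y})
                new.append(g - {x})
            else:
                new.append(g)
        # absorb: drop groups contained in another
        groups = [
            g for g in new
            if g and not any(g < h for h in new)
        ]
        # deduplicate while keeping order
        seen: list[set[str]] = []
        for g in groups:
            if g not in seen:
                seen.append(g)
        groups = seen
    # letters in order of each level's first appearance
    groups.sort(key=lambda g: min(levels.index(l) for l in g))
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    out = {l: "" for l in levels}
    for letter, g in zip(alphabet, groups):
        for l in levels:
            if l in g:
                out[l] += letter
    return out


def plot_group_means(analysis: TreatmentAnalysis, data: pd.DataFrame,
                     path, response: str = "epi_age",
                     treatment: str = "treatment") -> None:
    """Raw points with model-implied group means and standard errors."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = analysis.emmeans["treatment"].tolist()
    fig, ax = plt.subplots(figsize=(5, 4))
    rng = np.random.default_rng(0)
    for i, level in enumerate(order):
        vals = data.loc[data[treatment] == level, response].to_numpy()
        ax.scatter(
            np.full(vals.size, i) + rng.uniform(-0.12, 0.12, vals.size),
            vals, s=12, c="grey", alpha=0.6, edgecolor="none",
        )
    em = analysis.emmeans
    ax.errorbar(
        range(len(order)), em["emmean"], yerr=em["se"], fmt="o", c="tab:red",
        capsize=4, zorder=3,
    )
    for i, (_, row) in enumerate(em.iterrows()):
        ax.annotate(row["letter"], (i, row["emmean"]),
                    textcoords="offset points", xytext=(10, 10), color="tab:red")
    ax.set_xticks(range(len(order)), order)
    ax.set_ylabel("epigenetic age")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
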