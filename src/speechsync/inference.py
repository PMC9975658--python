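"""Trial-level inference: predictor assembly, binomial-logit mixed model,
likelihood-ratio tests, FDR control and collinearity diagnostics.

The model is a binomial GLMM with logit link: crossed random intercepts for
participant and item, optionally a by-participant random slope for syllabic
rate, and z-scored continuous fixed effects so each coefficient is the log
odds change per SD of its predictor (odds ratio = exp(coefficient)).

Random effects are integrated out with a Laplace approximation: for a given
set of variance parameters the joint penalized log-likelihood is maximized
over fixed effects and random effects by Newton iterations on the sparse
random-effects design, and the profiled Laplace objective

    l(theta) = loglik(beta_hat, u_hat) - u_hat' D^-1 u_hat / 2
               - log det(D)/2 - log det(Z' W Z + D^-1)/2

is optimized over the variance parameters.  Fixed-effect standard errors are
taken from the Schur complement of the joint Hessian at the mode, matching
conventional mixed-model reporting (Wald z tests).  This is the same
approximation lme4's glmer uses at nAGQ = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ModelFit",
    "build_predictor_table",
    "variance_inflation_factors",
    "fit_binomial_glmm",
    "likelihood_ratio_test",
    "fdr_adjust",
    "rate_accuracy_summary",
]


# ---------------------------------------------------------------------------
# predictor table


def zscore_columns(table: pd.DataFrame, columns) -> pd.DataFrame:
    """Return a copy with the named columns z-scored over all rows."""
    out = table.copy()
    for c in columns:
        x = out[c].to_numpy(float)
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError(f"cannot z-score constant column {c!r}")
        out[c] = (x - x.mean()) / sd
    return out


def variance_inflation_factors(table: pd.DataFrame, columns) -> dict:
    """VIF of each predictor against the others (1 / (1 - R_j^2))."""
    x = table[list(columns)].to_numpy(float)
    x = (x - x.mean(0)) / x.std(0, ddof=0)
    corr = (x.T @ x) / len(x)
    if np.linalg.matrix_rank(corr) < corr.shape[0]:
        raise ValueError(
            "perfect collinearity among predictors "
            f"{list(columns)} (singular correlation matrix)"
        )
    inv = np.linalg.inv(corr)
    return {c: float(inv[i, i]) for i, c in enumerate(columns)}


def build_predictor_table(
    trials: pd.DataFrame,
    participant_covariates: pd.DataFrame | None = None,
    item_covariates: pd.DataFrame | None = None,
    zscore: tuple[str, ...] = (),
    vif_bound: float = 10.0,
) -> pd.DataFrame:
    """Join trial, participant and item covariates into one modeling table.

    Continuous predictors named in ``zscore`` are standardized over the
    analyzed trials (after any upstream exclusions).  Join keys must be
    unique on the covariate side; missing keys and VIFs above ``vif_bound``
    raise with the offending rows/columns named.
    """
    df = trials.copy()
    for cov, key in ((participant_covariates, "participant"),
                     (item_covariates, "item")):
        if cov is None:
            continue
        if cov[key].duplicated().any():
            dups = cov.loc[cov[key].duplicated(), key].tolist()
            raise ValueError(f"duplicate {key} keys in covariates: {dups}")
        overlap = (set(df.columns) & set(cov.columns)) - {key}
        if overlap:
            raise ValueError(
                f"join collision on columns {sorted(overlap)}"
            )
        df = df.merge(cov, on=key, how="left", validate="many_to_one")
        missing = df[cov.columns].isna().any(axis=1)
        if missing.any():
            bad = df.loc[missing, key].unique().tolist()
            raise ValueError(f"no covariates for {key} values {bad}")
    if zscore:
        df = zscore_columns(df, zscore)
        vifs = variance_inflation_factors(df, zscore)
        too_big = {c: v for c, v in vifs.items() if v > vif_bound}
        if too_big:
            raise ValueError(
                f"variance inflation factors exceed {vif_bound}: {too_big}"
            )
        df.attrs["vif"] = vifs
    df.attrs["zscored"] = tuple(zscore)
    return df


# ---------------------------------------------------------------------------
# Laplace GLMM


@dataclass
class ModelFit:
    """Fitted binomial-logit (mixed) model."""

    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    n_params: int
    n_obs: int
    random_effect_sds: dict = field(default_factory=dict)
    converged: bool = True
    method: str = "laplace-glmm"

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.log_likelihood

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "estimate": self.coefficients,
            "se": self.standard_errors,
            "or": self.odds_ratios,
            "p": self.p_values,
        })


def _design_matrix(table: pd.DataFrame, fixed_effects) -> np.ndarray:
    cols = [np.ones(len(table))]
    for term in fixed_effects:
        if ":" in term:
            a, b = term.split(":")
            cols.append(table[a].to_numpy(float) * table[b].to_numpy(float))
        else:
            cols.append(table[term].to_numpy(float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effects design is rank deficient")
    return X


def _random_design(table, random_intercepts, random_slope):
    """Sparse random-effects design and block structure.

    Returns (Z, blocks) where blocks is a list of (name, n_levels).
    """
    n = len(table)
    mats, blocks = [], []
    for group in random_intercepts:
        codes, levels = pd.factorize(table[group])
        Z = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), codes)), shape=(n, len(levels)))
        mats.append(Z)
        blocks.append((f"{group}_intercept", len(levels)))
    if random_slope is not None:
        col, group = random_slope
        codes, levels = pd.factorize(table[group])
        Z = sparse.csr_matrix(
            (table[col].to_numpy(float), (np.arange(n), codes)),
            shape=(n, len(levels)))
        mats.append(Z)
        blocks.append((f"{col}|{group}", len(levels)))
    if not mats:
        return None, []
    return sparse.hstack(mats, format="csr"), blocks


def _bernoulli_loglik(y, eta):
    # numerically stable: -log(1 + exp(-(2y-1) eta)) summed
    s = (2.0 * y - 1.0) * eta
    return float(-np.logaddexp(0.0, -s).sum())


def _penalized_mode(X, Z, y, dinv, beta0, u0, max_iter=60, tol=1e-9):
    """Newton maximization of the joint penalized log-likelihood."""
    p = X.shape[1]
    q = Z.shape[1] if Z is not None else 0
    beta, u = beta0.copy(), u0.copy()

    def objective(beta, u):
        eta = X @ beta + (Z @ u if q else 0.0)
        return _bernoulli_loglik(y, eta) - 0.5 * float(u @ (dinv * u)), eta

    obj, eta = objective(beta, u)
    for _ in range(max_iter):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        r = y - mu
        gx = X.T @ r
        if q:
            gz = Z.T @ r - dinv * u
            Zw = Z.multiply(w[:, None])
            A11 = X.T @ (w[:, None] * X)
            A12 = (Zw.T @ X).T
            A22 = (Z.T @ Zw).toarray()
            A22[np.diag_indices_from(A22)] += dinv
            H = np.block([[A11, A12], [A12.T, A22]])
            g = np.concatenate([gx, gz])
        else:
            H = X.T @ (w[:, None] * X)
            g = gx
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, g, rcond=None)[0]
        step = 1.0
        for _ in range(30):
            nb = beta + step * delta[:p]
            nu = u + step * delta[p:] if q else u
            nobj, neta = objective(nb, nu)
            if nobj >= obj - 1e-12:
                break
            step *= 0.5
        improved = nobj - obj
        beta, u, obj, eta = nb, nu, nobj, neta
        if abs(improved) < tol * (abs(obj) + 1.0):
            break
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    return beta, u, obj, w


def _laplace_loglik(X, Z, y, blocks, log_sigmas, state):
    """Profiled Laplace log-likelihood at given log variance parameters."""
    sigmas = np.exp(np.clip(log_sigmas, -8.0, 3.0))
    dinv = np.concatenate([
        np.full(nlev, 1.0 / max(s**2, 1e-12))
        for (name, nlev), s in zip(blocks, sigmas)
    ])
    beta, u, pen_obj, w = _penalized_mode(
        X, Z, y, dinv, state["beta"], state["u"])
    state["beta"], state["u"] = beta, u
    Zw = Z.multiply(w[:, None])
    A22 = (Z.T @ Zw).toarray()
    A22[np.diag_indices_from(A22)] += dinv
    sign, logdet_h = np.linalg.slogdet(A22)
    if sign <= 0:
        return -np.inf, beta, u, w, dinv
    logdet_d = float(np.sum([
        2.0 * nlev * np.log(max(s, 1e-12))
        for (name, nlev), s in zip(blocks, sigmas)]))
    ll = pen_obj - 0.5 * logdet_d - 0.5 * logdet_h
    return ll, beta, u, w, dinv


def fit_binomial_glmm(
    table: pd.DataFrame,
    outcome: str = "correct",
    fixed_effects: tuple[str, ...] = (),
    random_intercepts: tuple[str, ...] = ("participant", "item"),
    random_slope: tuple[str, str] | None = None,
    fallback_to_intercepts: bool = True,
) -> ModelFit:
    """Fit a binomial-logit model, mixed if random effects are requested.

    Parameters
    ----------
    fixed_effects : column names; interactions written ``"a:b"``.
    random_intercepts : grouping columns with independent random intercepts
        (crossed), e.g. ``("participant", "item")``; empty for a plain GLM.
    random_slope : ``(covariate, group)`` for one random slope block,
        e.g. ``("syllabic_rate", "participant")``.
    fallback_to_intercepts : refit without the random slope if the full
        model fails, emitting a warning (the conventional response to GLMM
        non-convergence).
    """
    y = table[outcome].to_numpy(float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("outcome must be binary (or a proportion in [0,1])")
    X = _design_matrix(table, fixed_effects)
    terms = ["intercept", *fixed_effects]
    Z, blocks = _random_design(table, random_intercepts, random_slope)

    if Z is None:
        beta, u, obj, w = _penalized_mode(
            X, None, y, np.empty(0), np.zeros(X.shape[1]), np.empty(0))
        cov = np.linalg.inv(X.T @ (w[:, None] * X))
        se = np.sqrt(np.diag(cov))
        zstat = beta / se
        return ModelFit(
            terms=terms, coefficients=beta, standard_errors=se,
            p_values=2.0 * norm.sf(np.abs(zstat)),
            log_likelihood=obj, n_params=X.shape[1], n_obs=len(y),
            method="glm",
        )

    state = {"beta": np.zeros(X.shape[1]), "u": np.zeros(Z.shape[1])}

    def neg(log_sigmas):
        ll = _laplace_loglik(X, Z, y, blocks, log_sigmas, state)[0]
        return -ll if np.isfinite(ll) else 1e12

    x0 = np.full(len(blocks), np.log(0.5))
    res = minimize(neg, x0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400})
    if not res.success and random_slope is not None and fallback_to_intercepts:
        warnings.warn(
            "mixed model with random slope failed to converge; "
            "refitting with random intercepts only", stacklevel=2)
        return fit_binomial_glmm(
            table, outcome, fixed_effects, random_intercepts, None,
            fallback_to_intercepts=False)

    ll, beta, u, w, dinv = _laplace_loglik(X, Z, y, blocks, res.x, state)
    sigmas = np.exp(np.clip(res.x, -8.0, 3.0))

    # fixed-effect covariance: Schur complement of the joint Hessian
    Zw = Z.multiply(w[:, None])
    A11 = X.T @ (w[:, None] * X)
    A12 = (Zw.T @ X).T
    A22 = (Z.T @ Zw).toarray()
    A22[np.diag_indices_from(A22)] += dinv
    S = A11 - A12 @ np.linalg.solve(A22, A12.T)
    cov = np.linalg.inv(S)
    se = np.sqrt(np.diag(cov))
    zstat = beta / se

    return ModelFit(
        terms=terms, coefficients=beta, standard_errors=se,
        p_values=2.0 * norm.sf(np.abs(zstat)),
        log_likelihood=float(ll),
        n_params=X.shape[1] + len(blocks),
        n_obs=len(y),
        random_effect_sds={name: float(s)
                           for (name, _), s in zip(blocks, sigmas)},
        converged=bool(res.success),
    )


def likelihood_ratio_test(fit_reduced: ModelFit,
                          fit_full: ModelFit) -> tuple[float, int, float]:
    """Chi-square LRT between nested fits on the same data."""
    if fit_reduced.n_obs != fit_full.n_obs:
        raise ValueError("models were fitted on different data")
    df = fit_full.n_params - fit_reduced.n_params
    if df < 0:
        raise ValueError("fit_full must be the larger model")
    stat = max(0.0, 2.0 * (fit_full.log_likelihood
                           - fit_reduced.log_likelihood))
    if df == 0:
        return stat, 0, 1.0
    return stat, df, float(chi2_dist.sf(stat, df))


def fdr_adjust(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejected flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def rate_accuracy_summary(
    table: pd.DataFrame,
    rate_col: str = "syllabic_rate",
    outcome: str = "correct",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Accuracy per syllabic-rate condition with Wilson confidence bounds."""
    rows = []
    for rate, g in table.groupby(rate_col):
        k, n = int(g[outcome].sum()), len(g)
        lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
        rows.append((rate, n, k / n, lo, hi))
    return pd.DataFrame(
        rows, columns=[rate_col, "n", "accuracy", "ci_low", "ci_high"])
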