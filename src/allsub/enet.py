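"""Per-subgroup elastic-net regularization paths with cross-validation.

Two model families are supported: logistic regression for the binary
early-response outcome and Cox proportional hazards for relapse-free
survival.  Both minimize an elastic-net-penalized loss

    (1/n) sum_i loss_i(beta)  +  lambda * [ alpha ||beta||_1 + (1-alpha)/2 ||beta||^2 ]

over a descending geometric grid of penalty strengths lambda, with the mixing
parameter alpha fixed at 0.8 by default.  Ten-fold cross-validation produces a
deviance curve (binomial deviance, or Verweij-Van Houwelingen partial
likelihood deviance for Cox) whose minimum defines lambda_min and whose
one-standard-error point defines lambda_1se.  Model extraction follows two
policies: "1se_fallback_min" (the lambda_1se model, falling back to lambda_min
when the former has all coefficients zero) and "simplest_nondegenerate" (the
largest-lambda model with at least one nonzero coefficient).

Predictors are standardized to unit variance internally; coefficients are
reported on the original scale.  Logistic paths are solved by a warm-started
IRLS coordinate-descent kernel (the standard algorithm for this objective);
Cox paths are delegated to scikit-survival's Coxnet (Breslow ties).  Path
assembly, CV curves and extraction policies are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit
from scipy.special import expit, logsumexp
from sklearn.model_selection import StratifiedKFold

from .data_io import ExpressionMatrix

__all__ = [
    "RegularizationPath",
    "FittedModel",
    "fit_logistic_path",
    "fit_cox_path",
    "extract_model",
    "predict_logistic",
    "predict_risk",
]

_COEF_SNAP = 1e-10  # solver residue below this is treated as an exact zero
_PROB_EPS = 1e-10


@dataclass
class RegularizationPath:
    """An elastic-net path with its cross-validated deviance curve."""

    model_family: str  # "logistic" | "cox"
    alpha: float
    gene_ids: list[str]
    lambdas: np.ndarray  # strictly descending
    coefficients: np.ndarray  # genes x lambdas, original scale
    cv_mean: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    intercepts: np.ndarray | None = None  # logistic only

    def index_of(self, lam: float) -> int:
        return int(np.argmin(np.abs(self.lambdas - lam)))

    def n_nonzero(self) -> np.ndarray:
        return (np.abs(self.coefficients) > 0).sum(axis=0)


@dataclass
class FittedModel:
    """An extracted model: the nonzero coefficients at one point of the path."""

    model_family: str
    gene_ids: list[str]
    beta: np.ndarray
    lambda_used: float
    k: int
    intercept: float | None = None
    subgroup: int | None = None
    degenerate: bool = False


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd_safe
    Xs[:, sd == 0] = 0.0
    return Xs, mu, sd


def _lambda_grid(lambda_max: float, n_lambda: int, ratio: float) -> np.ndarray:
    return np.geomspace(lambda_max, lambda_max * ratio, n_lambda)


def _min_ratio(n: int, p: int) -> float:
    return 0.01 if n > p else 0.05


def _cv_summary(fold_dev: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cv_mean = fold_dev.mean(axis=0)
    cv_se = fold_dev.std(axis=0, ddof=1) / np.sqrt(fold_dev.shape[0])
    return cv_mean, cv_se


def _lambda_min_1se(lambdas, cv_mean, cv_se) -> tuple[float, float]:
    i_min = int(np.argmin(cv_mean))
    bound = cv_mean[i_min] + cv_se[i_min]
    # lambdas descend, so the first index within one SE is the largest such lambda
    i_1se = int(np.argmax(cv_mean <= bound))
    return float(lambdas[i_min]), float(lambdas[i_1se])


# ----------------------------------------------------------------- logistic

@njit(cache=True)
def _cd_logistic_path(Xs, y, lambdas, alpha, max_outer, max_inner, tol):  # pragma: no cover
    """Warm-started IRLS + coordinate-descent solver for the penalized
    binomial likelihood along a descending lambda grid (the glmnet scheme)."""
    n, p = Xs.shape
    L = lambdas.size
    coefs = np.zeros((p, L))
    intercepts = np.zeros(L)
    beta = np.zeros(p)
    b0 = np.log(y.mean() / (1.0 - y.mean()))
    xsq = np.empty(p)
    for l in range(L):
        lam = lambdas[l]
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        for _outer in range(max_outer):
            eta = b0 + Xs @ beta
            prob = np.empty(n)
            w = np.empty(n)
            z = np.empty(n)
            for i in range(n):
                e = eta[i]
                if e > 30.0:
                    e = 30.0
                elif e < -30.0:
                    e = -30.0
                pi = 1.0 / (1.0 + np.exp(-e))
                wi = pi * (1.0 - pi)
                if wi < 1e-5:
                    wi = 1e-5
                prob[i] = pi
                w[i] = wi
                z[i] = eta[i] + (y[i] - pi) / wi
            wsum = w.sum()
            for j in range(p):
                xsq[j] = 0.0
                for i in range(n):
                    xsq[j] += w[i] * Xs[i, j] * Xs[i, j]
            r = z - eta  # working residual z - b0 - X beta
            beta_prev = beta.copy()
            b0_prev = b0
            for _inner in range(max_inner):
                max_step = 0.0
                # intercept (unpenalized)
                num = 0.0
                for i in range(n):
                    num += w[i] * r[i]
                d0 = num / wsum
                if d0 != 0.0:
                    b0 += d0
                    for i in range(n):
                        r[i] -= d0
                    if abs(d0) > max_step:
                        max_step = abs(d0)
                for j in range(p):
                    u = beta[j] * xsq[j] / n
                    for i in range(n):
                        u += w[i] * Xs[i, j] * r[i] / n
                    if u > l1:
                        bj = (u - l1) / (xsq[j] / n + l2)
                    elif u < -l1:
                        bj = (u + l1) / (xsq[j] / n + l2)
                    else:
                        bj = 0.0
                    d = bj - beta[j]
                    if d != 0.0:
                        beta[j] = bj
                        for i in range(n):
                            r[i] -= d * Xs[i, j]
                        if abs(d) > max_step:
                            max_step = abs(d)
                if max_step < tol:
                    break
            shift = abs(b0 - b0_prev)
            for j in range(p):
                if abs(beta[j] - beta_prev[j]) > shift:
                    shift = abs(beta[j] - beta_prev[j])
            if shift < tol:
                break
        coefs[:, l] = beta
        intercepts[l] = b0
    return coefs, intercepts


def _logistic_path_coefs(
    Xs: np.ndarray, y: np.ndarray, lambdas: np.ndarray, alpha: float, seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Standardized-scale coefficients and intercepts along a descending grid."""
    coefs, intercepts = _cd_logistic_path(
        np.ascontiguousarray(Xs), np.ascontiguousarray(y, dtype=np.float64),
        np.ascontiguousarray(lambdas, dtype=np.float64), float(alpha),
        50, 200, 1e-7)
    coefs = coefs.copy()
    coefs[np.abs(coefs) < _COEF_SNAP] = 0.0
    return coefs, intercepts


def _binomial_deviance(y: np.ndarray, prob: np.ndarray) -> float:
    prob = np.clip(prob, _PROB_EPS, 1 - _PROB_EPS)
    return float(np.mean(-2 * (y * np.log(prob) + (1 - y) * np.log(1 - prob))))


def fit_logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    gene_ids: Sequence[str] | None = None,
    alpha: float = 0.8,
    n_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
    lambdas: Sequence[float] | None = None,
) -> RegularizationPath:
    """Elastic-net logistic path over a geometric lambda grid with stratified CV.

    ``X`` is samples x genes; ``y`` is 0/1.  lambda_max is the smallest penalty
    at which every gene coefficient is zero; the grid descends geometrically
    from there.  Fold assignment is stratified by outcome and seeded.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("y must contain both classes")
    if np.bincount(y.astype(int)).min() < 2:
        raise ValueError("need at least 2 samples per class")
    gene_ids = [str(g) for g in gene_ids] if gene_ids is not None else [f"g{i}" for i in range(p)]

    Xs, mu, sd = _standardize(X)
    if lambdas is None:
        ybar = y.mean()
        lambda_max = np.max(np.abs(Xs.T @ (y - ybar))) / (n * alpha)
        ratio = lambda_min_ratio if lambda_min_ratio is not None else _min_ratio(n, p)
        grid = _lambda_grid(lambda_max, n_lambda, ratio)
    else:
        grid = np.asarray(sorted(lambdas, reverse=True), float)

    coefs_s, icept_s = _logistic_path_coefs(Xs, y, grid, alpha, seed)
    sd_safe = np.where(sd > 0, sd, 1.0)
    coefs = coefs_s / sd_safe[:, None]
    intercepts = icept_s - (coefs_s * (mu / sd_safe)[:, None]).sum(axis=0)

    n_folds_eff = min(n_folds, int(np.bincount(y.astype(int)).min()))
    skf = StratifiedKFold(n_splits=n_folds_eff, shuffle=True, random_state=seed)
    fold_dev = np.empty((n_folds_eff, grid.size))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        Xs_tr, mu_tr, sd_tr = _standardize(X[tr])
        cs, bs = _logistic_path_coefs(Xs_tr, y[tr], grid, alpha, seed)
        sd_tr_safe = np.where(sd_tr > 0, sd_tr, 1.0)
        beta = cs / sd_tr_safe[:, None]
        b0 = bs - (cs * (mu_tr / sd_tr_safe)[:, None]).sum(axis=0)
        prob = expit(X[te] @ beta + b0)
        fold_dev[f] = [_binomial_deviance(y[te], prob[:, k]) for k in range(grid.size)]
    cv_mean, cv_se = _cv_summary(fold_dev)
    lam_min, lam_1se = _lambda_min_1se(grid, cv_mean, cv_se)
    return RegularizationPath(
        model_family="logistic", alpha=alpha, gene_ids=gene_ids, lambdas=grid,
        coefficients=coefs, cv_mean=cv_mean, cv_se=cv_se,
        lambda_min=lam_min, lambda_1se=lam_1se, intercepts=intercepts,
    )


# ---------------------------------------------------------------------- cox

def breslow_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow log partial likelihood of linear predictors ``lp``."""
    ll = 0.0
    for t in np.unique(time[event == 1]):
        d = (time == t) & (event == 1)
        ll += lp[d].sum() - d.sum() * logsumexp(lp[time >= t])
    return float(ll)


def _coxnet_coefs(Xs, time, event, grid, alpha):
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    y = Surv.from_arrays(event=event.astype(bool), time=time)
    model = CoxnetSurvivalAnalysis(
        l1_ratio=alpha, alphas=grid, tol=1e-7, max_iter=100000, normalize=False)
    model.fit(Xs, y)
    fitted = np.asarray(model.alphas_)
    coefs = np.zeros((Xs.shape[1], len(grid)))
    # coxnet can truncate the path; map fitted alphas back onto the requested grid
    for k, lam in enumerate(grid):
        j = int(np.argmin(np.abs(fitted - lam)))
        if np.isclose(fitted[j], lam, rtol=1e-6, atol=0):
            coefs[:, k] = model.coef_[:, j]
        elif lam > fitted.max():
            coefs[:, k] = 0.0
        else:
            coefs[:, k] = model.coef_[:, j]
    coefs[np.abs(coefs) < _COEF_SNAP] = 0.0
    return coefs


def fit_cox_path(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    gene_ids: Sequence[str] | None = None,
    alpha: float = 0.8,
    n_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
    lambdas: Sequence[float] | None = None,
) -> RegularizationPath:
    """Elastic-net Cox path (Breslow ties) with event-stratified CV.

    The CV criterion is the Verweij-Van Houwelingen partial likelihood
    deviance: -2 [ pl_full(beta_fold) - pl_trainfold(beta_fold) ].
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    X = np.asarray(X, float)
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    n, p = X.shape
    if event.sum() < 2:
        raise ValueError("need at least 2 events for a Cox fit")
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    gene_ids = [str(g) for g in gene_ids] if gene_ids is not None else [f"g{i}" for i in range(p)]

    Xs, mu, sd = _standardize(X)
    sd_safe = np.where(sd > 0, sd, 1.0)
    if lambdas is None:
        ratio = lambda_min_ratio if lambda_min_ratio is not None else _min_ratio(n, p)
        probe = CoxnetSurvivalAnalysis(
            l1_ratio=alpha, n_alphas=n_lambda, alpha_min_ratio=ratio, tol=1e-7)
        probe.fit(Xs, Surv.from_arrays(event=event.astype(bool), time=time))
        grid = np.asarray(probe.alphas_, float)
    else:
        grid = np.asarray(sorted(lambdas, reverse=True), float)

    coefs_s = _coxnet_coefs(Xs, time, event, grid, alpha)
    coefs = coefs_s / sd_safe[:, None]

    n_folds_eff = min(n_folds, int(min(event.sum(), n - event.sum()))) or min(n_folds, n)
    n_folds_eff = max(2, min(n_folds, n_folds_eff))
    skf = StratifiedKFold(n_splits=n_folds_eff, shuffle=True, random_state=seed)
    lp_full_center = X - X.mean(axis=0)  # centering stabilizes exp() in the likelihood
    fold_dev = np.empty((n_folds_eff, grid.size))
    for f, (tr, te) in enumerate(skf.split(X, event.astype(int))):
        Xs_tr, mu_tr, sd_tr = _standardize(X[tr])
        sd_tr_safe = np.where(sd_tr > 0, sd_tr, 1.0)
        cs = _coxnet_coefs(Xs_tr, time[tr], event[tr], grid, alpha)
        beta = cs / sd_tr_safe[:, None]
        for k in range(grid.size):
            lp_all = lp_full_center @ beta[:, k]
            pl_all = breslow_loglik(lp_all, time, event)
            pl_tr = breslow_loglik(lp_all[tr], time[tr], event[tr])
            fold_dev[f, k] = -2.0 * (pl_all - pl_tr)
    cv_mean, cv_se = _cv_summary(fold_dev)
    lam_min, lam_1se = _lambda_min_1se(grid, cv_mean, cv_se)
    return RegularizationPath(
        model_family="cox", alpha=alpha, gene_ids=gene_ids, lambdas=grid,
        coefficients=coefs, cv_mean=cv_mean, cv_se=cv_se,
        lambda_min=lam_min, lambda_1se=lam_1se, intercepts=None,
    )


# ----------------------------------------------------------------- policies

def _model_at(path: RegularizationPath, idx: int, subgroup: int | None) -> FittedModel:
    beta = path.coefficients[:, idx]
    nz = np.abs(beta) > 0
    return FittedModel(
        model_family=path.model_family,
        gene_ids=[g for g, keep in zip(path.gene_ids, nz) if keep],
        beta=beta[nz].copy(),
        lambda_used=float(path.lambdas[idx]),
        k=int(nz.sum()),
        intercept=float(path.intercepts[idx]) if path.intercepts is not None else None,
        subgroup=subgroup,
        degenerate=not nz.any(),
    )


def extract_model(
    path: RegularizationPath, policy: str = "1se_fallback_min", subgroup: int | None = None,
) -> FittedModel:
    """Extract one model from a path.

    ``1se_fallback_min``: the lambda_1se model, unless it has all coefficients
    zero, in which case the lambda_min model.  ``simplest_nondegenerate``: the
    model at the largest lambda with at least one nonzero coefficient.  If no
    candidate has a nonzero coefficient the returned model carries
    ``degenerate=True`` instead of raising.
    """
    nnz = path.n_nonzero()
    if policy == "1se_fallback_min":
        idx = path.index_of(path.lambda_1se)
        if nnz[idx] == 0:
            idx = path.index_of(path.lambda_min)
        return _model_at(path, idx, subgroup)
    if policy == "simplest_nondegenerate":
        nonzero_idx = np.where(nnz > 0)[0]
        idx = int(nonzero_idx[0]) if nonzero_idx.size else len(path.lambdas) - 1
        return _model_at(path, idx, subgroup)
    raise ValueError(f"unknown extraction policy {policy!r}")


# --------------------------------------------------------------- prediction

def _model_matrix(model: FittedModel, expr: ExpressionMatrix) -> np.ndarray:
    index = {g: i for i, g in enumerate(expr.gene_ids)}
    missing = [g for g in model.gene_ids if g not in index]
    if missing:
        raise ValueError(f"model gene(s) missing from expression matrix: {missing[:5]}")
    rows = [index[g] for g in model.gene_ids]
    return expr.values[rows, :].T  # samples x model genes


def predict_logistic(model: FittedModel, expr: ExpressionMatrix) -> np.ndarray:
    """Per-sample probability of the positive (bad-response / MRD-positive) class."""
    if model.model_family != "logistic":
        raise ValueError("model is not a logistic model")
    X = _model_matrix(model, expr)
    intercept = model.intercept if model.intercept is not None else 0.0
    return expit(intercept + X @ model.beta)


def predict_risk(model: FittedModel, expr: ExpressionMatrix) -> np.ndarray:
    """Per-sample relative risk score (Cox linear predictor, log-hazard scale)."""
    if model.model_family != "cox":
        raise ValueError("model is not a Cox model")
    X = _model_matrix(model, expr)
    return X @ model.beta
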