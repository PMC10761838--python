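"""Supervised-component generalized linear regression (SCGLR) of
multivariate species counts on climate covariates.

Components ``f_h = X u_h`` are built on the standardized covariate matrix by
maximizing, under ``||u|| = 1`` and orthogonality of the components, the
compromise criterion

    crit(u) = s * log(phi(u)) + (1 - s) * log(psi(u))

where ``phi`` is the variable-powered inertia of ``X u`` in the covariates
(power ``l``; at ``l = 1`` the mean squared correlation with the covariate
columns) and ``psi`` is the summed per-species Poisson log-likelihood gain of
adding ``X u`` to the previous components and extra covariates.  The
maximizer runs a projected gradient ascent on the unit sphere with
backtracking, so the criterion is non-decreasing over iterations; with
``s = 1`` and ``l = 1`` the first component reduces to the first principal
component of standardized X.

Spatial-block cross-validation clusters cell coordinates with Ward linkage,
holds out one block at a time, pools held-out predictions and reports the
per-species Spearman correlation between observed and predicted counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import gammaln
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

_ETA_CLIP = 30.0
_PSI_EPS = 1e-12


def poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, None)
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def poisson_irls(
    design: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit a Poisson log-link GLM by iteratively reweighted least squares.

    Returns (coefficients, fitted means, log-likelihood).
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(y, 0.0) + 0.5
    eta = np.log(mu)
    beta = np.zeros(design.shape[1])
    ll_old = -np.inf
    for _ in range(max_iter):
        z = eta + (y - mu) / mu
        wd = design * mu[:, None]
        try:
            beta = np.linalg.solve(design.T @ wd, wd.T @ z)
        except np.linalg.LinAlgError:
            w = np.sqrt(mu)
            beta, *_ = np.linalg.lstsq(design * w[:, None], z * w, rcond=None)
        eta = np.clip(design @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        ll = poisson_loglik(y, mu)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            break
        ll_old = ll
    return beta, mu, ll


@dataclass
class SCGLRModel:
    """Fitted supervised-component Poisson regression."""

    x_names: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    extra_names: list[str]
    loadings: np.ndarray  # (p, K), unit-norm columns
    coefs: pd.DataFrame  # species x (intercept, extras..., comp_1..comp_K)
    species: list[str]
    s: float
    l: float
    K: int
    crit_history: list[list[float]] = field(default_factory=list, repr=False)
    converged: list[bool] = field(default_factory=list)
    _x_train_std: np.ndarray | None = field(default=None, repr=False)

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.x_mean) / self.x_sd

    def components(self, x: np.ndarray) -> np.ndarray:
        return self.standardize(x) @ self.loadings

    def design(self, x: np.ndarray, extra: np.ndarray | None) -> np.ndarray:
        n = x.shape[0]
        cols = [np.ones((n, 1))]
        if self.extra_names:
            if extra is None or extra.shape[1] != len(self.extra_names):
                raise ValueError("extra-covariate schema does not match training")
            cols.append(np.asarray(extra, dtype=float))
        elif extra is not None and extra.size:
            raise ValueError("model was fitted without extra covariates")
        cols.append(self.components(x))
        return np.hstack(cols)


def _phi_and_grad(u: np.ndarray, corr: np.ndarray, l: float) -> tuple[float, np.ndarray]:
    """Variable-powered inertia and its gradient.

    ``corr`` is the covariate correlation matrix C = X'X/n of standardized X;
    ``a_j = (c_j'u)^2 / (u'Cu)`` is the squared correlation of Xu with
    covariate j and ``phi = (mean_j a_j^l)^(1/l)``.
    """
    cu = corr @ u
    q = float(u @ cu)
    a = cu**2 / q
    al = a ** (l - 1.0) if l != 1.0 else np.ones_like(a)
    phi = float(np.mean(a**l) ** (1.0 / l))
    # grad log phi = sum_j a_j^{l-1} grad a_j / sum_j a_j^l
    grad_a = 2.0 * (corr * cu[:, None] / q - np.outer(cu**2, cu) / q**2)  # (p grads stacked rows)
    grad_logphi = (al @ grad_a) / float(np.sum(a**l))
    return phi, grad_logphi


def fit_scglr(
    X: np.ndarray | pd.DataFrame,
    Y: np.ndarray | pd.DataFrame,
    extra: np.ndarray | pd.DataFrame | None = None,
    K: int = 3,
    s: float = 0.5,
    l: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int | None = 0,
) -> SCGLRModel:
    """Fit the supervised-component Poisson model.

    Parameters follow the criterion described in the module docstring:
    ``s`` trades covariate structure against multivariate GLM fit, ``l`` is
    the structural-relevance power, ``K`` the number of components.  Extra
    covariates (e.g. elevation, soil) enter every per-species GLM directly
    without participating in component construction.
    """
    x_names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.shape(X)[1])]
    species = list(Y.columns) if isinstance(Y, pd.DataFrame) else [f"sp{i}" for i in range(np.shape(Y)[1])]
    extra_names = (
        list(extra.columns) if isinstance(extra, pd.DataFrame) else
        ([] if extra is None else [f"e{i}" for i in range(np.shape(extra)[1])])
    )
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if np.any(Y < 0) or not np.allclose(Y, np.round(Y)):
        raise ValueError("Y must contain non-negative integer counts")
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("missing values are not supported")
    E = None if extra is None else np.asarray(extra, dtype=float)

    n, p = X.shape
    if not 0.0 <= s <= 1.0:
        raise ValueError("s must be in [0, 1]")
    if l < 1.0:
        raise ValueError("l must be >= 1")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if K > rank:
        raise ValueError(f"K={K} exceeds rank(X)={rank}")

    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0)
    x_sd[x_sd == 0] = 1.0
    Xs = (X - x_mean) / x_sd
    corr = Xs.T @ Xs / n

    base_cols = [np.ones((n, 1))]
    if E is not None and E.size:
        base_cols.append(E)
    Z_base = np.hstack(base_cols)

    rng = np.random.default_rng(seed)
    _, _, vt = np.linalg.svd(Xs, full_matrices=False)

    U = np.zeros((p, 0))
    crit_history: list[list[float]] = []
    converged: list[bool] = []

    for h in range(K):
        Z_prev = np.hstack([Z_base, Xs @ U]) if U.shape[1] else Z_base
        ll0 = np.array([poisson_irls(Z_prev, Y[:, k])[2] for k in range(Y.shape[1])])

        # constraint directions: u' C u_g = 0 keeps components orthogonal
        D = corr @ U if U.shape[1] else np.zeros((p, 0))
        Q, _ = np.linalg.qr(D) if D.shape[1] else (np.zeros((p, 0)), None)

        def project(v: np.ndarray) -> np.ndarray:
            return v - Q @ (Q.T @ v) if Q.shape[1] else v

        def evaluate(u: np.ndarray):
            f = Xs @ u
            Zf = np.hstack([Z_prev, f[:, None]])
            gammas = np.empty(Y.shape[1])
            resid = np.empty_like(Y)
            gain = 0.0
            for k in range(Y.shape[1]):
                beta, mu, ll = poisson_irls(Zf, Y[:, k])
                gammas[k] = beta[-1]
                resid[:, k] = Y[:, k] - mu
                gain += max(ll - ll0[k], 0.0)
            phi, grad_logphi = _phi_and_grad(u, corr, l)
            crit = s * np.log(phi) + (1.0 - s) * np.log(gain + _PSI_EPS)
            grad_psi = Xs.T @ (resid @ gammas)
            grad = s * grad_logphi + (1.0 - s) * grad_psi / (gain + _PSI_EPS)
            return crit, grad

        u = project(vt[0])
        if np.linalg.norm(u) < 1e-10:
            u = project(rng.standard_normal(p))
        u /= np.linalg.norm(u)

        history = []
        comp_converged = False
        val, grad = evaluate(u)
        history.append(val)
        step = 1.0
        for _ in range(max_iter):
            g = project(grad)
            g -= (g @ u) * u  # tangent to the unit sphere
            gn = np.linalg.norm(g)
            if gn < 1e-12:
                comp_converged = True
                break
            g /= gn
            improved = False
            trial_step = step * 2.0
            for _bt in range(50):
                u_try = project(u + trial_step * g)
                nrm = np.linalg.norm(u_try)
                if nrm > 1e-12:
                    u_try /= nrm
                    val_try, grad_try = evaluate(u_try)
                    if val_try >= val:
                        improved = True
                        break
                trial_step *= 0.5
            if not improved:
                comp_converged = True
                break
            delta = np.linalg.norm(u_try - np.sign(u_try @ u + 1e-300) * u)
            gain_val = val_try - val
            step = trial_step
            u, val, grad = u_try, val_try, grad_try
            history.append(val)
            if delta < tol or gain_val < 1e-9 * (abs(val) + 1.0):
                comp_converged = True
                break
        if not comp_converged:
            logger.warning("component %d did not converge in %d iterations", h + 1, max_iter)
        crit_history.append(history)
        converged.append(comp_converged)
        U = np.hstack([U, u[:, None]])

    # final per-species GLMs on the fitted components
    F = Xs @ U
    Z = np.hstack([Z_base, F])
    coef_rows = []
    for k in range(Y.shape[1]):
        beta, _, _ = poisson_irls(Z, Y[:, k])
        coef_rows.append(beta)
    coef_cols = ["intercept"] + extra_names + [f"comp_{h + 1}" for h in range(K)]
    coefs = pd.DataFrame(coef_rows, index=species, columns=coef_cols)

    return SCGLRModel(
        x_names=x_names,
        x_mean=x_mean,
        x_sd=x_sd,
        extra_names=extra_names,
        loadings=U,
        coefs=coefs,
        species=species,
        s=s,
        l=l,
        K=K,
        crit_history=crit_history,
        converged=converged,
        _x_train_std=Xs,
    )


def predict_abundance(
    model: SCGLRModel,
    X_new: np.ndarray | pd.DataFrame,
    extra_new: np.ndarray | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Expected counts ``exp(linear predictor)`` per cell and species, using
    the training standardization."""
    Xn = np.asarray(X_new, dtype=float)
    if Xn.shape[1] != len(model.x_names):
        raise ValueError("covariate schema does not match training")
    En = None if extra_new is None else np.asarray(extra_new, dtype=float)
    Z = model.design(Xn, En)
    eta = np.clip(Z @ model.coefs.to_numpy().T, -_ETA_CLIP, _ETA_CLIP)
    return pd.DataFrame(np.exp(eta), columns=model.species)


@dataclass
class ComponentInertia:
    share: np.ndarray  # percent per component
    cumulative: np.ndarray


def component_inertia(model: SCGLRModel) -> ComponentInertia:
    """Share of standardized-covariate inertia captured by each component.

    The components are mutually orthogonal vectors in sample space, so the
    share of component h is its own projection ``sum_j (f_h'x_j)^2 /
    ||f_h||^2`` over the total inertia ``||X||_F^2``; with K = rank(X) the
    cumulative share is 100%.
    """
    Xs = model._x_train_std
    if Xs is None:
        raise ValueError("model does not retain training data")
    F = Xs @ model.loadings
    total = float(np.sum(Xs**2))
    share = np.array(
        [float(np.sum((F[:, h] @ Xs) ** 2)) / float(F[:, h] @ F[:, h]) / total * 100.0
         for h in range(model.K)]
    )
    return ComponentInertia(share=share, cumulative=np.cumsum(share))


def make_spatial_blocks(coords: np.ndarray | pd.DataFrame, n_blocks: int = 23) -> np.ndarray:
    """Ward hierarchical clustering of cell coordinates cut at ``n_blocks``.

    Returns integer labels in ``1..n_blocks``; deterministic.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n_blocks > n:
        raise ValueError("n_blocks exceeds the number of cells")
    if n_blocks == n:
        return np.arange(1, n + 1)
    link = linkage(coords, method="ward")
    return fcluster(link, t=n_blocks, criterion="maxclust")


def pooled_spearman(observed: pd.DataFrame, predicted: pd.DataFrame) -> pd.Series:
    """Per-species Spearman correlation between observed and predicted
    values pooled over all cells; NaN where either side is constant."""
    obs = observed.to_numpy(dtype=float)
    pred = predicted.to_numpy(dtype=float)
    rhos = {}
    for j, sp_name in enumerate(observed.columns):
        o, p = obs[:, j], pred[:, j]
        if np.std(o) == 0 or np.std(p) == 0:
            rhos[sp_name] = np.nan
        else:
            rhos[sp_name] = float(spearmanr(o, p).statistic)
    return pd.Series(rhos)


@dataclass
class CVResult:
    blocks: np.ndarray
    species_rho: pd.Series  # per-species pooled out-of-block Spearman rho
    median_rho: float
    predictions: pd.DataFrame = field(repr=False, default=None)
    observed: pd.DataFrame = field(repr=False, default=None)


def cross_validate(
    X: np.ndarray | pd.DataFrame,
    Y: pd.DataFrame,
    extra: np.ndarray | pd.DataFrame | None,
    blocks: np.ndarray,
    K: int = 3,
    s: float = 0.5,
    l: float = 1.0,
    seed: int = 0,
    **fit_kwargs,
) -> CVResult:
    """Leave-one-block-out cross-validation.

    For each block the model is refitted on the remaining cells and the
    held-out cells predicted; held-out predictions are pooled across folds
    before computing one Spearman correlation per species.  Species with
    constant observed or predicted values give an undefined (NaN) rho.
    """
    Xa = np.asarray(X, dtype=float)
    Ya = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(np.asarray(Y))
    Ea = None if extra is None else np.asarray(extra, dtype=float)
    blocks = np.asarray(blocks)
    uniq = np.unique(blocks)
    if len(uniq) < 2:
        raise ValueError("need at least 2 blocks")

    pred = np.full(Ya.shape, np.nan)
    for b in uniq:
        test = blocks == b
        train = ~test
        model = fit_scglr(
            Xa[train], Ya.iloc[train], None if Ea is None else Ea[train],
            K=K, s=s, l=l, seed=seed, **fit_kwargs,
        )
        pred[test] = predict_abundance(
            model, Xa[test], None if Ea is None else Ea[test]
        ).to_numpy()

    rho = pooled_spearman(Ya, pd.DataFrame(pred, index=Ya.index, columns=Ya.columns))
    return CVResult(
        blocks=blocks,
        species_rho=rho,
        median_rho=float(rho.dropna().median()),
        predictions=pd.DataFrame(pred, index=Ya.index, columns=Ya.columns),
        observed=Ya,
    )


def simulate_abundance_dataset(
    n_cells: int = 500,
    n_covariates: int = 8,
    n_species: int = 20,
    n_noise_covariates: int = 2,
    seed: int = 0,
) -> dict:
    """Reference simulation: spatially smooth covariates, one planted
    gradient, Poisson species counts.

    Returns a dict with coords, X, Y (DataFrame), the true loading vector
    (zero on the trailing noise covariates) and the true gradient values.
    Used by the parameter-recovery and cross-validation benchmarks.
    """
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, 100.0, size=(n_cells, 2))
    n_struct = n_covariates - n_noise_covariates
    fields = [
        coords[:, 0],
        coords[:, 1],
        np.sin(coords[:, 0] / 15.0),
        np.cos(coords[:, 1] / 20.0),
        coords[:, 0] * coords[:, 1] / 100.0,
        np.sin((coords[:, 0] + coords[:, 1]) / 25.0),
    ]
    while len(fields) < n_struct:
        w = rng.uniform(8.0, 30.0, 2)
        fields.append(np.sin(coords[:, 0] / w[0]) * np.cos(coords[:, 1] / w[1]))
    X = np.column_stack(fields[:n_struct] + [rng.normal(size=n_cells) for _ in range(n_noise_covariates)])
    X += rng.normal(0.0, 0.05, size=X.shape)  # measurement noise
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)

    u = np.zeros(n_covariates)
    u[:n_struct] = rng.normal(size=n_struct)
    u /= np.linalg.norm(u)
    gradient = Xs @ u

    slopes = rng.choice([-1.0, 1.0], n_species) * rng.uniform(0.5, 1.0, n_species)
    intercepts = rng.uniform(0.5, 1.5, n_species)
    mu = np.exp(intercepts + np.outer(gradient, slopes))
    Y = pd.DataFrame(rng.poisson(mu), columns=[f"sp{k + 1}" for k in range(n_species)])
    return {"coords": coords, "X": X, "Y": Y, "u_true": u, "gradient": gradient,
            "slopes": slopes}


def select_k_by_cv(
    X, Y, extra, blocks, k_grid=range(1, 7), s: float = 0.5, l: float = 1.0, seed: int = 0
) -> tuple[int, dict[int, float]]:
    """Choose K maximizing the cross-validated median Spearman rho."""
    scores = {}
    for k in k_grid:
        try:
            scores[k] = cross_validate(X, Y, extra, blocks, K=k, s=s, l=l, seed=seed).median_rho
        except ValueError:
            continue
    best = max(scores, key=scores.get)
    return best, scores
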