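"""Batch-screening iterative lasso over wide genotype matrices.

Fits an L1-penalized GLM (gaussian or binomial) with unpenalized covariates
and per-variant penalty factors. Candidate variants enter the active set in
gradient-ranked batches; every reported solution is certified by a
Karush-Kuhn-Tucker check against the full variant set. Sparsity is selected
on a validation set and the chosen model is refit on the combined
score-development samples.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .io import GenotypeMatrix

logger = logging.getLogger(__name__)

try:  # optional compiled inner loop; pure-numpy fallback below
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to converge within the iteration budget."""


class DegeneratePathError(ValueError):
    """All screening gradients are zero; no lasso path exists."""


@dataclasses.dataclass
class FitConfig:
    family: str = "gaussian"
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    batch_size: int = 1000
    cd_tolerance: float = 1e-7
    max_cd_iter: int = 10_000
    early_stop_patience: int = 10
    kkt_tolerance: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclasses.dataclass
class LassoPath:
    """λ sequence with sparse coefficient vectors and validation metrics."""

    lambdas: np.ndarray
    variant_coefs: list[dict[int, float]]  # variant index -> standardized beta
    covariate_coefs: list[np.ndarray]  # intercept first
    active_counts: np.ndarray
    validation_metric: np.ndarray
    metric_name: str
    covariate_names: list[str]


@dataclasses.dataclass
class PRSModel:
    """Selected sparse model with per-effect-allele dosage-scale weights."""

    variant_ids: list[str]
    effect_allele: list[str]
    weights: np.ndarray
    train_freq: np.ndarray
    covariate_names: list[str]
    covariate_coefs: np.ndarray
    intercept: float
    lam: float
    family: str


# ---------------------------------------------------------------------------
# coordinate descent core

def _soft_threshold(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def _cd_cycles_py(X, wn, r, beta, sj, lw, max_iter, tol):
    p = X.shape[1]
    for it in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            xj = X[:, j]
            zj = np.dot(xj * wn, r) + sj[j] * beta[j]
            bj = _soft_threshold(zj, lw[j]) / sj[j]
            delta = bj - beta[j]
            if delta != 0.0:
                r -= delta * xj
                beta[j] = bj
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        if max_delta < tol:
            return it + 1
    return -1


if _HAVE_NUMBA:

    @njit(cache=True)
    def _cd_cycles_nb(X, wn, r, beta, sj, lw, max_iter, tol):  # pragma: no cover
        n, p = X.shape
        for it in range(max_iter):
            max_delta = 0.0
            for j in range(p):
                zj = sj[j] * beta[j]
                for i in range(n):
                    zj += X[i, j] * wn[i] * r[i]
                if zj > lw[j]:
                    bj = (zj - lw[j]) / sj[j]
                elif zj < -lw[j]:
                    bj = (zj + lw[j]) / sj[j]
                else:
                    bj = 0.0
                delta = bj - beta[j]
                if delta != 0.0:
                    for i in range(n):
                        r[i] -= delta * X[i, j]
                    beta[j] = bj
                    if abs(delta) > max_delta:
                        max_delta = abs(delta)
            if max_delta < tol:
                return it + 1
        return -1

    _cd_cycles = _cd_cycles_nb
else:  # pragma: no cover
    _cd_cycles = _cd_cycles_py


def cd_lasso(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    penalty_factors: np.ndarray,
    n_covariates: int,
    family: str = "gaussian",
    warm_start: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Coordinate-descent solution of the penalty-factor-weighted lasso.

    ``X`` holds the ``n_covariates`` unpenalized columns (intercept included)
    first, then penalized columns (standardized). Minimizes
    ``(1/2n)·loss + lam · Σ_j w_j |β_j]`` where the loss is the squared error
    (gaussian) or, for binomial, the IRLS-relinearized logistic deviance.
    """
    X = np.asarray(X, dtype=np.float64)
    if not X.flags.f_contiguous:
        X = np.asfortranarray(X)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    w = np.concatenate([np.zeros(n_covariates), np.asarray(penalty_factors, float)])
    if w.size != p:
        raise ValueError("penalty factor length mismatch")
    beta = np.zeros(p) if warm_start is None else np.asarray(warm_start, float).copy()

    if family == "gaussian":
        wn = np.full(n, 1.0 / n)
        sj = np.einsum("ij,ij->j", X, X) / n
        sj[sj == 0] = 1.0
        r = y - X @ beta
        status = _cd_cycles(X, wn, r, beta, sj, lam * w, max_iter, tol)
        if status < 0:
            raise ConvergenceError(f"gaussian CD did not converge at lambda={lam:g}")
        return beta

    if family != "binomial":
        raise ValueError(f"unknown family {family!r}")

    def penalized_obj(b):
        eta = np.clip(X @ b, -30, 30)
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        return -ll / n + lam * np.sum(w * np.abs(b))

    obj = penalized_obj(beta)
    for _outer in range(100):
        eta = np.clip(X @ beta, -30, 30)
        mu = expit(eta)
        irls_w = np.clip(mu * (1 - mu), 1e-5, None)
        z = eta + (y - mu) / irls_w
        wn = irls_w / n
        sj = np.einsum("ij,i,ij->j", X, irls_w, X) / n
        sj[sj == 0] = 1.0
        beta_old = beta.copy()
        r = z - X @ beta
        status = _cd_cycles(X, wn, r, beta, sj, lam * w, max_iter, tol)
        if status < 0:
            raise ConvergenceError(f"binomial CD did not converge at lambda={lam:g}")
        new_obj = penalized_obj(beta)
        halvings = 0
        while new_obj > obj + 1e-12 and halvings < 20:
            beta = 0.5 * (beta + beta_old)
            new_obj = penalized_obj(beta)
            halvings += 1
        step = np.max(np.abs(beta - beta_old))
        obj = new_obj
        if step < max(tol, 1e-9):
            return beta
    raise ConvergenceError(f"IRLS did not converge at lambda={lam:g}")


# ---------------------------------------------------------------------------
# path construction

def lambda_grid(
    screen_gradients: np.ndarray,
    penalty_factors: np.ndarray,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> np.ndarray:
    """Geometric λ sequence from λ_max (all penalized coefficients zero) down.

    ``screen_gradients`` are |x_jᵀ r| / n for the covariate-only residual r
    against standardized variant columns.
    """
    g = np.abs(np.asarray(screen_gradients, float))
    w = np.asarray(penalty_factors, float)
    penalized = w > 0
    if not penalized.any():
        raise DegeneratePathError("no penalized variants")
    ratios = g[penalized] / w[penalized]
    lam_max = float(ratios.max())
    if lam_max == 0:
        raise DegeneratePathError("all screening gradients are zero")
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def kkt_violations(
    beta_variants: np.ndarray,
    gradients: np.ndarray,
    lam: float,
    penalty_factors: np.ndarray,
    tol: float = 1e-6,
) -> np.ndarray:
    """Zero-coefficient variants whose gradient exceeds their λ·w_j bound.

    Returns violating variant indices sorted by violation magnitude,
    largest first.
    """
    g = np.abs(np.asarray(gradients, float))
    w = np.asarray(penalty_factors, float)
    excess = g - lam * w
    mask = (np.asarray(beta_variants) == 0) & (excess > tol)
    idx = np.flatnonzero(mask)
    return idx[np.argsort(-excess[idx], kind="stable")]


class _Workspace:
    """Standardized training/validation views of the genotype data."""

    def __init__(self, G, covariates, y, sample_idx, valid_idx=None):
        D, self.variant_meta = _dosage_matrix(G)
        self.train_idx = np.asarray(sample_idx)
        self.valid_idx = None if valid_idx is None else np.asarray(valid_idx)
        Dtr = D[self.train_idx]
        with np.errstate(invalid="ignore"):
            train_mean = np.nanmean(Dtr, axis=0)
        train_mean = np.where(np.isfinite(train_mean), train_mean, 0.0)
        D = np.where(np.isnan(D), train_mean, D)
        Dtr = D[self.train_idx]
        mean = Dtr.mean(axis=0)
        sd = Dtr.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        self.mean, self.sd = mean, sd
        self.freq = mean / 2.0
        self.Z = (D - mean) / sd  # standardized with training statistics

        self.y = np.asarray(y, dtype=float)
        cov = _covariate_frame(covariates, len(self.y))
        self.covariate_names = list(cov.columns)
        C = cov.to_numpy(dtype=float).reshape(len(self.y), -1)
        self.cov_mean = (
            C[self.train_idx].mean(axis=0) if C.shape[1] else np.zeros(0)
        )
        self.C = np.column_stack([np.ones(len(self.y)), C - self.cov_mean])

    @property
    def n_covariates(self) -> int:
        return self.C.shape[1]

    def design(self, active: list[int], rows: np.ndarray) -> np.ndarray:
        if active:
            return np.asfortranarray(
                np.concatenate([self.C[rows], self.Z[np.ix_(rows, active)]], axis=1)
            )
        return np.asfortranarray(self.C[rows])


def _dosage_matrix(G) -> tuple[np.ndarray, pd.DataFrame | None]:
    if isinstance(G, GenotypeMatrix):
        return G.dosages(), G.variants
    D = np.array(G, dtype=np.float64, copy=True)
    return D, None


def _covariate_frame(covariates, n_rows: int) -> pd.DataFrame:
    if covariates is None:
        return pd.DataFrame(index=range(n_rows))
    if isinstance(covariates, pd.DataFrame):
        return covariates
    arr = np.atleast_2d(np.asarray(covariates, float))
    return pd.DataFrame(arr, columns=[f"cov{i+1}" for i in range(arr.shape[1])])


def _covariate_only_fit(C: np.ndarray, y: np.ndarray, family: str) -> np.ndarray:
    if family == "gaussian":
        coef, *_ = np.linalg.lstsq(C, y, rcond=None)
        return coef
    coef = np.zeros(C.shape[1])
    for _ in range(100):  # Newton iterations; design is tiny
        eta = np.clip(C @ coef, -30, 30)
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-9, None)
        H = C.T @ (C * w[:, None])
        grad = C.T @ (y - mu)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        coef = coef + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return coef


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted one half."""
    labels = np.asarray(labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = rankdata(scores)
    return (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def _validation_metric(eta: np.ndarray, y: np.ndarray, family: str) -> float:
    if family == "gaussian":
        if np.std(eta) == 0 or np.std(y) == 0:
            return 0.0
        return float(np.corrcoef(eta, y)[0, 1] ** 2)
    auc = _auc_rank(eta, y)
    return 0.5 if np.isnan(auc) else float(auc)


def basil_fit(
    G,
    covariates,
    y,
    penalty_factors: np.ndarray,
    config: FitConfig,
    train_idx: np.ndarray,
    valid_idx: np.ndarray,
) -> LassoPath:
    """Fit the batch-screened lasso path with validation-metric tracking.

    Train and validation index sets must be disjoint. The returned path is
    KKT-certified against the full variant set at every reported λ.
    """
    train_idx = np.asarray(train_idx)
    valid_idx = np.asarray(valid_idx)
    if valid_idx.size == 0:
        raise ValueError("validation set is empty")
    if np.intersect1d(train_idx, valid_idx).size:
        raise ValueError("train and validation sets overlap")
    ws = _Workspace(G, covariates, y, train_idx, valid_idx)
    pf = np.asarray(penalty_factors, dtype=float)
    if pf.size != ws.Z.shape[1]:
        raise ValueError("penalty factor length mismatch")

    lambdas, path = _fit_path(ws, pf, config, lambdas=None, track_validation=True)
    return path


def _fit_path(
    ws: _Workspace,
    pf: np.ndarray,
    config: FitConfig,
    lambdas: np.ndarray | None,
    track_validation: bool,
) -> tuple[np.ndarray, LassoPath]:
    y_tr = ws.y[ws.train_idx]
    n = len(ws.train_idx)
    m = ws.Z.shape[1]
    Ztr = ws.Z[ws.train_idx]
    family = config.family

    cov_coef = _covariate_only_fit(ws.C[ws.train_idx], y_tr, family)
    eta0 = ws.C[ws.train_idx] @ cov_coef
    resid0 = y_tr - (eta0 if family == "gaussian" else expit(np.clip(eta0, -30, 30)))
    grads = np.abs(Ztr.T @ resid0) / n
    if lambdas is None:
        lambdas = lambda_grid(grads, pf, config.n_lambda, config.lambda_min_ratio)

    active: list[int] = list(np.flatnonzero(pf == 0))
    beta = np.concatenate([cov_coef, np.zeros(len(active))])
    n_cov = ws.n_covariates

    out_lambdas = []
    variant_coefs: list[dict[int, float]] = []
    covariate_coefs: list[np.ndarray] = []
    metrics: list[float] = []
    best_metric = -np.inf
    stall = 0

    for lam in lambdas:
        # screen: admit the strongest inactive variants by gradient / w_j
        inactive = np.setdiff1d(np.arange(m), np.asarray(active, int))
        if inactive.size:
            eta = _eta_train(ws, active, beta)
            r = y_tr - (eta if family == "gaussian" else expit(np.clip(eta, -30, 30)))
            g_inactive = np.abs(Ztr[:, inactive].T @ r) / n
            rank = g_inactive / np.where(pf[inactive] > 0, pf[inactive], np.inf)
            k = min(config.batch_size, inactive.size)
            order = np.lexsort((inactive, -rank))
            newly = inactive[order[:k]]
            newly = newly[rank[order[:k]] > 0]
            for j in newly:
                active.append(int(j))
            beta = np.concatenate([beta, np.zeros(len(newly))])

        # solve + KKT-certify against all variants, growing as needed
        while True:
            X = ws.design(active, ws.train_idx)
            beta = cd_lasso(
                X, y_tr, lam, pf[active], n_cov, family,
                warm_start=beta, tol=config.cd_tolerance,
                max_iter=config.max_cd_iter,
            )
            eta = X @ beta
            r = y_tr - (eta if family == "gaussian" else expit(np.clip(eta, -30, 30)))
            grads_all = np.abs(Ztr.T @ r) / n
            beta_var_full = np.zeros(m)
            beta_var_full[active] = beta[n_cov:]
            violators = kkt_violations(
                beta_var_full, grads_all, lam, pf, tol=config.kkt_tolerance
            )
            violators = [int(j) for j in violators if j not in set(active)]
            if not violators:
                break
            active.extend(violators)
            beta = np.concatenate([beta, np.zeros(len(violators))])

        out_lambdas.append(lam)
        coefs = {
            int(j): float(b)
            for j, b in zip(active, beta[n_cov:])
            if b != 0.0
        }
        variant_coefs.append(coefs)
        covariate_coefs.append(beta[:n_cov].copy())

        if track_validation:
            eta_val = _eta_rows(ws, active, beta, ws.valid_idx)
            metric = _validation_metric(eta_val, ws.y[ws.valid_idx], family)
            metrics.append(metric)
            if metric > best_metric + 1e-12:
                best_metric = metric
                stall = 0
            else:
                stall += 1
                if stall >= config.early_stop_patience:
                    logger.info(
                        "early stop after %d non-improving lambdas", stall
                    )
                    break
        else:
            metrics.append(np.nan)

    path = LassoPath(
        lambdas=np.asarray(out_lambdas),
        variant_coefs=variant_coefs,
        covariate_coefs=covariate_coefs,
        active_counts=np.array([len(c) for c in variant_coefs]),
        validation_metric=np.asarray(metrics),
        metric_name="R2" if family == "gaussian" else "AUC",
        covariate_names=ws.covariate_names,
    )
    return np.asarray(out_lambdas), path


def _eta_train(ws, active, beta):
    return _eta_rows(ws, active, beta, ws.train_idx)


def _eta_rows(ws, active, beta, rows):
    n_cov = ws.n_covariates
    eta = ws.C[rows] @ beta[:n_cov]
    if active:
        eta = eta + ws.Z[np.ix_(rows, active)] @ beta[n_cov:]
    return eta


def select_lambda(path: LassoPath) -> int:
    """Index of the validation-optimal λ; ties go to the sparser (larger) λ."""
    metric = np.asarray(path.validation_metric, float)
    if np.all(np.isnan(metric)):
        raise ValueError("path carries no validation metric")
    return int(np.nanargmax(metric))


def refit_final(
    G,
    covariates,
    y,
    lam: float,
    penalty_factors: np.ndarray,
    config: FitConfig,
    sample_idx: np.ndarray,
    variant_meta: pd.DataFrame | None = None,
    n_refit_lambda: int = 20,
) -> PRSModel:
    """Refit at the chosen λ value on the combined score-development set.

    The path is warm-started from the combined-set λ_max down to ``lam``
    for numerical stability; coefficients are de-standardized to
    per-effect-allele dosage weights and training allele frequencies are
    stored for missing-dosage imputation at scoring time.
    """
    sample_idx = np.asarray(sample_idx)
    ws = _Workspace(G, covariates, y, sample_idx)
    pf = np.asarray(penalty_factors, dtype=float)

    y_tr = ws.y[sample_idx]
    cov_coef = _covariate_only_fit(ws.C[sample_idx], y_tr, config.family)
    eta0 = ws.C[sample_idx] @ cov_coef
    mu0 = eta0 if config.family == "gaussian" else expit(np.clip(eta0, -30, 30))
    grads = np.abs(ws.Z[sample_idx].T @ (y_tr - mu0)) / len(sample_idx)
    ratios = grads[pf > 0] / pf[pf > 0]
    lam_max = float(ratios.max()) if ratios.size else lam
    if lam_max > lam:
        seq = np.geomspace(lam_max, lam, n_refit_lambda)
    else:
        seq = np.array([lam])
    _, path = _fit_path(ws, pf, config, lambdas=seq, track_validation=False)

    coefs = path.variant_coefs[-1]
    idx = np.array(sorted(coefs), dtype=int)
    beta_std = np.array([coefs[j] for j in idx])
    weights = beta_std / ws.sd[idx]
    cov_beta = path.covariate_coefs[-1]
    # undo centering: intercept on the original covariate / dosage scale
    intercept = float(
        cov_beta[0]
        - cov_beta[1:] @ ws.cov_mean
        - np.sum(beta_std * ws.mean[idx] / ws.sd[idx])
    )
    meta = variant_meta if variant_meta is not None else ws.variant_meta
    if meta is not None:
        ids = meta["id"].to_numpy()[idx].tolist()
        a1 = meta["a1"].to_numpy()[idx].tolist() if "a1" in meta else ["A"] * len(idx)
    else:
        ids = [f"var{j+1}" for j in idx]
        a1 = ["A"] * len(idx)
    return PRSModel(
        variant_ids=ids,
        effect_allele=a1,
        weights=weights,
        train_freq=ws.freq[idx],
        covariate_names=path.covariate_names,
        covariate_coefs=cov_beta[1:].copy(),
        intercept=intercept,
        lam=float(lam),
        family=config.family,
    )
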