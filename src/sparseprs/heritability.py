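"""Per-variant association scan and LD score regression.

The scan fits one linear or logistic regression per variant with shared
covariates; LD scores are windowed sums of small-sample-adjusted r²; the
regression of χ² statistics on LD scores separates polygenic signal (slope,
scaled to observed-scale SNP heritability) from confounding (intercept).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

logger = logging.getLogger(__name__)

#: median of the chi-square distribution with one degree of freedom
CHI2_MEDIAN_1DF = 0.4549


@dataclasses.dataclass
class AssociationResult:
    """Per-variant association statistics."""

    beta: np.ndarray
    se: np.ndarray
    chi2: np.ndarray
    n: int
    score_test: np.ndarray | None = None  # flags variants fit by score test

    def to_frame(self, variant_ids=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"beta": self.beta, "se": self.se, "chi2": self.chi2, "N": self.n}
        )
        if variant_ids is not None:
            df.insert(0, "id", np.asarray(variant_ids))
        return df


@dataclasses.dataclass
class HeritabilityEstimate:
    """Observed-scale h² with LDSC diagnostics (S7-shaped)."""

    h2_obs: float
    h2_obs_se: float
    intercept: float
    intercept_se: float
    lambda_gc: float
    mean_chi2: float
    ratio: float
    ratio_se: float


def quantile_normalize(y: np.ndarray) -> np.ndarray:
    """Map values to Normal quantiles of their (average) ranks."""
    y = np.asarray(y, float)
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf(ranks / (len(y) + 1))


def gwas_scan(
    G,
    y: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    family: str = "gaussian",
    quantile_normalize_pheno: bool = False,
) -> AssociationResult:
    """Per-variant GLM association with covariate adjustment.

    Gaussian scans use exact residualization (covariates projected out of
    the phenotype and every genotype column). Binomial scans fit a logistic
    regression per variant; on separation or non-convergence the variant is
    reported with a score-test statistic and flagged.
    """
    from .io import GenotypeMatrix

    if isinstance(G, GenotypeMatrix):
        D = G.dosages(impute_freq=G.allele_frequencies())
    else:
        D = np.asarray(G, float)
    y = np.asarray(y, float)
    n, m = D.shape
    C = _design(covariates, n)

    if family == "gaussian":
        if quantile_normalize_pheno:
            y = quantile_normalize(y)
        Q, _ = np.linalg.qr(C)
        y_r = y - Q @ (Q.T @ y)
        D_r = D - Q @ (Q.T @ D)
        xx = np.einsum("ij,ij->j", D_r, D_r)
        xx = np.where(xx == 0, np.nan, xx)
        xy = D_r.T @ y_r
        beta = xy / xx
        dof = n - C.shape[1] - 1
        sigma2 = (y_r @ y_r - beta * xy) / dof
        se = np.sqrt(sigma2 / xx)
        chi2 = (beta / se) ** 2
        return AssociationResult(beta=beta, se=se, chi2=chi2, n=n)

    if family != "binomial":
        raise ValueError(f"unknown family {family!r}")
    return _logistic_scan(D, y, C)


def _design(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    if isinstance(covariates, pd.DataFrame):
        C = covariates.to_numpy(dtype=float)
    else:
        C = np.atleast_2d(np.asarray(covariates, float))
    # standardize covariate variance for conditioning; intercept first
    mean, sd = C.mean(axis=0), C.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return np.column_stack([np.ones(n), (C - mean) / sd])


def _logistic_scan(D: np.ndarray, y: np.ndarray, C: np.ndarray) -> AssociationResult:
    n, m = D.shape
    beta = np.empty(m)
    se = np.empty(m)
    chi2 = np.empty(m)
    flagged = np.zeros(m, dtype=bool)

    # covariate-only fit reused for warm starts and score tests
    base = _newton_logistic(C, y)
    eta0 = C @ base
    mu0 = expit(eta0)
    w0 = mu0 * (1 - mu0)
    CwC_inv = np.linalg.pinv(C.T @ (C * w0[:, None]))

    for j in range(m):
        X = np.column_stack([C, D[:, j]])
        start = np.append(base, 0.0)
        coef, cov, ok = _newton_logistic_full(X, y, start)
        if ok and abs(coef[-1]) < 15:
            beta[j] = coef[-1]
            se[j] = np.sqrt(cov[-1, -1])
            chi2[j] = (beta[j] / se[j]) ** 2
        else:  # separation / non-convergence: fall back to the score test
            x = D[:, j]
            u = x @ (y - mu0)
            v = x @ (x * w0) - (x * w0) @ C @ CwC_inv @ (C.T @ (x * w0))
            chi2[j] = u**2 / v if v > 0 else 0.0
            beta[j] = np.nan
            se[j] = np.nan
            flagged[j] = True
    if flagged.any():
        logger.warning("score-test fallback for %d variants", int(flagged.sum()))
    return AssociationResult(beta=beta, se=se, chi2=chi2, n=n, score_test=flagged)


def _newton_logistic(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef = np.zeros(X.shape[1])
    for _ in range(100):
        mu = expit(np.clip(X @ coef, -30, 30))
        w = np.clip(mu * (1 - mu), 1e-9, None)
        step = np.linalg.pinv(X.T @ (X * w[:, None])) @ (X.T @ (y - mu))
        coef += step
        if np.max(np.abs(step)) < 1e-10:
            break
    return coef


def _newton_logistic_full(X, y, start):
    coef = start.copy()
    for _ in range(50):
        mu = expit(np.clip(X @ coef, -30, 30))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        H = X.T @ (X * w[:, None])
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return coef, None, False
        step = cov @ (X.T @ (y - mu))
        coef += step
        if np.max(np.abs(step)) < 1e-8:
            return coef, cov, True
    return coef, None, False


def ld_scores(G_reference, window_size: int = 50) -> np.ndarray:
    """Windowed LD scores with the small-sample r² adjustment.

    l_j = Σ_k over |k−j| ≤ window of r̂²_adj with
    r̂²_adj = r² − (1 − r²)/(n − 2); the self term contributes 1.
    """
    from .io import GenotypeMatrix

    if isinstance(G_reference, GenotypeMatrix):
        D = G_reference.dosages(impute_freq=G_reference.allele_frequencies())
    else:
        D = np.asarray(G_reference, float)
    n, m = D.shape
    sd = D.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (D - D.mean(axis=0)) / sd
    l = np.ones(m)  # self term: r² = 1 exactly, no adjustment applied
    for d in range(1, min(window_size, m - 1) + 1):
        r = np.einsum("ij,ij->j", Z[:, :-d], Z[:, d:]) / n
        r2 = r**2
        adj = r2 - (1 - r2) / (n - 2)
        l[: m - d] += adj
        l[d:] += adj
    return l


def ldsc_fit(
    chi2: np.ndarray,
    l: np.ndarray,
    N: int,
    M: int,
    n_blocks: int = 200,
) -> HeritabilityEstimate:
    """LD score regression of χ² on N·l/M with a block-jackknife SE.

    Weighted least squares with initial weights 1/max(l, 1), followed by one
    heteroskedasticity weight update from the fitted mean. Standard errors
    for slope, intercept, and the (intercept−1)/(mean χ²−1) ratio come from
    a delete-one-block jackknife.
    """
    chi2 = np.asarray(chi2, float)
    l = np.asarray(l, float)
    m = len(chi2)
    if M <= 0:
        raise ValueError("M must be positive")
    n_blocks = min(n_blocks, max(2, m // 10))
    if m < n_blocks:
        raise ValueError("fewer variants than jackknife blocks")

    x = N * l / M
    base_w = 1.0 / np.maximum(l, 1.0)
    slope, intercept = _wls(x, chi2, base_w)
    fitted = np.clip(intercept + slope * x, 0.1, None)
    weights = base_w / (2.0 * fitted**2)

    slope, intercept = _wls(x, chi2, weights)
    mean_chi2 = float(chi2.mean())

    # delete-one-block jackknife with fixed weights
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    slopes = np.empty(n_blocks)
    intercepts = np.empty(n_blocks)
    ratios = np.empty(n_blocks)
    for b in range(n_blocks):
        keep = np.ones(m, dtype=bool)
        keep[edges[b] : edges[b + 1]] = False
        s_b, i_b = _wls(x[keep], chi2[keep], weights[keep])
        slopes[b] = s_b
        intercepts[b] = i_b
        mc = chi2[keep].mean()
        ratios[b] = (i_b - 1) / (mc - 1) if mc > 1 else np.nan
    factor = (n_blocks - 1) / n_blocks
    h2_se = float(np.sqrt(factor * np.sum((slopes - slopes.mean()) ** 2)))
    int_se = float(np.sqrt(factor * np.sum((intercepts - intercepts.mean()) ** 2)))

    lambda_gc = float(np.median(chi2) / CHI2_MEDIAN_1DF)
    if mean_chi2 > 1:
        ratio = float((intercept - 1) / (mean_chi2 - 1))
        ok = np.isfinite(ratios)
        ratio_se = float(
            np.sqrt(factor * np.sum((ratios[ok] - ratios[ok].mean()) ** 2))
        )
    else:
        ratio, ratio_se = np.nan, np.nan
    return HeritabilityEstimate(
        h2_obs=float(slope),
        h2_obs_se=h2_se,
        intercept=float(intercept),
        intercept_se=int_se,
        lambda_gc=lambda_gc,
        mean_chi2=mean_chi2,
        ratio=ratio,
        ratio_se=ratio_se,
    )


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    xc = x - xm
    # constant-regressor guard (up to floating noise): slope unidentifiable
    if np.abs(xc).max() <= 1e-9 * max(1.0, np.abs(x).max()):
        return 0.0, float(ym)
    sxx = (w * xc**2).sum()
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    return float(slope), float(ym - slope * xm)


def heritability_table(
    estimates: dict[str, HeritabilityEstimate], families: dict[str, str] | None = None
) -> pd.DataFrame:
    """S7-shaped table of per-trait heritability estimates."""
    rows = []
    for trait, est in estimates.items():
        rows.append(
            {
                "trait": trait,
                "family": (families or {}).get(trait, "gaussian"),
                "h2_obs": est.h2_obs,
                "h2_obs_se": est.h2_obs_se,
                "lambda_GC": est.lambda_gc,
                "mean_chi2": est.mean_chi2,
                "intercept": est.intercept,
                "intercept_se": est.intercept_se,
                "ratio": est.ratio,
                "ratio_se": est.ratio_se,
            }
        )
    return pd.DataFrame(rows)
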