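"""Predictive-performance evaluation of PRS models on held-out samples.

Computes polygenic scores, covariate-only and full GLMs, and the metrics
R² (with approximate-SE confidence interval), Nagelkerke's and Tjur's
pseudo-R², and AUC with DeLong confidence intervals. Incremental predictive
performance is the full-model metric minus the covariate-only metric.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .prs_fit import PRSModel

logger = logging.getLogger(__name__)

BONFERRONI_N_TESTS = 2000


@dataclasses.dataclass
class EvaluationResult:
    """One metric for one (trait, population, model-type) triple."""

    trait: str
    population: str
    model_type: str  # genotype_only | covariate_only | full
    metric: str  # R2 | NagelkerkeR2 | TjurR2 | AUC
    value: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_value: float = np.nan


def compute_prs(G_target, model: PRSModel, variant_meta: pd.DataFrame | None = None):
    """Score samples as the dosage-weighted sum of model effect alleles.

    Missing dosages are imputed as twice the training allele frequency, as
    are variants absent from the target data entirely. When the target's
    allele orientation is flipped relative to the model, the dosage is
    reflected (2 - d); irreconcilable allele pairs are skipped and counted.
    """
    from .io import GenotypeMatrix

    if isinstance(G_target, GenotypeMatrix):
        D = G_target.dosages()
        meta = G_target.variants
    else:
        D = np.array(G_target, dtype=float, copy=True)
        meta = variant_meta
    n = D.shape[0]
    scores = np.zeros(n)
    if meta is not None:
        id_to_col = {vid: j for j, vid in enumerate(meta["id"])}
        target_a1 = meta["a1"].to_numpy() if "a1" in meta else None
        target_a2 = meta["a2"].to_numpy() if "a2" in meta else None
    else:
        id_to_col = {f"var{j+1}": j for j in range(D.shape[1])}
        target_a1 = target_a2 = None

    n_skipped = 0
    for vid, allele, weight, freq in zip(
        model.variant_ids, model.effect_allele, model.weights, model.train_freq
    ):
        col = id_to_col.get(vid)
        if col is None:
            scores += weight * 2.0 * freq
            continue
        d = D[:, col]
        if target_a1 is not None:
            if target_a1[col] == allele:
                pass
            elif target_a2 is not None and target_a2[col] == allele:
                d = 2.0 - d
            else:
                n_skipped += 1
                continue
        d = np.where(np.isnan(d), 2.0 * freq, d)
        scores += weight * d
    if n_skipped:
        logger.warning("skipped %d variants with unresolvable alleles", n_skipped)
    return scores


@dataclasses.dataclass
class CovariateModel:
    """Fitted covariate-only GLM, applied as a linear score."""

    columns: list[str]
    coef: np.ndarray  # aligned with columns
    intercept: float
    family: str

    def score(self, covariates: pd.DataFrame) -> np.ndarray:
        """Linear predictor; columns constant in the target are dropped."""
        eta = np.full(len(covariates), self.intercept)
        for name, b in zip(self.columns, self.coef):
            col = covariates[name].to_numpy(dtype=float)
            if np.ptp(col) == 0:
                continue  # e.g. array indicator constant in this population
            eta += b * col
        return eta


def fit_covariate_model(
    covariates: pd.DataFrame,
    y: np.ndarray,
    family: str,
    development_idx: np.ndarray | None = None,
) -> CovariateModel:
    """GLM of the trait on covariates over the score-development samples."""
    idx = np.arange(len(covariates)) if development_idx is None else np.asarray(development_idx)
    C = covariates.iloc[idx]
    yd = np.asarray(y, float)[idx]
    keep = [c for c in C.columns if np.ptp(C[c].to_numpy(dtype=float)) > 0]
    dropped = set(C.columns) - set(keep)
    if dropped:
        logger.warning("dropping constant covariate columns: %s", sorted(dropped))
    X = np.column_stack([np.ones(len(C))] + [C[c].to_numpy(dtype=float) for c in keep])
    coef = _glm_fit(X, yd, family)
    return CovariateModel(columns=keep, coef=coef[1:], intercept=float(coef[0]), family=family)


def _glm_fit(X: np.ndarray, y: np.ndarray, family: str) -> np.ndarray:
    # aliased columns are dropped via pinv-based least squares inside Newton
    if family == "gaussian":
        return np.linalg.lstsq(X, y, rcond=None)[0]
    if family != "binomial":
        raise ValueError(f"unknown family {family!r}")
    coef = np.zeros(X.shape[1])
    for _ in range(200):
        eta = np.clip(X @ coef, -30, 30)
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-9, None)
        H = X.T @ (X * w[:, None])
        step = np.linalg.pinv(H) @ (X.T @ (y - mu))
        coef += step
        if np.max(np.abs(step)) < 1e-10:
            break
    return coef


@dataclasses.dataclass
class FullModelFit:
    """trait ~ 1 + covariate_score + PRS, with the PRS-term Wald p-value."""

    coef: np.ndarray  # intercept, covariate-score, prs
    p_value_prs: float
    loglik: float
    loglik_null: float
    fitted: np.ndarray
    degenerate: bool = False


def fit_full_model(
    covariate_score: np.ndarray, prs: np.ndarray, y: np.ndarray, family: str
) -> FullModelFit:
    """GLM of the trait on the covariate-only score and the PRS.

    The intercept absorbs trait-mean (or prevalence) differences between the
    development and target populations. A constant PRS column is aliased:
    the fit is flagged degenerate and the p-value reported as NaN
    (non-significant).
    """
    import statsmodels.api as sm

    y = np.asarray(y, float)
    degenerate = np.ptp(np.asarray(prs, float)) == 0
    cols = [np.ones_like(y), np.asarray(covariate_score, float)]
    if not degenerate:
        cols.append(np.asarray(prs, float))
    X = np.column_stack(cols)
    fam = sm.families.Gaussian() if family == "gaussian" else sm.families.Binomial()
    res = sm.GLM(y, X, family=fam).fit()
    null = sm.GLM(y, np.ones_like(y), family=fam).fit()
    if degenerate:
        coef = np.append(res.params, 0.0)
        p_prs = np.nan
    else:
        coef = res.params
        p_prs = float(res.pvalues[-1])
    return FullModelFit(
        coef=np.asarray(coef),
        p_value_prs=p_prs,
        loglik=float(res.llf),
        loglik_null=float(null.llf),
        fitted=np.asarray(res.fittedvalues),
        degenerate=bool(degenerate),
    )


def nagelkerke_r2(loglik_null: float, loglik_model: float, n: int) -> float:
    """Nagelkerke (Cragg–Uhler) pseudo-R²."""
    cox_snell = 1.0 - np.exp((2.0 / n) * (loglik_null - loglik_model))
    max_cs = 1.0 - np.exp((2.0 / n) * loglik_null)
    return float(cox_snell / max_cs)


def tjur_r2(fitted_probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Coefficient of discrimination: mean(p̂ | case) − mean(p̂ | control)."""
    p = np.asarray(fitted_probabilities, float)
    lab = np.asarray(labels).astype(bool)
    if lab.all() or not lab.any():
        raise ValueError("labels must contain both classes")
    return float(p[lab].mean() - p[~lab].mean())


def auc_with_delong_ci(
    scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float]:
    """AUC with a DeLong-variance Wald confidence interval, clipped to [0,1]."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    n1, n0 = len(pos), len(neg)
    if n1 == 0 or n0 == 0:
        raise ValueError("labels must contain both classes")
    # structural components via midranks (ties count one half)
    all_ranks = stats.rankdata(scores)
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    auc = (all_ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    v10 = (all_ranks[labels] - pos_ranks) / n0  # P(neg < pos_i)
    v01 = 1.0 - (all_ranks[~labels] - neg_ranks) / n1
    var = np.var(v10, ddof=1) / n1 + np.var(v01, ddof=1) / n0
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def r2_with_se(
    predicted: np.ndarray, observed: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Squared Pearson correlation with an approximate-SE Wald interval.

    SE ≈ sqrt(4 R² (1−R²)² (n−2)² / ((n²−1)(n+3))).
    """
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    n = len(observed)
    if np.std(predicted) == 0 or np.std(observed) == 0:
        return 0.0, 0.0, 0.0
    r2 = float(np.corrcoef(predicted, observed)[0, 1] ** 2)
    se = np.sqrt(4 * r2 * (1 - r2) ** 2 * (n - 2) ** 2 / ((n**2 - 1) * (n + 3)))
    z = stats.norm.ppf(1 - alpha / 2)
    return r2, float(max(0.0, r2 - z * se)), float(min(1.0, r2 + z * se))


def incremental_performance(
    full: EvaluationResult, covariate_only: EvaluationResult
) -> float:
    """Full-model metric minus covariate-only metric, contract-checked."""
    for field in ("trait", "population", "metric"):
        if getattr(full, field) != getattr(covariate_only, field):
            raise ValueError(
                f"mismatched {field}: {getattr(full, field)!r} vs "
                f"{getattr(covariate_only, field)!r}"
            )
    return float(full.value - covariate_only.value)


def is_significant(p_value: float, n_tests: int = BONFERRONI_N_TESTS) -> bool:
    """Strict Bonferroni threshold: p < 0.05 / n_tests."""
    if np.isnan(p_value):
        return False
    return bool(p_value < 0.05 / n_tests)


def evaluate_trait(
    trait: str,
    population: str,
    prs: np.ndarray,
    covariate_score: np.ndarray,
    y: np.ndarray,
    family: str,
) -> list[EvaluationResult]:
    """All S6-style metric rows for one trait/population pair.

    For gaussian traits: R² for each of genotype-only, covariate-only, and
    full models. For binomial traits: Nagelkerke/Tjur pseudo-R² and AUC.
    The full-model rows carry the Wald p-value of the PRS term.
    """
    y = np.asarray(y, float)
    n = len(y)
    full = fit_full_model(covariate_score, prs, y, family)
    results: list[EvaluationResult] = []

    if family == "gaussian":
        for model_type, pred in (
            ("genotype_only", prs),
            ("covariate_only", covariate_score),
            ("full", full.fitted),
        ):
            r2, lo, hi = r2_with_se(pred, y)
            results.append(
                EvaluationResult(
                    trait, population, model_type, "R2", r2, lo, hi,
                    full.p_value_prs if model_type == "full" else np.nan,
                )
            )
        return results

    import statsmodels.api as sm

    fam = sm.families.Binomial()
    null_llf = sm.GLM(y, np.ones(n), family=fam).fit().llf
    for model_type, predictor in (
        ("genotype_only", prs),
        ("covariate_only", covariate_score),
    ):
        if np.ptp(np.asarray(predictor, float)) == 0:
            fitted = np.full(n, y.mean())
            llf = null_llf
        else:
            res = sm.GLM(
                y, np.column_stack([np.ones(n), predictor]), family=fam
            ).fit()
            fitted, llf = np.asarray(res.fittedvalues), float(res.llf)
        _append_binary_rows(
            results, trait, population, model_type, fitted, llf, null_llf,
            predictor, y, np.nan,
        )
    _append_binary_rows(
        results, trait, population, "full", full.fitted, full.loglik,
        full.loglik_null, full.fitted, y, full.p_value_prs,
    )
    return results


def _append_binary_rows(
    results, trait, population, model_type, fitted, llf, null_llf, ranker, y, p
):
    n = len(y)
    results.append(
        EvaluationResult(
            trait, population, model_type, "NagelkerkeR2",
            nagelkerke_r2(null_llf, llf, n), p_value=p,
        )
    )
    results.append(
        EvaluationResult(
            trait, population, model_type, "TjurR2",
            tjur_r2(fitted, y), p_value=p,
        )
    )
    if np.ptp(np.asarray(ranker, float)) == 0:
        auc, lo, hi = 0.5, 0.5, 0.5
    else:
        auc, lo, hi = auc_with_delong_ci(ranker, y)
    results.append(
        EvaluationResult(trait, population, model_type, "AUC", auc, lo, hi, p)
    )


def results_to_frame(results: list[EvaluationResult]) -> pd.DataFrame:
    """S6-shaped table: trait, population, model, metric, value, CI, p."""
    return pd.DataFrame(
        {
            "trait": [r.trait for r in results],
            "population": [r.population for r in results],
            "model": [r.model_type for r in results],
            "metric": [r.metric for r in results],
            "value": [r.value for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p_value": [r.p_value for r in results],
        }
    )
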