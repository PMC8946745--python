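import numpy as np
import pytest
from scipy.special import expit

from sparseprs import prs_fit
from sparseprs import simulate as sim


# ---------------------------------------------------------------------------
# independent oracles


def ista_lasso(X, y, lam, w, n_unpen, family="gaussian", n_iter=200_000):
    """Proximal-gradient (ISTA) minimizer — independent of coordinate descent."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    wfull = np.concatenate([np.zeros(n_unpen), np.asarray(w, float)])
    L = np.linalg.norm(X, 2) ** 2 / n  # Lipschitz constant of the smooth part
    if family == "binomial":
        L = L / 4 + 1e-12
    step = 1.0 / L
    beta = np.zeros(p)
    for _ in range(n_iter):
        if family == "gaussian":
            grad = -X.T @ (y - X @ beta) / n
        else:
            grad = -X.T @ (y - expit(X @ beta)) / n
        z = beta - step * grad
        beta_new = np.sign(z) * np.maximum(np.abs(z) - step * lam * wfull, 0.0)
        beta_new[:n_unpen] = z[:n_unpen]
        if np.max(np.abs(beta_new - beta)) < 1e-12:
            beta = beta_new
            break
        beta = beta_new
    return beta


def penalized_objective(X, y, beta, lam, w, n_unpen, family="gaussian"):
    n = len(y)
    eta = X @ beta
    if family == "gaussian":
        loss = 0.5 * np.sum((y - eta) ** 2) / n
    else:
        loss = np.sum(np.logaddexp(0.0, eta) - y * eta) / n
    wfull = np.concatenate([np.zeros(n_unpen), np.asarray(w, float)])
    return loss + lam * np.sum(wfull * np.abs(beta))


def _std(x):
    return (x - x.mean()) / x.std()


# ---------------------------------------------------------------------------
# lambda_grid


class TestLambdaGrid:
    def test_single_variant_closed_form(self):
        lams = prs_fit.lambda_grid(np.array([0.4]), np.array([1.0]), 3, 0.01)
        assert lams[0] == pytest.approx(0.4)

    def test_penalty_factor_scaling(self):
        lams = prs_fit.lambda_grid(np.array([0.4]), np.array([0.5]), 3, 0.01)
        assert lams[0] == pytest.approx(0.8)

    def test_geometric_spacing(self):
        lams = prs_fit.lambda_grid(np.array([1.0]), np.array([1.0]), 3, 0.01)
        np.testing.assert_allclose(lams, [1.0, 0.1, 0.01])

    def test_degenerate(self):
        with pytest.raises(prs_fit.DegeneratePathError):
            prs_fit.lambda_grid(np.zeros(4), np.ones(4), 5, 0.01)
        with pytest.raises(prs_fit.DegeneratePathError):
            prs_fit.lambda_grid(np.ones(4), np.zeros(4), 5, 0.01)


# ---------------------------------------------------------------------------
# cd_lasso


class TestCdLasso:
    def test_univariate_soft_threshold(self):
        # x standardized, x'y/n = 0.5, lambda = 0.2 -> beta = 0.3
        rng = np.random.default_rng(0)
        n = 400
        x = _std(rng.standard_normal(n))
        y = 0.5 * x + _std(rng.standard_normal(n))
        y = y - y @ x / n * x + 0.5 * x  # force x'y/n = 0.5 exactly
        X = x[:, None]
        beta = prs_fit.cd_lasso(X, y, 0.2, np.array([1.0]), 0)
        assert beta[0] == pytest.approx(0.3, abs=1e-9)

    def test_univariate_penalty_scaling(self):
        rng = np.random.default_rng(1)
        n = 400
        x = _std(rng.standard_normal(n))
        y = rng.standard_normal(n)
        y = y - y @ x / n * x + 0.5 * x
        beta = prs_fit.cd_lasso(x[:, None], y, 0.2, np.array([0.5]), 0)
        assert beta[0] == pytest.approx(0.4, abs=1e-9)

    @pytest.mark.parametrize("family", ["gaussian", "binomial"])
    def test_objective_matches_ista_oracle(self, family):
        rng = np.random.default_rng(2)
        n, m = 50, 8
        X = np.column_stack([np.ones(n), rng.standard_normal((n, m))])
        X[:, 1:] = (X[:, 1:] - X[:, 1:].mean(0)) / X[:, 1:].std(0)
        w = rng.choice([0.5, 0.75, 1.0], m)
        if family == "gaussian":
            y = X[:, 1] - 0.5 * X[:, 3] + rng.standard_normal(n)
        else:
            y = (rng.random(n) < expit(X[:, 1] - X[:, 3])).astype(float)
        lam = 0.05
        beta = prs_fit.cd_lasso(X, y, lam, w, 1, family, tol=1e-10)
        obj_cd = penalized_objective(X, y, beta, lam, w, 1, family)
        beta_or = ista_lasso(X, y, lam, w, 1, family)
        obj_or = penalized_objective(X, y, beta_or, lam, w, 1, family)
        assert obj_cd <= obj_or + 1e-5
        assert abs(obj_cd - obj_or) < 1e-5

    def test_objective_monotone_across_cycles(self):
        rng = np.random.default_rng(3)
        n, m = 80, 12
        X = rng.standard_normal((n, m))
        X = (X - X.mean(0)) / X.std(0)
        y = X @ rng.normal(0, 0.5, m) + rng.standard_normal(n)
        w = np.ones(m)
        lam = 0.1
        objs = []
        for k in range(1, 8):
            beta = prs_fit._cd_cycles_py.__wrapped__ if False else None
            b = np.zeros(m)
            r = y - X @ b
            prs_fit._cd_cycles_py(
                np.asfortranarray(X), np.full(n, 1 / n), r, b,
                np.ones(m), lam * w, k, 0.0,
            )
            objs.append(penalized_objective(X, y, b, lam, w, 0))
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_nonconvergence_flagged(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        with pytest.raises(prs_fit.ConvergenceError):
            prs_fit.cd_lasso(X, y, 1e-6, np.ones(5), 0, max_iter=1, tol=1e-14)


# ---------------------------------------------------------------------------
# kkt_violations


class TestKKT:
    def test_no_violation_at_lambda_max(self):
        rng = np.random.default_rng(5)
        g = np.abs(rng.standard_normal(20))
        w = np.ones(20)
        lam_max = g.max()
        out = prs_fit.kkt_violations(np.zeros(20), g, lam_max, w)
        assert out.size == 0

    def test_constructed_violator(self):
        g = np.array([0.1, 0.15])
        w = np.array([1.0, 1.0])
        out = prs_fit.kkt_violations(np.zeros(2), g, 0.1, w)
        assert list(out) == [1]

    def test_matches_dense_recomputation(self):
        rng = np.random.default_rng(6)
        n, m = 100, 40
        X = rng.standard_normal((n, m))
        X = (X - X.mean(0)) / X.std(0)
        r = rng.standard_normal(n)
        beta = np.zeros(m)
        beta[[3, 7]] = 1.0  # active ones are exempt
        w = rng.choice([0.5, 1.0], m)
        lam = 0.08
        g = np.abs(X.T @ r) / n
        expected = {
            j for j in range(m) if beta[j] == 0 and g[j] > lam * w[j] + 1e-6
        }
        got = set(prs_fit.kkt_violations(beta, g, lam, w))
        assert got == expected


# ---------------------------------------------------------------------------
# basil_fit and selection


def _fit_dense_oracle(ws_free_data, lambdas, pf, family, tol=1e-9):
    """No-screening lasso path: every variant active from the start."""
    X, y, C = ws_free_data
    n_cov = C.shape[1]
    design = np.column_stack([C, X])
    w = pf
    beta = np.zeros(design.shape[1])
    out = []
    for lam in lambdas:
        beta = prs_fit.cd_lasso(
            design, y, lam, w, n_cov, family, warm_start=beta, tol=tol
        )
        out.append(beta.copy())
    return out


def _standardized_problem(seed, n=300, m=60, family="gaussian"):
    rng = np.random.default_rng(seed)
    X = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
    keep = X.std(0) > 0
    X = X[:, keep]
    m = X.shape[1]
    Z = (X - X.mean(0)) / X.std(0)
    beta_true = np.zeros(m)
    beta_true[rng.choice(m, 5, replace=False)] = rng.normal(0, 0.4, 5)
    cov = rng.standard_normal((n, 2))
    eta = Z @ beta_true + cov @ [0.3, -0.2]
    if family == "gaussian":
        y = eta + rng.standard_normal(n)
    else:
        y = (rng.random(n) < expit(eta)).astype(float)
    return X, Z, cov, y, beta_true


@pytest.mark.parametrize("family", ["gaussian", "binomial"])
def test_basil_equals_dense_oracle(family):
    X, Z, cov, y, _ = _standardized_problem(7, n=250, m=40, family=family)
    n = len(y)
    tr = np.arange(0, 200)
    va = np.arange(200, n)
    pf = np.ones(Z.shape[1])
    config = prs_fit.FitConfig(
        family=family, n_lambda=20, lambda_min_ratio=0.05, batch_size=5,
        cd_tolerance=1e-9, early_stop_patience=100, kkt_tolerance=1e-8,
    )
    import pandas as pd

    path = prs_fit.basil_fit(X, pd.DataFrame(cov), y, pf, config, tr, va)

    # oracle on the identically standardized training design
    Ztr = Z[tr] if False else None
    Xtr = X[tr]
    mean, sd = Xtr.mean(0), Xtr.std(0)
    sd[sd == 0] = 1
    Ztrain = (Xtr - mean) / sd
    Cdes = np.column_stack([np.ones(len(tr)), cov[tr] - cov[tr].mean(0)])
    dense = _fit_dense_oracle((Ztrain, y[tr], Cdes), path.lambdas, pf, family)
    for k, lam in enumerate(path.lambdas):
        full = np.zeros(Z.shape[1])
        for j, b in path.variant_coefs[k].items():
            full[j] = b
        np.testing.assert_allclose(full, dense[k][Cdes.shape[1]:], atol=1e-6)


def test_null_signal_selects_nothing_useful():
    rng = np.random.default_rng(8)
    X, Z, cov, y, _ = _standardized_problem(8, n=400, m=50)
    y = rng.permutation(y)
    import pandas as pd

    config = prs_fit.FitConfig(n_lambda=30, batch_size=10, early_stop_patience=5)
    tr, va = np.arange(300), np.arange(300, 400)
    path = prs_fit.basil_fit(X, pd.DataFrame(cov), y, np.ones(Z.shape[1]), config, tr, va)
    k = prs_fit.select_lambda(path)
    assert path.active_counts[k] <= 10
    assert path.validation_metric[k] < 0.1


def test_penalty_factor_prioritization_duplicated_columns():
    import pandas as pd

    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        n, m = 300, 20
        X = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        X[:, 1] = X[:, 0]  # exact duplicate pair
        pf = np.ones(m)
        pf[0], pf[1] = 0.5, 1.0
        beta = np.zeros(m)
        beta[0] = 0.5
        Z = (X - X.mean(0)) / np.where(X.std(0) == 0, 1, X.std(0))
        y = Z @ beta + rng.standard_normal(n)
        tr, va = np.arange(250), np.arange(250, n)
        config = prs_fit.FitConfig(n_lambda=40, batch_size=3, early_stop_patience=100)
        path = prs_fit.basil_fit(X, None, y, pf, config, tr, va)
        entry = {0: None, 1: None}
        for k, coefs in enumerate(path.variant_coefs):
            for j in (0, 1):
                if entry[j] is None and j in coefs:
                    entry[j] = k
        assert entry[0] is not None
        assert entry[1] is None or entry[0] < entry[1]


class TestSelectLambda:
    def _path(self, metric):
        k = len(metric)
        return prs_fit.LassoPath(
            lambdas=np.geomspace(1, 0.01, k),
            variant_coefs=[{} for _ in range(k)],
            covariate_coefs=[np.zeros(1) for _ in range(k)],
            active_counts=np.zeros(k, int),
            validation_metric=np.asarray(metric, float),
            metric_name="R2",
            covariate_names=[],
        )

    def test_argmax(self):
        assert prs_fit.select_lambda(self._path([0.1, 0.3, 0.2])) == 1

    def test_tie_prefers_sparser(self):
        assert prs_fit.select_lambda(self._path([0.3, 0.3])) == 0

    def test_monotone_metric(self):
        assert prs_fit.select_lambda(self._path([0.1, 0.2, 0.3])) == 2


class TestRefitFinal:
    def test_destandardization_algebra(self):
        # sd_j = 2 halves the per-dosage weight relative to standardized beta
        rng = np.random.default_rng(9)
        n = 500
        x = rng.binomial(2, 0.5, n).astype(float)
        x = (x - x.mean()) / x.std() * 2 + 1  # force sd = 2
        y = 0.8 * x + rng.standard_normal(n)
        X = x[:, None]
        config = prs_fit.FitConfig(n_lambda=10, batch_size=5)
        model = prs_fit.refit_final(
            X, None, y, 0.01, np.ones(1), config, np.arange(n)
        )
        Z = (x - x.mean()) / 2.0
        beta_std = prs_fit.cd_lasso(
            np.column_stack([np.ones(n), Z]), y, 0.01, np.ones(1), 1, tol=1e-9
        )[1]
        assert model.weights[0] == pytest.approx(beta_std / 2.0, rel=1e-5)

    def test_refit_on_training_set_matches_path(self):
        import pandas as pd

        X, Z, cov, y, _ = _standardized_problem(10, n=260, m=30)
        tr, va = np.arange(200), np.arange(200, 260)
        pf = np.ones(Z.shape[1])
        config = prs_fit.FitConfig(
            n_lambda=15, batch_size=10, early_stop_patience=100, cd_tolerance=1e-9
        )
        path = prs_fit.basil_fit(X, pd.DataFrame(cov), y, pf, config, tr, va)
        k = len(path.lambdas) // 2
        model = prs_fit.refit_final(
            X[tr], pd.DataFrame(cov[tr]), y[tr], float(path.lambdas[k]), pf,
            config, np.arange(len(tr)),
        )
        # de-standardize the path coefficients for comparison
        mean, sd = X[tr].mean(0), X[tr].std(0)
        sd = np.where(sd == 0, 1, sd)
        expected = {j: b / sd[j] for j, b in path.variant_coefs[k].items()}
        got = dict(zip([int(v[3:]) - 1 for v in model.variant_ids], model.weights))
        assert set(got) == set(expected)
        for j in expected:
            assert got[j] == pytest.approx(expected[j], abs=1e-6)

    def test_parameter_recovery(self):
        cfg = sim.SimulationConfig(
            n_per_population={"dev": 4000}, m_variants=2000, n_causal=50,
            h2_true=0.5, seed=42,
        )
        data = sim.simulate_dataset(cfg)
        labels = data.split.to_numpy()
        tr = np.flatnonzero(labels == "train")
        va = np.flatnonzero(labels == "validation")
        config = prs_fit.FitConfig(n_lambda=30, batch_size=200, early_stop_patience=5)
        pf = np.ones(2000)
        path = prs_fit.basil_fit(
            data.genotypes, data.covariates, data.phenotype, pf, config, tr, va
        )
        k = prs_fit.select_lambda(path)
        dev = np.sort(np.concatenate([tr, va]))
        model = prs_fit.refit_final(
            data.genotypes, data.covariates, data.phenotype,
            float(path.lambdas[k]), pf, config, dev,
            variant_meta=data.genotypes.variants,
        )
        selected = {int(v[3:]) - 1 for v in model.variant_ids}
        beta = data.truth.beta_true
        causal = np.flatnonzero(data.truth.causal_mask)
        strong = causal[
            np.abs(beta[causal]) >= np.quantile(np.abs(beta[causal]), 0.75)
        ]
        frac = np.mean([j in selected for j in strong])
        assert frac >= 0.6
        # sign agreement of selected causal weights
        ids = [int(v[3:]) - 1 for v in model.variant_ids]
        signs = [
            np.sign(w) == np.sign(beta[j])
            for j, w in zip(ids, model.weights)
            if data.truth.causal_mask[j] and beta[j] != 0
        ]
        assert np.mean(signs) >= 0.95


class TestContracts:
    def test_empty_validation(self):
        X = np.random.default_rng(0).binomial(2, 0.4, size=(50, 5)).astype(float)
        y = np.random.default_rng(1).standard_normal(50)
        with pytest.raises(ValueError, match="validation"):
            prs_fit.basil_fit(
                X, None, y, np.ones(5), prs_fit.FitConfig(), np.arange(40), np.array([], int)
            )

    def test_overlapping_sets(self):
        X = np.random.default_rng(0).binomial(2, 0.4, size=(50, 5)).astype(float)
        y = np.random.default_rng(1).standard_normal(50)
        with pytest.raises(ValueError, match="overlap"):
            prs_fit.basil_fit(
                X, None, y, np.ones(5), prs_fit.FitConfig(), np.arange(40), np.arange(30, 50)
            )
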