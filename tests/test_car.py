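import numpy as np
import pandas as pd
import pytest
from scipy import stats

from betascape import NeighborGraph, car_loglik, fit_car, nagelkerke_r2, sample_car_response
from betascape.car import lambda_interval, whiten_residuals
from betascape.prep import ModelMatrix


def make_mm(graph, y, X_cols, weights=None, cell_ids=None):
    n = graph.n
    preds = pd.DataFrame(X_cols) if X_cols else pd.DataFrame(index=np.arange(n))
    return ModelMatrix(
        response=np.asarray(y, dtype=float),
        boxcox_power=1.0,
        predictors=preds,
        weights=np.ones(n) if weights is None else np.asarray(weights, dtype=float),
        graph=graph,
        cell_ids=cell_ids or list(graph.nodes),
        beta_w=np.asarray(y, dtype=float),
    )


def random_instance(seed, n_max=50):
    """A random connected-ish queen sub-grid with random data and weights."""
    rng = np.random.default_rng(seed)
    side = int(rng.integers(3, 8))
    cells = [(i, j) for i in range(side) for j in range(side)]
    rng.shuffle(cells)
    cells = sorted(cells[: min(n_max, int(rng.integers(8, side * side + 1)))])
    graph = NeighborGraph.from_cells(cells)
    n = graph.n
    X = {"x1": rng.normal(size=n), "x2": rng.uniform(size=n)}
    y = rng.normal(size=n)
    w = rng.uniform(0.5, 3.0, size=n)
    return make_mm(graph, y, X, weights=w), rng


def dense_oracle_loglik(mm, lam, beta, sigma2, style="W"):
    """Brute-force likelihood through an explicit covariance matrix."""
    X = np.column_stack([np.ones(mm.n), mm.predictors.to_numpy()])
    M = mm.graph.car_matrix(style)
    D_inv_sqrt = np.diag(1.0 / np.sqrt(mm.weights))
    cov = sigma2 * D_inv_sqrt @ np.linalg.inv(np.eye(mm.n) - lam * M) @ D_inv_sqrt
    return stats.multivariate_normal.logpdf(mm.response, mean=X @ beta, cov=cov)


class TestCarLoglik:
    def test_two_cell_closed_form(self):
        graph = NeighborGraph([(0, 0), (0, 1)], np.array([[0.0, 1.0], [1.0, 0.0]]))
        mm = make_mm(graph, [1.0, 1.0], {})
        # beta = [0] so residuals are (1, 1)
        got = car_loglik(mm, 0.5, np.array([0.0]), 1.0, style="B")
        expected = -np.log(2 * np.pi) + 0.5 * np.log(0.75) - 0.5
        assert got == pytest.approx(expected, abs=1e-12)

    def test_lambda_zero_unit_weights_is_iid_normal(self):
        rng = np.random.default_rng(0)
        cells = [(0, j) for j in range(12)]
        graph = NeighborGraph.from_cells(cells)
        y = rng.normal(size=12)
        mm = make_mm(graph, y, {})
        beta = np.array([0.3])
        got = car_loglik(mm, 0.0, beta, 2.0)
        expected = stats.norm.logpdf(y, loc=0.3, scale=np.sqrt(2.0)).sum()
        assert got == pytest.approx(expected, abs=1e-10)

    def test_sigma2_doubling_identity(self):
        mm, _ = random_instance(3)
        beta = np.zeros(3)
        l1 = car_loglik(mm, 0.1, beta, 1.0)
        l2 = car_loglik(mm, 0.1, beta, 2.0)
        # quadratic term halves, normalization adds -(n/2) ln 2
        X = np.column_stack([np.ones(mm.n), mm.predictors.to_numpy()])
        r = mm.response - X @ beta
        from betascape.car import _precision_kernel

        quad = r @ _precision_kernel(mm, 0.1, "W") @ r
        assert l2 - l1 == pytest.approx(-mm.n / 2 * np.log(2) + quad / 4, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("style", ["B", "W"])
    def test_matches_dense_oracle(self, seed, style):
        mm, rng = random_instance(seed)
        lo, hi = lambda_interval(mm.graph, style)
        lam = float(rng.uniform(max(lo, -3) * 0.9, min(hi, 3) * 0.9))
        beta = rng.normal(size=3)
        sigma2 = float(rng.uniform(0.5, 2.0))
        got = car_loglik(mm, lam, beta, sigma2, style=style)
        want = dense_oracle_loglik(mm, lam, beta, sigma2, style=style)
        assert got == pytest.approx(want, abs=1e-8)

    def test_out_of_interval_lambda_errors_with_bounds(self):
        mm, _ = random_instance(1)
        with pytest.raises(ValueError, match="admissible interval"):
            car_loglik(mm, 5.0, np.zeros(3), 1.0, style="B")


class TestFitCar:
    def test_lambda_zero_data_reduces_to_wls(self):
        rng = np.random.default_rng(7)
        cells = [(i, j) for i in range(10) for j in range(10)]
        graph = NeighborGraph.from_cells(cells)
        n = graph.n
        x = rng.normal(size=n)
        w = rng.uniform(0.5, 2.0, size=n)
        y = 1.0 + 2.0 * x + rng.normal(size=n) / np.sqrt(w)
        mm = make_mm(graph, y, {"x": x}, weights=w)
        fit = fit_car(mm)
        # weighted least squares oracle via statsmodels-free closed form
        Xd = np.column_stack([np.ones(n), x])
        Wd = np.diag(w)
        beta_wls = np.linalg.solve(Xd.T @ Wd @ Xd, Xd.T @ Wd @ y)
        fit0 = fit_car(mm, fix_lambda=0.0)
        assert np.allclose(
            [fit0.coefficients["Intercept"], fit0.coefficients["x"]], beta_wls, atol=1e-6
        )
        # the free-lambda fit finds no significant spatial structure
        assert fit.lr_lambda_p > 0.01

    def test_profile_stationarity(self):
        rng = np.random.default_rng(11)
        cells = [(i, j) for i in range(5) for j in range(5)]
        graph = NeighborGraph.from_cells(cells)
        x = rng.normal(size=25)
        y = sample_car_response(graph, np.column_stack([np.ones(25), x]), [1.0, 0.5], 0.4, 1.0, seed=3)
        mm = make_mm(graph, y, {"x": x})
        fit = fit_car(mm)
        beta = np.array([fit.coefficients["Intercept"], fit.coefficients["x"]])
        ll_hat = car_loglik(mm, fit.lam, beta, fit.sigma2)
        for d in (-1e-3, 1e-3):
            assert car_loglik(mm, fit.lam + d, beta, fit.sigma2) <= ll_hat + 1e-9

    def test_loglik_field_consistent_with_direct_evaluation(self):
        mm, _ = random_instance(21)
        fit = fit_car(mm)
        beta = np.array(list(fit.coefficients.values()))
        assert fit.loglik == pytest.approx(car_loglik(mm, fit.lam, beta, fit.sigma2), abs=1e-8)

    def test_permutation_equivariance(self):
        mm, rng = random_instance(4)
        fit1 = fit_car(mm)
        perm = rng.permutation(mm.n)
        graph_p = NeighborGraph(
            [mm.graph.nodes[i] for i in perm], mm.graph.W[np.ix_(perm, perm)]
        )
        mm_p = make_mm(
            graph_p,
            mm.response[perm],
            {c: mm.predictors[c].to_numpy()[perm] for c in mm.predictors},
            weights=mm.weights[perm],
        )
        fit2 = fit_car(mm_p)
        assert fit1.lam == pytest.approx(fit2.lam, abs=1e-7)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-7)
        for k in fit1.coefficients:
            assert fit1.coefficients[k] == pytest.approx(fit2.coefficients[k], rel=1e-6)

    def test_singular_design_reported(self):
        graph = NeighborGraph.from_cells([(0, j) for j in range(10)])
        x = np.arange(10.0)
        mm = make_mm(graph, np.ones(10), {"x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="singular design"):
            fit_car(mm)

    def test_linkless_graph_rejected(self):
        graph = NeighborGraph([(0, 0), (0, 5), (0, 10), (5, 5), (9, 9), (3, 7)], np.zeros((6, 6)))
        mm = make_mm(graph, np.random.default_rng(0).normal(size=6), {})
        with pytest.raises(ValueError, match="no links"):
            fit_car(mm)

    def test_parameter_recovery_small(self):
        cells = [(i, j) for i in range(12) for j in range(12)]
        graph = NeighborGraph.from_cells(cells)
        n = graph.n
        rng = np.random.default_rng(99)
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        lams, betas = [], []
        for s in range(12):
            y = sample_car_response(graph, X, [1.0, 2.0], 0.8, 1.0, seed=s)
            fit = fit_car(make_mm(graph, y, {"x": x}))
            lams.append(fit.lam)
            betas.append([fit.coefficients["Intercept"], fit.coefficients["x"]])
        assert np.mean(lams) == pytest.approx(0.8, abs=0.12)
        assert np.allclose(np.mean(betas, axis=0), [1.0, 2.0], atol=0.25)

    def test_whitened_residuals_decorrelated(self):
        cells = [(i, j) for i in range(10) for j in range(10)]
        graph = NeighborGraph.from_cells(cells)
        X = np.ones((100, 1))
        y = sample_car_response(graph, X, [0.0], 0.9, 1.0, seed=5)
        mm = make_mm(graph, y, {})
        fit = fit_car(mm)
        u = whiten_residuals(mm, fit)
        assert np.std(u) == pytest.approx(1.0, abs=0.25)


class TestNagelkerke:
    def test_no_improvement_zero(self):
        assert nagelkerke_r2(-10.0, -10.0, 25) == 0.0

    def test_hand_example(self):
        assert nagelkerke_r2(-35.0, -50.0, 30) == pytest.approx(1 - np.exp(-1.0))

    def test_monotone_in_loglik(self):
        r = [nagelkerke_r2(ll, -50.0, 30) for ll in (-45.0, -40.0, -35.0)]
        assert r[0] < r[1] < r[2]

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(-1.0, -2.0, 0)

    def test_fit_r2_in_unit_interval(self):
        mm, _ = random_instance(17)
        fit = fit_car(mm)
        assert 0.0 <= fit.nagelkerke < 1.0
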