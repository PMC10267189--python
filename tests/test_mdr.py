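"""Multiview distances and the weighted elastic net."""

import numpy as np
import pandas as pd
import pytest

import foodwebedm as fw
from foodwebedm.ccm import InteractionNetwork, LinkResult
from foodwebedm.mdr import _local_fits, build_multiview_weights


def _full_network(names, adjacency):
    links = [LinkResult(source=names[j], target=names[i], best_lag=0,
                        rho_full=1.0, rho_min=0.0, surrogate_pass=True,
                        kendall_p=0.0, fisher_p=0.0, accepted=True)
             for i in range(len(names)) for j in range(len(names))
             if i != j and adjacency[i][j]]
    return InteractionNetwork(species=list(names), links=links)


@pytest.fixture
def chaotic_panel():
    rng = np.random.default_rng(0)
    n = 150
    x = np.empty((n, 2))
    x[0] = (0.4, 0.3)
    for t in range(n - 1):
        x[t + 1, 0] = x[t, 0] * (3.8 - 3.8 * x[t, 0] - 0.05 * x[t, 1])
        x[t + 1, 1] = x[t, 1] * (3.5 - 3.5 * x[t, 1] - 0.1 * x[t, 0])
    x = (x - x.mean(0)) / x.std(0, ddof=1)
    return pd.DataFrame(x, columns=["u", "v"])


class TestMultiviewWeights:
    def test_small_candidate_space_is_enumerated(self, chaotic_panel):
        """With one cause and E=2 there are only 5 candidate SSRs, so two
        different seeds must keep identical sets."""
        a = build_multiview_weights("u", ["v"], chaotic_panel, E=2, seed=1)
        b = build_multiview_weights("u", ["v"], chaotic_panel, E=2, seed=99)
        assert set(a.ssrs) == set(b.ssrs)
        assert a.weights.sum() == pytest.approx(1.0)
        assert np.all(a.weights >= 0)

    def test_theta_zero_gives_unit_weights(self, chaotic_panel):
        mv = build_multiview_weights("u", ["v"], chaotic_panel, E=2, seed=1)
        assert np.all(mv.state_weights(0.0) == 1.0)

    def test_identical_states_zero_distance_unit_weight(self):
        panel = pd.DataFrame({"u": np.tile([0.5, -0.5], 20),
                              "v": np.tile([-1.0, 1.0], 20)})
        mv = build_multiview_weights("u", ["v"], panel, E=2, seed=0)
        # period-2 series: states two steps apart are identical
        assert mv.distances[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert mv.state_weights(2.0)[0, 2] == pytest.approx(1.0)

    def test_distance_matrix_properties(self, chaotic_panel):
        mv = build_multiview_weights("u", ["v"], chaotic_panel, E=2, seed=1)
        d = mv.distances
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert np.all(d >= 0)


class TestWeightedElasticNet:
    def _problem(self, seed=0, n=50, k=5):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, k))
        beta = rng.normal(size=k)
        y = X @ beta + rng.normal(0, 0.1, n)
        w = rng.uniform(0.1, 1.0, n)
        return X, y, w

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_lambda_zero_matches_weighted_ols(self, seed):
        X, y, w = self._problem(seed)
        b, b0 = fw.weighted_elastic_net(X, y, w, 0.0, 0.5)
        Xa = np.column_stack([np.ones(len(y)), X])
        beta = np.linalg.solve(Xa.T * w @ Xa, Xa.T * w @ y)
        assert np.allclose(b, beta[1:], atol=1e-8)
        assert b0 == pytest.approx(beta[0], abs=1e-8)

    @pytest.mark.parametrize("lam", [0.1, 1.0, 10.0])
    def test_alpha_one_matches_ridge(self, lam):
        X, y, w = self._problem(3)
        b, b0 = fw.weighted_elastic_net(X, y, w, lam, 1.0)
        Xa = np.column_stack([np.ones(len(y)), X])
        P = np.eye(6)
        P[0, 0] = 0.0  # intercept unpenalised
        beta = np.linalg.solve(Xa.T * w @ Xa + lam * P, Xa.T * w @ y)
        assert np.allclose(b, beta[1:], atol=1e-8)

    def test_zero_response_gives_zero_coefficients(self):
        X, _, w = self._problem(4)
        b, b0 = fw.weighted_elastic_net(X, np.zeros(50), w, 0.5, 0.3)
        assert np.allclose(b, 0.0)
        assert b0 == 0.0

    def test_objective_not_worse_than_reference_points(self):
        """The returned minimiser beats both the zero vector and the OLS
        solution on the penalised objective."""
        X, y, w = self._problem(5)
        lam, alpha = 0.8, 0.25

        def obj(b, b0):
            r = y - b0 - X @ b
            return ((w * r * r).sum() + lam * (alpha * (b ** 2).sum()
                    + (1 - alpha) * np.abs(b).sum()))

        b, b0 = fw.weighted_elastic_net(X, y, w, lam, alpha)
        bo, bo0 = fw.weighted_elastic_net(X, y, w, 0.0, 1.0)
        zero_b0 = (w * y).sum() / w.sum()
        assert obj(b, b0) <= obj(bo, bo0) + 1e-10
        assert obj(b, b0) <= obj(np.zeros(5), zero_b0) + 1e-10

    def test_nonfinite_inputs_rejected(self):
        X, y, w = self._problem(6)
        y[0] = np.nan
        with pytest.raises(ValueError):
            fw.weighted_elastic_net(X, y, w, 0.1, 0.5)


class TestEstimateJacobians:
    def test_var1_recovery(self):
        """On linear VAR(1) data the local coefficients recover the fixed
        transition matrix A with small median element error."""
        rng = np.random.default_rng(3)
        A = np.array([[0.6, -0.3, 0.0],
                      [0.2, 0.5, -0.2],
                      [0.0, 0.3, 0.4]])
        n = 300
        X = np.zeros((n, 3))
        for t in range(n - 1):
            X[t + 1] = A @ X[t] + rng.normal(0, 0.05, 3)
        panel = pd.DataFrame(X, columns=["a", "b", "c"])
        net = _full_network(["a", "b", "c"], A != 0)
        jac = fw.estimate_jacobians(net, panel, seed=0)
        med_err = np.median(np.abs(jac.matrices - A[None]), axis=0)
        mask = (A != 0) | np.eye(3, dtype=bool)
        assert np.all(med_err[mask] < 0.2)
        assert np.median(med_err[mask]) < 0.1

    def test_structural_zeros_are_exact(self):
        rng = np.random.default_rng(3)
        A = np.array([[0.6, -0.3, 0.0],
                      [0.2, 0.5, 0.0],
                      [0.0, 0.3, 0.4]])
        n = 200
        X = np.zeros((n, 3))
        for t in range(n - 1):
            X[t + 1] = A @ X[t] + rng.normal(0, 0.05, 3)
        panel = pd.DataFrame(X, columns=["a", "b", "c"])
        net = _full_network(["a", "b", "c"], A != 0)
        jac = fw.estimate_jacobians(net, panel, seed=0)
        assert np.all(jac.matrices[:, 0, 2] == 0.0)
        assert np.all(jac.matrices[:, 1, 2] == 0.0)
        assert np.all(jac.matrices[:, 2, 0] == 0.0)

    def test_theta_zero_lambda_zero_equals_global_ols(self, chaotic_panel):
        """With unit weights and no penalty, every local fit equals the one
        global OLS solution."""
        X = chaotic_panel[["u", "v"]].to_numpy()[:-1]
        y = chaotic_panel["u"].to_numpy()[1:]
        W = np.ones((len(y), len(y)))
        coefs, intercepts, _ = _local_fits(X, y, W, 0.0, 0.0, loo=False)
        Xa = np.column_stack([np.ones(len(y)), X])
        beta = np.linalg.lstsq(Xa, y, rcond=None)[0]
        assert np.allclose(coefs, beta[1:], atol=1e-6)
        assert np.allclose(intercepts, beta[0], atol=1e-6)

    def test_no_cause_node_flagged(self, chaotic_panel):
        net = InteractionNetwork(species=["u", "v"], links=[])
        jac = fw.estimate_jacobians(net, chaotic_panel, seed=0)
        assert set(jac.flagged) == {"u", "v"}
        # off-diagonals are structural zeros
        assert np.all(jac.matrices[:, 0, 1] == 0.0)
        assert np.all(jac.matrices[:, 1, 0] == 0.0)
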