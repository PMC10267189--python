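"""Causal-link testing: surrogates, convergence, pruning, metrics."""

import numpy as np
import pandas as pd
import pytest

import foodwebedm as fw
from foodwebedm.ccm import LinkResult
from foodwebedm.edm import RhoCurve
from tests.conftest import make_table


def _seasonal_series(values):
    n = len(values)
    years = np.repeat(np.arange(1, n // 4 + 2), 4)[:n]
    seasons = np.tile(["winter", "spring", "summer", "autumn"],
                      n // 4 + 1)[:n]
    idx = pd.MultiIndex.from_arrays([years, seasons],
                                    names=["year", "season"])
    return pd.Series(np.asarray(values, dtype=float), index=idx)


class TestSeasonalSurrogates:
    def test_constant_series_maps_to_itself(self):
        s = _seasonal_series(np.full(16, 3.0))
        surr = fw.make_seasonal_surrogates(s, n=5, seed=0)
        assert np.allclose(surr, 3.0)

    def test_anomaly_multiset_preserved(self):
        rng = np.random.default_rng(2)
        s = _seasonal_series(rng.normal(size=20))
        seasons = s.index.get_level_values("season").to_numpy()
        means = pd.Series(s.to_numpy()).groupby(seasons).transform("mean")
        anomalies = np.sort(s.to_numpy() - means.to_numpy())
        surr = fw.make_seasonal_surrogates(s, n=10, seed=1)
        for row in surr:
            surr_anom = np.sort(row - means.to_numpy())
            assert np.allclose(surr_anom, anomalies)

    def test_reproducible_and_seasonal_means_preserved(self):
        """Fixed seed reproduces the set; every surrogate's seasonal
        climatology (mean over years, per season) equals the original's."""
        rng = np.random.default_rng(3)
        s = _seasonal_series(rng.normal(size=24))
        a = fw.make_seasonal_surrogates(s, n=4, seed=7)
        b = fw.make_seasonal_surrogates(s, n=4, seed=7)
        assert np.array_equal(a, b)
        big = fw.make_seasonal_surrogates(s, n=500, seed=7)
        seasons = s.index.get_level_values("season").to_numpy()
        for se in np.unique(seasons):
            observed = big[:, seasons == se].mean()
            assert observed == pytest.approx(
                s.to_numpy()[seasons == se].mean(), abs=0.15)

    def test_too_few_years_errors(self):
        s = _seasonal_series(np.arange(4.0))
        with pytest.raises(ValueError):
            fw.make_seasonal_surrogates(s)


class TestConvergence:
    def test_increasing_curve_significant(self):
        lengths = np.arange(10, 110, 5)
        curve = RhoCurve(lengths=lengths,
                         rhos=np.linspace(0.1, 0.8, lengths.size),
                         n_pred=150)
        kendall_p, fisher_p = fw.test_convergence(curve)
        assert kendall_p < 0.001
        assert fisher_p < 0.001

    def test_constant_curve_not_significant(self):
        lengths = np.arange(10, 60, 5)
        curve = RhoCurve(lengths=lengths,
                         rhos=np.full(lengths.size, 0.4), n_pred=100)
        kendall_p, fisher_p = fw.test_convergence(curve)
        assert kendall_p >= 0.5
        assert fisher_p >= 0.5

    def test_fisher_closed_form(self):
        """rho 0.0 (n=30) vs 0.8 (n=150): z = (atanh(.8)-0)/sqrt(1/27+1/147)
        gives a one-sided p well below 0.05."""
        curve = RhoCurve(lengths=np.array([10, 20, 30, 150]),
                         rhos=np.array([0.0, 0.3, 0.6, 0.8]), n_pred=150)
        _, fisher_p = fw.test_convergence(curve, n_min=30, n_full=150)
        from scipy.stats import norm
        z = np.arctanh(0.8) / np.sqrt(1 / 27 + 1 / 147)
        assert fisher_p == pytest.approx(norm.sf(z), rel=1e-10)
        assert fisher_p < 0.05

    def test_exact_rho_one_is_clamped(self):
        curve = RhoCurve(lengths=np.array([10, 20, 30, 40]),
                         rhos=np.array([0.2, 0.5, 0.9, 1.0]), n_pred=50)
        _, fisher_p = fw.test_convergence(curve)
        assert np.isfinite(fisher_p)


class TestAssessLink:
    def test_identical_series_accepted_at_lag0(self):
        x = np.empty(80)
        x[0] = 0.31
        for t in range(79):
            x[t + 1] = 3.9 * x[t] * (1.0 - x[t])
        x = (x - x.mean()) / x.std(ddof=1)
        s = _seasonal_series(x)
        res = fw.assess_link(s.rename("x"), s.rename("x2"), E_effect=2,
                             seed=0, n_subsamples=30)
        assert res.accepted
        assert res.rho_full > 0.99
        # with E=2 both lag 0 and lag -1 coordinates sit inside the delay
        # vector, so either is a correct "self-causality" lag
        assert res.best_lag in (0, -1)


class TestPruneIndirect:
    def _link(self, src, tgt, lag, rho, accepted=True):
        return LinkResult(source=src, target=tgt, best_lag=lag,
                          rho_full=rho, rho_min=0.1, surrogate_pass=True,
                          kendall_p=0.01, fisher_p=0.01, accepted=accepted)

    def test_two_step_chain_pruned(self):
        links = [self._link("x", "y", 0, 0.9),
                 self._link("y", "z", 0, 0.8),
                 self._link("x", "z", -1, 0.5)]
        net = fw.InteractionNetwork(species=["x", "y", "z"], links=links)
        net = fw.prune_indirect(net)
        assert links[2].pruned_as_indirect
        assert not links[0].pruned_as_indirect

    def test_equal_lag_retained(self):
        links = [self._link("x", "y", -1, 0.9),
                 self._link("y", "z", 0, 0.8),
                 self._link("x", "z", -1, 0.5)]
        net = fw.InteractionNetwork(species=["x", "y", "z"], links=links)
        net = fw.prune_indirect(net)
        assert not links[2].pruned_as_indirect

    def test_no_chain_identity_and_idempotence(self):
        links = [self._link("x", "y", 0, 0.9),
                 self._link("z", "y", -1, 0.7)]
        net = fw.InteractionNetwork(species=["x", "y", "z"], links=links)
        fw.prune_indirect(net)
        first = [l.pruned_as_indirect for l in links]
        fw.prune_indirect(net)
        assert [l.pruned_as_indirect for l in links] == first
        assert not any(first)


class TestNetworkMetrics:
    def _net(self, n_nodes, edges, names=None):
        names = names or [f"n{i}" for i in range(n_nodes)]
        links = [LinkResult(source=a, target=b, best_lag=0, rho_full=0.5,
                            rho_min=0.1, surrogate_pass=True, kendall_p=0.01,
                            fisher_p=0.01, accepted=True)
                 for a, b in edges]
        return fw.InteractionNetwork(species=names, links=links)

    def test_density_and_connectance(self):
        edges = [(f"n{i}", f"n{j}") for i in range(5) for j in range(5)
                 if i != j]
        net = self._net(5, edges)
        m = fw.network_metrics(net)
        assert m["L"] == 20
        assert m["link_density"] == 4.0
        assert m["connectance"] == pytest.approx(0.8)

    def test_food_chain_length(self, trophic):
        net = self._net(3, [("P1", "H1"), ("H1", "C1")],
                        names=["P1", "H1", "C1"])
        m = fw.network_metrics(net, trophic)
        assert m["food_chain_length"] == 3

    def test_empty_network(self):
        net = self._net(0, [], names=[])
        m = fw.network_metrics(net)
        assert m["L"] == 0 and m["link_density"] == 0.0
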