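"""Stability, synchrony and diversity statistics."""

import numpy as np
import pandas as pd
import pytest

import foodwebedm as fw
from foodwebedm.mdr import JacobianSeries
from foodwebedm.stability import _phi


def _jac(matrices, species):
    matrices = np.asarray(matrices, dtype=float)
    return JacobianSeries(species=list(species),
                          times=np.arange(matrices.shape[0]),
                          matrices=matrices)


class TestStructuralStability:
    def test_trace_arithmetic(self):
        jac = _jac([np.diag([-0.2, -0.3, -0.1])], ["P1", "H1", "C1"])
        assert fw.structural_stability(jac).iloc[0] == pytest.approx(-0.6)

    def test_identity_matrix(self):
        jac = _jac([np.eye(4)], ["a", "b", "c", "d"])
        assert fw.structural_stability(jac).iloc[0] == 4.0

    def test_simulator_fixed_point_trace(self):
        """The single-producer fixed point (r=0.5, a=-0.5) has Jacobian 0.5,
        so Tr(J) converges to 0.5."""
        cfg = fw.SimConfig(n_producers=1, n_herbivores=0, n_omnivores=0,
                           n_predators=0, years=20, noise_sd=0.0, seed=1,
                           temp_sensitivity=0.0)
        _, truth = fw.simulate_foodweb(cfg, coefficients=np.array([[-0.5]]),
                                       growth_rates=np.array([0.5]))
        jac = _jac(truth.true_jacobians, truth.species)
        assert fw.structural_stability(jac).iloc[-1] == pytest.approx(
            0.5, abs=1e-8)


class TestTrophicContributions:
    def test_three_group_split(self, trophic):
        jac = _jac([np.diag([-0.2, -0.3, -0.1])], ["P1", "H1", "C1"])
        out = fw.trophic_contributions(jac, trophic)
        assert out["contribution_producer"].iloc[0] == pytest.approx(-0.2)
        assert out["contribution_consumer"].iloc[0] == pytest.approx(-0.3)
        assert out["contribution_predator"].iloc[0] == pytest.approx(-0.1)

    def test_all_producers(self, trophic):
        jac = _jac([np.diag([0.3, 0.4])], ["P1", "P2"])
        out = fw.trophic_contributions(jac, trophic)
        assert out["contribution_producer"].iloc[0] == pytest.approx(0.7)
        assert out["contribution_consumer"].iloc[0] == 0.0

    def test_decomposition_exact_on_random_jacobians(self, trophic):
        """Group sums reconstitute Tr(J) to machine precision (brute-force
        partition oracle)."""
        rng = np.random.default_rng(8)
        species = ["P1", "P2", "H1", "H2", "O1", "C1"]
        jac = _jac(rng.normal(size=(50, 6, 6)), species)
        out = fw.trophic_contributions(jac, trophic)
        total = out.sum(axis=1).to_numpy()
        assert np.allclose(total, np.trace(jac.matrices, axis1=1, axis2=2),
                           rtol=1e-12, atol=1e-14)
        # oracle: per-element partition
        for t in (0, 17):
            diag = np.diag(jac.matrices[t])
            groups = trophic.groups(species)
            for g in ("producer", "consumer", "predator"):
                expect = sum(d for d, gg in zip(diag, groups) if gg == g)
                assert out[f"contribution_{g}"].iloc[t] == pytest.approx(
                    expect, rel=1e-12)

    def test_unmapped_species_errors(self, trophic):
        jac = _jac([np.eye(2)], ["P1", "mystery"])
        with pytest.raises(KeyError):
            fw.trophic_contributions(jac, trophic)


class TestTemporalStability:
    def _panel(self, totals_pattern, species=("P1", "H1")):
        vals = np.column_stack([totals_pattern,
                                np.zeros(len(totals_pattern))])
        return pd.DataFrame(vals, columns=list(species))

    def test_constant_totals_zero_cv(self, trophic):
        panel = pd.DataFrame({"P1": np.full(12, 5.0),
                              "H1": np.full(12, 2.0)})
        out = fw.temporal_stability(panel, trophic)
        assert np.allclose(out["cv_community"], 0.0)

    def test_hand_computed_cv(self, trophic):
        """Totals alternating 10, 20 in a 6-window: sd = 5.477…, mean 15."""
        panel = pd.DataFrame({"P1": np.tile([10.0, 20.0], 3)})
        out = fw.temporal_stability(
            panel, fw.TrophicAssignment({"P1": "producer"}), window=6)
        expected = np.std([10, 20, 10, 20, 10, 20], ddof=1) / 15.0
        assert out["cv_community"].iloc[0] == pytest.approx(expected)
        assert expected == pytest.approx(0.36514837, abs=1e-6)

    def test_scale_invariance(self, small_table, trophic):
        panel = small_table.site_panel("s1")
        out1 = fw.temporal_stability(panel, trophic)
        out2 = fw.temporal_stability(panel * 2.0, trophic)
        assert np.allclose(out1["cv_community"], out2["cv_community"])

    def test_zero_mean_window_is_missing(self, trophic):
        panel = pd.DataFrame({"P1": np.zeros(8)})
        out = fw.temporal_stability(
            panel, fw.TrophicAssignment({"P1": "producer"}))
        assert out["cv_community"].isna().all()


class TestSynchrony:
    def test_identical_species_phi_one(self, trophic):
        base = 5.0 + np.sin(np.arange(1, 7))
        panel = pd.DataFrame({"P1": base, "P2": base, "H1": base})
        tro = fw.TrophicAssignment({"P1": "producer", "P2": "producer",
                                    "H1": "herbivore"})
        out = fw.synchrony(panel, tro, window=6)
        assert out["phi_community"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_compensating_species_phi_zero(self):
        t = np.arange(1, 7)
        panel = pd.DataFrame({"P1": 5.0 + np.sin(t), "P2": 5.0 - np.sin(t)})
        tro = fw.TrophicAssignment({"P1": "producer", "P2": "producer"})
        out = fw.synchrony(panel, tro, window=6)
        assert out["phi_community"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_independent_species_mean_phi(self):
        """For independent species, E[var(total)] = sum of variances, so
        mean phi ≈ Σσ_i²/(Σσ_i)²."""
        rng = np.random.default_rng(5)
        sds = np.array([1.0, 2.0, 3.0])
        phis, expected = [], []
        for _ in range(400):
            block = pd.DataFrame(rng.normal(0, sds, size=(6, 3)),
                                 columns=["a", "b", "c"])
            phis.append(_phi(block))
            s = block.std(ddof=1).to_numpy()
            expected.append((s ** 2).sum() / s.sum() ** 2)
        assert np.mean(phis) == pytest.approx(np.mean(expected), rel=0.15)

    def test_scale_and_translation_invariance(self, small_table, trophic):
        panel = small_table.site_panel("s1")
        out1 = fw.synchrony(panel, trophic, window=6)
        out2 = fw.synchrony(panel * 3.0, trophic, window=6)
        assert np.allclose(out1["phi_community"], out2["phi_community"])

    def test_single_species_group_flagged_as_one(self, trophic):
        panel = pd.DataFrame({"P1": 5.0 + np.sin(np.arange(12.0)),
                              "H1": 3.0 + np.cos(np.arange(12.0))})
        out = fw.synchrony(panel, trophic, window=6)
        assert np.allclose(out["phi_producer"], 1.0)

    def test_all_constant_species_missing(self):
        panel = pd.DataFrame({"P1": np.full(8, 2.0), "P2": np.full(8, 3.0)})
        tro = fw.TrophicAssignment({"P1": "producer", "P2": "producer"})
        out = fw.synchrony(panel, tro, window=6)
        assert out["phi_community"].isna().all()


class TestDiversity:
    def test_uniform_abundances(self):
        panel = pd.DataFrame(np.ones((3, 4)), columns=list("abcd"))
        out = fw.diversity_indices(panel)
        assert np.allclose(out["richness"], 4)
        assert np.allclose(out["simpson"], 1 - 1 / 4)
        assert np.allclose(out["shannon"], np.log(4))

    def test_single_species(self):
        panel = pd.DataFrame({"a": [2.0], "b": [0.0]})
        out = fw.diversity_indices(panel)
        assert out["richness"].iloc[0] == 1
        assert out["simpson"].iloc[0] == pytest.approx(0.0)
        assert out["shannon"].iloc[0] == pytest.approx(0.0)

    def test_hand_computed_simpson(self):
        panel = pd.DataFrame({"a": [1.0], "b": [3.0]})
        out = fw.diversity_indices(panel)
        assert out["simpson"].iloc[0] == pytest.approx(0.375)

    def test_zero_total_missing(self):
        panel = pd.DataFrame({"a": [0.0], "b": [0.0]})
        out = fw.diversity_indices(panel)
        assert out["richness"].iloc[0] == 0
        assert np.isnan(out["simpson"].iloc[0])
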