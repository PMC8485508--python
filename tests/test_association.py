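import numpy as np
import pandas as pd
import pytest

from gutshift.association import (GPConfig, GPPosterior, classify_treatment_trend,
                                  compare_networks, fit_gp_posterior,
                                  log_ratio_trajectory, summarize_associations)
from gutshift.preprocess import ClrInstance, dirichlet_instances
from gutshift.tables import CountTable


def gaussian_instance(d: int, t: int, seed: int, wide_days: bool = True) -> ClrInstance:
    """Non-compositional latent matrix; widely spaced days make the
    squared-exponential kernel the exact identity."""
    rng = np.random.default_rng(seed)
    days = np.arange(t) * (1e4 if wide_days else 1.0)
    return ClrInstance(values=rng.standard_normal((d, t)), days=days,
                       enforce_closure=False, taxon_ids=[f"x{i}" for i in range(d)])


class TestFitGpPosterior:
    def test_conjugacy_closed_form_with_identity_kernel(self):
        """With K = I the posterior mean of Sigma equals the inverse-Wishart
        closed form (Xi + SSE)/(nu + T - D - 1) within Monte-Carlo error."""
        d, t = 5, 100
        inst = gaussian_instance(d, t, seed=0)
        cfg = GPConfig(nugget=0.0, n_posterior_draws=2_000, seed=1)
        post = fit_gp_posterior([inst], cfg, store_covariance=True)
        yc = inst.values - inst.values.mean(axis=1, keepdims=True)
        closed = (np.eye(d) + yc @ yc.T) / ((d + 3) + t - d - 1)
        draws = post.covariance_draws
        se = draws.std(axis=0, ddof=1) / np.sqrt(draws.shape[0])
        assert (np.abs(draws.mean(axis=0) - closed) <= 3 * se).all()

    def test_null_coverage_two_taxa(self):
        """Independent rows, true rho = 0: credible interval covers zero in
        >= 90% of seeds and the posterior median stays near zero."""
        covered, medians = 0, []
        for s in range(100):
            inst = gaussian_instance(2, 50, seed=1_000 + s)
            post = fit_gp_posterior([inst], GPConfig(nugget=0.0,
                                                     n_posterior_draws=400, seed=s))
            edge = summarize_associations(post).iloc[0]
            covered += not edge.significant
            medians.append(edge.rho_median)
        assert covered >= 90
        assert np.mean(np.abs(medians)) < 0.2

    def test_pooling_identical_evidence_does_not_widen_ci(self):
        inst = gaussian_instance(3, 40, seed=7)
        cfg = GPConfig(nugget=0.0, n_posterior_draws=2_000, seed=3)
        single = summarize_associations(fit_gp_posterior([inst], cfg))
        pooled = summarize_associations(fit_gp_posterior([inst, inst], cfg))
        merged = single.merge(pooled, on=["taxon_i", "taxon_j"],
                              suffixes=("_one", "_two"))
        width_one = merged["ci_high_one"] - merged["ci_low_one"]
        width_two = merged["ci_high_two"] - merged["ci_low_two"]
        assert (np.abs(merged["rho_median_two"] - merged["rho_median_one"]) < 0.05).all()
        assert (width_two <= width_one + 0.02).all()

    def test_draws_are_valid_correlation_matrices(self):
        table = CountTable(np.random.default_rng(0).integers(1, 500, (6, 8)),
                           [f"t{i}" for i in range(6)], [f"s{i}" for i in range(8)])
        inst = dirichlet_instances(table, days=np.arange(8, dtype=float),
                                   n_instances=4, seed=2)
        post = fit_gp_posterior(inst, GPConfig(n_posterior_draws=20, seed=5))
        for r in post.draws:
            assert np.allclose(r, r.T)
            assert np.allclose(np.diag(r), 1.0)
            assert r.min() >= -1.0 and r.max() <= 1.0
            assert np.linalg.eigvalsh(r).min() >= -1e-8

    def test_duplicate_days_without_nugget_rejected(self):
        inst = ClrInstance(values=np.random.default_rng(1).standard_normal((3, 4)),
                           days=np.array([0.0, 1e-9, 2e-9, 1.0]),
                           enforce_closure=False)
        with pytest.raises(ValueError, match="nugget"):
            fit_gp_posterior([inst], GPConfig(nugget=0.0, n_posterior_draws=5))

    def test_improper_prior_dof_rejected(self):
        inst = gaussian_instance(4, 10, seed=3)
        with pytest.raises(ValueError, match="prior_dof"):
            fit_gp_posterior([inst], GPConfig(prior_dof=4.0, n_posterior_draws=5))

    def test_clr_depth_invariance(self):
        """CLR-scale correlation is unchanged when per-sample depths are
        rescaled (compositional invariance through the Dirichlet step)."""
        rng = np.random.default_rng(9)
        base = rng.integers(50, 500, size=(5, 10))
        t1 = CountTable(base * 1, [f"t{i}" for i in range(5)],
                        [f"s{i}" for i in range(10)])
        t2 = CountTable(base * 10, [f"t{i}" for i in range(5)],
                        [f"s{i}" for i in range(10)])
        days = np.arange(10, dtype=float)
        cfg = GPConfig(n_posterior_draws=200, seed=11)
        med1 = summarize_associations(
            fit_gp_posterior(dirichlet_instances(t1, days, 16, seed=4), cfg))
        med2 = summarize_associations(
            fit_gp_posterior(dirichlet_instances(t2, days, 16, seed=4), cfg))
        merged = med1.merge(med2, on=["taxon_i", "taxon_j"], suffixes=("_1", "_2"))
        assert np.abs(merged["rho_median_1"] - merged["rho_median_2"]).max() < 0.25


class TestSummarizeAssociations:
    def _posterior(self, pair_values: np.ndarray) -> GPPosterior:
        n = len(pair_values)
        draws = np.zeros((n, 2, 2))
        draws[:, 0, 0] = draws[:, 1, 1] = 1.0
        draws[:, 0, 1] = draws[:, 1, 0] = pair_values
        return GPPosterior(draws=draws, taxon_ids=["a", "b"])

    def test_constant_draws(self):
        edges = summarize_associations(self._posterior(np.full(100, 0.7)))
        e = edges.iloc[0]
        assert e.rho_median == 0.7
        assert (e.ci_low, e.ci_high) == (0.7, 0.7)
        assert e.significant and e.strong and e.sign == 1

    def test_symmetric_draws_not_significant(self):
        vals = np.concatenate([np.linspace(-0.9, 0.9, 101)])
        e = summarize_associations(self._posterior(vals)).iloc[0]
        assert not e.significant

    def test_percentiles_match_normal_quantiles(self):
        rng = np.random.default_rng(0)
        vals = np.clip(rng.normal(0.6, 0.05, size=10_001), -1, 1)
        e = summarize_associations(self._posterior(vals)).iloc[0]
        assert e.rho_median == pytest.approx(0.6, abs=0.01)
        assert e.ci_low == pytest.approx(0.6 - 1.96 * 0.05, abs=0.01)
        assert e.ci_high == pytest.approx(0.6 + 1.96 * 0.05, abs=0.01)
        assert e.significant and e.strong

    def test_strong_threshold_is_strict(self):
        e = summarize_associations(self._posterior(np.full(10, 0.5))).iloc[0]
        assert not e.strong  # "in excess of" 0.5 means strictly above

    def test_needs_two_draws(self):
        with pytest.raises(ValueError, match="2 pooled draws"):
            summarize_associations(self._posterior(np.array([0.1])))


class TestCompareNetworks:
    def _edges(self, entries):
        rows = [{"taxon_i": i, "taxon_j": j, "rho_median": r,
                 "ci_low": r - 0.1, "ci_high": r + 0.1,
                 "significant": True, "strong": abs(r) > 0.5,
                 "sign": int(np.sign(r))} for i, j, r in entries]
        return pd.DataFrame(rows)

    def test_identical_lists_fully_shared(self):
        e = self._edges([("x", "y", 0.8), ("x", "z", -0.7)])
        rep = compare_networks(e, e)
        assert rep["n_shared"] == 2 and rep["n_unique_a"] == rep["n_unique_b"] == 0

    def test_disjoint_lists_share_nothing(self):
        a = self._edges([("x", "y", 0.8)])
        b = self._edges([("p", "q", 0.9)])
        assert compare_networks(a, b)["n_shared"] == 0

    def test_set_arithmetic_and_signs(self):
        a = self._edges([("x", "y", 0.8), ("x", "z", -0.7)])
        b = self._edges([("x", "y", 0.9)])
        rep = compare_networks(a, b)
        assert rep["n_shared"] == 1 and rep["shared_positive"] == 1
        assert rep["n_unique_a"] == 1 and rep["unique_a"] == [("x", "z")]
        assert rep["sign_flips"] == []


class TestLogRatioTrajectory:
    def _instances_from_counts(self, counts: np.ndarray, n_instances=64):
        table = CountTable(counts, [f"t{i}" for i in range(counts.shape[0])],
                           [f"s{j}" for j in range(counts.shape[1])])
        return dirichlet_instances(table, days=np.arange(counts.shape[1], dtype=float),
                                   n_instances=n_instances, seed=0)

    def test_constant_composition_is_flat(self):
        counts = np.tile(np.array([[4_000], [3_000], [3_000]]), (1, 6))
        traj = log_ratio_trajectory(self._instances_from_counts(counts), "t0")
        assert traj["median"].max() - traj["median"].min() < 0.05

    def test_rising_share_gives_increasing_clr(self):
        counts = np.vstack([np.array([100, 200, 400, 800, 1_600, 3_200]),
                            np.full(6, 5_000), np.full(6, 5_000)])
        traj = log_ratio_trajectory(self._instances_from_counts(counts), "t0")
        assert (np.diff(traj["median"]) > 0).all()

    def test_unknown_taxon_rejected(self):
        counts = np.full((2, 4), 100)
        with pytest.raises(KeyError, match="tZ"):
            log_ratio_trajectory(self._instances_from_counts(counts), "tZ")

    def test_trend_classification(self):
        traj = pd.DataFrame({"day": [-4, -2, 2, 4], "median": [0.0, 0.1, 1.0, 1.2]})
        assert classify_treatment_trend(traj) == "rising"
        traj["median"] = [1.0, 1.1, 0.2, 0.1]
        assert classify_treatment_trend(traj) == "falling"
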