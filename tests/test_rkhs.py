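"""Gibbs sampler correctness, chain arithmetic and posterior summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kernova as kv
from kernova.rkhs import DegenerateResponseError

from conftest import make_genotype_matrix


@pytest.fixture(scope="module")
def geno60():
    cfg = kv.SimulationConfig(n_individuals=60, n_markers=80, seed=21)
    return kv.qc_filter(kv.simulate_genotypes(cfg))


@pytest.fixture(scope="module")
def G60(geno60):
    return kv.vanraden_G(geno60)


class TestChainConfig:
    @pytest.mark.parametrize(
        "iters,burn,thin,expect",
        [
            (50_000, 20_000, 10, 3_000),
            (6_000, 1_000, 5, 1_000),
            (130, 30, 7, 14),
            (101, 100, 1, 1),
        ],
    )
    def test_retained_draw_arithmetic(self, iters, burn, thin, expect):
        cfg = kv.ChainConfig(seed=0, iterations=iters, burn_in=burn, thin=thin)
        assert cfg.n_retained == expect

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        iters=st.integers(2, 10_000),
        burn_frac=st.floats(0.0, 0.99),
        thin=st.integers(1, 50),
    )
    def test_retained_count_equals_recording_schedule(self, iters, burn_frac,
                                                      thin):
        burn = int(iters * burn_frac)
        cfg = kv.ChainConfig(seed=0, iterations=iters, burn_in=burn, thin=thin)
        recorded = sum(
            1 for it in range(1, iters + 1)
            if it > burn and (it - burn) % thin == 0
        )
        assert cfg.n_retained == recorded

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            kv.ChainConfig(seed=0, iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            kv.ChainConfig(seed=0, thin=0)

    def test_sampler_returns_configured_draw_count(self, G60):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(60)
        chain = kv.ChainConfig(seed=1, iterations=130, burn_in=30, thin=7)
        fit = kv.fit_gibbs(G60, y, chain=chain)
        assert fit.n_retained == 14
        assert fit.samples_var_k.shape == (14, 1)


class TestRidgeSolution:
    def test_zero_response_gives_zero(self, G60):
        np.testing.assert_allclose(kv.ridge_solution(G60, np.zeros(60), 1.0), 0.0)

    def test_identity_kernel_halves_response(self):
        y = np.arange(4.0)
        K = kv.Kernel(np.eye(4), "I")
        np.testing.assert_allclose(kv.ridge_solution(K, y, 1.0), y / 2)

    def test_small_lambda_interpolates_full_rank_kernel(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((6, 6))
        K = kv.Kernel(A @ A.T + np.eye(6), "K")
        y = rng.standard_normal(6)
        np.testing.assert_allclose(kv.ridge_solution(K, y, 1e-10), y, atol=1e-6)

    def test_invalid_lambda(self, G60):
        with pytest.raises(ValueError):
            kv.ridge_solution(G60, np.zeros(60), 0.0)


class TestGibbsSampler:
    def test_oracle_equivalence_fixed_variances(self, G60):
        """With variances clamped, posterior mean g equals the ridge fit."""
        rng = np.random.default_rng(2)
        y = rng.standard_normal(60)
        lam = 2.0
        ridge = kv.ridge_solution(G60, y, lam)
        fit = kv.fit_gibbs(
            G60, y, fix_var_k=[1.0], fix_var_e=lam, fit_intercept=False,
            store_g=True,
            chain=kv.ChainConfig(seed=3, iterations=2100, burn_in=100, thin=1),
        )
        se = fit.samples_g.std(axis=0, ddof=1) / np.sqrt(fit.n_retained)
        z = np.abs(fit.g_mean - ridge) / se
        assert np.quantile(z, 0.99) < 3.5
        assert np.abs(fit.g_mean - ridge).max() < 0.1

    def test_unit_weights_identical_to_unweighted(self, G60):
        rng = np.random.default_rng(6)
        y = rng.standard_normal(60)
        chain = kv.ChainConfig(seed=9, iterations=300, burn_in=100, thin=2)
        a = kv.fit_gibbs(G60, kv.ResponseVector(y), chain=chain)
        b = kv.fit_gibbs(G60, kv.ResponseVector(y, weights=np.ones(60)), chain=chain)
        np.testing.assert_array_equal(a.samples_var_k, b.samples_var_k)
        np.testing.assert_array_equal(a.g_mean, b.g_mean)

    def test_prior_propriety_all_masked(self):
        """With no observed data the variance draws follow the prior."""
        y = kv.ResponseVector(np.full(80, np.nan))
        prior = kv.PriorSpec(df=5.0, scale=2.0)
        fit = kv.fit_gibbs(
            kv.Kernel(np.eye(80), "I"), y, prior=prior, fit_intercept=False,
            chain=kv.ChainConfig(seed=4, iterations=6000, burn_in=500, thin=1),
        )
        draws = fit.samples_var_k[:, 0]
        expect = 5.0 * 2.0 / 3.0  # nu*S/(nu-2)
        # batch-means standard error to absorb autocorrelation
        batches = draws[: 50 * (draws.size // 50)].reshape(-1, 50).mean(axis=1)
        se = batches.std(ddof=1) / np.sqrt(batches.size)
        assert abs(draws.mean() - expect) < 3 * se

    def test_weight_draws_sum_to_one(self, geno60):
        rng = np.random.default_rng(7)
        y = rng.standard_normal(60)
        G = kv.vanraden_G(geno60)
        D = kv.dominance_D(geno60)
        fit = kv.fit_gibbs(
            [G, D, kv.hadamard(G, D)], y,
            chain=kv.ChainConfig(seed=5, iterations=400, burn_in=100, thin=3),
        )
        w = fit.samples_var_k / fit.samples_var_k.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(w.sum(axis=1), 1.0)
        assert (fit.samples_var_k > 0).all() and (fit.samples_var_e > 0).all()

    def test_degenerate_response_rejected(self, G60):
        with pytest.raises(DegenerateResponseError):
            kv.fit_gibbs(G60, np.ones(60))

    def test_dimension_and_psd_validation(self, G60):
        with pytest.raises(ValueError, match="dimension"):
            kv.fit_gibbs(G60, np.zeros(10))
        bad = kv.Kernel(np.diag([1.0] * 59 + [-1.0]), "bad")
        with pytest.raises(ValueError, match="PSD"):
            kv.fit_gibbs(bad, np.random.default_rng(0).standard_normal(60))

    def test_single_observed_response_rejected(self):
        vals = np.full(5, np.nan)
        vals[0] = 1.0
        with pytest.raises(ValueError, match="observed"):
            kv.ResponseVector(vals)


class TestPredict:
    def test_duplicate_genotype_gets_training_twin_value(self, geno60):
        """A masked duplicate of a training individual shares its kernel row,
        so its sampled genetic value matches the twin's exactly."""
        d = geno60.dosages.copy()
        d[-1] = d[0]
        g = make_genotype_matrix(d)
        K = kv.gaussian_kernel(kv.additive_coding(g), theta=0.05)
        rng = np.random.default_rng(8)
        y = rng.standard_normal(60)
        y[-1] = np.nan
        fit = kv.fit_gibbs(
            K, kv.ResponseVector(y),
            chain=kv.ChainConfig(seed=6, iterations=600, burn_in=100, thin=2),
        )
        pred = kv.predict(fit, np.array([59]))
        assert pred[0] == pytest.approx(fit.g_mean[0], abs=1e-10)

    def test_zero_genetic_variance_predicts_zero(self, G60):
        rng = np.random.default_rng(9)
        y = rng.standard_normal(60)
        y[:10] = np.nan
        fit = kv.fit_gibbs(
            G60, kv.ResponseVector(y), fix_var_k=[1e-12], fix_var_e=1.0,
            chain=kv.ChainConfig(seed=7, iterations=500, burn_in=100, thin=2),
        )
        assert np.abs(kv.predict(fit, np.arange(10))).max() < 1e-4

    def test_masked_rows_do_not_shift_variance_estimates(self, geno60):
        """Posterior variance ratios agree between a fit with masked test rows
        and a fit on the training subset alone, within Monte-Carlo error."""
        rng = np.random.default_rng(10)
        G = kv.vanraden_G(geno60)
        vals, vecs = np.linalg.eigh(G.matrix)
        g_true = vecs @ (np.sqrt(np.clip(vals, 0, None)) * rng.standard_normal(60))
        y = g_true + rng.standard_normal(60) * 0.7
        chain = kv.ChainConfig(seed=11, iterations=4000, burn_in=1000, thin=3)
        y_masked = y.copy()
        y_masked[40:] = np.nan
        full = kv.fit_gibbs(G, kv.ResponseVector(y_masked), chain=chain)
        sub = kv.Kernel(G.matrix[:40][:, :40], "G")
        train = kv.fit_gibbs(sub, y[:40], chain=chain)
        h2_full = full.H2
        h2_train = train.H2
        assert abs(h2_full - h2_train) < 0.1

    def test_out_of_range_index_rejected(self, G60):
        y = np.random.default_rng(1).standard_normal(60)
        fit = kv.fit_gibbs(G60, y, chain=kv.ChainConfig(
            seed=2, iterations=200, burn_in=100, thin=1))
        with pytest.raises(ValueError):
            kv.predict(fit, np.array([60]))


class TestVariancePartition:
    def test_single_kernel_relative_weight_is_one(self, G60):
        y = np.random.default_rng(3).standard_normal(60)
        fit = kv.fit_gibbs(G60, y, chain=kv.ChainConfig(
            seed=4, iterations=400, burn_in=100, thin=1))
        tab = kv.variance_partition(fit).set_index("ratio")
        assert tab.loc["V_G/V_K", "mean"] == pytest.approx(1.0)
        assert tab.loc["H2", "mean"] == pytest.approx(
            tab.loc["V_G/V_P", "mean"], abs=1e-12
        )

    def test_relative_weights_sum_to_one(self, geno60):
        y = np.random.default_rng(5).standard_normal(60)
        G, D = kv.vanraden_G(geno60), kv.dominance_D(geno60)
        fit = kv.fit_gibbs([G, D], y, chain=kv.ChainConfig(
            seed=6, iterations=400, burn_in=100, thin=1))
        tab = kv.variance_partition(fit).set_index("ratio")
        total = tab.loc["V_G/V_K", "mean"] + tab.loc["V_D/V_K", "mean"]
        assert total == pytest.approx(1.0, abs=1e-9)


class TestFitResultOutputs:
    def test_save_writes_draws_summary_and_genetic_values(self, G60, tmp_path):
        y = np.random.default_rng(13).standard_normal(60)
        fit = kv.fit_gibbs(G60, y, chain=kv.ChainConfig(
            seed=14, iterations=600, burn_in=100, thin=2))
        fit.save(tmp_path / "fit")
        import json
        summary = json.loads((tmp_path / "fit" / "summary.json").read_text())
        assert summary["kernel_names"] == ["G"]
        assert summary["chain"]["seed"] == 14
        assert 0 < summary["effective_sample_size"]["var_G"] <= fit.n_retained
        draws = (tmp_path / "fit" / "draws.tsv").read_text().splitlines()
        assert len(draws) == fit.n_retained + 1
        gv = (tmp_path / "fit" / "genetic_values.tsv").read_text().splitlines()
        assert gv[0].split("\t") == ["id", "g_mean", "g_sd"]
        assert len(gv) == 61

    def test_ess_near_n_for_independent_draws(self, G60):
        y = np.random.default_rng(15).standard_normal(60)
        fit = kv.fit_gibbs(G60, y, chain=kv.ChainConfig(
            seed=16, iterations=900, burn_in=100, thin=2))
        fit.samples_var_e = np.random.default_rng(17).standard_normal(400) ** 2
        ess = fit.effective_sample_size()["var_e"]
        assert ess > 200  # iid draws: ESS ~ n


class TestDensityReport:
    def _fit(self, G60, n_draws=300):
        y = np.random.default_rng(7).standard_normal(60)
        return kv.fit_gibbs(G60, y, chain=kv.ChainConfig(
            seed=8, iterations=2 * n_draws + 100, burn_in=100, thin=2))

    def test_unimodal_posterior_flagged_as_single_mode(self, G60, tmp_path):
        fit = self._fit(G60)
        out = tmp_path / "dens.tsv"
        report = kv.posterior_density_report(fit, out)
        assert report["H2"]["n_modes"] >= 1
        assert out.exists()

    def test_degenerate_draws_flagged(self, G60):
        fit = self._fit(G60)
        fit.samples_var_k[:] = 1.0
        fit.samples_var_e[:] = 1.0
        report = kv.posterior_density_report(fit)
        assert all(v["degenerate"] for v in report.values())

    def test_tight_normal_draws_single_mode(self, G60):
        fit = self._fit(G60)
        rng = np.random.default_rng(12)
        fit.samples_var_k[:, 0] = rng.normal(0.5, 0.01, fit.n_retained)
        fit.samples_var_e[:] = 0.5
        report = kv.posterior_density_report(fit)
        assert report["H2"]["n_modes"] == 1

    def test_too_few_draws_rejected(self, G60):
        y = np.random.default_rng(9).standard_normal(60)
        fit = kv.fit_gibbs(G60, y, chain=kv.ChainConfig(
            seed=10, iterations=150, burn_in=100, thin=1))
        with pytest.raises(ValueError, match="100"):
            kv.posterior_density_report(fit)
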