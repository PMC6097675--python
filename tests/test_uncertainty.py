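"""Delta-approximation intervals, Metropolis-Hastings sampling, and chain
diagnostics, checked on analytically tractable targets."""

import numpy as np
import pytest

from krillassess.errors import ConfigurationError, InvalidStateError
from krillassess.estimation import FitResult, PhaseAssignment
from krillassess.objective import NLLBreakdown
from krillassess.uncertainty import (
    asymptotic_intervals,
    geweke_and_acf,
    heidelberger_welch,
    mcmc_sample,
    spectrum0_ar,
)


def _gaussian_fit(mean, cov):
    """A FitResult for the NLL of a multivariate Gaussian with known
    mean/covariance (quadratic objective: the asymptotics are exact)."""
    mean = np.asarray(mean, dtype=float)
    prec = np.linalg.inv(np.asarray(cov, dtype=float))

    def nll(z):
        d = np.asarray(z) - mean
        return 0.5 * float(d @ prec @ d)

    return FitResult(
        config_name="gaussian_toy",
        params=None,
        u_opt=mean.copy(),
        active_idx=np.arange(mean.size),
        active_names=[f"param_{i}" for i in range(mean.size)],
        breakdown=NLLBreakdown(
            survey_index=np.zeros(0), survey_comp=np.zeros(0), fishery_comp=0.0, catch=0.0
        ),
        nll=0.0,
        gradient=np.zeros(mean.size),
        max_gradient=0.0,
        hessian=prec,
        hessian_ok=True,
        converged=True,
        assignment=PhaseAssignment(phases={}),
        adapter=None,
        objective_fn=nll,
    )


COV_2D = np.array([[2.0, 0.6], [0.6, 0.5]])
MEAN_2D = np.array([1.0, -2.0])


class TestAsymptoticIntervals:
    def test_gaussian_sds_are_exact(self):
        fit = _gaussian_fit(MEAN_2D, COV_2D)
        table = asymptotic_intervals(fit)
        np.testing.assert_allclose(table["sd"], np.sqrt(np.diag(COV_2D)), rtol=1e-12)
        np.testing.assert_allclose(table["estimate"], MEAN_2D, atol=1e-12)

    def test_linear_derived_quantity_matches_closed_form(self):
        fit = _gaussian_fit(MEAN_2D, COV_2D)
        w = np.array([0.7, -1.3])
        table = asymptotic_intervals(fit, derived={"combo": lambda z: float(w @ z)})
        row = table[table["name"] == "combo"].iloc[0]
        assert row.sd == pytest.approx(np.sqrt(w @ COV_2D @ w), rel=1e-6)
        assert row.estimate == pytest.approx(float(w @ MEAN_2D), abs=1e-9)

    def test_unavailable_without_hessian(self):
        fit = _gaussian_fit(MEAN_2D, COV_2D)
        fit.hessian_ok = False
        with pytest.raises(InvalidStateError):
            asymptotic_intervals(fit)

    def test_derived_sd_matches_parametric_bootstrap(self):
        # nonlinear derived quantity: delta method vs sampling from the
        # Gaussian approximation
        fit = _gaussian_fit(MEAN_2D, COV_2D)
        fn = lambda z: float(np.exp(0.3 * z[0]) + z[1] ** 2)
        table = asymptotic_intervals(fit, derived={"nl": fn})
        sd_delta = table[table["name"] == "nl"].iloc[0].sd
        rng = np.random.default_rng(42)
        draws = rng.multivariate_normal(MEAN_2D, COV_2D, size=4000)
        vals = np.exp(0.3 * draws[:, 0]) + draws[:, 1] ** 2
        assert sd_delta == pytest.approx(np.std(vals), rel=0.08)


class TestMCMC:
    def test_recovers_gaussian_target(self):
        fit = _gaussian_fit(MEAN_2D, COV_2D)
        res = mcmc_sample(fit, n_total=50_000, thin=5, burn_in=5_000, rng=7)
        assert 0.1 < res.acceptance_rate < 0.6
        n = res.n_saved
        for j in range(2):
            chain = res.chains[:, j]
            _, _, ess = geweke_and_acf(chain)
            mc_se = np.sqrt(COV_2D[j, j] / max(ess, 10))
            assert np.mean(chain) == pytest.approx(MEAN_2D[j], abs=3 * mc_se)
            assert np.std(chain) == pytest.approx(np.sqrt(COV_2D[j, j]), rel=0.1)

    def test_delta_and_mcmc_sds_agree_on_quadratic(self):
        # on a quadratic objective the two uncertainty routes coincide:
        # discrepancies seen in nonlinear models are not sampler artifacts
        fit = _gaussian_fit(MEAN_2D, COV_2D)
        asym = asymptotic_intervals(fit)["sd"].to_numpy()
        res = mcmc_sample(fit, n_total=50_000, thin=5, burn_in=5_000, rng=3)
        mc = res.chains.std(axis=0)
        np.testing.assert_allclose(mc, asym, rtol=0.05)

    def test_thinning_arithmetic(self):
        fit = _gaussian_fit(MEAN_2D, COV_2D)
        # saved = floor((n_total - burn_in)/thin), the bookkeeping used for
        # the production-scale runs (10M samples / thin 2000 -> 5000 saved)
        res = mcmc_sample(fit, n_total=10_000, thin=2, burn_in=0, rng=1, adapt_steps=0)
        assert res.n_saved == 5_000
        assert (10_000_000 - 0) // 2_000 == 5_000

    def test_seeded_chains_bit_identical(self):
        fit = _gaussian_fit(MEAN_2D, COV_2D)
        r1 = mcmc_sample(fit, n_total=2_000, thin=2, burn_in=200, rng=5)
        r2 = mcmc_sample(fit, n_total=2_000, thin=2, burn_in=200, rng=5)
        np.testing.assert_array_equal(r1.chains, r2.chains)

    def test_bad_bookkeeping_rejected(self):
        fit = _gaussian_fit(MEAN_2D, COV_2D)
        with pytest.raises(ConfigurationError):
            mcmc_sample(fit, n_total=100, burn_in=100, thin=1)

    def test_assessment_fit_chain_behaves(self, fit_cfgI):
        """Sampling a real fitted configuration: tuned acceptance rate in
        (0.1, 0.6) and the default monitor includes the derived terminal
        quantities."""
        res = mcmc_sample(fit_cfgI, n_total=3_000, thin=3, burn_in=300, rng=11)
        assert 0.1 < res.acceptance_rate < 0.6
        assert res.n_saved == (3_000 - 300) // 3
        assert len(res.labels) <= 27
        assert "SSB_2015" in res.labels and "R_2015" in res.labels
        assert np.all(np.isfinite(res.chains))


class TestHeidelbergerWelch:
    def test_iid_chains_pass(self):
        passes = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(5.0, 1.0, 5_000)
            hw = heidelberger_welch(x)
            passes += hw.stationarity_pass
        assert passes >= 18

    def test_trended_chain_fails_stationarity(self):
        rng = np.random.default_rng(1)
        n = 5_000
        x = rng.normal(0.0, 1.0, n) + np.linspace(0.0, 3.0, n)  # drift of 3 SD
        hw = heidelberger_welch(x)
        assert not hw.stationarity_pass

    def test_zero_mean_chain_halfwidth_guard(self):
        x = np.zeros(500)
        hw = heidelberger_welch(x)
        assert hw.halfwidth_pass and hw.warning

    def test_short_chain_rejected(self):
        with pytest.raises(ConfigurationError):
            heidelberger_welch(np.zeros(50))


class TestGewekeAndESS:
    def test_iid_z_scores_mostly_standard(self):
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(100 + seed).normal(0.0, 1.0, 4_000)
            z, _, _ = geweke_and_acf(x)
            hits += abs(z) < 1.96
        assert hits >= 18

    def test_ar1_effective_size_closed_form(self):
        rho, n = 0.9, 40_000
        rng = np.random.default_rng(3)
        x = np.empty(n)
        x[0] = rng.normal()
        innov = rng.normal(0, np.sqrt(1 - rho**2), n)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + innov[t]
        _, _, ess = geweke_and_acf(x, max_lag=200)
        expected = n * (1 - rho) / (1 + rho)
        assert ess == pytest.approx(expected, rel=0.25)

    def test_duplicated_chain_is_autocorrelated(self):
        # each value appearing twice gives lag-1 autocorrelation 1/2 (the
        # standard n-denominator estimator sits just below it)
        x = np.repeat(np.random.default_rng(0).normal(size=2_000), 2)
        _, acf, _ = geweke_and_acf(x)
        assert acf[0] == pytest.approx(0.5, abs=0.03)
        assert acf[0] > 0.4

    def test_ess_against_arviz(self):
        arviz = pytest.importorskip("arviz")
        x = np.random.default_rng(9).normal(size=3_000)
        _, _, ess = geweke_and_acf(x)
        ref = float(arviz.ess(x))
        assert ess == pytest.approx(ref, rel=0.2)


class TestSpectrum0:
    def test_white_noise_matches_variance(self):
        x = np.random.default_rng(2).normal(0, 2.0, 20_000)
        assert spectrum0_ar(x) == pytest.approx(4.0, rel=0.1)

    def test_ar1_spectral_density(self):
        # s(0) = sigma_e^2 / (1-rho)^2 for an AR(1)
        rho = 0.7
        rng = np.random.default_rng(8)
        n = 50_000
        x = np.empty(n)
        x[0] = 0.0
        innov = rng.normal(0, 1.0, n)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + innov[t]
        assert spectrum0_ar(x) == pytest.approx(1.0 / (1 - rho) ** 2, rel=0.15)
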