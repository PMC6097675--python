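"""Likelihood components and penalty stack."""

import numpy as np
import pytest
from dataclasses import replace

from scipy.stats import lognorm

from krillassess.core import ModelStructure, ParameterSet, project
from krillassess.errors import DataError, InvalidParameterError
from krillassess.objective import (
    PenaltyStack,
    f_penalty,
    lognormal_nll,
    multinomial_nll,
    recruitment_penalty,
    total_objective,
)
from krillassess.simtest import generate_pseudodata


class TestLognormalNLL:
    def test_perfect_fit_attains_constant_minimum(self):
        obs = np.array([120.0, 300.0, 55.0])
        cv = 0.3
        at_min = lognormal_nll(obs, obs, cv)
        sigma2 = np.log1p(cv**2)
        assert at_min == pytest.approx(3 * 0.5 * np.log(sigma2))
        for mult in (0.7, 1.3):
            assert lognormal_nll(obs, obs * mult, cv) > at_min

    def test_single_point_against_density_oracle(self):
        obs, pred, cv = 100.0, 150.0, 0.3
        sigma = np.sqrt(np.log1p(cv**2))
        # -log density of a lognormal with log-mean log(pred), up to the
        # pred-independent constant log(obs * sqrt(2 pi))
        oracle = -lognorm.logpdf(obs, s=sigma, scale=pred)
        const = np.log(obs * np.sqrt(2 * np.pi))
        assert lognormal_nll(obs, pred, cv) == pytest.approx(oracle - const, rel=1e-12)

    def test_smaller_cv_penalizes_mismatch_more(self):
        resid = lambda cv: lognormal_nll(100.0, 130.0, cv) - lognormal_nll(
            100.0, 100.0, cv
        )
        assert resid(0.15) > resid(0.3)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(DataError):
            lognormal_nll([1.0, -2.0], [1.0, 1.0], 0.3, series="idx")
        with pytest.raises(DataError):
            lognormal_nll([1.0], [1.0], 0.0)


class TestMultinomialNLL:
    def test_uniform_entropy(self):
        p = np.full(4, 0.25)
        assert multinomial_nll(p, p, 1.0) == pytest.approx(np.log(4))

    def test_hand_computed_example(self):
        assert multinomial_nll([1.0, 0.0], [0.8, 0.2], 10.0) == pytest.approx(
            -10 * np.log(0.8)
        )

    def test_linear_in_effective_n(self):
        obs = np.array([0.5, 0.3, 0.2])
        pred = np.array([0.4, 0.4, 0.2])
        one = multinomial_nll(obs, pred, 1.0)
        assert multinomial_nll(obs, pred, 7.0) == pytest.approx(7 * one)

    def test_floor_prevents_log_zero(self):
        val = multinomial_nll([0.5, 0.5], [1.0, 0.0], 5.0)
        assert np.isfinite(val)

    def test_bad_inputs_rejected(self):
        with pytest.raises(DataError):
            multinomial_nll([0.5, 0.5], [0.5, 0.5], 0.0)
        with pytest.raises(DataError):
            multinomial_nll([0.9, 0.3], [0.5, 0.5], 5.0)


class TestPenalties:
    def test_equilibrium_on_curve_zeroes_bh_penalties(self):
        s = ModelStructure(bias_correct=False)
        p = replace(ParameterSet.defaults(s), mu_f=-30.0)
        traj = project(p, None, s)
        pen = recruitment_penalty(p, traj, PenaltyStack(), s)
        n = s.n_rec_devs
        sigma_R = np.exp(p.ln_sigma_R)
        assert pen["L1"] == pytest.approx(n * np.log(sigma_R))  # residual term zero
        assert pen["L2"] == pytest.approx(0.0, abs=1e-12)
        assert pen["L3"] == pytest.approx(0.0, abs=1e-12)
        assert pen["L4"] == 0.0

    def test_single_deviation_residual(self):
        # sigma_R = 0.7: a deviation of 0.7 contributes 0.7^2/(2*0.49) = 0.5
        s = ModelStructure(bias_correct=False)
        p = replace(ParameterSet.defaults(s), mu_f=-30.0)
        eps = np.zeros(s.n_rec_devs)
        eps[10] = 0.7
        p2 = replace(p, eps_R=eps)
        traj = project(p2, None, s)
        stack = PenaltyStack(lambda2=0, lambda3=0, lambda4=0)
        pen = recruitment_penalty(p2, traj, stack, s)
        sigma_R = np.exp(p.ln_sigma_R)
        assert pen["L1"] - s.n_rec_devs * np.log(sigma_R) == pytest.approx(0.5, rel=1e-4)

    def test_quadratic_scaling_of_deviations(self):
        s = ModelStructure(bias_correct=False)
        rng = np.random.default_rng(0)
        eps = rng.normal(0, 0.3, s.n_rec_devs)
        stack = PenaltyStack(lambda2=0, lambda3=0, lambda4=0)
        base = replace(ParameterSet.defaults(s), mu_f=-30.0)
        vals = []
        for mult in (1.0, 2.0):
            p = replace(base, eps_R=eps * mult)
            traj = project(p, None, s)
            pen = recruitment_penalty(p, traj, stack, s)
            vals.append(pen["L1"] - s.n_rec_devs * np.log(np.exp(p.ln_sigma_R)))
        assert vals[1] == pytest.approx(4 * vals[0], rel=1e-9)

    def test_f_penalty_examples(self):
        stack = PenaltyStack(lambda5=0.5, lambda6=10.0, f_cap=1.5)
        pen = f_penalty(np.array([1.0, -1.0]), np.array([0.1, 0.1]), stack)
        assert pen["L5"] == pytest.approx(1.0)
        assert pen["L6"] == 0.0
        pen = f_penalty(np.array([0.0]), np.array([2.0]), stack)
        assert pen["L6"] == pytest.approx(10.0 * 0.25)
        off = PenaltyStack(lambda5=0.0, lambda6=0.0)
        pen = f_penalty(np.array([3.0]), np.array([9.0]), off)
        assert pen["L5"] == 0.0 and pen["L6"] == 0.0
        disabled = PenaltyStack(enable_f=False)
        pen = f_penalty(np.array([3.0]), np.array([9.0]), disabled)
        assert pen["L5"] == 0.0 and pen["L6"] == 0.0

    def test_negative_weight_rejected(self):
        with pytest.raises(InvalidParameterError):
            PenaltyStack(lambda5=-1.0)


class TestTotalObjective:
    def test_breakdown_totals_are_consistent(self, defaults, bundle):
        bd = total_objective(defaults, bundle)
        parts = (
            bd.survey_index.sum()
            + bd.survey_comp.sum()
            + bd.fishery_comp
            + bd.catch
            + sum(bd.penalties.values())
        )
        assert bd.total == pytest.approx(parts, abs=1e-10)

    def test_survey_order_invariance(self, defaults, bundle):
        import copy

        total1 = total_objective(defaults, bundle).total
        shuffled = copy.deepcopy(bundle)
        perm = [3, 0, 5, 1, 4, 2]
        shuffled.surveys = [shuffled.surveys[i] for i in perm]
        # survey-indexed parameters must follow their surveys
        p2 = replace(
            defaults,
            alpha_s=defaults.alpha_s[perm],
            beta_s=defaults.beta_s[perm],
            ln_q_s=defaults.ln_q_s[perm],
        )
        assert total_objective(p2, shuffled).total == pytest.approx(total1, rel=1e-12)

    def test_error_free_pseudodata_attains_component_minima(self, fit_cfgI, bundle):
        pseudo = generate_pseudodata(fit_cfgI, bundle)
        bd = total_objective(fit_cfgI.params, pseudo)
        # lognormal components at their constant minima
        for i, sv in enumerate(pseudo.surveys):
            sigma2 = np.log1p(sv.index_cvs**2)
            assert bd.survey_index[i] == pytest.approx(
                float(np.sum(0.5 * np.log(sigma2))), abs=1e-8
            )
        # multinomial components at the entropy of the observations
        for i, sv in enumerate(pseudo.surveys):
            if len(sv.comp_years):
                entropy = -np.sum(
                    sv.effective_n[:, None] * sv.comp_props * np.log(sv.comp_props + 1e-300)
                )
                assert bd.survey_comp[i] == pytest.approx(entropy, abs=1e-6)

    def test_finite_for_in_bounds_parameters(self, defaults, bundle):
        rng = np.random.default_rng(2)
        lo, hi = defaults.bounds()
        x = defaults.to_vector()
        for _ in range(5):
            jitter = rng.normal(0, 0.05, x.size)
            xj = np.clip(x + jitter, np.where(np.isfinite(lo), lo + 1e-6, -np.inf),
                         np.where(np.isfinite(hi), hi - 1e-6, np.inf))
            bd = total_objective(defaults.with_vector(xj), bundle)
            assert np.isfinite(bd.total)
            # L1 carries the ln(sigma_R) normalization (negative for
            # sigma_R < 1); the pure penalty terms are nonnegative
            assert all(
                bd.penalties[k] >= 0 for k in ("L2", "L3", "L4", "L5", "L6")
            )
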