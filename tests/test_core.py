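"""Population-dynamics building blocks: selectivity, growth, recruitment,
projection, and parameter bookkeeping."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from krillassess.config import PRESETS, preset
from krillassess.core import (
    DEFAULT_STRUCTURE,
    ModelStructure,
    ParameterSet,
    age_length_matrix,
    beverton_holt,
    count_parameters,
    logistic_selectivity,
    mean_length_at_age,
    project,
    unfished_spawning_biomass,
)
from krillassess.errors import (
    ConfigurationError,
    InvalidParameterError,
    InvalidStateError,
)
from krillassess.synth import template_bundle, default_scenario


# ---------------------------------------------------------------------------
# logistic selectivity
# ---------------------------------------------------------------------------


class TestLogisticSelectivity:
    def test_midpoint_is_half(self):
        for beta in (0.06, 1.0, 2.8):
            assert logistic_selectivity(1.3, 1.3, beta) == pytest.approx(0.5)

    def test_monotone_and_in_unit_interval(self):
        ages = np.arange(1, 8)
        s = logistic_selectivity(ages, 1.3, 2.8)
        assert np.all(np.diff(s) > 0)
        assert np.all((s > 0) & (s < 1))
        # reference values from direct evaluation of the closed form
        expected = 1.0 / (1.0 + np.exp(-(ages - 1.3) / 2.8))
        np.testing.assert_allclose(s, expected, rtol=1e-12)

    def test_knife_edge_limit(self):
        assert logistic_selectivity(4.0, 3.3, 1e-12) == pytest.approx(1.0)
        assert logistic_selectivity(3.0, 3.3, 1e-12) == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_spread_rejected(self):
        with pytest.raises(InvalidParameterError):
            logistic_selectivity(2.0, 1.3, 0.0)

    @given(
        alpha=st.floats(-2, 8),
        beta=st.floats(0.05, 10),
        a1=st.floats(0.5, 10),
        a2=st.floats(0.5, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_property(self, alpha, beta, a1, a2):
        lo, hi = min(a1, a2), max(a1, a2)
        if hi - lo > 1e-9:
            s_lo = logistic_selectivity(lo, alpha, beta)
            s_hi = logistic_selectivity(hi, alpha, beta)
            assert s_hi >= s_lo
            # strictly increasing away from floating-point saturation
            if 1e-12 < s_lo and s_hi < 1.0 - 1e-12:
                assert s_hi > s_lo


# ---------------------------------------------------------------------------
# age-length conversion
# ---------------------------------------------------------------------------


class TestAgeLengthMatrix:
    edges = DEFAULT_STRUCTURE.length_bin_edges
    ages = DEFAULT_STRUCTURE.ages

    def test_default_growth_values(self):
        # ln(Linf)=4.11, ln(k)=-0.799, ln(sigma_v)=1.459 imply Linf ~ 60.9 mm,
        # k ~ 0.45 / yr, sigma_v ~ 4.30 mm
        assert np.exp(4.11) == pytest.approx(60.9, abs=0.1)
        assert np.exp(-0.799) == pytest.approx(0.450, abs=0.001)
        assert np.exp(1.459) == pytest.approx(4.30, abs=0.005)
        P = age_length_matrix(4.11, -0.799, 1.459, self.edges, self.ages)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert P.shape == (7, 30)

    def test_degenerate_spread_is_unit_mass(self):
        P = age_length_matrix(4.11, -0.799, -20.0, self.edges, self.ages)
        L = mean_length_at_age(self.ages, 4.11, -0.799)
        for i, mu in enumerate(L):
            b = np.searchsorted(self.edges, mu, side="right") - 1
            assert P[i, b] == pytest.approx(1.0)

    def test_matches_quadrature_oracle(self):
        P = age_length_matrix(4.11, -0.799, 1.459, self.edges, self.ages)
        mu = mean_length_at_age(self.ages, 4.11, -0.799)
        sigma = np.exp(1.459)
        for i in (0, 3, 6):
            for b in (0, 5, 15, 29):
                lo = -np.inf if b == 0 else self.edges[b]
                hi = np.inf if b == len(self.edges) - 2 else self.edges[b + 1]
                oracle, _ = quad(
                    lambda x: norm.pdf(x, mu[i], sigma),
                    max(lo, mu[i] - 12 * sigma),
                    min(hi, mu[i] + 12 * sigma),
                )
                assert P[i, b] == pytest.approx(oracle, abs=1e-6)

    def test_empty_bins_rejected(self):
        with pytest.raises(ConfigurationError):
            age_length_matrix(4.11, -0.799, 1.459, np.array([10.0]), self.ages)


# ---------------------------------------------------------------------------
# Beverton-Holt recruitment
# ---------------------------------------------------------------------------


class TestBevertonHolt:
    @pytest.mark.parametrize("h", [0.3, 0.5, 0.85, 0.99])
    def test_steepness_identities(self, h):
        r0, b0 = 2e6, 5e5
        assert beverton_holt(b0, h, r0, b0) == pytest.approx(r0, rel=1e-12)
        assert beverton_holt(0.2 * b0, h, r0, b0) == pytest.approx(h * r0, rel=1e-12)
        assert beverton_holt(0.0, h, r0, b0) == 0.0

    def test_monotone_in_ssb(self):
        ssb = np.linspace(0, 1e6, 200)
        r = beverton_holt(ssb, 0.85, 2e6, 5e5)
        assert np.all(np.diff(r) >= 0)

    def test_against_ab_reparameterization_oracle(self):
        # R = a S / (b + S) with a = 4 h R0 / (5h - 1), b = B0 (1 - h)/(5h - 1)
        h, r0, b0 = 0.85, 2e6, 5e5
        a = 4 * h * r0 / (5 * h - 1)
        b = b0 * (1 - h) / (5 * h - 1)
        s = 0.5 * b0
        assert beverton_holt(s, h, r0, b0) == pytest.approx(a * s / (b + s), rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidStateError):
            beverton_holt(1.0, 0.85, 1.0, 0.0)
        with pytest.raises(InvalidParameterError):
            beverton_holt(1.0, 0.1, 1.0, 1.0)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


def _unfished_params(structure):
    p = ParameterSet.defaults(structure)
    return replace(p, mu_f=-30.0)  # F ~ 1e-13: effectively unfished


class TestProject:
    def test_unfished_equilibrium_holds_ssb_at_b0(self):
        s = ModelStructure(bias_correct=False)
        p = _unfished_params(s)
        traj = project(p, template_bundle(default_scenario(s)))
        assert traj.B0 == pytest.approx(unfished_spawning_biomass(p), rel=1e-12)
        np.testing.assert_allclose(traj.SSB_y, traj.B0, rtol=1e-9)
        np.testing.assert_allclose(traj.R_y, np.exp(p.ln_R0), rtol=1e-12)

    def test_single_cohort_survival_is_exponential(self, structure):
        p = ParameterSet.defaults(structure)
        traj = project(p, None, structure)
        M = np.exp(p.ln_M)
        sel = 1.0 / (1.0 + np.exp(-(structure.ages - p.alpha_f) / p.beta_f))
        # one-step survival for a tracked cohort
        for t, a in [(0, 0), (5, 2), (20, 4)]:
            z = M + sel[a] * traj.F_y[t]
            assert traj.N[t + 1, a + 1] == pytest.approx(
                traj.N[t, a] * np.exp(-z), rel=1e-12
            )

    def test_three_age_baranov_against_brute_force(self):
        # spreadsheet-style oracle on a hand-set 3-age stock
        N = np.array([1000.0, 400.0, 150.0])
        M, F = 0.8, 0.1
        sel = np.array([0.2, 0.7, 1.0])
        Z = M + sel * F
        catch_oracle = []
        survivors_oracle = []
        for a in range(3):
            deaths = N[a] * (1 - np.exp(-Z[a]))
            catch_oracle.append(deaths * (sel[a] * F) / Z[a])
            survivors_oracle.append(N[a] - deaths)
        catch = sel * F / Z * (1 - np.exp(-Z)) * N
        np.testing.assert_allclose(catch, catch_oracle, atol=1e-10)
        np.testing.assert_allclose(N * np.exp(-Z), survivors_oracle, atol=1e-10)

    def test_numbers_conservation(self, truth_and_trajectory):
        # N_{y+1,a+1} + natural deaths + Baranov catch = N_{y,a}
        _, traj = truth_and_trajectory
        N, Z, C = traj.N, traj.Z, traj.catch_at_age
        deaths = N * (1 - np.exp(-Z))
        m_frac = deaths - C  # natural deaths by subtraction of Baranov catch
        survivors = N * np.exp(-Z)
        np.testing.assert_allclose(survivors + m_frac + C, N, rtol=1e-9)
        # and the stored recurrence matches the survivors
        np.testing.assert_allclose(N[1:, 1:-1], survivors[:-1, :-2], rtol=1e-9)

    def test_predictions_nonnegative_and_comps_normalized(self, truth_and_trajectory):
        _, traj = truth_and_trajectory
        assert np.all(traj.N >= 0) and np.all(traj.SSB_y >= 0)
        for comp in traj.predicted_comp:
            if len(comp):
                np.testing.assert_allclose(comp.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            traj.predicted_fishery_comp.sum(axis=1), 1.0, atol=1e-9
        )

    def test_deterministic_bit_identical(self, scenario, truth_and_trajectory):
        truth, traj = truth_and_trajectory
        again = project(truth, template_bundle(scenario))
        assert np.array_equal(traj.N, again.N)
        assert np.array_equal(traj.predicted_catch, again.predicted_catch)


# ---------------------------------------------------------------------------
# parameter bookkeeping
# ---------------------------------------------------------------------------


EXPECTED_N_PARS = {
    "cfgI": 48, "cfgII": 49, "cfgIII": 49, "cfgIV": 49, "cfgV": 49,
    "cfgVI": 51, "cfgVII": 54, "cfgVIII": 63, "cfgIX": 90, "cfgX": 91,
    "cfgXI": 91, "cfgXII": 92, "cfgXIII": 93, "cfgXIV": 94, "cfgXV": 96,
    "cfgXVI": 96, "cfgXVII": 104, "cfgXVIII": 104, "cfgXIX": 105,
    "cfgXX": 106, "cfgXXI": 107, "cfgXXII": 107,
}


class TestParameterBookkeeping:
    def test_total_scalar_count_is_118(self, defaults):
        assert defaults.n_total == 118
        assert len(defaults.to_vector()) == 118
        assert len(defaults.slot_names()) == 118

    @pytest.mark.parametrize("name", PRESETS)
    def test_preset_parameter_counts(self, name):
        assert count_parameters(preset(name)) == EXPECTED_N_PARS[name]

    def test_all_groups_cover_the_census(self, defaults):
        groups = defaults.group_indices()
        idx = np.concatenate(list(groups.values()))
        assert len(idx) == 118
        assert len(np.unique(idx)) == 118  # each scalar in exactly one group

    def test_unknown_group_rejected(self):
        with pytest.raises(ConfigurationError):
            preset("cfgI").__class__(name="bad", estimated_groups=("nope",))

    def test_bounds_follow_parameter_table(self, defaults):
        lo, hi = defaults.bounds()
        names = defaults.slot_names()
        by_name = dict(zip(names, zip(lo, hi)))
        assert by_name["eps_R[1971]"] == (-15, 15)
        assert by_name["eps_f[1976]"] == (-12, 8)
        assert by_name["ln_M"] == (-5, 5)
        assert by_name["h"] == (0.21, 1.0)
        assert by_name["ln_Linf"] == (2.5, 5.0)
        assert by_name["ln_k"] == (-10, 5)
        assert by_name["ln_sigma_v"] == (0.2, 5.0)
        assert by_name["ln_R0"] == (-np.inf, np.inf)

    def test_vector_round_trip(self, defaults):
        x = defaults.to_vector()
        x2 = defaults.with_vector(x).to_vector()
        np.testing.assert_array_equal(x, x2)
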